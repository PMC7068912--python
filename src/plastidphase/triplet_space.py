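"""Triplet frequency dictionaries and the 63-dimensional frequency space.

Each fragment is tiled into non-overlapping, gap-free triplets (the W(3,3)
dictionary, always read from the first position of the fragment) and
converted into a 64-component frequency vector f_w = n_w / M, where M is the
number of tiled triplets.  Since the frequencies sum to 1, only 63 of them
are independent; the component dropped is the triplet whose frequency has
the least standard deviation over the whole fragment ensemble of a genome —
the least informative coordinate for telling fragments apart.  Distances in
this space are plain Euclidean.

Triplets containing a non-ACGT symbol are skipped and M reduced
accordingly, preserving the unit-sum constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

#: the 64 triplets in fixed lexicographic order AAA..TTT
TRIPLETS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))
TRIPLET_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRIPLETS)}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class InsufficientDataError(ValueError):
    """Too few dictionaries to compute an ensemble statistic."""


@dataclass
class TripletDictionary:
    """Frequency dictionary of one fragment: f_w over 64 triplets, plus M."""

    vector: np.ndarray  # shape (64,), frequencies in lexicographic order
    M: int  # number of tiled triplets

    @property
    def freqs(self) -> dict[str, float]:
        """Non-zero frequencies as a plain mapping."""
        return {
            TRIPLETS[i]: float(self.vector[i])
            for i in np.nonzero(self.vector)[0]
        }

    def __getitem__(self, triplet: str) -> float:
        return float(self.vector[TRIPLET_INDEX[triplet]])


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def triplet_frequencies(sequence: str, q: int = 3, t: int = 3) -> TripletDictionary:
    """W(q,t) frequency dictionary of one sequence; default W(3,3).

    Windows start at offsets 0, t, 2t, ... within the sequence; incomplete
    final windows and windows containing non-ACGT symbols are dropped.
    Only q=3 maps into the shared 64-triplet coordinate order; other q are
    rejected (the analysis uses triplets throughout).
    """
    if q != 3:
        raise ValueError("only triplet (q=3) dictionaries are supported")
    if len(sequence) < q:
        raise ValueError(f"sequence of length {len(sequence)} shorter than q={q}")
    codes = _encode(sequence)
    starts = np.arange(0, len(sequence) - q + 1, t)
    windows = codes[starts[:, None] + np.arange(q)]
    valid = (windows >= 0).all(axis=1)
    tri = windows[valid].astype(np.int64) @ np.array([16, 4, 1])
    counts = np.bincount(tri, minlength=64).astype(float)
    m = int(valid.sum())
    vector = counts / m if m > 0 else counts
    return TripletDictionary(vector=vector, M=m)


def count_matrix(sequences: Sequence[str], t: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized triplet counting for equal-length sequences.

    Returns (counts, M): an (n, 64) count matrix and the per-sequence number
    of valid (fully ACGT) triplets.
    """
    n = len(sequences)
    if n == 0:
        return np.zeros((0, 64)), np.zeros(0, dtype=int)
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have equal length")
    codes = _BASE_CODE[
        np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    ].reshape(n, length)
    k = length // 3
    c0 = codes[:, 0 : 3 * k : 3]
    c1 = codes[:, 1 : 3 * k : 3]
    c2 = codes[:, 2 : 3 * k : 3]
    valid = (c0 >= 0) & (c1 >= 0) & (c2 >= 0)
    tri = c0.astype(np.int64) * 16 + c1 * 4 + c2
    rows = np.repeat(np.arange(n), k).reshape(n, k)
    counts = np.zeros((n, 64))
    np.add.at(counts, (rows[valid], tri[valid]), 1.0)
    m = valid.sum(axis=1)
    return counts, m


def frequency_vectors(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(n, 64) frequency matrix and per-sequence M for equal-length sequences."""
    counts, m = count_matrix(sequences)
    freqs = np.divide(counts, m[:, None], out=np.zeros_like(counts), where=m[:, None] > 0)
    return freqs, m


def _stack(dicts: Sequence[TripletDictionary] | np.ndarray) -> np.ndarray:
    if isinstance(dicts, np.ndarray):
        return dicts
    return np.vstack([d.vector for d in dicts])


def ensemble_sd(dicts: Sequence[TripletDictionary] | np.ndarray) -> np.ndarray:
    """Population SD of each triplet frequency over the ensemble.

    Each column is put into a canonical (sorted) order before summation, so
    the result is bit-identical under any permutation of the input list —
    otherwise float rounding could break tie-breaking between near-equal
    columns.
    """
    vectors = np.sort(_stack(dicts), axis=0)
    return vectors.std(axis=0)  # population SD (ddof=0)


def select_excluded_triplet(dicts: Sequence[TripletDictionary] | np.ndarray) -> str:
    """Triplet with the least population standard deviation over the ensemble.

    Ties are broken toward the lexicographically smallest triplet.
    """
    vectors = _stack(dicts)
    if vectors.shape[0] < 2:
        raise InsufficientDataError(
            "need at least 2 dictionaries to rank standard deviations"
        )
    return TRIPLETS[int(np.argmin(ensemble_sd(vectors)))]


@dataclass
class FrequencyMatrix:
    """n fragments as points in the 63-dimensional triplet-frequency space."""

    points: np.ndarray  # (n, 63)
    excluded_triplet: str
    fragment_index: list[int] = field(default_factory=list)

    #: the full lexicographic order the columns were derived from
    triplet_order: tuple[str, ...] = TRIPLETS

    @property
    def columns(self) -> list[str]:
        return [t for t in self.triplet_order if t != self.excluded_triplet]

    def restore_full(self) -> np.ndarray:
        """Reinsert the excluded column (1 - row sum), back to (n, 64)."""
        n = self.points.shape[0]
        full = np.empty((n, 64))
        j = TRIPLET_INDEX[self.excluded_triplet]
        full[:, :j] = self.points[:, :j]
        full[:, j] = 1.0 - self.points.sum(axis=1)
        full[:, j + 1 :] = self.points[:, j:]
        return full


def build_matrix(
    dicts: Sequence[TripletDictionary] | np.ndarray,
    excluded: str,
    fragment_index: Iterable[int] | None = None,
) -> FrequencyMatrix:
    """Drop the excluded triplet's column to get the (n, 63) point matrix."""
    if excluded not in TRIPLET_INDEX:
        raise ValueError(f"{excluded!r} is not one of the 64 triplets")
    vectors = _stack(dicts)
    j = TRIPLET_INDEX[excluded]
    points = np.delete(vectors, j, axis=1)
    index = list(fragment_index) if fragment_index is not None else list(range(len(points)))
    return FrequencyMatrix(points=points, excluded_triplet=excluded, fragment_index=index)


def euclidean_distance(
    w1: TripletDictionary | np.ndarray, w2: TripletDictionary | np.ndarray
) -> float:
    """Euclidean distance between two frequency dictionaries (all 64 axes)."""
    v1 = w1.vector if isinstance(w1, TripletDictionary) else np.asarray(w1)
    v2 = w2.vector if isinstance(w2, TripletDictionary) else np.asarray(w2)
    return float(np.linalg.norm(v1 - v2))


class TripletFrequencyVectorizer(BaseEstimator, TransformerMixin):
    """Map fragment sequences to points in 63-dimensional frequency space.

    sklearn-style transformer: ``fit`` learns which triplet to exclude (the
    least-SD one over the fitted ensemble, unless ``excluded_triplet`` is
    given); ``transform`` tiles each sequence into W(3,3) frequencies and
    drops that column.

    Parameters
    ----------
    excluded_triplet : str or None
        Fix the dropped triplet instead of learning it.

    Attributes
    ----------
    excluded_triplet_ : str
        The dropped triplet after fitting.
    sd_ : ndarray of shape (64,)
        Population SD of each triplet frequency over the fitted ensemble.
    """

    def __init__(self, excluded_triplet: str | None = None):
        self.excluded_triplet = excluded_triplet

    def fit(self, X: Sequence[str], y=None) -> "TripletFrequencyVectorizer":
        freqs, _ = frequency_vectors(list(X))
        self.sd_ = ensemble_sd(freqs)
        if self.excluded_triplet is not None:
            if self.excluded_triplet not in TRIPLET_INDEX:
                raise ValueError(f"{self.excluded_triplet!r} is not a triplet")
            self.excluded_triplet_ = self.excluded_triplet
        else:
            if len(X) < 2:
                raise InsufficientDataError(
                    "need at least 2 sequences to learn the excluded triplet"
                )
            self.excluded_triplet_ = TRIPLETS[int(np.argmin(self.sd_))]
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        freqs, _ = frequency_vectors(list(X))
        return np.delete(freqs, TRIPLET_INDEX[self.excluded_triplet_], axis=1)
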