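"""Geometry of the phase clusters in principal-component space.

The fragment cloud is embedded with PCA (top three components, deterministic
sign convention), the visually identified clusters are verified with
K-means, and the diagnostics of the eight-cluster pattern are computed:

* per-phase centroids in PC coordinates;
* signed circuit areas of the forward triangle (F0, F1, F2) and the backward
  triangle (B0, B1, B2) in a chosen PC plane — opposite signs mean the two
  reading-frame circuits run counter-directed, the mirror symmetry seen in
  chloroplasts; equal signs mean the rotational arrangement typical of
  bacteria;
* U/D orientation of the merged F2-B2 cluster along PC3;
* phase-abundance statistics (counts, their SD over the six coding phases,
  and the strand biases |Fj| - |Bj|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .phase_labeling import CODING_PHASES, PhaseLabel
from .triplet_space import FrequencyMatrix


class DegenerateEmbeddingError(ValueError):
    def __init__(self, rank: int):
        self.rank = rank
        super().__init__(f"matrix rank {rank} < 3; cannot embed in 3 components")


class GeometryUndefinedError(ValueError):
    def __init__(self, phase: PhaseLabel):
        self.phase = phase
        super().__init__(f"coding phase {phase.value} is empty; geometry undefined")


@dataclass
class Embedding:
    coords: np.ndarray  # (n, 3) PC coordinates
    explained_variance: np.ndarray  # 3 fractions
    sign_convention: tuple[int, ...]  # per-component flips applied (+1/-1)


def _as_array(matrix: FrequencyMatrix | np.ndarray) -> np.ndarray:
    return matrix.points if isinstance(matrix, FrequencyMatrix) else np.asarray(matrix)


def pca_embed(matrix: FrequencyMatrix | np.ndarray) -> Embedding:
    """Top-3 PCA of the column-centered point matrix.

    PCA component signs are arbitrary; each component is flipped so that its
    largest-magnitude loading is positive, making embeddings reproducible
    across runs and libraries.
    """
    x = _as_array(matrix)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 points to embed")
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    if rank < 3:
        raise DegenerateEmbeddingError(rank)
    pca = PCA(n_components=3, svd_solver="full")
    coords = pca.fit_transform(x)
    flips = []
    for k in range(3):
        loading = pca.components_[k]
        sign = 1 if loading[int(np.argmax(np.abs(loading)))] >= 0 else -1
        flips.append(sign)
        coords[:, k] *= sign
    return Embedding(
        coords=coords,
        explained_variance=pca.explained_variance_ratio_.copy(),
        sign_convention=tuple(flips),
    )


def kmeans_verify(
    matrix: FrequencyMatrix | np.ndarray,
    K: int = 4,
    seed: int = 0,
    restarts: int = 10,
) -> np.ndarray:
    """Best-inertia K-means assignment over ``restarts`` initializations.

    Clusters are renumbered by ascending centroid norm so that runs with
    different seeds are comparable.
    """
    x = _as_array(matrix)
    if K < 2:
        raise ValueError("K must be at least 2")
    if x.shape[0] < K:
        raise ValueError(f"{x.shape[0]} points cannot form {K} clusters")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(np.linalg.norm(km.cluster_centers_, axis=1), kind="stable")
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    return relabel[raw]


def signed_area(p0, p1, p2) -> float:
    """Signed area of triangle p0->p1->p2; positive = counterclockwise."""
    p0, p1, p2 = (np.asarray(p) for p in (p0, p1, p2))
    a = p1 - p0
    b = p2 - p0
    return float((a[0] * b[1] - a[1] * b[0]) / 2.0)


@dataclass
class PhaseGeometry:
    centroids: dict[PhaseLabel, np.ndarray]
    area_F: float
    area_B: float
    symmetry: str  # "mirror" | "rotational"
    orientation: str  # "U" | "D"
    abundances: dict[PhaseLabel, int] = field(default_factory=dict)
    coding_sd: float = 0.0
    bias: tuple[int, int, int] = (0, 0, 0)


def phase_abundance_stats(
    labels: Sequence[PhaseLabel],
) -> tuple[dict[PhaseLabel, int], float, tuple[int, int, int]]:
    """Counts per label, population SD of the six coding-phase counts, and
    the strand biases (|F0|-|B0|, |F1|-|B1|, |F2|-|B2|)."""
    counts = {p: 0 for p in PhaseLabel}
    for lab in labels:
        counts[PhaseLabel(lab)] += 1
    coding = np.array([counts[p] for p in CODING_PHASES], dtype=float)
    coding_sd = float(coding.std())  # population SD
    bias = (
        counts[PhaseLabel.F0] - counts[PhaseLabel.B0],
        counts[PhaseLabel.F1] - counts[PhaseLabel.B1],
        counts[PhaseLabel.F2] - counts[PhaseLabel.B2],
    )
    return counts, coding_sd, bias


def classify_geometry(
    embedding: Embedding,
    labels: Sequence[PhaseLabel],
    plane: tuple[int, int] = (0, 1),
    orientation_flip: bool = False,
) -> PhaseGeometry:
    """Full geometric diagnostic of the phase clusters.

    ``plane`` gives the 0-based PC pair in which circuit areas are taken
    (default PC1-PC2).  ``symmetry`` is "mirror" when the forward and
    backward circuits are counter-directed (signed areas of opposite sign),
    else "rotational".  ``orientation`` is U when the pooled F2+B2 centroid
    lies above the pooled centroid of the remaining coding phases along PC3
    in the sign-canonicalized embedding (D otherwise); ``orientation_flip``
    applies a global flip to match an external plotting convention.
    """
    labels = [PhaseLabel(l) for l in labels]
    coords = embedding.coords
    if len(labels) != coords.shape[0]:
        raise ValueError("labels must parallel embedding rows")
    label_arr = np.array([l.value for l in labels])

    centroids: dict[PhaseLabel, np.ndarray] = {}
    for phase in PhaseLabel:
        mask = label_arr == phase.value
        if mask.any():
            centroids[phase] = coords[mask].mean(axis=0)
    for phase in CODING_PHASES:
        if phase not in centroids:
            raise GeometryUndefinedError(phase)

    i, j = plane
    pf = [centroids[p][[i, j]] for p in (PhaseLabel.F0, PhaseLabel.F1, PhaseLabel.F2)]
    pb = [centroids[p][[i, j]] for p in (PhaseLabel.B0, PhaseLabel.B1, PhaseLabel.B2)]
    area_f = signed_area(*pf)
    area_b = signed_area(*pb)
    symmetry = "mirror" if area_f * area_b < 0 else "rotational"

    mask2 = (label_arr == "F2") | (label_arr == "B2")
    mask_rest = np.isin(label_arr, ["F0", "F1", "B0", "B1"])
    up = coords[mask2, 2].mean() > coords[mask_rest, 2].mean()
    if orientation_flip:
        up = not up
    orientation = "U" if up else "D"

    abundances, coding_sd, bias = phase_abundance_stats(labels)
    return PhaseGeometry(
        centroids=centroids,
        area_F=area_f,
        area_B=area_b,
        symmetry=symmetry,
        orientation=orientation,
        abundances=abundances,
        coding_sd=coding_sd,
        bias=bias,
    )
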