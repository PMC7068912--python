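"""Annotated synthetic genomes with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* forward-strand genes are i.i.d. codon strings drawn from a biased
  64-codon usage distribution — the source of the three separable
  reading-frame signals;
* backward-strand genes are codon strings (by default from the same usage)
  reverse-complemented onto the forward strand, so the backward phases are
  the Chargaff images of forward readings;
* intergenic stretches are i.i.d. nucleotides at a neutral GC level — the
  junk cloud;
* a dense block of short GC-rich RNA genes (tRNA/rRNA-annotated) separated
  by short spacers — the tail cluster.

Stop codons are not modelled: the analysis depends only on triplet
composition, not translatability.

The module also carries the analytic oracle: the exact expected triplet
distribution of non-overlapping tiling at each frame shift over an infinite
i.i.d. codon stream, and the mapping from fragment phase labels to frame
shifts.  With L odd and divisible by 3, L = 3m with m odd, so
(L-1)/2 = 3(m-1)/2 + 1 == 1 (mod 3): the tiling (which starts at the
fragment's first position) sits at codon-frame shift (j-1) mod 3 for a
fragment labeled phase j.  In particular the phase-1 fragments, not the
phase-0 ones, read genes in frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import AnnotatedRegion, Category, GenomeRecord, Strand
from .triplet_space import TRIPLETS, TRIPLET_INDEX

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: RC_PERM[i] = lexicographic index of the reverse complement of triplet i
RC_PERM = np.array(
    [TRIPLET_INDEX[t.translate(_COMPLEMENT)[::-1]] for t in TRIPLETS]
)

# ground-truth stratum codes
STRATUM_INTERGENIC = 0
STRATUM_FORWARD_GENE = 1
STRATUM_BACKWARD_GENE = 2
STRATUM_RNA_GENE = 3
STRATUM_SPACER = 4

STRATUM_NAMES = {
    STRATUM_INTERGENIC: "intergenic",
    STRATUM_FORWARD_GENE: "forward_gene",
    STRATUM_BACKWARD_GENE: "backward_gene",
    STRATUM_RNA_GENE: "rna_gene",
    STRATUM_SPACER: "spacer",
}


class SpecError(ValueError):
    """The synthetic genome specification cannot be realized."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# codon usage construction


def position_composition_usage(
    pi0: np.ndarray, pi1: np.ndarray, pi2: np.ndarray
) -> np.ndarray:
    """Codon usage as a product of per-position base compositions (ACGT order)."""
    pi0, pi1, pi2 = (np.asarray(p, dtype=float) for p in (pi0, pi1, pi2))
    for p in (pi0, pi1, pi2):
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
            raise SpecError("each position composition must be a 4-simplex")
    usage = np.einsum("i,j,k->ijk", pi0, pi1, pi2).reshape(64)
    return usage / usage.sum()


def complement_composition(pi: np.ndarray) -> np.ndarray:
    """Base composition of the complementary strand: A<->T, C<->G."""
    pi = np.asarray(pi, dtype=float)
    return pi[[3, 2, 1, 0]]


def default_codon_usage() -> np.ndarray:
    """Default biased usage with the strand complementarity of plastomes.

    Built as a product of position compositions with two structural
    properties observed to drive the chloroplast cluster geometry: the
    first-position composition is the complement of the second-position
    one, and the third (wobble) position composition is self-complementary.
    Under these, the backward-strand reading of a gene reproduces the
    forward readings with frames 0 and 1 swapped — the F0-B1 / F1-B0 /
    F2-B2 cluster pairing and the mirror (counter-directed circuit)
    symmetry.
    """
    pi0 = np.array([0.36, 0.22, 0.12, 0.30])
    pi1 = complement_composition(pi0)
    pi2 = np.array([0.22, 0.28, 0.28, 0.22])  # self-complementary
    return position_composition_usage(pi0, pi1, pi2)


def chargaff_symmetrize(usage: np.ndarray) -> np.ndarray:
    """Average a usage with its reverse-complement image: p(c)=p(RC(c))."""
    usage = np.asarray(usage, dtype=float)
    return (usage + usage[RC_PERM]) / 2.0


#: fixed per-mille codon weights of the bacteria-like control usage (see
#: :func:`control_codon_usage`), in lexicographic triplet order
_CONTROL_USAGE_WEIGHTS = np.array(
    [
        19,  8,  9, 20,  6,  1, 21, 13, 26,  6, 15,  0,  5,  3,  8, 18,
        51, 35, 74, 29, 17,  8,  6,  8, 58, 13, 62,  2,  1,  5, 10,  4,
        40, 22,  6, 17, 22, 41, 10,  6,  0, 10, 16,  3,  8,  3,  7,  5,
         0, 10,  5, 13, 50, 48,  7, 17,  6,  3,  1,  3, 47,  1,  8,  3,
    ],
    dtype=float,
)


def control_codon_usage() -> np.ndarray:
    """Codon usage of the bacteria-like (rotational) control.

    A fixed, strongly Chargaff-asymmetric usage without the strand
    complementarity of :func:`default_codon_usage`.  Its reading-frame
    asymmetry is large enough that both leading between-cluster principal
    components are antisymmetric under reverse complementation, so the
    backward phase triangle projects as the point reflection (a 180-degree
    rotation) of the forward one: the two circuits run in the same
    direction — the rotational arrangement seen in bacterial genomes —
    instead of mirroring each other.
    """
    return _CONTROL_USAGE_WEIGHTS / _CONTROL_USAGE_WEIGHTS.sum()


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class TailBlockSpec:
    n_rna_genes: int = 30
    rna_length_range: tuple[int, int] = (90, 150)
    rna_gc: float = 0.62
    spacer_length: int = 45


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome; defaults emulate a plastome.

    The default sizes give a genome of plastome scale (~1.2e5 nt, ~10^4
    fragments at L=603/R=11) that is about 60% protein-coding with
    intergenic gaps long enough to populate the junk cluster, plus a dense
    GC-rich RNA block for the tail cluster.
    """

    N: int = 120_000
    codon_usage: np.ndarray = field(default_factory=default_codon_usage)
    #: usage for backward-strand genes; None = same as forward
    backward_codon_usage: np.ndarray | None = None
    n_forward_genes: int = 30
    n_backward_genes: int = 30
    gene_length_range: tuple[int, int] = (900, 1500)
    intergenic_gc: float = 0.37
    tail_block: TailBlockSpec | None = field(default_factory=TailBlockSpec)
    seed: int = 0

    def __post_init__(self):
        usage = np.asarray(self.codon_usage, dtype=float)
        if usage.shape != (64,) or not np.isclose(usage.sum(), 1.0):
            raise SpecError("codon_usage must be a 64-simplex")
        if self.backward_codon_usage is not None:
            b = np.asarray(self.backward_codon_usage, dtype=float)
            if b.shape != (64,) or not np.isclose(b.sum(), 1.0):
                raise SpecError("backward_codon_usage must be a 64-simplex")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo <= 0 or hi < lo:
            raise SpecError("gene lengths must be positive multiples of 3")
        if self.tail_block is not None and self.tail_block.rna_gc < 0.55:
            raise SpecError("tail RNA genes must be GC-rich (rna_gc >= 0.55)")


def chloroplast_like_spec(seed: int = 0, **overrides) -> SyntheticGenomeSpec:
    """The default mirror-symmetric (plastome-like) specification."""
    return replace(SyntheticGenomeSpec(seed=seed), **overrides)


def bacteria_like_spec(seed: int = 0, **overrides) -> SyntheticGenomeSpec:
    """Control whose per-strand usages break the plastome complementarity.

    Both strands carry :func:`control_codon_usage` (the per-strand fields
    are set explicitly and can be overridden independently); the resulting
    phase geometry is rotational rather than mirror.
    """
    usage = control_codon_usage()
    return replace(
        SyntheticGenomeSpec(
            seed=seed, codon_usage=usage, backward_codon_usage=usage
        ),
        **overrides,
    )


# ---------------------------------------------------------------------------
# generation


@dataclass
class GroundTruth:
    """Per-position generating stratum and codon offset (mRNA sense; -1 outside genes)."""

    stratum: np.ndarray  # uint8, index p-1 for 1-based position p
    codon_offset: np.ndarray  # int8

    def stratum_name(self, position: int) -> str:
        return STRATUM_NAMES[int(self.stratum[position - 1])]


_TRIPLET_ARR = np.array(TRIPLETS)
_BASES = np.array(list("ACGT"))


def _iid_bases(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _codon_string(rng: np.random.Generator, n_codons: int, usage: np.ndarray) -> str:
    return "".join(_TRIPLET_ARR[rng.choice(64, size=n_codons, p=usage)])


def generate(spec: SyntheticGenomeSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Generate a genome, its annotation and per-position ground truth.

    Features are placed left to right in a seed-determined order; the same
    seed always yields the identical genome.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    n_genes = spec.n_forward_genes + spec.n_backward_genes

    gene_lengths = rng.integers(lo // 3, hi // 3 + 1, size=n_genes) * 3
    strands = [Strand.FORWARD] * spec.n_forward_genes + [Strand.BACKWARD] * spec.n_backward_genes
    strands = [strands[i] for i in rng.permutation(n_genes)]

    elements: list[tuple[str, int, Strand | None]] = [
        ("gene", int(length), strand) for length, strand in zip(gene_lengths, strands)
    ]
    tail_length = 0
    if spec.tail_block is not None and spec.tail_block.n_rna_genes > 0:
        tb = spec.tail_block
        rlo, rhi = tb.rna_length_range
        rna_lengths = rng.integers(rlo, rhi + 1, size=tb.n_rna_genes)
        tail_length = int(rna_lengths.sum()) + tb.spacer_length * (tb.n_rna_genes - 1)
        elements.insert(
            int(rng.integers(0, len(elements) + 1)), ("tail", tail_length, None)
        )
    else:
        rna_lengths = np.zeros(0, dtype=int)

    total_features = int(gene_lengths.sum()) + tail_length
    if total_features > spec.N:
        raise SpecError(
            f"total feature length {total_features} exceeds genome length {spec.N}"
        )
    spare = spec.N - total_features
    n_gaps = len(elements) + 1
    gap_lengths = rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))

    usage_f = np.asarray(spec.codon_usage, dtype=float)
    usage_b = (
        np.asarray(spec.backward_codon_usage, dtype=float)
        if spec.backward_codon_usage is not None
        else usage_f
    )

    parts: list[str] = []
    regions: list[AnnotatedRegion] = []
    stratum = np.zeros(spec.N, dtype=np.uint8)
    offset = np.full(spec.N, -1, dtype=np.int8)
    pos = 1  # next 1-based position to fill

    def _append(segment: str) -> int:
        nonlocal pos
        parts.append(segment)
        start = pos
        pos += len(segment)
        return start

    def _gap(length: int) -> None:
        if length > 0:
            _append(_iid_bases(rng, length, spec.intergenic_gc))

    for (kind, length, strand), gap in zip(elements, gap_lengths):
        _gap(int(gap))
        if kind == "gene":
            n_codons = length // 3
            if strand is Strand.FORWARD:
                start = _append(_codon_string(rng, n_codons, usage_f))
                end = start + length - 1
                stratum[start - 1 : end] = STRATUM_FORWARD_GENE
                offset[start - 1 : end] = np.tile([0, 1, 2], n_codons)
                regions.append(
                    AnnotatedRegion(start, end, Strand.FORWARD, Category.PROTEIN_CODING)
                )
            else:
                mrna = _codon_string(rng, n_codons, usage_b)
                start = _append(reverse_complement(mrna))
                end = start + length - 1
                stratum[start - 1 : end] = STRATUM_BACKWARD_GENE
                # mRNA coordinate of forward position p is end - p + 1
                offset[start - 1 : end] = np.tile([2, 1, 0], n_codons)
                regions.append(
                    AnnotatedRegion(start, end, Strand.BACKWARD, Category.PROTEIN_CODING)
                )
        else:  # tail block
            tb = spec.tail_block
            for k, rna_len in enumerate(rna_lengths):
                if k > 0 and tb.spacer_length > 0:
                    s = _append(_iid_bases(rng, tb.spacer_length, tb.rna_gc))
                    stratum[s - 1 : s + tb.spacer_length - 1] = STRATUM_SPACER
                start = _append(_iid_bases(rng, int(rna_len), tb.rna_gc))
                end = start + int(rna_len) - 1
                stratum[start - 1 : end] = STRATUM_RNA_GENE
                category = Category.TRNA if k % 2 == 0 else Category.RRNA
                regions.append(AnnotatedRegion(start, end, Strand.FORWARD, category))
    _gap(int(gap_lengths[-1]))

    sequence = "".join(parts)
    assert len(sequence) == spec.N
    record = GenomeRecord(
        id=f"synthetic-{spec.seed}",
        sequence=sequence,
        regions=sorted(regions),
        is_circular=False,
    )
    return record, GroundTruth(stratum=stratum, codon_offset=offset)


# ---------------------------------------------------------------------------
# analytic oracle


def expected_frame_distribution(codon_usage: np.ndarray, shift: int) -> np.ndarray:
    """Exact triplet distribution of W(3,3) tiling an infinite i.i.d. codon
    stream at frame shift ``shift`` (0 = in frame).

    Computed by enumeration over all 64^2 ordered two-codon pairs: the
    tiled triplet at shift s is positions s..s+2 of the six-letter word
    c1 + c2.
    """
    usage = np.asarray(codon_usage, dtype=float)
    shift = shift % 3
    if shift == 0:
        return usage.copy()
    dist = np.zeros(64)
    for i, c1 in enumerate(TRIPLETS):
        for j, c2 in enumerate(TRIPLETS):
            word = c1 + c2
            tri = word[shift : shift + 3]
            dist[TRIPLET_INDEX[tri]] += usage[i] * usage[j]
    return dist


def label_to_frame_shift(phase_index: int) -> int:
    """Codon-frame shift of the W(3,3) tiling of a fragment labeled phase j.

    The tiling starts at the fragment's first position, (L-1)/2 == 1 (mod 3)
    for every valid L, and the label is the center-to-gene-start distance
    mod 3, so the shift is (j - 1) mod 3.
    """
    return (phase_index - 1) % 3


def rc_transform(dist: np.ndarray) -> np.ndarray:
    """Distribution of the reverse complement of a triplet drawn from ``dist``."""
    return np.asarray(dist)[RC_PERM]


def expected_phase_distribution(
    codon_usage: np.ndarray,
    phase,
    backward_codon_usage: np.ndarray | None = None,
) -> np.ndarray:
    """Expected triplet distribution of fragments of one coding phase.

    For a forward phase Fj this is the frame-shift-(j-1 mod 3) reading of
    the forward codon stream.  For a backward phase Bj the fragment tiles
    the forward strand, i.e. it reads the reverse complement of the
    backward gene's codon stream; enumeration gives the same shift mapping
    applied to the mRNA stream followed by the reverse-complement transform
    of the resulting triplet distribution.
    """
    value = getattr(phase, "value", str(phase))
    if value not in {"F0", "F1", "F2", "B0", "B1", "B2"}:
        raise ValueError(f"{value!r} is not a coding phase")
    j = int(value[1])
    shift = label_to_frame_shift(j)
    if value[0] == "F":
        return expected_frame_distribution(codon_usage, shift)
    usage_b = backward_codon_usage if backward_codon_usage is not None else codon_usage
    return rc_transform(expected_frame_distribution(usage_b, shift))


def derive_phase_pairing(
    codon_usage: np.ndarray,
    backward_codon_usage: np.ndarray | None = None,
) -> dict[str, str]:
    """Nearest backward partner of each forward phase, from the oracle.

    Returns e.g. {"F0": "B1", "F1": "B0", "F2": "B2"} — the pairing the
    fragment clusters of a genome generated with this usage will show.
    """
    f_dists = {
        f"F{j}": expected_phase_distribution(codon_usage, f"F{j}") for j in range(3)
    }
    b_dists = {
        f"B{j}": expected_phase_distribution(
            codon_usage, f"B{j}", backward_codon_usage
        )
        for j in range(3)
    }
    pairing = {}
    for fname, fd in f_dists.items():
        pairing[fname] = min(
            b_dists, key=lambda b: float(np.linalg.norm(fd - b_dists[b]))
        )
    return pairing
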