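"""Assigning each fragment one of eight labels: F0..F2, B0..B2, JUNK, TAIL.

The label is read off the annotation, never the sequence:

* JUNK — at least half of the fragment (ceil(L/2) positions) lies outside
  every annotated coding region ("coding" understood widely: protein genes,
  tRNA, rRNA and other RNA genes all count).
* TAIL — not junk, and at least half of the fragment is covered by tRNA/rRNA
  (or other RNA) regions; these are the RNA-gene-dense stretches that form
  the GC-rich eighth cluster.
* F0/F1/F2 — the center falls in a forward-strand region; the index is the
  distance from the region start to the central nucleotide, mod 3.
* B0/B1/B2 — the center falls in a backward-strand region; the distance is
  taken from the region *end* (the backward gene's own start).

When the center sits in several overlapping regions, the region with the
largest overlap with the fragment wins (ties: forward strand, then smaller
start).  When the center is in a short annotation gap but the fragment is
still mostly coding, the phase of the largest-overlap region is used, so
every fragment gets exactly one label.
"""

from __future__ import annotations

import enum
from typing import Sequence

import numpy as np

from .fragmentation import Fragment
from .genome_io import AnnotatedRegion, RNA_CATEGORIES, Strand


class PhaseLabel(str, enum.Enum):
    F0 = "F0"
    F1 = "F1"
    F2 = "F2"
    B0 = "B0"
    B1 = "B1"
    B2 = "B2"
    JUNK = "JUNK"
    TAIL = "TAIL"


CODING_PHASES: tuple[PhaseLabel, ...] = (
    PhaseLabel.F0,
    PhaseLabel.F1,
    PhaseLabel.F2,
    PhaseLabel.B0,
    PhaseLabel.B1,
    PhaseLabel.B2,
)

_FORWARD_PHASES = (PhaseLabel.F0, PhaseLabel.F1, PhaseLabel.F2)
_BACKWARD_PHASES = (PhaseLabel.B0, PhaseLabel.B1, PhaseLabel.B2)


def region_phase(region: AnnotatedRegion, center: int) -> PhaseLabel:
    """Phase of a fragment whose central nucleotide sits in ``region``."""
    if region.strand is Strand.FORWARD:
        return _FORWARD_PHASES[(center - region.start) % 3]
    return _BACKWARD_PHASES[(region.end - center) % 3]


def _coverage(length: int, regions: Sequence[AnnotatedRegion], rna_only: bool) -> np.ndarray:
    cov = np.zeros(length + 2, dtype=np.int32)  # 1-based diff array
    for r in regions:
        if rna_only and r.category not in RNA_CATEGORIES:
            continue
        cov[r.start] += 1
        cov[min(r.end + 1, length + 1)] -= 1
    return (np.cumsum(cov[: length + 1]) > 0)[1:]  # cov_bool[p-1] for position p


def noncoding_overlap(fragment: Fragment, regions: Sequence[AnnotatedRegion]) -> int:
    """Number of fragment positions not covered by any region (any category)."""
    end = fragment.start + fragment.length - 1
    covered = 0
    for p in range(fragment.start, end + 1):
        if any(r.start <= p <= r.end for r in regions):
            covered += 1
    return fragment.length - covered


def _overlap(region: AnnotatedRegion, start: int, end: int) -> int:
    return max(0, min(region.end, end) - max(region.start, start) + 1)


def _pick_region(
    candidates: list[AnnotatedRegion], start: int, end: int
) -> AnnotatedRegion:
    """Largest fragment overlap; ties -> forward strand, then smaller start."""
    return max(
        candidates,
        key=lambda r: (_overlap(r, start, end), r.strand is Strand.FORWARD, -r.start),
    )


def label_fragment(
    fragment: Fragment,
    regions: Sequence[AnnotatedRegion],
    junk_threshold: int | None = None,
) -> PhaseLabel:
    """Label a single fragment (reference implementation; see also
    :func:`label_fragments` for the vectorized whole-genome path)."""
    L = fragment.length
    threshold = junk_threshold if junk_threshold is not None else (L + 1) // 2
    end = fragment.start + L - 1

    if noncoding_overlap(fragment, regions) >= threshold:
        return PhaseLabel.JUNK

    rna_regions = [r for r in regions if r.category in RNA_CATEGORIES]
    rna_covered = L - noncoding_overlap(fragment, rna_regions)
    if rna_covered >= threshold:
        return PhaseLabel.TAIL

    overlapping = [r for r in regions if _overlap(r, fragment.start, end) > 0]
    containing = [r for r in overlapping if r.start <= fragment.center <= r.end]
    region = _pick_region(containing or overlapping, fragment.start, end)
    return region_phase(region, fragment.center)


def label_fragments(
    fragments: Sequence[Fragment],
    regions: Sequence[AnnotatedRegion],
    genome_length: int,
) -> list[PhaseLabel]:
    """Label all fragments of one genome (coverage arrays + prefix sums)."""
    if not fragments:
        return []
    L = fragments[0].length
    threshold = (L + 1) // 2

    cov_any = _coverage(genome_length, regions, rna_only=False)
    cov_rna = _coverage(genome_length, regions, rna_only=True)
    cum_any = np.concatenate([[0], np.cumsum(cov_any)])
    cum_rna = np.concatenate([[0], np.cumsum(cov_rna)])

    starts = np.array([f.start for f in fragments])
    ends = starts + L - 1
    coding_cover = cum_any[ends] - cum_any[starts - 1]
    rna_cover = cum_rna[ends] - cum_rna[starts - 1]

    is_junk = (L - coding_cover) >= threshold
    is_tail = ~is_junk & (rna_cover >= threshold)

    sorted_regions = sorted(regions, key=lambda r: r.start)
    region_starts = np.array([r.start for r in sorted_regions])
    max_len = max((r.length for r in sorted_regions), default=0)

    labels: list[PhaseLabel] = []
    for i, frag in enumerate(fragments):
        if is_junk[i]:
            labels.append(PhaseLabel.JUNK)
            continue
        if is_tail[i]:
            labels.append(PhaseLabel.TAIL)
            continue
        end = ends[i]
        # candidate regions: start <= end and end >= frag.start; region
        # starts are sorted, and any overlapping region starts within
        # max_len of the window
        lo = np.searchsorted(region_starts, frag.start - max_len, side="left")
        hi = np.searchsorted(region_starts, end, side="right")
        overlapping = [
            r for r in sorted_regions[lo:hi] if _overlap(r, frag.start, end) > 0
        ]
        containing = [r for r in overlapping if r.start <= frag.center <= r.end]
        region = _pick_region(containing or overlapping, frag.start, end)
        labels.append(region_phase(region, frag.center))
    return labels


def estimate_border_junk(L: int, R: int, n_regions: int) -> float:
    """Expected number of border fragments labeled JUNK: L/(2R) * n * 2.

    Each coding/non-coding border contributes about L/(2R) junk-labeled
    windows; the factor 2 counts both forward- and backward-oriented
    coding regions (each region has two borders).
    """
    if L <= 0 or R <= 0 or n_regions < 0:
        raise ValueError("arguments must be positive")
    return L / (2 * R) * n_regions * 2


def phase_counts(labels: Sequence[PhaseLabel]) -> dict[PhaseLabel, int]:
    counts = {p: 0 for p in PhaseLabel}
    for lab in labels:
        counts[lab] += 1
    return counts
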