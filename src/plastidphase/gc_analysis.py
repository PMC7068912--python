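"""GC-content statistics per fragment, per ensemble, and across genomes.

Per genome: whole-genome GC, per-fragment GC laid out along the sequence
(the positional profile), and ensemble means for the coding fragments (all
six phases pooled), the junk fragments and the tail fragments.  Across a
corpus: Pearson (optionally Spearman) correlations of those four ensemble
means between genomes — in chloroplasts the genome/coding/junk means track
each other closely while the tail ensemble stays pinned above 0.5
regardless of genome-wide GC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fragmentation import Fragment
from .genome_io import GenomeRecord
from .phase_labeling import PhaseLabel

ENSEMBLE_KEYS = ("genome", "coding", "junk", "tail")

_CODING_VALUES = {"F0", "F1", "F2", "B0", "B1", "B2"}


class UndefinedContentError(ValueError):
    """GC-content of an empty or all-ambiguous sequence."""


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); non-ACGT symbols are ignored."""
    if not sequence:
        raise UndefinedContentError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedContentError("sequence contains no unambiguous bases")
    return gc / (gc + at)


@dataclass
class GCProfile:
    genome_id: str
    per_fragment: pd.DataFrame  # columns: index, center, gc, phase
    genome_gc: float
    ensemble_means: dict[str, float]  # keys: genome, coding, junk, tail (NaN if absent)


def build_gc_profile(
    genome: GenomeRecord,
    fragments: Sequence[Fragment],
    labels: Sequence[PhaseLabel],
) -> GCProfile:
    """Per-fragment GC with phase, plus the four ensemble means.

    Genomes without tail fragments (or without junk) report NaN for that
    ensemble mean, mirroring real plastomes in which the tail phase is
    absent altogether.
    """
    if len(fragments) != len(labels):
        raise ValueError("labels must parallel fragments")
    phase = [PhaseLabel(l).value for l in labels]
    gc = np.array([gc_content(f.sequence) for f in fragments])
    table = pd.DataFrame(
        {
            "index": [f.index for f in fragments],
            "center": [f.center for f in fragments],
            "gc": gc,
            "phase": phase,
        }
    )
    phase_arr = np.array(phase)
    coding_mask = np.isin(phase_arr, list(_CODING_VALUES))
    junk_mask = phase_arr == "JUNK"
    tail_mask = phase_arr == "TAIL"
    means = {
        "genome": gc_content(genome.sequence),
        "coding": float(gc[coding_mask].mean()) if coding_mask.any() else math.nan,
        "junk": float(gc[junk_mask].mean()) if junk_mask.any() else math.nan,
        "tail": float(gc[tail_mask].mean()) if tail_mask.any() else math.nan,
    }
    return GCProfile(
        genome_id=genome.id,
        per_fragment=table,
        genome_gc=means["genome"],
        ensemble_means=means,
    )


def cross_genome_correlations(
    summaries: Sequence[GCProfile], method: str = "pearson"
) -> pd.DataFrame:
    """Correlations of the four ensemble GC means across genomes.

    Genomes lacking an ensemble (NaN mean) are excluded pairwise.  Returns a
    symmetric 4x4 DataFrame with unit diagonal over (genome, coding, junk,
    tail).
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 genomes for cross-genome correlations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method {method!r}")
    data = pd.DataFrame(
        [[s.ensemble_means[k] for k in ENSEMBLE_KEYS] for s in summaries],
        columns=list(ENSEMBLE_KEYS),
        index=[s.genome_id for s in summaries],
    )
    corr = data.corr(method=method)  # pairwise NaN exclusion
    np.fill_diagonal(corr.values, 1.0)
    return corr
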