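"""Shared fixtures: synthetic study genomes run once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plastidphase import (
    GenomeRecord,
    bacteria_like_spec,
    chloroplast_like_spec,
    generate,
)
from plastidphase.gc_analysis import build_gc_profile
from plastidphase.pipeline import GenomeResult, RunConfig, run_genome
from plastidphase.synthetic_data import (
    GroundTruth,
    SyntheticGenomeSpec,
    position_composition_usage,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@dataclass
class PipelineRun:
    spec: SyntheticGenomeSpec
    record: GenomeRecord
    truth: GroundTruth
    result: GenomeResult


def _run(spec: SyntheticGenomeSpec) -> PipelineRun:
    record, truth = generate(spec)
    result = run_genome(RunConfig(), record)
    return PipelineRun(spec=spec, record=record, truth=truth, result=result)


@pytest.fixture(scope="session")
def mirror_run() -> PipelineRun:
    """Default plastome-like genome, full pipeline."""
    return _run(chloroplast_like_spec(seed=1))


@pytest.fixture(scope="session")
def control_run() -> PipelineRun:
    """Bacteria-like control genome, full pipeline."""
    return _run(bacteria_like_spec(seed=1))


def _self_complementary_pi(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@pytest.fixture(scope="session")
def gc_corpus_profiles():
    """Small corpus with varying genome GC but near-constant tail GC.

    Genome-wide GC is moved through both the intergenic composition and the
    wobble-position composition of the codon usage; the RNA-block GC stays
    in a narrow band around 0.62, mimicking the pinned tail ensemble of
    real plastomes.
    """
    profiles = []
    wobble_gc = [0.40, 0.48, 0.56, 0.64, 0.72]
    intergenic = [0.30, 0.34, 0.38, 0.42, 0.46]
    rna_gc = [0.62, 0.60, 0.63, 0.61, 0.64]
    from dataclasses import replace

    from plastidphase import TailBlockSpec, fragmentize, label_fragments

    for k in range(5):
        pi0 = np.array([0.36, 0.22, 0.12, 0.30])
        usage = position_composition_usage(
            pi0, pi0[[3, 2, 1, 0]], _self_complementary_pi(wobble_gc[k])
        )
        spec = chloroplast_like_spec(
            seed=10 + k,
            N=60_000,
            n_forward_genes=15,
            n_backward_genes=15,
            codon_usage=usage,
            intergenic_gc=intergenic[k],
            tail_block=replace(TailBlockSpec(), rna_gc=rna_gc[k]),
        )
        record, _truth = generate(spec)
        frags = fragmentize(record)
        labels = label_fragments(frags, record.regions, record.length)
        profiles.append(build_gc_profile(record, frags, labels))
    return profiles
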