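"""End-to-end orchestration: genome -> fragments -> 63-dim points -> labels
-> embedding -> geometry -> GC summaries, plus corpus-level aggregation.

All stages are pure library calls; this module wires them together, writes
the tabular outputs, and keeps a machine-readable manifest per run.  A
failure in any stage is re-raised as :class:`StageError` naming the stage;
outputs are written only after every stage has finished, so no partial
output files are left behind.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_geometry, fragmentation, gc_analysis, phase_labeling, triplet_space
from .cluster_geometry import Embedding, GeometryUndefinedError, PhaseGeometry
from .gc_analysis import GCProfile
from .genome_io import GenomeRecord, write_table
from .phase_labeling import PhaseLabel

logger = logging.getLogger("plastidphase")

LABEL_ORDER = ["F0", "F1", "F2", "B0", "B1", "B2", "JUNK", "TAIL"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    fragment_length: int = fragmentation.DEFAULT_FRAGMENT_LENGTH
    step: int = fragmentation.DEFAULT_STEP
    kmeans_k: int = 4
    kmeans_restarts: int = 10
    seed: int = 0
    plane: tuple[int, int] = (0, 1)  # 0-based PC pair for circuit areas
    orientation_flip: bool = False
    correlation_method: str = "pearson"

    def __post_init__(self):
        fragmentation.validate_parameters(self.fragment_length, self.step)
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be at least 2")
        i, j = self.plane
        if i == j or not all(0 <= p <= 2 for p in (i, j)):
            raise ValueError("plane must name two distinct components among PC1..PC3")


@dataclass
class GenomeResult:
    genome_id: str
    fragments: pd.DataFrame  # genome_id, index, start, center, gc, phase
    matrix: triplet_space.FrequencyMatrix
    labels: list[PhaseLabel]
    embedding: Embedding
    clusters: np.ndarray
    geometry: PhaseGeometry | None
    geometry_error: str | None
    gc_profile: GCProfile

    @property
    def excluded_triplet(self) -> str:
        return self.matrix.excluded_triplet


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except GeometryUndefinedError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc
    logger.info("stage %-18s done in %6.2fs", name, time.perf_counter() - t0)
    return out


def run_genome(
    config: RunConfig,
    genome: GenomeRecord,
    out_dir: str | Path | None = None,
) -> GenomeResult:
    """Run the full per-genome analysis; optionally write all outputs.

    Stages: fragmentize -> triplet frequencies -> least-SD triplet exclusion
    -> 63-dim matrix -> phase labeling -> PCA -> K-means -> geometry ->
    GC profile.  An empty coding phase (e.g. a genome without annotation)
    leaves ``geometry`` as None with the reason in ``geometry_error``;
    every other output is still produced.
    """
    L, R = config.fragment_length, config.step
    fragments = _stage("fragmentize", fragmentation.fragmentize, genome, L, R)
    sequences = [f.sequence for f in fragments]
    freqs, _m = _stage("triplet_frequencies", triplet_space.frequency_vectors, sequences)
    excluded = _stage("select_excluded_triplet", triplet_space.select_excluded_triplet, freqs)
    matrix = _stage("build_matrix", triplet_space.build_matrix, freqs, excluded)
    labels = _stage(
        "label_fragments",
        phase_labeling.label_fragments,
        fragments,
        genome.regions,
        genome.length,
    )
    embedding = _stage("pca_embed", cluster_geometry.pca_embed, matrix)
    clusters = _stage(
        "kmeans_verify",
        cluster_geometry.kmeans_verify,
        matrix,
        config.kmeans_k,
        config.seed,
        config.kmeans_restarts,
    )
    geometry: PhaseGeometry | None
    geometry_error: str | None
    try:
        geometry = _stage(
            "classify_geometry",
            cluster_geometry.classify_geometry,
            embedding,
            labels,
            config.plane,
            config.orientation_flip,
        )
        geometry_error = None
    except GeometryUndefinedError as exc:
        geometry = None
        geometry_error = str(exc)
        logger.warning("geometry undefined for %s: %s", genome.id, exc)
    gc_profile = _stage(
        "build_gc_profile", gc_analysis.build_gc_profile, genome, fragments, labels
    )

    frag_table = gc_profile.per_fragment.copy()
    frag_table.insert(0, "genome_id", genome.id)
    frag_table.insert(2, "start", [f.start for f in fragments])
    frag_table = frag_table[["genome_id", "index", "start", "center", "gc", "phase"]]

    result = GenomeResult(
        genome_id=genome.id,
        fragments=frag_table,
        matrix=matrix,
        labels=labels,
        embedding=embedding,
        clusters=clusters,
        geometry=geometry,
        geometry_error=geometry_error,
        gc_profile=gc_profile,
    )
    counts = phase_labeling.phase_counts(labels)
    logger.info(
        "%s: %d fragments, excluded=%s, symmetry=%s, counts=%s",
        genome.id,
        len(fragments),
        excluded,
        geometry.symmetry if geometry else "undefined",
        {k.value: v for k, v in counts.items() if v},
    )
    if out_dir is not None:
        _write_genome_outputs(config, result, Path(out_dir))
    return result


def geometry_row(result: GenomeResult) -> dict:
    """One summary row per genome (the geometry TSV schema)."""
    counts = phase_labeling.phase_counts(result.labels)
    row = {
        "genome_id": result.genome_id,
        "excluded_triplet": result.excluded_triplet,
        "area_F": result.geometry.area_F if result.geometry else float("nan"),
        "area_B": result.geometry.area_B if result.geometry else float("nan"),
        "symmetry": result.geometry.symmetry if result.geometry else "undefined",
        "orientation": result.geometry.orientation if result.geometry else "undefined",
    }
    for name in LABEL_ORDER:
        row[f"n_{name}"] = counts[PhaseLabel(name)]
    if result.geometry:
        row["coding_sd"] = result.geometry.coding_sd
        row["bias0"], row["bias1"], row["bias2"] = result.geometry.bias
    else:
        row["coding_sd"] = float("nan")
        row["bias0"] = row["bias1"] = row["bias2"] = float("nan")
    for key in gc_analysis.ENSEMBLE_KEYS:
        row[f"gc_{key}"] = result.gc_profile.ensemble_means[key]
    return row


def _write_genome_outputs(config: RunConfig, result: GenomeResult, out_dir: Path) -> None:
    target = out_dir / result.genome_id
    try:
        target.mkdir(parents=True, exist_ok=True)
        write_table(result.fragments, target / "fragments.tsv")

        header = (
            f"# excluded_triplet={result.excluded_triplet}"
            f" fragment_length={config.fragment_length} step={config.step}\n"
        )
        with open(target / "frequency_matrix.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(
                result.matrix.points, columns=result.matrix.columns
            ).to_csv(fh, sep="\t", index=False)

        emb = pd.DataFrame(result.embedding.coords, columns=["PC1", "PC2", "PC3"])
        emb.insert(0, "index", result.fragments["index"].to_numpy())
        emb["phase"] = result.fragments["phase"].to_numpy()
        emb["kmeans_cluster"] = result.clusters
        write_table(emb, target / "embedding.tsv")

        write_table(pd.DataFrame([geometry_row(result)]), target / "geometry_summary.tsv")

        manifest = {
            "genome_id": result.genome_id,
            "config": asdict(config),
            "n_fragments": int(len(result.fragments)),
            "excluded_triplet": result.excluded_triplet,
            "explained_variance": [float(v) for v in result.embedding.explained_variance],
            "pca_sign_convention": list(result.embedding.sign_convention),
            "symmetry": result.geometry.symmetry if result.geometry else None,
            "orientation": result.geometry.orientation if result.geometry else None,
            "geometry_error": result.geometry_error,
            "gc": {k: float(v) for k, v in result.gc_profile.ensemble_means.items()},
        }
        with open(target / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        shutil.rmtree(target, ignore_errors=True)
        raise


@dataclass
class CorpusResult:
    geometry: pd.DataFrame  # one row per genome
    excluded_tally: dict[str, int]
    correlations: pd.DataFrame | None
    contingency: pd.DataFrame | None = field(default=None)


def run_corpus(
    config: RunConfig,
    genomes: list[GenomeRecord],
    out_dir: str | Path | None = None,
) -> CorpusResult:
    """Per-genome analysis plus corpus-level summaries.

    Produces one geometry row per genome, the tally of excluded triplets,
    the cross-genome GC correlation matrix (>= 3 genomes), and the U/D x
    excluded-triplet contingency over the two most frequent excluded
    triplets (only when both dimensions have >= 2 levels).
    """
    if not genomes:
        raise ValueError("corpus must contain at least one genome")
    results = [run_genome(config, g, out_dir) for g in genomes]
    geometry = pd.DataFrame([geometry_row(r) for r in results])

    tally: dict[str, int] = {}
    for r in results:
        tally[r.excluded_triplet] = tally.get(r.excluded_triplet, 0) + 1

    correlations = None
    if len(genomes) >= 3:
        profiles = [r.gc_profile for r in results]
        means = np.array(
            [[p.ensemble_means[k] for k in gc_analysis.ENSEMBLE_KEYS] for p in profiles]
        )
        if np.nanstd(means, axis=0).max() == 0:
            logger.warning("ensemble GC means have zero variance; correlations undefined")
        else:
            correlations = gc_analysis.cross_genome_correlations(
                profiles, method=config.correlation_method
            )

    contingency = None
    top = sorted(tally, key=lambda t: (-tally[t], t))[:2]
    orientations = geometry["orientation"].unique()
    if len(top) == 2 and len([o for o in orientations if o != "undefined"]) >= 2:
        sub = geometry[geometry["excluded_triplet"].isin(top)]
        contingency = pd.crosstab(sub["orientation"], sub["excluded_triplet"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(geometry, out_dir / "corpus_geometry.tsv")
        write_table(
            pd.DataFrame(
                sorted(tally.items()), columns=["excluded_triplet", "n_genomes"]
            ),
            out_dir / "excluded_triplet_tally.tsv",
        )
        if correlations is not None:
            correlations.to_csv(out_dir / "gc_correlations.tsv", sep="\t")
        if contingency is not None:
            contingency.to_csv(out_dir / "orientation_contingency.tsv", sep="\t")
    return CorpusResult(
        geometry=geometry,
        excluded_tally=tally,
        correlations=correlations,
        contingency=contingency,
    )
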