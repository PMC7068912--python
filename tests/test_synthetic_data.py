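"""Generator ground truth and the analytic frame-shift oracle."""

import numpy as np
import pytest

from plastidphase.fragmentation import fragmentize
from plastidphase.genome_io import Strand
from plastidphase.phase_labeling import PhaseLabel, label_fragments
from plastidphase.synthetic_data import (
    RC_PERM,
    SpecError,
    SyntheticGenomeSpec,
    TailBlockSpec,
    chloroplast_like_spec,
    control_codon_usage,
    default_codon_usage,
    derive_phase_pairing,
    expected_frame_distribution,
    expected_phase_distribution,
    generate,
    label_to_frame_shift,
    rc_transform,
    reverse_complement,
)
from plastidphase.triplet_space import TRIPLETS, frequency_vectors


class TestSpecValidation:
    def test_infeasible_packing_rejected(self):
        spec = SyntheticGenomeSpec(N=10_000, n_forward_genes=10, n_backward_genes=10)
        with pytest.raises(SpecError):
            generate(spec)

    def test_gene_lengths_must_be_codon_multiples(self):
        with pytest.raises(SpecError):
            SyntheticGenomeSpec(gene_length_range=(1000, 1500))

    def test_tail_must_be_gc_rich(self):
        with pytest.raises(SpecError):
            SyntheticGenomeSpec(tail_block=TailBlockSpec(rna_gc=0.4))


class TestGenerate:
    def test_same_seed_identical_output(self):
        a_rec, a_truth = generate(chloroplast_like_spec(seed=5))
        b_rec, b_truth = generate(chloroplast_like_spec(seed=5))
        assert a_rec.sequence == b_rec.sequence
        assert a_rec.regions == b_rec.regions
        np.testing.assert_array_equal(a_truth.stratum, b_truth.stratum)
        np.testing.assert_array_equal(a_truth.codon_offset, b_truth.codon_offset)

    def test_zero_gene_spec_is_all_junk(self):
        spec = SyntheticGenomeSpec(
            N=20_000, n_forward_genes=0, n_backward_genes=0, tail_block=None, seed=3
        )
        record, truth = generate(spec)
        assert not record.regions
        assert (truth.stratum == 0).all()
        frags = fragmentize(record)
        labels = label_fragments(frags, record.regions, record.length)
        assert set(labels) == {PhaseLabel.JUNK}

    def test_single_gene_fragments_follow_center_arithmetic(self):
        spec = SyntheticGenomeSpec(
            N=5_000,
            n_forward_genes=1,
            n_backward_genes=0,
            gene_length_range=(4200, 4200),
            tail_block=None,
            seed=7,
        )
        record, _ = generate(spec)
        (gene,) = record.regions
        frags = fragmentize(record)
        labels = label_fragments(frags, record.regions, record.length)
        f_phases = (PhaseLabel.F0, PhaseLabel.F1, PhaseLabel.F2)
        checked = 0
        for frag, lab in zip(frags, labels):
            if lab in f_phases:
                assert gene.start <= frag.center <= gene.end
                assert lab == f_phases[(frag.center - gene.start) % 3]
                checked += 1
        assert checked > 100

    def test_backward_gene_is_reverse_complemented_codon_stream(self):
        spec = SyntheticGenomeSpec(
            N=32_000,
            n_forward_genes=0,
            n_backward_genes=1,
            gene_length_range=(30_000, 30_000),
            tail_block=None,
            seed=11,
        )
        record, truth = generate(spec)
        (gene,) = record.regions
        assert gene.strand is Strand.BACKWARD
        # mRNA-sense codon offsets run 0,1,2 from the region end inward
        segment = truth.codon_offset[gene.start - 1 : gene.end]
        assert segment[-1] == 0 and segment[-2] == 1 and segment[-3] == 2
        # in-frame mRNA codons follow the backward usage more closely than
        # any shifted reading would follow junk composition: check the
        # empirical in-frame distribution against usage
        mrna = reverse_complement(record.sequence[gene.start - 1 : gene.end])
        freqs, _ = frequency_vectors([mrna])
        l1 = np.abs(freqs[0] - spec.codon_usage).sum()
        assert l1 < 0.15

    def test_ground_truth_strata_match_annotation(self, mirror_run):
        record, truth = mirror_run.record, mirror_run.truth
        for region in record.regions:
            segment = truth.stratum[region.start - 1 : region.end]
            assert len(set(segment.tolist())) == 1

    def test_tail_fragments_are_gc_rich(self, mirror_run):
        prof = mirror_run.result.gc_profile.per_fragment
        tail_gc = prof.loc[prof["phase"] == "TAIL", "gc"]
        assert len(tail_gc) > 50
        assert (tail_gc >= 0.5).mean() >= 0.99


class TestRevcompSwapProperty:
    def test_mirrored_genome_swaps_strand_phases(self):
        spec = SyntheticGenomeSpec(
            N=60_003,  # (N - L) divisible by R so mirrored windows align
            n_forward_genes=8,
            n_backward_genes=8,
            gene_length_range=(900, 1200),
            tail_block=None,
            seed=13,
        )
        record, _ = generate(spec)
        labels = label_fragments(
            fragmentize(record), record.regions, record.length
        )

        from plastidphase.genome_io import AnnotatedRegion, GenomeRecord

        n = record.length
        flipped = GenomeRecord(
            id="rc",
            sequence=reverse_complement(record.sequence),
            regions=sorted(
                AnnotatedRegion(
                    n - r.end + 1,
                    n - r.start + 1,
                    Strand.BACKWARD if r.strand is Strand.FORWARD else Strand.FORWARD,
                    r.category,
                )
                for r in record.regions
            ),
        )
        flipped_labels = label_fragments(
            fragmentize(flipped), flipped.regions, flipped.length
        )
        swap = {"F0": "B0", "F1": "B1", "F2": "B2", "B0": "F0", "B1": "F1",
                "B2": "F2", "JUNK": "JUNK", "TAIL": "TAIL"}
        expected = [PhaseLabel(swap[l.value]) for l in labels]
        assert flipped_labels[::-1] == expected


class TestFrameShiftOracle:
    def test_in_frame_phase_returns_usage_itself(self):
        usage = default_codon_usage()
        # phase index 1 reads in frame: (L-1)/2 == 1 (mod 3)
        assert label_to_frame_shift(1) == 0
        np.testing.assert_allclose(
            expected_phase_distribution(usage, "F1"), usage, atol=1e-15
        )

    def test_uniform_usage_uniform_for_every_phase(self):
        uniform = np.full(64, 1 / 64)
        for phase in ("F0", "F1", "F2", "B0", "B1", "B2"):
            np.testing.assert_allclose(
                expected_phase_distribution(uniform, phase), uniform, atol=1e-12
            )

    def test_shifted_readings_are_proper_distributions(self):
        usage = control_codon_usage()
        for shift in (0, 1, 2):
            d = expected_frame_distribution(usage, shift)
            assert np.isclose(d.sum(), 1.0)
            assert (d >= 0).all()

    def test_each_backward_phase_is_rc_image_of_one_forward_phase(self):
        usage = default_codon_usage()
        f = {p: expected_phase_distribution(usage, p) for p in ("F0", "F1", "F2")}
        b = {p: expected_phase_distribution(usage, p) for p in ("B0", "B1", "B2")}
        for j in range(3):
            np.testing.assert_allclose(
                b[f"B{j}"], rc_transform(f[f"F{j}"]), atol=1e-15
            )

    def test_rc_transform_is_involution(self):
        rng = np.random.default_rng(17)
        d = rng.dirichlet(np.ones(64))
        np.testing.assert_allclose(rc_transform(rc_transform(d)), d)
        assert len(set(RC_PERM.tolist())) == 64

    def test_default_usage_pairing_is_chloroplast_like(self):
        assert derive_phase_pairing(default_codon_usage()) == {
            "F0": "B1",
            "F1": "B0",
            "F2": "B2",
        }

    def test_non_coding_phase_rejected(self):
        with pytest.raises(ValueError):
            expected_phase_distribution(default_codon_usage(), "JUNK")


class TestCentroidConvergence:
    def test_empirical_phase_centroids_converge_to_oracle(self):
        """Fragment centroids from a long-gene genome approach the exact
        frame-shift distributions (>= 1e5 codons per phase)."""
        spec = SyntheticGenomeSpec(
            N=960_000,
            n_forward_genes=2,
            n_backward_genes=2,
            gene_length_range=(225_000, 225_000),
            tail_block=None,
            seed=42,
        )
        record, truth = generate(spec)
        frags = fragmentize(record)
        freqs, _ = frequency_vectors([f.sequence for f in frags])
        labels = label_fragments(frags, record.regions, record.length)
        lab = np.array([l.value for l in labels])
        starts = np.array([f.start for f in frags])
        L = 603
        inside = np.array(
            [
                (truth.stratum[s - 1 : s + L - 1] != 0).all()
                and len(set(truth.stratum[s - 1 : s + L - 1].tolist())) == 1
                for s in starts
            ]
        )
        for phase in ("F0", "F1", "F2", "B0", "B1", "B2"):
            mask = (lab == phase) & inside
            assert mask.sum() > 5_000
            centroid = freqs[mask].mean(axis=0)
            oracle = expected_phase_distribution(spec.codon_usage, phase)
            assert np.abs(centroid - oracle).sum() < 0.02
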