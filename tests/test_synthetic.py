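import numpy as np
import pandas as pd
import pytest

from rhodosurvey.abundance import copies_per_genome, transcript_fraction
from rhodosurvey.hydropathy import DEFAULT_TOPOLOGY, call_topology, hydropathy_profile
from rhodosurvey.motifs import extract_motif
from rhodosurvey.screen import screen_opsin
from rhodosurvey.synthetic import (
    make_community_coverage,
    make_decoy,
    make_opsin,
    make_transcript_counts,
)


class TestMakeOpsin:
    def test_full_identity_native_motif_reproduces_scaffold(self, reference):
        rec, truth = make_opsin(1.0, reference.native_motif, seed=99)
        assert rec.aa_sequence == reference.aa_sequence
        assert truth.target_identity_to_reference == 1.0

    def test_seeded_determinism(self):
        r1, _ = make_opsin(0.8, ("D", "T", "Q", "E"), seed=7)
        r2, _ = make_opsin(0.8, ("D", "T", "Q", "E"), seed=7)
        assert r1.aa_sequence == r2.aa_sequence

    def test_different_seeds_differ(self):
        r1, _ = make_opsin(0.8, ("D", "T", "Q", "E"), seed=7)
        r2, _ = make_opsin(0.8, ("D", "T", "Q", "E"), seed=8)
        assert r1.aa_sequence != r2.aa_sequence

    def test_realised_identity_within_tolerance(self, reference):
        for target in (0.6, 0.75, 0.9):
            rec, _ = make_opsin(target, ("D", "T", "T", "T"), seed=13)
            realised = sum(
                a == b for a, b in zip(rec.aa_sequence, reference.aa_sequence)
            ) / len(reference.aa_sequence)
            assert abs(realised - target) <= 0.03

    def test_planted_motif_read_back_by_annotator(self, reference):
        rec, truth = make_opsin(0.8, ("D", "T", "Q", "E"), seed=7)
        call = extract_motif(rec, reference)
        assert (
            call.residue_97, call.residue_101, call.residue_105, call.residue_108
        ) == truth.planted_motif

    def test_retinal_lysine_untouched(self, reference):
        rec, _ = make_opsin(0.6, ("D", "T", "Q", "E"), seed=31)
        assert rec.aa_sequence[reference.retinal_lysine_pr - 1] == "K"

    def test_nonstandard_motif_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            make_opsin(0.8, ("D", "T", "B", "E"), seed=1)

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_opsin(0.2, ("D", "T", "Q", "E"), seed=1)


class TestMakeDecoy:
    def test_six_tm_has_exactly_six_segments(self):
        rec, truth = make_decoy("six_tm", seed=4)
        assert call_topology(rec.aa_sequence, DEFAULT_TOPOLOGY).tm_count == 6
        assert truth.tm_segment_count == 6

    def test_no_lysine_fails_screen_for_that_reason(self, reference):
        rec, _ = make_decoy("no_lysine", seed=4)
        result = screen_opsin(rec, reference)
        assert result.fail_reasons == ["no_retinal_lysine"]

    def test_soluble_profile_below_threshold(self):
        rec, _ = make_decoy("soluble", seed=4)
        profile = hydropathy_profile(rec.aa_sequence, DEFAULT_TOPOLOGY.window)
        assert profile.max() < DEFAULT_TOPOLOGY.threshold

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown decoy kind"):
            make_decoy("seven_tm", seed=1)

    def test_seeded_determinism(self):
        r1, _ = make_decoy("soluble", seed=9)
        r2, _ = make_decoy("soluble", seed=9)
        assert r1.aa_sequence == r2.aa_sequence


class TestMakeCommunityCoverage:
    def test_noise_free_recovery_is_exact(self):
        table, truth = make_community_coverage(
            n_samples=1, depths=[25.0], planted={"g1": 0.7},
            uscg_mean_coverage=100.0, noise="none",
        )
        assert copies_per_genome(table, "S01", {"g1"}) == pytest.approx(0.7, abs=1e-9)

    def test_zero_copies_gives_zero_coverage(self):
        table, _ = make_community_coverage(
            n_samples=1, depths=[25.0], planted={"g1": 0.0}, noise="none",
        )
        cov = table.coverage
        assert float(cov.loc[cov["gene_id"] == "g1", "coverage"].iloc[0]) == 0.0

    def test_poisson_mean_recovery_over_samples(self):
        """Monte-Carlo: mean estimate over 50 noisy samples near truth."""
        table, _ = make_community_coverage(
            n_samples=50, depths=[25.0] * 50, planted={"g1": 0.5},
            uscg_mean_coverage=200.0, noise="poisson", seed=11,
        )
        estimates = [
            copies_per_genome(table, s, {"g1"}) for s in table.sample_ids
        ]
        # per-sample sd ~ sqrt(0.5/200) = 0.05; 3 SE over 50 samples
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.5) < 3 * se + 1e-12

    def test_empty_planted_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_community_coverage(1, [25.0], planted={})

    def test_nonpositive_uscg_mean_rejected(self):
        with pytest.raises(ValueError):
            make_community_coverage(1, [25.0], planted={"g": 1.0}, uscg_mean_coverage=0)

    def test_seeded_determinism(self):
        t1, _ = make_community_coverage(
            3, [25.0, 75.0, 125.0], {"g": 0.4}, noise="lognormal", seed=5
        )
        t2, _ = make_community_coverage(
            3, [25.0, 75.0, 125.0], {"g": 0.4}, noise="lognormal", seed=5
        )
        pd.testing.assert_frame_equal(t1.coverage, t2.coverage)


class TestMakeTranscriptCounts:
    def test_deterministic_rounding(self):
        df, _ = make_transcript_counts(0.02, 1_000_000, noise="none")
        assert int(df["rhodopsin_reads"].iloc[0]) == 200

    def test_zero_fraction(self):
        df, _ = make_transcript_counts(0.0, 5_000, noise="binomial", seed=3)
        assert int(df["rhodopsin_reads"].iloc[0]) == 0

    def test_binomial_recovery_within_ci(self):
        """Planted 0.004% at 10M reads: estimate inside the 99% interval."""
        df, _ = make_transcript_counts(0.004, 10_000_000, seed=3, noise="binomial")
        reads = int(df["rhodopsin_reads"].iloc[0])
        est = transcript_fraction(reads, 10_000_000)
        p = 0.004 / 100
        half = 2.576 * np.sqrt(p * (1 - p) / 10_000_000) * 100
        assert abs(est - 0.004) < half

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_transcript_counts(101.0, 100)
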