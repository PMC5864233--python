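import numpy as np
import pandas as pd
import pytest

from rhodosurvey.abundance import (
    USCG_IDS,
    CoverageTable,
    copies_per_genome,
    copy_number_profile,
    depth_profile,
    gene_set_profile,
    relative_abundance,
    transcript_fraction,
    transcript_summary,
)


def build_table(gene_coverages, uscg_coverages=None, depth=25.0, sample_id="S01"):
    """One-sample coverage table with explicit USCG coverages."""
    if uscg_coverages is None:
        uscg_coverages = [100.0] * 10
    rows = [
        (sample_id, cog, cov, True) for cog, cov in zip(USCG_IDS, uscg_coverages)
    ] + [(sample_id, g, c, False) for g, c in gene_coverages.items()]
    coverage = pd.DataFrame(rows, columns=["sample_id", "gene_id", "coverage", "is_uscg"])
    metadata = pd.DataFrame(
        {"sample_id": [sample_id], "depth_m": [depth], "date": ["2020-01-01"]}
    )
    return CoverageTable(coverage=coverage, metadata=metadata)


class TestCopiesPerGenome:
    def test_unit_ratio(self):
        table = build_table({"g1": 100.0})
        assert copies_per_genome(table, "S01", {"g1"}) == pytest.approx(1.0)

    def test_zero_coverage_gene(self):
        table = build_table({"g1": 0.0})
        assert copies_per_genome(table, "S01", {"g1"}) == 0.0

    def test_direct_arithmetic(self):
        # USCG coverages 2..20 have mean 11; gene coverage 7.7 -> 0.7
        table = build_table({"g1": 7.7}, uscg_coverages=[2, 4, 6, 8, 10, 12, 14, 16, 18, 20])
        assert copies_per_genome(table, "S01", {"g1"}) == pytest.approx(0.7)

    def test_absent_gene_counts_as_zero(self):
        table = build_table({"g1": 50.0})
        assert copies_per_genome(table, "S01", {"ghost"}) == 0.0

    def test_missing_uscg_error_names_sample_and_marker(self):
        rows = [("S01", cog, 100.0, True) for cog in USCG_IDS[:9]]
        rows.append(("S01", "g1", 10.0, False))
        coverage = pd.DataFrame(rows, columns=["sample_id", "gene_id", "coverage", "is_uscg"])
        metadata = pd.DataFrame({"sample_id": ["S01"], "depth_m": [25.0], "date": [""]})
        with pytest.raises(ValueError, match="S01.*COG0552"):
            CoverageTable(coverage=coverage, metadata=metadata)

    def test_scale_invariance(self):
        """Multiplying every coverage in a sample by c leaves estimates unchanged."""
        table = build_table({"g1": 37.5, "g2": 12.1})
        base = copies_per_genome(table, "S01", {"g1", "g2"})
        scaled_cov = table.coverage.assign(coverage=table.coverage["coverage"] * 7.3)
        scaled = CoverageTable(coverage=scaled_cov, metadata=table.metadata)
        assert copies_per_genome(scaled, "S01", {"g1", "g2"}) == pytest.approx(
            base, abs=1e-12
        )

    def test_additivity_over_disjoint_sets(self):
        table = build_table({"g1": 30.0, "g2": 20.0, "g3": 12.5})
        whole = copies_per_genome(table, "S01", {"g1", "g2", "g3"})
        parts = copies_per_genome(table, "S01", {"g1"}) + copies_per_genome(
            table, "S01", {"g2", "g3"}
        )
        assert whole == pytest.approx(parts, abs=1e-12)


class TestDepthProfile:
    def test_single_sample_degenerate_stats(self):
        values = pd.DataFrame({"sample_id": ["S01"], "copies_per_genome": [0.42]})
        metadata = pd.DataFrame({"sample_id": ["S01"], "depth_m": [25.0]})
        prof = depth_profile(values, metadata)
        row = prof.iloc[0]
        assert row["mean"] == row["median"] == 0.42
        assert row["q3"] - row["q1"] == 0.0

    def test_three_values_at_one_depth(self):
        values = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "copies_per_genome": [0.6, 0.7, 0.8]}
        )
        metadata = pd.DataFrame({"sample_id": ["a", "b", "c"], "depth_m": [75.0] * 3})
        prof = depth_profile(values, metadata)
        assert prof.iloc[0]["mean"] == pytest.approx(0.7)
        assert prof.iloc[0]["median"] == pytest.approx(0.7)
        assert prof.iloc[0]["n"] == 3

    def test_groups_by_exact_depth(self):
        values = pd.DataFrame(
            {"sample_id": ["a", "b"], "copies_per_genome": [0.1, 0.9]}
        )
        metadata = pd.DataFrame({"sample_id": ["a", "b"], "depth_m": [25.0, 200.0]})
        prof = depth_profile(values, metadata)
        assert list(prof["depth_m"]) == [25.0, 200.0]


class TestRelativeAbundance:
    def test_single_category_is_unity(self):
        profile = pd.DataFrame(
            {"sample_id": ["S01"] * 2, "gene_id": ["g1", "g2"],
             "copies_per_genome": [0.3, 0.2]}
        )
        out = relative_abundance(profile, {"g1": "SAR11", "g2": "SAR11"})
        assert out["fraction"].iloc[0] == pytest.approx(1.0)

    def test_two_categories_three_to_one(self):
        profile = pd.DataFrame(
            {"sample_id": ["S01"] * 2, "gene_id": ["g1", "g2"],
             "copies_per_genome": [0.3, 0.1]}
        )
        out = relative_abundance(profile, {"g1": "blue", "g2": "green"})
        by_cat = dict(zip(out["category"], out["fraction"]))
        assert by_cat["blue"] == pytest.approx(0.75)
        assert by_cat["green"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        profile = pd.DataFrame(
            {
                "sample_id": ["S01"] * 8,
                "gene_id": genes,
                "copies_per_genome": rng.uniform(0.01, 1, size=8),
            }
        )
        cats = {g: f"c{i % 3}" for i, g in enumerate(genes)}
        out = relative_abundance(profile, cats)
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_sample_reports_nan(self):
        profile = pd.DataFrame(
            {"sample_id": ["S01"], "gene_id": ["g1"], "copies_per_genome": [0.0]}
        )
        out = relative_abundance(profile, {"g1": "x"})
        assert np.isnan(out["fraction"].iloc[0])

    def test_unmapped_gene_is_unassigned(self):
        profile = pd.DataFrame(
            {"sample_id": ["S01"], "gene_id": ["g1"], "copies_per_genome": [0.5]}
        )
        out = relative_abundance(profile, {})
        assert list(out["category"]) == ["unassigned"]


class TestGeneSetProfile:
    def test_singleton_set_equals_copies_per_genome(self):
        table = build_table({"blh": 55.0, "crtI": 20.0})
        prof = gene_set_profile(table, {"only_blh": ["blh"]})
        expected = copies_per_genome(table, "S01", {"blh"})
        assert prof.iloc[0]["mean"] == pytest.approx(expected)

    def test_empty_set_is_zero(self):
        table = build_table({"blh": 55.0})
        prof = gene_set_profile(table, {"nothing": []})
        assert prof.iloc[0]["mean"] == 0.0

    def test_unknown_gene_skipped_and_counted(self):
        table = build_table({"blh": 55.0})
        prof = gene_set_profile(table, {"set": ["blh", "ghost"]})
        assert prof.iloc[0]["n_unknown"] == 1
        assert prof.iloc[0]["mean"] == pytest.approx(
            copies_per_genome(table, "S01", {"blh"})
        )

    def test_overlapping_sets_rejected_by_default(self):
        table = build_table({"blh": 55.0})
        with pytest.raises(ValueError, match="both sets"):
            gene_set_profile(table, {"a": ["blh"], "b": ["blh"]})


class TestTranscriptFraction:
    def test_surface_scale_arithmetic(self):
        assert transcript_fraction(200, 1_000_000) == pytest.approx(0.02)

    def test_zero_reads(self):
        assert transcript_fraction(0, 10_000) == 0.0

    def test_reads_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            transcript_fraction(11, 10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transcript_fraction(-1, 10)

    def test_summary_joins_depths(self):
        counts = pd.DataFrame(
            {"sample_id": ["T01"], "rhodopsin_reads": [400],
             "total_nonrrna_reads": [10_000_000]}
        )
        meta = pd.DataFrame({"sample_id": ["T01"], "depth_m": [200.0]})
        out = transcript_summary(counts, meta)
        assert out.iloc[0]["fraction_percent"] == pytest.approx(0.004)
        assert out.iloc[0]["depth_m"] == 200.0


def test_profile_additivity_matches_per_gene_sum():
    """Category value equals the sum of member-gene values in a sample."""
    table = build_table({"g1": 10.0, "g2": 25.0, "g3": 40.0})
    profile = copy_number_profile(table)
    total = profile["copies_per_genome"].sum()
    assert total == pytest.approx(copies_per_genome(table, "S01", {"g1", "g2", "g3"}))
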