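import textwrap

import pytest

from rhodosurvey.records import ProteinRecord
from rhodosurvey.screen import read_hmm_hits, screen_opsin
from rhodosurvey.synthetic import make_decoy, make_opsin


class TestScreenOpsin:
    def test_reference_record_passes(self, reference):
        rec = ProteinRecord(id="ref", aa_sequence=reference.aa_sequence)
        result = screen_opsin(rec, reference)
        assert result.passed
        assert result.tm_count == 7
        # reported position is 0-based; the frame stores 1-based 231
        assert result.retinal_lysine_position == reference.retinal_lysine_pr - 1

    def test_synthetic_opsin_passes(self, reference):
        rec, _ = make_opsin(0.8, ("D", "T", "Q", "E"), seed=7)
        result = screen_opsin(rec, reference)
        assert result.passed and result.tm_count == 7

    def test_no_lysine_decoy_fails_with_reason(self, reference):
        rec, _ = make_decoy("no_lysine", seed=1)
        result = screen_opsin(rec, reference)
        assert not result.passed
        assert "no_retinal_lysine" in result.fail_reasons

    def test_six_tm_decoy_fails_with_reason(self, reference):
        rec, _ = make_decoy("six_tm", seed=1)
        result = screen_opsin(rec, reference)
        assert not result.passed
        assert "tm_count_not_7" in result.fail_reasons
        assert result.tm_count == 6

    def test_soluble_decoy_has_no_segments(self, reference):
        rec, _ = make_decoy("soluble", seed=1)
        result = screen_opsin(rec, reference)
        assert not result.passed
        assert result.tm_count == 0

    def test_failures_enumerated_not_short_circuited(self, reference):
        # six-TM construct keeps its lysine: both the topology failure and
        # the lysine-outside-TM7 failure must be reported
        rec, truth = make_decoy("six_tm", seed=3)
        assert truth.retinal_lysine_present
        result = screen_opsin(rec, reference)
        assert set(result.fail_reasons) >= {"tm_count_not_7", "lysine_outside_tm7"}

    def test_sequence_shorter_than_window_is_ambiguous(self, reference):
        rec = ProteinRecord(id="short", aa_sequence="MKLLA")
        result = screen_opsin(rec, reference)
        assert result.fail_reasons == ["ambiguous_sequence"]

    def test_x_rich_sequence_flagged_ambiguous(self, reference):
        seq = reference.aa_sequence[:100] + "X" * 100
        rec = ProteinRecord(id="xrich", aa_sequence=seq)
        result = screen_opsin(rec, reference)
        assert not result.passed
        assert "ambiguous_sequence" in result.fail_reasons


HMM_TBLOUT = textwrap.dedent("""\
    #                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----
    # target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target
    #------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ ----- ----- --- --- --- --- --- --- --- ---------------------
    PR0001               -          bac_rhodopsin        -            1.2e-40  140.1   0.1   1.5e-40  139.8   0.1   1.0   1   0   0   1   1   1   1 candidate opsin
    PR0002               -          bac_rhodopsin        -            3.4e-12   45.0   0.0   4.1e-12   44.7   0.0   1.1   1   0   0   1   1   1   1 -
    PR0003               -          bac_rhodopsin        -            2.0e-06   22.3   0.0   2.6e-06   22.0   0.0   1.0   1   0   0   1   1   1   1 -
    WEAK01               -          bac_rhodopsin        -            0.0042    8.1   0.0   0.0055    7.9   0.0   1.0   1   0   0   1   1   1   1 -
    WEAK02               -          bac_rhodopsin        -            1.3      2.0   0.0   1.9       1.8   0.0   1.0   1   0   0   1   1   1   1 -
    """)


class TestReadHmmHits:
    def test_threshold_filter(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(HMM_TBLOUT)
        assert read_hmm_hits(path, evalue_max=1e-5) == {"PR0001", "PR0002", "PR0003"}

    def test_comments_only_file_is_empty(self, tmp_path):
        path = tmp_path / "empty.tbl"
        path.write_text("# nothing here\n# at all\n")
        assert read_hmm_hits(path) == set()

    def test_fixture_round_trip_exact_ids(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(HMM_TBLOUT)
        assert read_hmm_hits(path, evalue_max=10.0) == {
            "PR0001", "PR0002", "PR0003", "WEAK01", "WEAK02",
        }

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tbl"
        path.write_text("# header\ntoo few fields\n")
        with pytest.raises(ValueError, match=":2"):
            read_hmm_hits(path)

    def test_domtblout_dialect(self, tmp_path):
        line = (
            "PR0001 - 249 bac_rhodopsin - 240 5.1e-40 139.0 0.1 1 1 "
            "6.0e-42 7.2e-40 138.5 0.1 5 240 4 248 2 249 0.98 candidate"
        )
        path = tmp_path / "hits.domtbl"
        path.write_text("# header\n" + line + "\n")
        assert read_hmm_hits(path, evalue_max=1e-5) == {"PR0001"}
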