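import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splintseq import probe_design as pdz
from splintseq.probe_design import (
    DEFAULT_JUNCTION_TABLE,
    OfftargetIndex,
    ParseError,
    ProbeCandidate,
    TranscriptRecord,
    assemble_probe,
    assemble_singleplex_probe,
    enumerate_candidates,
    filter_reference,
    junction_quality,
    offtarget_screen,
    rank_and_select,
    read_order_sheet,
    read_transcripts,
    revcomp,
    split_arms,
    structure_score,
    write_order_sheet,
)

ANCHOR = pdz.DEFAULT_ANCHOR

dna = st.text(alphabet="ACGT", min_size=25, max_size=25)


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path


class TestReadTranscripts:
    def test_identity_read(self, tmp_path):
        p = write_fasta(tmp_path / "t.fa", [("tx1|geneA", "ACGT" * 25)])
        recs = read_transcripts(p)
        assert len(recs) == 1
        assert recs[0].transcript_id == "tx1"
        assert recs[0].gene_id == "geneA"
        assert len(recs[0].sequence) == 100

    def test_u_and_case_normalized(self, tmp_path):
        p = write_fasta(tmp_path / "t.fa", [("tx1", "acgu")])
        assert read_transcripts(p)[0].sequence == "ACGT"

    def test_ambiguity_code_rejected_with_record_name(self, tmp_path):
        p = write_fasta(tmp_path / "t.fa", [("badrec", "ACGTN")])
        with pytest.raises(ParseError, match="badrec"):
            read_transcripts(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ParseError):
            read_transcripts(p)


class TestFilterReference:
    def make(self, base_means):
        import pandas as pd

        transcripts = [
            TranscriptRecord(f"t{i}", g, "ACGT" * 10)
            for i, g in enumerate(base_means)
        ]
        table = pd.DataFrame(
            {"gene_id": list(base_means), "base_mean": list(base_means.values())}
        )
        return transcripts, table

    def test_strict_less_than_removal_keeps_boundary(self):
        transcripts, table = self.make({"a": 5, "b": 10, "c": 300})
        kept = filter_reference(transcripts, table, min_base_mean=10)
        assert {t.gene_id for t in kept} == {"b", "c"}

    def test_all_above_threshold_is_identity(self):
        transcripts, table = self.make({"a": 11, "b": 300})
        assert filter_reference(transcripts, table) == transcripts

    def test_missing_genes_dropped_with_warning(self):
        import pandas as pd

        transcripts, _ = self.make({"a": 5})
        empty = pd.DataFrame({"gene_id": [], "base_mean": []})
        with pytest.warns(UserWarning):
            assert filter_reference(transcripts, empty, missing="drop") == []

    def test_missing_genes_kept_under_keep_policy(self):
        import pandas as pd

        transcripts, _ = self.make({"a": 5})
        empty = pd.DataFrame({"gene_id": [], "base_mean": []})
        assert filter_reference(transcripts, empty, missing="keep") == transcripts


class TestEnumerateCandidates:
    def test_window_counts(self):
        seq25 = "ACGTA" * 5
        assert len(enumerate_candidates(TranscriptRecord("t", "g", seq25))) == 1
        seq30 = "ACGTA" * 6
        assert len(enumerate_candidates(TranscriptRecord("t", "g", seq30))) == 6

    def test_g_homotetramer_windows_excluded(self):
        seq = "ACGTA" * 4 + "GGGG" + "TACGT" * 4  # GGGG at [20, 24)
        cands = enumerate_candidates(TranscriptRecord("t", "g", seq))
        for c in cands:
            assert "GGGG" not in c.target_25mer
        # every window covering the run is gone: starts max(0,24-25+1)=0..20
        starts = {c.start for c in cands}
        assert starts == set(range(len(seq) - 24)) - set(range(0, 21))

    def test_c_homotetramer_excluded_unless_legacy(self):
        seq = "ACGTA" * 4 + "CCCC" + "TACGT" * 4
        default = enumerate_candidates(TranscriptRecord("t", "g", seq))
        assert all("CCCC" not in c.target_25mer for c in default)
        legacy = enumerate_candidates(
            TranscriptRecord("t", "g", seq), legacy_g_filter=True
        )
        assert any("CCCC" in c.target_25mer for c in legacy)

    def test_short_transcript_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert enumerate_candidates(TranscriptRecord("t", "g", "ACGT")) == []

    def test_random_sequence_count_matches_combinatorial_rule(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        cands = enumerate_candidates(TranscriptRecord("t", "g", seq))
        expected = sum(
            1
            for i in range(len(seq) - 24)
            if "GGGG" not in seq[i : i + 25] and "CCCC" not in seq[i : i + 25]
        )
        assert len(cands) == expected


class TestSplitArms:
    @pytest.mark.parametrize("arm5_len", range(2, 23, 2))
    def test_arm_lengths_sum_to_footprint(self, arm5_len):
        t = "ACGTACGTACGTACGTACGTACGTA"
        arm5, arm3, _ = split_arms(t, arm5_len)
        assert len(arm5) == arm5_len
        assert len(arm5) + len(arm3) == 25

    def test_default_split_is_18_7(self):
        arm5, arm3, _ = split_arms("A" * 25)
        assert (len(arm5), len(arm3)) == (18, 7)
        assert arm5 == "T" * 18 and arm3 == "T" * 7

    @given(dna, st.integers(min_value=1, max_value=24))
    @settings(max_examples=50, deadline=None)
    def test_arms_reverse_complement_their_subwindows(self, t, arm5_len):
        arm5, arm3, junction = split_arms(t, arm5_len)
        assert arm5 == revcomp(t[:arm5_len])
        assert arm3 == revcomp(t[arm5_len:])
        assert junction == arm3[-1] + arm5[0]

    @pytest.mark.parametrize("bad", [0, 25, -3])
    def test_out_of_range_arm_length_raises(self, bad):
        with pytest.raises(ValueError):
            split_arms("A" * 25, bad)


class TestJunctionQuality:
    def test_printed_quality_classes(self):
        assert junction_quality("TG") == "disfavored"
        assert junction_quality("CG") == "disfavored"
        assert junction_quality("GA") == "disfavored"
        assert junction_quality("TC") == "favored"
        assert junction_quality("CC") == "favored"
        assert junction_quality("AC") == "favored"
        assert junction_quality("AT") == "neutral"

    def test_all_16_pairs_present_and_g_disfavored(self):
        assert len(DEFAULT_JUNCTION_TABLE) == 16
        for j, q in DEFAULT_JUNCTION_TABLE.items():
            if "G" in j:
                assert q == "disfavored"

    def test_malformed_junction_raises(self):
        with pytest.raises(ValueError):
            junction_quality("XX")


class TestOfftargetScreen:
    def test_exact_copy_in_other_gene_fails_at_zero(self):
        window = "ACGTA" * 5
        target = TranscriptRecord("t1", "g1", "T" * 10 + window + "T" * 10)
        other = TranscriptRecord("t2", "g2", "A" * 5 + window + "C" * 5)
        cand = ProbeCandidate("t1", "g1", 10, window)
        ok, mm = offtarget_screen(cand, [target, other])
        assert not ok and mm == 0

    def test_own_gene_excluded_and_empty_reference_passes(self):
        window = "ACGTA" * 5
        target = TranscriptRecord("t1", "g1", window)
        cand = ProbeCandidate("t1", "g1", 0, window)
        ok, mm = offtarget_screen(cand, [target])
        assert ok and mm == math.inf

    @pytest.mark.parametrize("n_mismatch,expected", [(5, False), (6, True)])
    def test_six_mismatch_boundary(self, n_mismatch, expected, rng):
        window = "".join(rng.choice(list("ACGT"), size=25))
        mutated = list(window)
        for i in rng.choice(25, size=n_mismatch, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        offtarget = TranscriptRecord("t2", "g2", "".join(mutated))
        cand = ProbeCandidate("t1", "g1", 0, window)
        ok, mm = offtarget_screen(cand, [offtarget], min_mismatches=6)
        assert ok is expected and mm == n_mismatch

    def test_reverse_strand_scan_behind_flag(self):
        window = "ACGTT" * 5
        rc_carrier = TranscriptRecord("t2", "g2", revcomp(window))
        cand = ProbeCandidate("t1", "g1", 0, window)
        ok_fwd, mm_fwd = offtarget_screen(cand, [rc_carrier])
        ok_rev, mm_rev = offtarget_screen(cand, [rc_carrier], scan_reverse=True)
        assert mm_rev == 0 and not ok_rev
        assert mm_fwd > 0


class TestStructureScore:
    def test_homopolymer_cannot_pair(self):
        assert structure_score("A" * 60) == 0.0

    def test_hairpin_scores_below_shuffled_control(self):
        stem = "GCATGCATGCATGCATGCAT"
        hairpin = stem + "A" * 20 + revcomp(stem)
        shuffled = list(hairpin)
        random.Random(42).shuffle(shuffled)
        assert structure_score(hairpin) < structure_score("".join(shuffled))

    @given(st.text(alphabet="ACGT", min_size=10, max_size=40))
    @settings(max_examples=20, deadline=None)
    def test_reverse_complement_symmetry(self, seq):
        assert structure_score(seq) == pytest.approx(
            structure_score(revcomp(seq))
        )

    def test_unknown_backend_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            structure_score("ACGT" * 15, backend="nope")


class TestRankAndSelect:
    def make(self, scores_starts):
        return [
            ProbeCandidate("t", "g", start, "A" * 25, structure_dG=score)
            for score, start in scores_starts
        ]

    def test_fewer_than_n_returns_all(self):
        chosen = rank_and_select(self.make([(0.0, i) for i in range(4)]), n=10)
        assert len(chosen) == 4
        assert [c.rank for c in chosen] == [1, 2, 3, 4]

    def test_exactly_n_returned_from_surplus(self):
        chosen = rank_and_select(self.make([(-i, i) for i in range(15)]), n=10)
        assert len(chosen) == 10
        # least structure (highest score) first
        assert chosen[0].structure_dG == 0.0

    def test_ties_broken_by_lower_start(self):
        chosen = rank_and_select(self.make([(-1.0, 50), (-1.0, 3)]), n=2)
        assert [c.start for c in chosen] == [3, 50]

    def test_stable_under_input_shuffling(self, rng):
        cands = self.make([(-(i % 5), i) for i in range(20)])
        a = [c.start for c in rank_and_select(list(cands), n=10)]
        shuffled = list(cands)
        rng.shuffle(shuffled)
        b = [c.start for c in rank_and_select(shuffled, n=10)]
        assert a == b


class TestAssembly:
    def test_layout_and_barcode_copy_rule(self):
        arm5, arm3 = "T" * 18, "T" * 7
        probe = assemble_probe(arm5, arm3, ANCHOR, "ACGTACGT")
        assert len(probe) == 60
        assert probe[:18] == arm5 and probe[-7:] == arm3
        assert probe[18:22] == "ACGT"  # positions 5-8 of the barcode
        assert probe[22:45] == ANCHOR
        assert probe[45:53] == "ACGTACGT"

    def test_singleplex_linker_is_35nt(self):
        probe = assemble_singleplex_probe("T" * 18, "T" * 7, ANCHOR)
        assert len(probe) == 60
        assert len(probe) - 25 == 35

    @pytest.mark.parametrize(
        "anchor,barcode", [("A" * 22, "ACGTACGT"), (ANCHOR, "ACGT")]
    )
    def test_length_mismatch_raises(self, anchor, barcode):
        with pytest.raises(ValueError):
            assemble_probe("T" * 18, "T" * 7, anchor, barcode)


class TestOrderSheet:
    def make_probes(self, n):
        probes = []
        for i in range(n):
            p = ProbeCandidate("t1", "g1", i, "A" * 25, arm5="T" * 18,
                               arm3="T" * 7)
            p.probe_seq = assemble_probe(p.arm5, p.arm3, ANCHOR, "ACGTACGT")
            probes.append(p)
        return probes

    def test_roundtrip_and_well_layout(self, tmp_path):
        probes = self.make_probes(96)
        df = write_order_sheet(probes, tmp_path / "order.tsv",
                               fasta_path=tmp_path / "order.fa")
        assert len(df) == 96
        assert df["well"].iloc[0] == "A1"
        assert df["well"].iloc[-1] == "H12"
        back = read_order_sheet(tmp_path / "order.tsv")
        assert list(back["sequence"]) == [p.probe_seq for p in probes]
        assert (tmp_path / "order.fa").read_text().count(">") == 96

    def test_empty_probe_list_raises(self, tmp_path):
        with pytest.raises(ValueError):
            write_order_sheet([], tmp_path / "order.tsv")
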