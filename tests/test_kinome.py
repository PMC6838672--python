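"""Target design: FASTA parsing, segment location, digestion, accessibility."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tloopsrm.kinome import (KinaseRecord, KinomeError, SegmentNotFoundError,
                             SegmentParams, TargetParams, design_targets,
                             digest, locate_activation_segment, read_kinome)

AA = "ACDEFGHIKLMNPQRSTVWY"
PERMISSIVE = SegmentParams(min_gap=0, max_gap=60)


def brute_force_digest(sequence: str, enzymes, max_missed: int) -> set:
    """Independent oracle: enumerate all substrings between cleavage points."""
    cuts = set()
    for i in range(1, len(sequence)):
        prev, nxt = sequence[i - 1], sequence[i]
        if "trypsin" in enzymes and prev in "KR" and nxt != "P":
            cuts.add(i)
        if "lysC" in enzymes and prev == "K":
            cuts.add(i)
    bounds = [0, *sorted(cuts), len(sequence)]
    out = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            if j - i - 1 <= max_missed:
                out.add((sequence[bounds[i]:bounds[j]], bounds[i] + 1, j - i - 1))
    return out


class TestReadKinome:
    def test_two_entries_roundtrip(self, tmp_path):
        fasta = tmp_path / "k.fasta"
        fasta.write_text(">KIN001 GENE1\nMKTAYIAK\n>sp|P04049|RAF1_HUMAN x GN=RAF1\nMEHIQGAWK\n")
        records = read_kinome(fasta)
        assert [r.kinase_id for r in records] == ["KIN001", "P04049"]
        assert [r.gene for r in records] == ["GENE1", "RAF1"]
        assert [len(r.sequence) for r in records] == [8, 9]

    def test_digit_in_sequence_rejected(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        fasta.write_text(">K1 G1\nMKT4YIAK\n")
        with pytest.raises(KinomeError, match="K1"):
            read_kinome(fasta)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        with caplog.at_level("WARNING"):
            assert read_kinome(fasta) == []
        assert any("no FASTA records" in m for m in caplog.messages)

    def test_annotation_sidecar_sets_segment_span(self, tmp_path):
        fasta = tmp_path / "k.fasta"
        fasta.write_text(">K1 G1\nMKTAYIAKDFGAPE\n")
        ann = tmp_path / "ann.tsv"
        ann.write_text("kinase_id\tsegment_start\tsegment_end\nK1\t3\t8\n")
        (rec,) = read_kinome(fasta, ann)
        assert rec.segment_span == (3, 8)
        # externally supplied spans bypass motif search entirely
        assert locate_activation_segment(rec) == (3, 8)


class TestLocateSegment:
    def test_constructed_interval(self):
        rec = KinaseRecord("X", "X", "AAADFGLARTSAPEAAA")
        assert locate_activation_segment(rec, PERMISSIVE) == (4, 14)

    def test_missing_ape_downstream(self):
        rec = KinaseRecord("X", "X", "AAADFGLARTSAAA")
        with pytest.raises(SegmentNotFoundError):
            locate_activation_segment(rec, PERMISSIVE)

    def test_second_dfg_wins_when_first_has_no_valid_ape(self):
        # first DFG: gap to APE too long; second DFG within bounds
        seq = "DFG" + "A" * 50 + "DFG" + "C" * 20 + "APE"
        rec = KinaseRecord("X", "X", seq)
        params = SegmentParams(min_gap=15, max_gap=40)
        start, end = locate_activation_segment(rec, params)
        assert start == 54  # second DFG
        assert end == len(seq)
        # brute-force oracle: first (dfg, ape) pair in scan order with valid gap
        pairs = [
            (d.start() + 1, a.end())
            for d in re.finditer("DFG", seq)
            for a in re.finditer("APE", seq)
            if 15 <= a.start() - d.end() <= 40
        ]
        assert (start, end) == pairs[0]

    def test_fallback_patterns_apply(self):
        seq = "AAADWGLLL" + "A" * 15 + "APDAAA"
        rec = KinaseRecord("X", "X", seq)
        start, end = locate_activation_segment(
            rec, SegmentParams(min_gap=10, max_gap=40))
        assert seq[start - 1:start + 2] == "DWG"
        assert seq[end - 3:end] == "APD"

    @given(prefix_len=st.integers(min_value=0, max_value=30))
    @settings(max_examples=25, deadline=None)
    def test_position_equivariance(self, prefix_len):
        base = "DFG" + "L" * 20 + "APE"
        rec0 = KinaseRecord("X", "X", base)
        recn = KinaseRecord("X", "X", "A" * prefix_len + base)
        s0, e0 = locate_activation_segment(rec0, PERMISSIVE)
        sn, en = locate_activation_segment(recn, PERMISSIVE)
        assert (sn, en) == (s0 + prefix_len, e0 + prefix_len)


class TestDigest:
    @pytest.mark.parametrize("seq,enzymes,max_missed,expected", [
        ("GHLSEGLVTKR", {"trypsin"}, 0, ["GHLSEGLVTK", "R"]),
        ("AKPR", {"trypsin"}, 0, ["AKPR"]),
        ("AKPR", {"trypsin", "lysC"}, 0, ["AK", "PR"]),
    ])
    def test_cleavage_rules(self, seq, enzymes, max_missed, expected):
        assert [p.sequence for p in digest(seq, enzymes, max_missed)] == expected

    def test_missed_cleavage_enumeration(self):
        peps = digest("KRK", {"trypsin"}, 1)
        by_missed = {}
        for p in peps:
            by_missed.setdefault(p.missed_cleavages, set()).add(p.sequence)
        assert by_missed[0] == {"K", "R"}  # the two K's give the same string
        assert sum(1 for p in peps if p.missed_cleavages == 0) == 3
        assert by_missed[1] == {"KR", "RK"}

    def test_errors(self):
        with pytest.raises(KinomeError):
            digest("", {"trypsin"})
        with pytest.raises(KinomeError):
            digest("AK", {"pepsin"})

    @given(seq=st.text(alphabet=AA, min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_zero_missed_concatenation_reconstructs_sequence(self, seq):
        peps = [p for p in digest(seq, {"trypsin"}, 0)]
        assert "".join(p.sequence for p in peps) == seq

    @given(seq=st.text(alphabet=AA, min_size=1, max_size=30),
           max_missed=st.integers(min_value=0, max_value=3),
           lysc=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, seq, max_missed, lysc):
        enzymes = {"trypsin", "lysC"} if lysc else {"trypsin"}
        got = {(p.sequence, p.start, p.missed_cleavages)
               for p in digest(seq, enzymes, max_missed)}
        assert got == brute_force_digest(seq, enzymes, max_missed)


class TestDesignTargets:
    def test_single_and_double_phospho_forms(self, toy_kinase):
        targets, report = design_targets([toy_kinase])
        mine = [t for t in targets if t.backbone == "GHLSEGLVTK"]
        position_sets = {tuple(sorted(t.phospho_positions)) for t in mine}
        assert {(4,), (9,), (4, 9)} <= position_sets
        assert report.empty
        labels = set().union(*(t.site_labels for t in mine))
        assert {"TOY1_S16", "TOY1_T21"} <= labels

    def test_every_target_maps_to_a_segment_site(self, toy_kinase):
        targets, _ = design_targets([toy_kinase])
        seg = locate_activation_segment(toy_kinase)
        for t in targets:
            for k in t.kinase_ids:
                assert k == toy_kinase.kinase_id
            # at least one phospho position is an S/T/Y inside the segment
            starts = [m.start() + 1 for m in re.finditer(
                re.escape(t.backbone), toy_kinase.sequence)]
            assert any(
                seg[0] <= start + p - 1 <= seg[1]
                for start in starts for p in t.phospho_positions)

    def test_inaccessible_peptide_reported(self):
        # segment present but its only site sits on a 45-mer with no K/R
        seq = "AAK" + "DFG" + "A" * 10 + "S" + "A" * 24 + "APE" + "AAK"
        rec = KinaseRecord("K1", "G1", seq)
        targets, report = design_targets([rec])
        assert targets == []
        assert list(report["reason"]) == ["no accessible peptide"]

    def test_shared_peptide_merges_kinase_ids(self, toy_kinase):
        other = KinaseRecord("KIN002", "TOY2",
                             toy_kinase.sequence.replace("MAAAAK", "MCCCCK"))
        targets, _ = design_targets([toy_kinase, other])
        mine = [t for t in targets if t.backbone == "GHLSEGLVTK"
                and t.phospho_positions == frozenset({4})]
        assert len(mine) == 1
        assert mine[0].kinase_ids == frozenset({"KIN001", "KIN002"})

    def test_multiplicity_one_only(self, toy_kinase):
        targets, _ = design_targets(
            [toy_kinase], TargetParams(multiplicities=(1,)))
        assert all(t.multiplicity == 1 for t in targets)
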