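"""Masses, fragment ions, collision energy and transition selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyt_mass

from tloopsrm.assay import (AssayError, AssayParams, ModifiedPeptide,
                            build_assay, collision_energy, fragment_mz,
                            peptide_neutral_mass, precursor_mz,
                            site_determining_ions, transitions_to_frame)
from tloopsrm.constants import (HEAVY_LABEL, NEUTRAL_LOSS_H3PO4, PHOSPHO,
                                PROTON, WATER)

from conftest import make_target

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_peptide_mz(seq, n_phospho=0, label_mass=0.0, charge=1):
    """Independent route: pyteomics neutral mass + explicit mod masses."""
    neutral = pyt_mass.fast_mass(seq, ion_type="M", charge=0)
    neutral += PHOSPHO * n_phospho + label_mass
    return (neutral + charge * PROTON) / charge


class TestPrecursorMz:
    def test_phosphopeptide_light_2plus(self):
        pep = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "light", 2)
        assert precursor_mz(pep) == pytest.approx(560.7735, abs=1e-3)
        # independent pyteomics route; constants differ below 1e-4 Th
        assert precursor_mz(pep) == pytest.approx(
            oracle_peptide_mz("GHLSEGLVTK", 1, 0.0, 2), abs=1e-4)

    def test_heavy_shifts_by_label_over_charge(self):
        light = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "light", 2)
        heavy = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "heavy", 2)
        assert precursor_mz(heavy) == pytest.approx(564.7806, abs=1e-3)
        assert precursor_mz(heavy) - precursor_mz(light) == pytest.approx(
            HEAVY_LABEL["K"] / 2, abs=1e-12)

    def test_single_glycine(self):
        pep = ModifiedPeptide("G", frozenset(), "light", 1)
        assert precursor_mz(pep) == pytest.approx(76.0393, abs=1e-3)

    def test_heavy_requires_cterm_kr(self):
        with pytest.raises(AssayError, match="C-terminal"):
            ModifiedPeptide("GHLSEGLVTA", frozenset(), "heavy", 2)


class TestFragmentMz:
    def test_y1_lysine(self):
        pep = ModifiedPeptide("AK", frozenset(), "light", 2)
        assert fragment_mz(pep, "y", 1) == pytest.approx(147.1128, abs=1e-3)

    def test_b2_gh(self):
        pep = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "light", 2)
        assert fragment_mz(pep, "b", 2) == pytest.approx(195.0877, abs=1e-3)

    def test_neutral_loss_is_fixed_mass_difference(self):
        pep = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "light", 2)
        with_loss = fragment_mz(pep, "y", 7, 1, neutral_loss=True)
        without = fragment_mz(pep, "y", 7, 1, neutral_loss=False)
        assert without - with_loss == pytest.approx(NEUTRAL_LOSS_H3PO4, abs=1e-9)

    def test_neutral_loss_requires_phospho_on_fragment(self):
        pep = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "light", 2)
        with pytest.raises(AssayError, match="no phosphate"):
            fragment_mz(pep, "y", 3, 1, neutral_loss=True)  # y3 = VTK

    def test_heavy_label_rides_on_y_not_b(self):
        light = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "light", 2)
        heavy = ModifiedPeptide("GHLSEGLVTK", frozenset({4}), "heavy", 2)
        assert fragment_mz(heavy, "y", 5) - fragment_mz(light, "y", 5) == \
            pytest.approx(HEAVY_LABEL["K"], abs=1e-12)
        assert fragment_mz(heavy, "b", 5) == fragment_mz(light, "b", 5)

    @given(seq=st.text(alphabet=AA, min_size=2, max_size=20),
           data=st.data())
    @settings(max_examples=200, deadline=None)
    def test_by_complementarity(self, seq, data):
        """mz(b_i) + mz(y_{n-i}) == neutral mass + 2 protons, any mods."""
        sty = [i + 1 for i, aa in enumerate(seq) if aa in "STY"]
        positions = frozenset(
            data.draw(st.sets(st.sampled_from(sty), max_size=2))) if sty \
            else frozenset()
        label = "heavy" if seq[-1] in "KR" and data.draw(st.booleans()) \
            else "light"
        pep = ModifiedPeptide(seq, positions, label, 2)
        n = len(seq)
        i = data.draw(st.integers(min_value=1, max_value=n - 1))
        total = fragment_mz(pep, "b", i) + fragment_mz(pep, "y", n - i)
        assert total == pytest.approx(
            peptide_neutral_mass(pep) + 2 * PROTON, abs=1e-9)


class TestCollisionEnergy:
    @pytest.mark.parametrize("mz,z,expected", [
        (500.0, 2, 17.905),
        (700.0, 3, 28.881),
        (700.0, 4, 28.881),   # same branch as charge 3
    ])
    def test_charge_branches(self, mz, z, expected):
        assert collision_energy(mz, z) == pytest.approx(expected, abs=1e-9)

    def test_charge_below_two_rejected(self):
        with pytest.raises(AssayError):
            collision_energy(500.0, 1)

    def test_continuous_and_offset(self):
        assert collision_energy(500.0, 2, offset=1.5) == pytest.approx(19.405)
        for z in (3, 4, 5):
            assert collision_energy(650.0, z) == collision_energy(650.0, 3)


class TestSiteDeterminingIons:
    def test_two_sites_exhaustive(self):
        got = set(site_determining_ions("GHLSEGLVTK", {4, 9}))
        # oracle: enumerate ion spans and keep proper-subset coverage
        expected = set()
        n = 10
        for i in range(1, n):
            cov = {p for p in (4, 9) if p <= i}
            if cov and cov != {4, 9}:
                expected.add(("b", i))
        for j in range(1, n):
            cov = {p for p in (4, 9) if p >= n - j + 1}
            if cov and cov != {4, 9}:
                expected.add(("y", j))
        assert got == expected
        assert {("b", 4), ("b", 8), ("y", 2), ("y", 6)} <= got

    def test_single_candidate_yields_nothing(self):
        assert site_determining_ions("GHLSEGLVTK", {4}) == []

    def test_adjacent_candidates_single_cut(self):
        got = set(site_determining_ions("GHLSTGLVAK", {4, 5}))
        assert got == {("b", 4), ("y", 6)}

    def test_non_sty_candidate_rejected(self):
        with pytest.raises(AssayError):
            site_determining_ions("GHLSEGLVTK", {1})


class TestBuildAssay:
    def test_survey_mode_three_transitions_per_precursor(self, toy_target):
        assay = build_assay(toy_target, mode="survey")
        for z in assay.precursor_charges:
            for label in ("light", "heavy"):
                assert len(assay.channel(label, z)) == 3

    def test_quantification_mode_caps_at_seven_with_site_determining(self):
        target = make_target("GHLSEGLVTK", {4}, {"K1"})
        assay = build_assay(target, mode="quantification")
        for z in assay.precursor_charges:
            ch = assay.channel("light", z)
            assert len(ch) <= 7
            assert any(t.site_determining for t in ch)

    def test_light_heavy_share_annotations(self, toy_target):
        assay = build_assay(toy_target, mode="quantification")
        for z in assay.precursor_charges:
            light = [t.annotation for t in assay.channel("light", z)]
            heavy = [t.annotation for t in assay.channel("heavy", z)]
            assert light == heavy

    def test_library_ranks_steer_selection(self, toy_target):
        ranks = {"b3": 100.0, "b4": 90.0, "b5": 80.0}
        assay = build_assay(toy_target, mode="survey", library_ranks=ranks)
        chosen = {t.annotation for t in assay.channel("light", 2)}
        assert chosen == {"b3", "b4", "b5"}

    def test_default_ranking_prefers_long_y_ions(self, toy_target):
        assay = build_assay(toy_target, mode="survey")
        chosen = [t for t in assay.channel("light", 2)]
        assert all(t.ion_type == "y" for t in chosen)
        assert max(t.ion_index for t in chosen) == len(toy_target.backbone) - 1

    def test_ce_follows_charge_branch(self, toy_target):
        assay = build_assay(toy_target, mode="survey")
        for t in assay.transitions:
            assert t.collision_energy == pytest.approx(
                collision_energy(t.precursor_mz, t.precursor_charge))

    def test_nontryptic_cterm_rejected(self):
        target = make_target("GHLSEGLVTA", {4}, {"K1"})
        object.__setattr__(target, "tryptic_cterm", False)
        with pytest.raises(AssayError):
            build_assay(target)

    def test_very_short_peptide_emits_what_exists(self, caplog):
        target = make_target("ASK", {2}, {"K1"})
        with caplog.at_level("WARNING"):
            assay = build_assay(target, mode="survey")
        assert len(assay.channel("light", 2)) >= 1

    def test_transition_export_columns(self, toy_target):
        df = transitions_to_frame([build_assay(toy_target, "survey")])
        assert {"modified_sequence", "precursor_mz", "product_mz",
                "annotation", "collision_energy"} <= set(df.columns)
        assert df["modified_sequence"].str.contains(r"\[\+80\]").all()
        heavy = df[df["label"] == "heavy"]
        assert heavy["modified_sequence"].str.endswith("[+8]").all()
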