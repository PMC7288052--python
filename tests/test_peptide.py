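"""Sequence representation, homologation scan and exact-mass arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betascan.peptide import (
    CH2_MASS,
    FREE_AA_FORMULA,
    PROTON_MASS,
    TAPP,
    BackboneClass,
    CTerminus,
    HomologationError,
    MolecularFormula,
    PeptideSequence,
    Residue,
    ScanSpec,
    Stereo,
    UnknownSideChainError,
    enumerate_scan,
    homologate,
    molecular_formula,
    monoisotopic_mass,
    tapp_scan_spec,
)


class TestMolecularFormula:
    def test_parse_and_str_round_trip(self):
        f = MolecularFormula.parse("C30H35N5O5")
        assert f["C"] == 30 and f["H"] == 35 and f["N"] == 5 and f["O"] == 5
        assert str(f) == "C30H35N5O5"

    def test_arithmetic_is_elementwise(self):
        a = MolecularFormula.parse("C2H5NO2")
        b = MolecularFormula.parse("H2O")
        assert str(a + b) == "C2H7NO3"
        assert str(a - b) == "C2H3NO"

    def test_subtraction_below_zero_rejected(self):
        with pytest.raises(ValueError):
            MolecularFormula.parse("H2O") - MolecularFormula.parse("C")


class TestMolecularFormulaOfPeptides:
    def test_tapp_formula(self):
        assert str(molecular_formula(TAPP)) == "C30H35N5O5"

    def test_single_glycine_amide_hand_sum(self):
        # glycine C2H5NO2, amide end: -OH +NH2 -> C2H6N2O
        seq = PeptideSequence((Residue("Gly", stereo=Stereo.ACHIRAL),))
        assert str(molecular_formula(seq)) == "C2H6N2O"

    def test_acid_terminus_keeps_free_acid_composition(self):
        seq = PeptideSequence(
            (Residue("Gly", stereo=Stereo.ACHIRAL),), c_terminus=CTerminus.ACID
        )
        assert str(molecular_formula(seq)) == "C2H5NO2"

    def test_every_beta2h_analogue_is_parent_plus_ch2(self):
        parent = molecular_formula(TAPP)
        for ana in enumerate_scan(TAPP, tapp_scan_spec()):
            assert ana.formula - parent == MolecularFormula.parse("CH2")


class TestMonoisotopicMass:
    def test_tapp_protonated_ion(self):
        f = MolecularFormula.parse("C30H35N5O5")
        assert monoisotopic_mass(f, "M+H") == pytest.approx(546.2711, abs=5e-5)

    def test_homologated_protonated_ion(self):
        f = MolecularFormula.parse("C31H37N5O5")
        assert monoisotopic_mass(f, "M+H") == pytest.approx(560.2867, abs=5e-5)

    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass(MolecularFormula({})) == 0.0

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError):
            monoisotopic_mass(MolecularFormula({"Xx": 1}))

    def test_adduct_increment_is_one_proton(self):
        f = MolecularFormula.parse("C30H35N5O5")
        delta = monoisotopic_mass(f, "M+H") - monoisotopic_mass(f)
        assert delta == pytest.approx(PROTON_MASS, abs=1e-4)


class TestHomologate:
    def test_position4_formula(self):
        ana = homologate(TAPP, 4, BackboneClass.BETA2H, Stereo.R)
        assert str(ana.formula) == "C31H37N5O5"
        assert ana.name == "[(R)-β2hPhe4]-TAPP"
        assert not ana.tentative

    def test_position2_name(self):
        ana = homologate(TAPP, 2, BackboneClass.BETA2H, Stereo.S)
        assert ana.name == "[(S)-β2hAla2]-TAPP"

    def test_meta_tyr_override_is_tentative(self):
        ana = homologate(
            TAPP, 1, BackboneClass.BETA2H, Stereo.R, side_chain_override="mTyr"
        )
        assert ana.name == "[(R)-β2h-m-Tyr1]-TAPP"
        assert ana.tentative
        assert ana.display_name.endswith("*")

    def test_differs_from_parent_only_at_position(self):
        ana = homologate(TAPP, 3, BackboneClass.BETA2H, Stereo.S)
        for i, (old, new) in enumerate(
            zip(TAPP.residues, ana.sequence.residues), start=1
        ):
            if i == 3:
                assert new.backbone_class is BackboneClass.BETA2H
            else:
                assert old == new

    @pytest.mark.parametrize("position", [0, 5])
    def test_invalid_position_rejected(self, position):
        with pytest.raises(HomologationError):
            homologate(TAPP, position)

    def test_double_homologation_rejected(self):
        once = homologate(TAPP, 4).sequence
        with pytest.raises(HomologationError):
            homologate(once, 4)

    def test_unknown_side_chain_rejected(self):
        with pytest.raises(UnknownSideChainError):
            homologate(TAPP, 1, side_chain_override="Xyz")

    def test_ascii_naming_option(self):
        ana = homologate(TAPP, 4, stereo=Stereo.S)
        assert ana.name_ascii() == "[(S)-b2hPhe4]-TAPP"


class TestEnumerateScan:
    def test_full_tapp_scan_has_ten_unique_analogues(self):
        analogues = enumerate_scan(TAPP, tapp_scan_spec())
        assert len(analogues) == 10
        assert len({a.name for a in analogues}) == 10

    def test_empty_spec_yields_empty_list(self):
        assert enumerate_scan(TAPP, ScanSpec(positions=frozenset())) == []

    def test_single_position_both_stereo(self):
        spec = ScanSpec(positions=frozenset({4}))
        names = [a.name for a in enumerate_scan(TAPP, spec)]
        assert names == ["[(R)-β2hPhe4]-TAPP", "[(S)-β2hPhe4]-TAPP"]

    def test_output_size_formula(self):
        spec = tapp_scan_spec()
        expected = sum(
            len(spec.stereo_set) * (1 + len(spec.side_chain_variants.get(p, ())))
            for p in spec.positions
        )
        assert len(enumerate_scan(TAPP, spec)) == expected == 10

    def test_deterministic_order(self):
        a = [x.name for x in enumerate_scan(TAPP, tapp_scan_spec())]
        b = [x.name for x in enumerate_scan(TAPP, tapp_scan_spec())]
        assert a == b
        assert a[0].startswith("[(R)-β2hTyr1")  # position 1, base chain, R first

    def test_every_analogue_mass_shift_is_one_ch2(self):
        parent_mh = monoisotopic_mass(molecular_formula(TAPP), "M+H")
        for ana in enumerate_scan(TAPP, tapp_scan_spec()):
            assert ana.mass_mh - parent_mh == pytest.approx(CH2_MASS, abs=1e-3)


class TestResidueInvariants:
    def test_rs_label_on_achiral_residue_rejected(self):
        with pytest.raises(ValueError):
            Residue("Gly", stereo=Stereo.R)

    def test_beta_residue_formula_is_alpha_plus_ch2(self):
        for sc in FREE_AA_FORMULA:
            alpha = Residue(sc, stereo=Stereo.ACHIRAL if sc == "Gly" else Stereo.L)
            stereo = Stereo.ACHIRAL if sc == "Gly" else Stereo.R
            for cls in (BackboneClass.BETA2H, BackboneClass.BETA3H):
                beta = Residue(sc, backbone_class=cls, stereo=stereo)
                assert beta.formula - alpha.formula == MolecularFormula.parse("CH2")


@given(
    pos=st.integers(min_value=1, max_value=4),
    stereo=st.sampled_from([Stereo.R, Stereo.S]),
)
@settings(derandomize=True, max_examples=20)
def test_formula_arithmetic_order_independent(pos, stereo):
    """Homologating then deriving the formula equals parent formula + CH2."""
    ana = homologate(TAPP, pos, BackboneClass.BETA2H, stereo)
    assert molecular_formula(ana.sequence) == molecular_formula(TAPP) + MolecularFormula.parse("CH2")
    assert ana.mass_mh - monoisotopic_mass(molecular_formula(TAPP), "M+H") == pytest.approx(
        CH2_MASS, abs=1e-3
    )
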