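"""Unit and property tests for the per-composition chemistry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commchem.chem import (
    AminoAcidComposition,
    BasisSet,
    ElementalComposition,
    QEC_BASIS,
    UndefinedMetricError,
    UnknownAminoAcidError,
    _net_charge,
    aa_to_elements,
    basis_projection,
    gravy,
    isoelectric_point,
    metrics_suite,
    zc,
)
from commchem.constants import AA_CODES


def elems(ec):
    return (ec.c, ec.h, ec.n, ec.o, ec.s)


@st.composite
def compositions(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    codes = draw(st.lists(st.sampled_from(AA_CODES), min_size=n, max_size=n, unique=True))
    counts = draw(
        st.lists(
            st.floats(min_value=0.1, max_value=50, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    chains = draw(st.floats(min_value=0.1, max_value=5))
    return AminoAcidComposition(dict(zip(codes, counts)), chains=chains)


class TestElementalComposition:
    @pytest.mark.parametrize(
        "counts,terminal,expected",
        [
            ({"Gly": 1}, True, (2, 5, 1, 2, 0)),  # free glycine
            ({"Gly": 1}, False, (2, 3, 1, 1, 0)),  # glycine residue
            ({"Gly": 1, "Ala": 1}, True, (5, 10, 2, 3, 0)),  # Gly-Ala dipeptide
        ],
    )
    def test_residue_sums(self, counts, terminal, expected):
        ec = aa_to_elements(AminoAcidComposition(counts), include_terminal_water=terminal)
        assert elems(ec) == pytest.approx(expected)
        assert ec.z == 0

    def test_unknown_code_is_named(self):
        with pytest.raises(UnknownAminoAcidError, match="Xyz"):
            AminoAcidComposition({"Xyz": 1})

    def test_empty_composition_rejected(self):
        with pytest.raises(UndefinedMetricError):
            aa_to_elements(AminoAcidComposition({}))

    def test_one_and_three_letter_codes_pool(self):
        aa = AminoAcidComposition({"G": 1, "Gly": 2})
        assert aa.counts == {"Gly": 3.0}


class TestZc:
    @pytest.mark.parametrize(
        "ec,expected",
        [
            (ElementalComposition(2, 5, 1, 2, 0), 1.0),  # glycine
            (ElementalComposition(5, 11, 1, 2, 1), -0.4),  # methionine
            (ElementalComposition(1, 0, 0, 2, 0), 4.0),  # CO2
        ],
    )
    def test_known_values(self, ec, expected):
        assert zc(ec) == pytest.approx(expected)

    def test_requires_carbon(self):
        with pytest.raises(UndefinedMetricError):
            zc(ElementalComposition(0, 2, 0, 1, 0))

    @given(compositions())
    @settings(max_examples=50, deadline=None)
    def test_terminal_water_invariance(self, aa):
        assert zc(aa_to_elements(aa, True)) == pytest.approx(
            zc(aa_to_elements(aa, False)), abs=1e-12
        )


class TestBasisProjection:
    @pytest.mark.parametrize(
        "ec,expected",
        [
            (ElementalComposition(5, 10, 2, 3, 0), (0.0, 0.0)),  # glutamine: a basis species
            (ElementalComposition(2, 3, 1, 1, 0), (-0.6, 0.3)),  # glycine residue
            (ElementalComposition(2, 5, 1, 2, 0), (0.4, 0.3)),  # free glycine
        ],
    )
    def test_known_values(self, ec, expected):
        nh2o, no2 = basis_projection(ec, n_residues=1)
        assert (nh2o, no2) == pytest.approx(expected, abs=1e-12)

    def test_terminal_water_shifts_nh2o_by_one(self):
        aa = AminoAcidComposition({"Gly": 1})
        with_w = basis_projection(aa_to_elements(aa, True), 1)
        without = basis_projection(aa_to_elements(aa, False), 1)
        assert with_w[0] - without[0] == pytest.approx(1.0)
        assert with_w[1] == pytest.approx(without[1])  # nO2 unaffected

    @given(compositions())
    @settings(max_examples=50, deadline=None)
    def test_element_balance_reconstruction(self, aa):
        ec = aa_to_elements(aa)
        coeffs = np.linalg.solve(QEC_BASIS.matrix(), ec.as_vector())
        rebuilt = QEC_BASIS.matrix() @ coeffs
        assert np.allclose(rebuilt, ec.as_vector(), atol=1e-9)

    def test_singular_basis_rejected(self):
        water = ElementalComposition(0, 2, 0, 1, 0)
        o2 = ElementalComposition(0, 0, 0, 2, 0)
        with pytest.raises(ValueError, match="singular"):
            BasisSet(species=(("a", water), ("b", water), ("c", water), ("H2O", water), ("O2", o2)))


class TestGravy:
    @pytest.mark.parametrize(
        "counts,expected",
        [({"Ala": 5}, 1.8), ({"Ile": 1, "Val": 1}, 4.35), ({"Arg": 2}, -4.5)],
    )
    def test_known_values(self, counts, expected):
        assert gravy(AminoAcidComposition(counts)) == pytest.approx(expected)

    def test_matches_protparam(self):
        # independent oracle: Biopython's ProtParam uses the same published scale
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(5)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            seq = "".join(rng.choice(list(letters), size=60))
            ours = gravy(AminoAcidComposition.from_sequence(seq))
            assert ours == pytest.approx(ProteinAnalysis(seq).gravy(), abs=1e-9)


class TestIsoelectricPoint:
    def test_two_group_midpoint(self):
        # triglycine: only the termini ionize, so pI is the pK midpoint
        pi = isoelectric_point(AminoAcidComposition({"Gly": 3}))
        assert pi == pytest.approx((7.5 + 3.55) / 2, abs=0.01)

    @pytest.mark.parametrize(
        "counts,bound,side",
        [({"Asp": 4, "Gly": 4}, 4.05, "below"), ({"Lys": 4, "Gly": 4}, 10.0, "above")],
    )
    def test_charged_compositions(self, counts, bound, side):
        aa = AminoAcidComposition(counts)
        pi = isoelectric_point(aa)
        assert pi < bound if side == "below" else pi > bound
        assert abs(_net_charge(aa, pi)) < 1e-4

    @given(compositions())
    @settings(max_examples=50, deadline=None)
    def test_root_bracketing(self, aa):
        pi = isoelectric_point(aa)
        assert 0 <= pi <= 14
        if 1 <= pi <= 13:
            assert _net_charge(aa, pi - 1) > 0 > _net_charge(aa, pi + 1)

    def test_no_ionizable_groups_rejected(self):
        with pytest.raises(UndefinedMetricError):
            isoelectric_point(AminoAcidComposition({"Ala": 3}, chains=0))


class TestMetricsSuite:
    def test_worked_values(self):
        aa = AminoAcidComposition({"Gly": 10})
        assert metrics_suite(aa, which=["length"])["length"] == pytest.approx(10)
        one = metrics_suite(AminoAcidComposition({"Gly": 1}), which=["H/C", "O/C", "MW"])
        assert one["H/C"] == pytest.approx(1.5)
        assert one["O/C"] == pytest.approx(0.5)
        assert one["MW"] == pytest.approx(57.05, abs=0.01)

    def test_unknown_metric_lists_valid_names(self):
        with pytest.raises(ValueError, match="valid metrics"):
            metrics_suite(AminoAcidComposition({"Gly": 1}), which=["entropy"])

    def test_metric_names_case_insensitive(self):
        out = metrics_suite(AminoAcidComposition({"Gly": 2}), which=["zc", "NH2O"])
        assert set(out) == {"Zc", "nH2O"}

    @given(compositions(), st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity_under_scaling(self, aa, k):
        base = metrics_suite(aa)
        scaled = metrics_suite(aa.scaled(k))
        for name, value in base.items():
            assert scaled[name] == pytest.approx(value, rel=1e-9, abs=1e-9), name

    def test_sequence_oracle_equivalence(self):
        seq = "GAVLIMFWPSTCYNQDEKRH"
        by_seq = metrics_suite(AminoAcidComposition.from_sequence(seq))
        by_hand = metrics_suite(AminoAcidComposition({c: 1 for c in AA_CODES}))
        for name, value in by_seq.items():
            assert by_hand[name] == pytest.approx(value, abs=1e-9), name


def test_zc_no2_covariation():
    """Zc and nO2 strongly covary across random compositions."""
    rng = np.random.default_rng(42)
    zcs, no2s = [], []
    for _ in range(1000):
        vec = rng.dirichlet(np.ones(20)) * 100
        aa = AminoAcidComposition(dict(zip(AA_CODES, vec)))
        out = metrics_suite(aa, which=["Zc", "nO2"])
        zcs.append(out["Zc"])
        no2s.append(out["nO2"])
    r = np.corrcoef(zcs, no2s)[0, 1]
    assert r >= 0.8
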