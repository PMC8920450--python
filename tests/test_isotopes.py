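"""Unit and property tests for the mass-isotopomer forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from midaflux.isotopes import (
    ElementalComposition,
    IsotopeTable,
    LabelingParameters,
    MassIsotopomerDistribution,
    composition_from_sequence,
    default_residue_sites,
    em_asymptote,
    excess_distribution,
    labeled_distribution,
    labeling_sites,
    mida_curve,
    natural_distribution,
)

from oracle import envelope_multinomial, envelope_per_atom, labeled_envelope_binomial

# independent residue-formula oracle (standard amino-acid residue compositions)
RESIDUE_FORMULAS = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1}, "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2}, "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1}, "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}, "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1}, "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3}, "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1}, "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}, "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1}, "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2}, "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def oracle_composition(seq: str) -> dict:
    out = {"H": 2, "O": 1}  # terminal water
    for ch in seq:
        for el, c in RESIDUE_FORMULAS[ch].items():
            out[el] = out.get(el, 0) + c
    return out


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("G", {"C": 2, "H": 5, "N": 1, "O": 2}),
            ("GG", {"C": 4, "H": 8, "N": 2, "O": 3}),
            ("AG", {"C": 5, "H": 10, "N": 2, "O": 3}),
        ],
    )
    def test_small_peptides(self, seq, expected):
        assert composition_from_sequence(seq).counts == expected

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet=sorted(RESIDUE_FORMULAS), min_size=1, max_size=30))
    def test_matches_residue_formula_oracle(self, seq):
        comp = composition_from_sequence(seq)
        assert comp.counts == oracle_composition(seq)

    def test_unknown_residue_names_character_and_position(self):
        with pytest.raises(ValueError, match=r"'B' at position 3"):
            composition_from_sequence("GGBG")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_from_sequence("")

    def test_carbamidomethyl_adds_adduct_per_cysteine(self):
        plain = composition_from_sequence("CC").counts
        mod = composition_from_sequence("CC", carbamidomethyl=True).counts
        assert mod["C"] == plain["C"] + 4 and mod["N"] == plain["N"] + 2

    def test_composition_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            ElementalComposition({})
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})


class TestLabelingSites:
    def test_zero_table_gives_zero(self):
        assert labeling_sites("GAVL", dict.fromkeys("GAVL", 0.0)) == 0.0

    def test_single_residue_identity(self):
        assert labeling_sites("A", {"A": 4.0}) == 4.0

    def test_gg_sums_table_values(self):
        assert labeling_sites("GG", {"G": 2.06}) == pytest.approx(4.12)

    def test_missing_residue_rejected(self):
        with pytest.raises(ValueError, match="'V'"):
            labeling_sites("GV", {"G": 2.06})

    def test_default_table_covers_all_residues(self):
        sites = default_residue_sites()
        assert set(sites) == set(RESIDUE_FORMULAS)
        assert all(v >= 0 for v in sites.values())


class TestNaturalDistribution:
    def test_single_carbon_reads_off_table(self, toy_table):
        d = natural_distribution(ElementalComposition({"C": 1}), toy_table, 1)
        assert d[0] == pytest.approx(0.9893) and d[1] == pytest.approx(0.0107)

    def test_two_carbons_binomial(self, toy_table):
        d = natural_distribution(ElementalComposition({"C": 2}), toy_table, 2)
        assert d[0] == pytest.approx(0.9893**2, abs=1e-12)
        assert d[1] == pytest.approx(2 * 0.9893 * 0.0107, abs=1e-12)

    def test_monoisotopic_elements_all_in_m0(self, toy_table):
        d = natural_distribution(ElementalComposition({"X": 7}), toy_table, 3)
        assert d.abundances == (1.0, 0.0, 0.0, 0.0)

    def test_element_missing_from_table_rejected(self, toy_table):
        with pytest.raises(ValueError, match="'N'"):
            natural_distribution(ElementalComposition({"N": 1}), toy_table, 2)

    def test_matches_enumeration_oracles(self, isotope_table):
        rng = np.random.default_rng(7)
        from oracle import random_composition

        for _ in range(20):
            counts = random_composition(rng, isotope_table.isotopes, max_atoms=12)
            got = natural_distribution(ElementalComposition(counts), isotope_table, 4).as_array()
            want = envelope_multinomial(counts, isotope_table.isotopes, 4)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_per_atom_and_multinomial_oracles_agree(self, isotope_table):
        counts = {"C": 3, "H": 2, "O": 2, "S": 1}
        a = envelope_per_atom(counts, isotope_table.isotopes, 4)
        b = envelope_multinomial(counts, isotope_table.isotopes, 4)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_raw_truncation_sums_below_one(self, isotope_table):
        comp = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY")
        d = natural_distribution(comp, isotope_table, 3)
        assert sum(d.abundances) < 1.0
        assert sum(d.renormalize().abundances) == pytest.approx(1.0, abs=1e-12)


class TestLabeledDistribution:
    def test_p_zero_matches_natural(self, isotope_table):
        comp = composition_from_sequence("GAVLK")
        nat = natural_distribution(comp, isotope_table, 3).as_array()
        lab = labeled_distribution(
            comp, LabelingParameters(p=0.0, n=10.0), isotope_table, 3
        ).as_array()
        np.testing.assert_allclose(lab, nat, atol=1e-12)

    def test_n_zero_matches_natural(self, isotope_table):
        comp = composition_from_sequence("GAVLK")
        nat = natural_distribution(comp, isotope_table, 3).as_array()
        lab = labeled_distribution(
            comp, LabelingParameters(p=0.05, n=0.0), isotope_table, 3
        ).as_array()
        np.testing.assert_allclose(lab, nat, atol=1e-12)

    def test_p_to_zero_limit(self, isotope_table):
        comp = composition_from_sequence("GAVLK")
        nat = natural_distribution(comp, isotope_table, 3).as_array()
        lab = labeled_distribution(
            comp, LabelingParameters(p=1e-12, n=20.0), isotope_table, 3
        ).as_array()
        assert np.max(np.abs(lab - nat)) < 1e-9

    def test_single_site_enumeration(self, toy_table):
        # one labelable H, one mono-isotopic X atom; natural 2H = 1e-4
        comp = ElementalComposition({"X": 1, "H": 1})
        lab = labeled_distribution(comp, LabelingParameters(p=0.05, n=1.0), toy_table, 1)
        p_eff = 0.05 + 1e-4
        assert lab[0] == pytest.approx(1 - p_eff, abs=1e-12)
        assert lab[1] == pytest.approx(p_eff, abs=1e-12)

    def test_n_exceeding_hydrogen_rejected(self, isotope_table):
        with pytest.raises(ValueError, match="exceed"):
            labeled_distribution(
                ElementalComposition({"C": 1, "H": 2}),
                LabelingParameters(p=0.05, n=3.0),
                isotope_table, 3,
            )

    def test_matches_binomial_oracle(self, isotope_table):
        counts = {"C": 16, "H": 32, "O": 2}
        p_eff = 0.05 + isotope_table.natural_h2()
        want = labeled_envelope_binomial(counts, 22, p_eff, isotope_table.isotopes, 4)
        got = labeled_distribution(
            ElementalComposition(counts), LabelingParameters(p=0.05, n=22.0),
            isotope_table, 4,
        ).as_array()
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_fractional_n_interpolates(self, isotope_table):
        comp = composition_from_sequence("GAVLK")
        mid = labeled_distribution(comp, LabelingParameters(0.05, 2.5), isotope_table, 3).as_array()
        lo = labeled_distribution(comp, LabelingParameters(0.05, 2.0), isotope_table, 3).as_array()
        hi = labeled_distribution(comp, LabelingParameters(0.05, 3.0), isotope_table, 3).as_array()
        np.testing.assert_allclose(mid, 0.5 * lo + 0.5 * hi, atol=1e-12)


class TestExcessDistribution:
    def test_identical_inputs_zero(self, isotope_table):
        comp = composition_from_sequence("GG")
        d = natural_distribution(comp, isotope_table, 3).renormalize()
        em = excess_distribution(d, d)
        assert all(v == 0 for v in em.values)

    def test_simple_subtraction(self):
        a = MassIsotopomerDistribution((0.90, 0.10), renormalized=True)
        b = MassIsotopomerDistribution((0.95, 0.05), renormalized=True)
        em = excess_distribution(a, b)
        assert em.values == pytest.approx((-0.05, 0.05))

    def test_sums_to_zero_for_renormalized_pairs(self, isotope_table):
        comp = composition_from_sequence("ACDEFGHIK")
        nat = natural_distribution(comp, isotope_table, 5).renormalize(3)
        lab = labeled_distribution(comp, LabelingParameters(0.05, 15.0), isotope_table, 5).renormalize(3)
        assert sum(excess_distribution(lab, nat).values) == pytest.approx(0.0, abs=1e-9)
        assert excess_distribution(lab, nat)[0] <= 0  # label always depletes M0

    def test_length_mismatch_rejected(self):
        a = MassIsotopomerDistribution((0.9, 0.1), renormalized=True)
        b = MassIsotopomerDistribution((0.8, 0.1, 0.1), renormalized=True)
        with pytest.raises(ValueError, match="mismatch"):
            excess_distribution(a, b)


class TestEmAsymptote:
    PALMITATE = ElementalComposition({"C": 16, "H": 32, "O": 2})

    def test_zero_at_p_zero(self, isotope_table):
        for ch in (1, 2, 3):
            assert em_asymptote(
                self.PALMITATE, LabelingParameters(0.0, 22.0), isotope_table, ch
            ) == pytest.approx(0.0, abs=1e-12)

    def test_em1_increases_with_n_for_palmitate(self, isotope_table):
        # EM1 rises with site count up to the binomial turnover near n ~ 1/p;
        # over the GC-MS channels (M0-M2) that covers the whole palmitate
        # regime (n = 22).  Beyond the turnover EM1 declines again as label
        # mass moves into M2+, so monotonicity is asserted on the valid range.
        values = [
            em_asymptote(self.PALMITATE, LabelingParameters(0.05, n), isotope_table, 1, k=2)
            for n in range(1, 24)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[0] > 0

    def test_em1_nondecreasing_in_p(self, isotope_table):
        # as with n, EM1 is monotone in p only while n * p stays below the
        # binomial mode; n = 4 keeps the whole design range [0, 0.08] valid
        comp = composition_from_sequence("GAVLKGAVLKGAVLK")
        values = [
            em_asymptote(comp, LabelingParameters(p, 4.0), isotope_table, 1)
            for p in np.linspace(0.0, 0.08, 9)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_em0_depletion_monotone_in_p_for_large_n(self, isotope_table):
        # the monoisotopic depletion -EM0 is monotone in p even where EM1 is
        # not, which is why the combined estimator is well-conditioned
        comp = composition_from_sequence("GAVLKGAVLKGAVLK")
        # -EM0 = EM1+EM2+EM3 since the excess vector sums to zero
        depletion = [
            sum(em_asymptote(comp, LabelingParameters(p, 20.0), isotope_table, ch, k=3)
                for ch in (1, 2, 3))
            for p in np.linspace(0.0, 0.08, 9)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(depletion, depletion[1:]))

    def test_palmitate_matches_enumeration_oracle(self, isotope_table):
        counts = {"C": 16, "H": 32, "O": 2}
        p_eff = 0.05 + isotope_table.natural_h2()
        k_int = 5
        nat = envelope_multinomial(counts, isotope_table.isotopes, k_int)
        lab = labeled_envelope_binomial(counts, 22, p_eff, isotope_table.isotopes, k_int)
        nat = nat[:4] / nat[:4].sum()
        lab = lab[:4] / lab[:4].sum()
        want = lab[1] - nat[1]
        got = em_asymptote(self.PALMITATE, LabelingParameters(0.05, 22.0), isotope_table, 1)
        assert got == pytest.approx(want, abs=1e-10)

    def test_invalid_channel_rejected(self, isotope_table):
        with pytest.raises(ValueError, match="channel"):
            em_asymptote(self.PALMITATE, LabelingParameters(0.05, 22.0), isotope_table, 0)


class TestMidaCurve:
    def test_zero_grid_gives_zero_coefficients(self, isotope_table):
        comp = composition_from_sequence("GAVLK")
        curve = mida_curve(comp, 10.0, isotope_table, 1, [0.0, 0.0, 0.0])
        assert curve.coefficients == (0.0, 0.0, 0.0)

    def test_fit_agrees_within_reported_deviation(self, isotope_table):
        comp = composition_from_sequence("GAVLKGAVLK")
        grid = [0.01, 0.02, 0.03, 0.04, 0.05]
        curve = mida_curve(comp, 15.0, isotope_table, 1, grid)
        for p in grid:
            direct = em_asymptote(comp, LabelingParameters(p, 15.0), isotope_table, 1)
            assert abs(curve(p) - direct) <= curve.max_abs_deviation + 1e-12

    def test_fit_accuracy_improves_with_degree(self, isotope_table):
        # EM1(p) is strongly curved for many-site peptides (it passes through
        # a maximum near n*p ~ 1), so the quadratic default is only a coarse
        # approximation there; a cubic tightens it by an order of magnitude
        grid = np.arange(0.01, 0.0601, 0.005)
        comp = composition_from_sequence("GAVLK")
        n = labeling_sites("GAVLK", default_residue_sites())
        assert mida_curve(comp, n, isotope_table, 1, grid).max_abs_deviation < 5e-4
        assert mida_curve(comp, n, isotope_table, 1, grid, degree=3).max_abs_deviation < 1e-5
        comp20 = composition_from_sequence("ACDEFGHIKLMNPQRSTVWY")
        n20 = labeling_sites("ACDEFGHIKLMNPQRSTVWY", default_residue_sites())
        d2 = mida_curve(comp20, n20, isotope_table, 1, grid).max_abs_deviation
        d3 = mida_curve(comp20, n20, isotope_table, 1, grid, degree=3).max_abs_deviation
        assert d3 < d2

    def test_degenerate_grid_rejected(self, isotope_table):
        comp = composition_from_sequence("GG")
        with pytest.raises(ValueError, match="at least"):
            mida_curve(comp, 4.0, isotope_table, 1, [0.01, 0.02])


class TestInvariants:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(c=st.integers(0, 4), h=st.integers(0, 8), o=st.integers(0, 3), s=st.integers(0, 2))
    def test_truncated_raw_sum_below_one(self, isotope_table, c, h, o, s):
        counts = {k: v for k, v in zip("CHOS", (c, h, o, s)) if v}
        if not counts:
            counts = {"C": 1}
        d = natural_distribution(ElementalComposition(counts), isotope_table, 3)
        assert sum(d.abundances) <= 1.0 + 1e-9

    def test_untruncated_envelope_sums_to_one(self, isotope_table):
        # depth beyond any reachable mass offset => full distribution
        comp = ElementalComposition({"C": 3, "O": 1})
        d = natural_distribution(comp, isotope_table, 12)
        assert sum(d.abundances) == pytest.approx(1.0, abs=1e-12)
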