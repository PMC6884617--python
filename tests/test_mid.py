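"""MID arithmetic: theoretical natural MIDs, correction, convolution."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from glutrace.mid import (
    FormulaError,
    IsotopeAbundances,
    MIDVector,
    build_correction_matrix,
    convolve_mids,
    correct_mid,
    is_normalize,
    natural_mid,
    parse_formula,
)

P13C = 0.0107


def brute_force_carbon_mid(n_atoms: int, p: float) -> np.ndarray:
    """Oracle: enumerate all 2**n labeling states of an n-carbon molecule."""
    out = np.zeros(n_atoms + 1)
    for state in itertools.product([0, 1], repeat=n_atoms):
        k = sum(state)
        out[k] += p**k * (1 - p) ** (n_atoms - k)
    return out


class TestNaturalMid:
    def test_c6_binomial(self):
        """Six carbons at natural 13C follow the binomial formula."""
        mid = natural_mid("C6", IsotopeAbundances.carbon_only(P13C))
        expected = binom.pmf(np.arange(7), 6, P13C)
        np.testing.assert_allclose(mid.abundances, expected, atol=1e-12)
        assert mid[0] == pytest.approx(0.93748, abs=5e-5)
        assert mid[1] == pytest.approx(0.06084, abs=5e-5)

    @pytest.mark.parametrize("n_atoms", [1, 3, 6, 10])
    @pytest.mark.parametrize("p", [0.0107, 0.2])
    def test_matches_exhaustive_enumeration(self, n_atoms, p):
        """Convolution equals brute-force enumeration of labeling states."""
        mid = natural_mid(f"C{n_atoms}", IsotopeAbundances.carbon_only(p))
        np.testing.assert_allclose(mid.abundances, brute_force_carbon_mid(n_atoms, p), atol=1e-12)

    def test_monoisotopic_is_delta(self):
        mid = natural_mid("C6H12O6", IsotopeAbundances.monoisotopic())
        assert mid[0] == pytest.approx(1.0)
        assert mid.abundances[1:].sum() == pytest.approx(0.0)

    def test_single_atom_even_split(self):
        mid = natural_mid("C1", IsotopeAbundances.carbon_only(0.5))
        np.testing.assert_allclose(mid.abundances, [0.5, 0.5])

    def test_truncation_renormalizes(self):
        mid = natural_mid("C10", IsotopeAbundances.carbon_only(0.2), max_shift=3)
        assert len(mid) == 4
        assert mid.abundances.sum() == pytest.approx(1.0)

    def test_unknown_element_raises(self):
        with pytest.raises(FormulaError):
            natural_mid("C2Xx3")


class TestCorrectionMatrix:
    def test_c2_column_zero_expansion(self):
        """Unlabeled column of a 2-carbon tracer is the direct expansion."""
        m = build_correction_matrix("C2", abundances=IsotopeAbundances.carbon_only(P13C))
        p = P13C
        np.testing.assert_allclose(
            m.matrix[:, 0], [(1 - p) ** 2, 2 * p * (1 - p), p**2], atol=1e-12
        )

    def test_identity_without_heavy_isotopes(self):
        m = build_correction_matrix("C4H6O4", abundances=IsotopeAbundances.monoisotopic())
        np.testing.assert_allclose(m.matrix, np.eye(5), atol=1e-12)

    def test_lower_triangular_at_full_purity(self):
        m = build_correction_matrix("C5H9NO4", tracer_positions=5)
        assert np.allclose(np.triu(m.matrix, k=1), 0.0)

    @given(
        n_c=st.integers(1, 6),
        extra_h=st.integers(0, 12),
        purity=st.floats(0.9, 1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_column_sums_are_probabilities(self, n_c, extra_h, purity):
        m = build_correction_matrix(
            f"C{n_c}H{extra_h}" if extra_h else f"C{n_c}", purity=purity
        )
        sums = m.matrix.sum(axis=0)
        assert np.all(sums <= 1 + 1e-12)
        assert np.all(np.diag(m.matrix) > 0)

    def test_tracer_positions_exceeding_formula(self):
        with pytest.raises(FormulaError):
            build_correction_matrix("C2H4O", tracer_positions=3)


class TestCorrectMid:
    def test_natural_spectrum_corrects_to_unlabeled(self):
        """The unlabeled compound's measured MID corrects to pure M0."""
        abund = IsotopeAbundances()
        raw = natural_mid("C5H9NO4", abund, max_shift=5, metabolite="glutamate")
        matrix = build_correction_matrix("C5H9NO4", abundances=abund)
        corrected = correct_mid(raw, matrix)
        assert corrected[0] == pytest.approx(1.0, abs=1e-9)
        assert corrected.corrected

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_on_simplex(self, seed):
        """matrix @ x followed by correction recovers x exactly (noiseless)."""
        rng = np.random.default_rng(seed)
        matrix = build_correction_matrix("C6H8O7", tracer_positions=6)
        x = rng.dirichlet(np.ones(7))
        raw_ab = matrix.matrix @ x
        raw = MIDVector("citrate", raw_ab / raw_ab.sum())
        recovered = correct_mid(raw, matrix)
        np.testing.assert_allclose(recovered.abundances, x, atol=1e-9)

    def test_identity_matrix_is_noop(self):
        matrix = build_correction_matrix("C3", abundances=IsotopeAbundances.monoisotopic())
        raw = MIDVector("lactate", np.array([0.2, 0.3, 0.5, 0.0]))
        np.testing.assert_allclose(correct_mid(raw, matrix).abundances, raw.abundances)

    def test_correction_monotone_in_natural_abundance(self):
        """More natural 13C never inflates corrected label of an unlabeled compound."""
        prev = None
        for p in (0.005, 0.0107, 0.02, 0.05):
            abund = IsotopeAbundances.carbon_only(p)
            raw = natural_mid("C6", abund, max_shift=6)
            corrected = correct_mid(raw, build_correction_matrix("C6", abundances=abund))
            labeled = corrected.abundances[1:].sum()
            assert labeled <= 1e-9
            if prev is not None:
                assert labeled <= prev + 1e-9
            prev = labeled

    def test_dimension_mismatch_and_zero_raw(self):
        matrix = build_correction_matrix("C3")
        with pytest.raises(ValueError, match="match"):
            correct_mid(MIDVector("x", np.array([1.0, 0.0])), matrix)
        with pytest.raises(ValueError, match="zero"):
            correct_mid(
                MIDVector("x", np.zeros(4), normalized=False), matrix
            )


class TestConvolve:
    def test_delta_is_identity_element(self):
        a = MIDVector("a", np.array([0.3, 0.5, 0.2]))
        delta = MIDVector("d", np.array([1.0]))
        np.testing.assert_allclose(convolve_mids(a, delta).abundances, a.abundances)

    def test_two_coin_flips(self):
        half = MIDVector("h", np.array([0.5, 0.5]))
        np.testing.assert_allclose(
            convolve_mids(half, half).abundances, [0.25, 0.5, 0.25]
        )

    @pytest.mark.parametrize("n,d", [(3, 0.2), (7, 0.5)])
    def test_self_convolution_is_binomial(self, n, d):
        unit = MIDVector("u", np.array([1 - d, d]))
        acc = unit
        for _ in range(n - 1):
            acc = convolve_mids(acc, unit)
        np.testing.assert_allclose(acc.abundances, binom.pmf(np.arange(n + 1), n, d), atol=1e-12)


class TestISNormalize:
    @pytest.mark.parametrize(
        "analyte,is_area,rf,expected",
        [(1000, 500, 1.0, 2.0), (0, 500, 1.0, 0.0), (1000, 500, 0.5, 1.0)],
    )
    def test_ratio(self, analyte, is_area, rf, expected):
        assert is_normalize(analyte, is_area, rf) == pytest.approx(expected)

    def test_zero_internal_standard_names_sample(self):
        with pytest.raises(ValueError, match="well_3"):
            is_normalize(100, 0, sample="well_3")


class TestMIDVector:
    def test_normalized_invariant_enforced(self):
        with pytest.raises(ValueError):
            MIDVector("x", np.array([0.5, 0.4]))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            MIDVector("x", np.array([1.1, -0.1]))

    def test_renormalized(self):
        v = MIDVector("x", np.array([2.0, 2.0]), normalized=False).renormalized()
        np.testing.assert_allclose(v.abundances, [0.5, 0.5])

    def test_formula_parsing_round_trip(self):
        f = parse_formula("C5H9NO4")
        assert f["C"] == 5 and f["H"] == 9 and f["N"] == 1 and f["O"] == 4
        assert parse_formula(str(f)).counts == f.counts
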