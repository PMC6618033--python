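import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxometrics.ccfi import (
    band_label,
    ccfi,
    curve_rmsr,
    generate_comparison_data,
    interpret_ccfi,
    joint_span,
)
from taxometrics.curves import TaxometricCurve
from taxometrics.io import IndicatorMatrix


def _curve(y, x=None):
    y = np.asarray(y, dtype=float)
    return TaxometricCurve("MAMBAC", np.arange(len(y)) if x is None else x, y)


class TestCurveRmsr:
    def test_identical_curves_give_zero(self):
        c = _curve([1.0, 2.0, 3.0, 2.0])
        assert curve_rmsr(c, c) == 0.0

    def test_constant_offset_after_scaling(self):
        # curves spanning [0,1] jointly and differing by a constant delta
        a = _curve([0.0, 0.5, 1.0])
        b = _curve([0.25, 0.75, 1.0])  # joint span still 1.0
        delta = 0.25
        expected = np.sqrt(np.mean((np.array([0.25, 0.25, 0.0])) ** 2))
        assert curve_rmsr(a, b) == pytest.approx(expected)
        assert curve_rmsr(_curve([0.0, 0.0]), _curve([1.0, 1.0])) == pytest.approx(1.0)
        del delta

    def test_matches_direct_formula_on_toy_vectors(self):
        a = np.array([0.1, 0.9, 0.4, 0.6])
        b = np.array([0.3, 0.2, 0.8, 0.5])
        lo, hi = 0.1, 0.9  # joint extrema
        sa, sb = (a - lo) / (hi - lo), (b - lo) / (hi - lo)
        expected = np.sqrt(np.mean((sa - sb) ** 2))
        assert curve_rmsr(_curve(a), _curve(b)) == pytest.approx(expected)

    def test_interpolation_onto_data_grid(self):
        data = _curve([0.0, 1.0, 0.0], x=np.array([0.0, 1.0, 2.0]))
        comp = _curve([0.0, 0.5, 1.0, 0.5, 0.0],
                      x=np.array([0.0, 0.5, 1.0, 1.5, 2.0]))
        assert curve_rmsr(data, comp) == pytest.approx(0.0)

    def test_disjoint_grids_rejected(self):
        a = _curve([1.0, 2.0], x=np.array([0.0, 1.0]))
        b = _curve([1.0, 2.0], x=np.array([5.0, 6.0]))
        with pytest.raises(ValueError, match="disjoint"):
            curve_rmsr(a, b)

    def test_common_span_scale(self):
        a, b = _curve([0.0, 1.0]), _curve([0.0, 3.0])
        assert curve_rmsr(a, b, scale_span=joint_span(a.y, b.y)) == pytest.approx(
            np.sqrt(np.mean((np.array([0.0, 2.0]) / 3.0) ** 2))
        )


class TestCcfiIndex:
    def test_equal_rmsrs_sit_on_the_dividing_line(self):
        assert ccfi(0.3, 0.3) == pytest.approx(0.5)

    def test_perfect_taxonic_fit(self):
        assert ccfi(0.0, 0.4) == 1.0

    def test_perfect_dimensional_fit(self):
        assert ccfi(0.4, 0.0) == 0.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ccfi(0.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(1e-6, 10), b=st.floats(1e-6, 10))
    def test_label_swap_antisymmetry(self, a, b):
        assert ccfi(a, b) + ccfi(b, a) == pytest.approx(1.0)
        assert 0.0 <= ccfi(a, b) <= 1.0


class TestInterpretation:
    def test_published_anbp_values_mean_categorical(self):
        out = interpret_ccfi({"MAXEIG": 0.694, "LMODE": 0.709, "MAMBAC": 0.704})
        assert out.mean_ccfi == pytest.approx(0.702, abs=0.0005)
        assert out.mean_label == "taxonic"
        assert "categorical" in out.verdict
        assert out.unanimous

    def test_fuzzy_range_is_ambiguous(self):
        assert band_label(0.50) == "ambiguous"
        assert band_label(0.45) == "ambiguous"
        assert band_label(0.55) == "ambiguous"

    def test_clear_bands(self):
        assert band_label(0.30) == "dimensional"
        assert band_label(0.70) == "taxonic"

    def test_weak_leans_between_bands(self):
        assert band_label(0.42) == "weak dimensional lean"
        assert band_label(0.58) == "weak taxonic lean"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            interpret_ccfi({})


class TestComparisonData:
    def test_dimensional_replicate_of_uncorrelated_sample(self):
        rng = np.random.default_rng(0)
        emp = IndicatorMatrix(rng.normal(size=(945, 2)), ["a", "b"])
        ens = generate_comparison_data(emp, "dimensional", n_replicates=2, seed=5)
        for rep in ens.replicates:
            r = np.corrcoef(rep.scores, rowvar=False)[0, 1]
            assert abs(r) < 0.1

    def test_taxonic_replicate_block_sizes(self, anbp_taxonic):
        ens = generate_comparison_data(
            anbp_taxonic.matrix, "taxonic", base_rate=0.101,
            n_replicates=2, seed=5,
        )
        assert ens.base_rate == 0.101
        for rep in ens.replicates:
            assert rep.n_cases == 945
            assert int(rep.taxon_mask().sum()) == 95  # round(0.101 * 945)

    def test_bootstrap_values_come_from_empirical_marginals(self, anbp_taxonic):
        m = anbp_taxonic.matrix
        ens = generate_comparison_data(m, "dimensional", n_replicates=2, seed=9)
        for rep in ens.replicates:
            for j in range(m.n_indicators):
                assert np.isin(rep.scores[:, j], m.scores[:, j]).all()

    def test_realized_correlations_match_target(self, anbp_taxonic):
        m = anbp_taxonic.matrix
        target = np.corrcoef(m.scores, rowvar=False)
        ens = generate_comparison_data(m, "dimensional", n_replicates=3, seed=2)
        iu = np.triu_indices(m.n_indicators, 1)
        for rep, attained in zip(ens.replicates, ens.corr_rmsr):
            real = np.corrcoef(rep.scores, rowvar=False)
            rmsr = np.sqrt(np.mean((real - target)[iu] ** 2))
            assert rmsr == pytest.approx(attained, abs=1e-12)
            assert rmsr < 0.05

    def test_unknown_structure_rejected(self, anbp_taxonic):
        with pytest.raises(ValueError, match="structure"):
            generate_comparison_data(anbp_taxonic.matrix, "hybrid", seed=0)

    def test_replicates_are_seed_deterministic(self, anbp_taxonic):
        a = generate_comparison_data(anbp_taxonic.matrix, "dimensional",
                                     n_replicates=2, seed=3)
        b = generate_comparison_data(anbp_taxonic.matrix, "dimensional",
                                     n_replicates=2, seed=3)
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra.scores, rb.scores)
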