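import numpy as np
import pytest
from scipy import stats

from taxometrics.screening import cohens_d, screen
from taxometrics.simulate import (
    IndicatorSpec,
    ScenarioSpec,
    anbp_scenario,
    bn_scenario,
    make_dimensional,
    make_taxonic,
    mixture_implied_correlation,
)


def _true_d(sample, name):
    m = sample.matrix
    j = m.indicator_names.index(name)
    return cohens_d(m.scores[m.taxon_mask(), j], m.scores[m.complement_mask(), j])


class TestScenarioPresets:
    def test_anbp_preset(self):
        sc = anbp_scenario()
        assert sc.k == 4
        assert sc.n_total == 945
        assert sc.base_rate == 0.101
        assert sc.n_taxon == 95
        assert [i.d for i in sc.indicators] == [2.51, 1.57, 1.56, -2.07]
        assert sc.r_within == 0.275

    def test_bn_preset(self):
        sc = bn_scenario()
        assert sc.k == 5
        assert sc.n_total == 960
        assert sc.base_rate == 0.114
        assert sc.n_taxon == 109
        assert [i.d for i in sc.indicators] == [1.63, 3.68, 1.25, 1.67, 1.82]
        assert sc.r_within == 0.27

    def test_presets_are_immutable(self):
        with pytest.raises(AttributeError):
            anbp_scenario().base_rate = 0.5

    def test_invalid_specs_rejected(self):
        inds = anbp_scenario().indicators
        with pytest.raises(ValueError, match="base_rate"):
            ScenarioSpec("x", 900, 1.2, inds, 0.2)
        with pytest.raises(ValueError, match="taxon size"):
            ScenarioSpec("x", 100, 0.1, inds, 0.2)
        with pytest.raises(ValueError, match="r_within"):
            ScenarioSpec("x", 900, 0.1, inds, 1.5)


class TestMakeTaxonic:
    def test_group_sizes(self, anbp_taxonic):
        m = anbp_taxonic.matrix
        assert int(m.taxon_mask().sum()) == 95
        assert int(m.complement_mask().sum()) == 850

    def test_same_seed_is_bit_identical(self):
        a = make_taxonic(anbp_scenario(), seed=7)
        b = make_taxonic(anbp_scenario(), seed=7)
        np.testing.assert_array_equal(a.matrix.scores, b.matrix.scores)
        assert list(a.matrix.group) == list(b.matrix.group)

    def test_different_seeds_differ(self):
        a = make_taxonic(anbp_scenario(), seed=7)
        b = make_taxonic(anbp_scenario(), seed=8)
        assert not np.array_equal(a.matrix.scores, b.matrix.scores)

    def test_realized_d_matches_targets(self, anbp_taxonic):
        for ind in anbp_taxonic.spec.indicators:
            assert _true_d(anbp_taxonic, ind.name) == pytest.approx(ind.d, abs=0.15)

    def test_first_indicator_d_over_seeds(self):
        """Mean realized d of the heavy-skew bulimia indicator, 10 seeds."""
        sc = anbp_scenario()
        ds = [_true_d(make_taxonic(sc, s), "bulimia") for s in range(1, 11)]
        assert np.mean(ds) == pytest.approx(2.51, abs=0.15)

    def test_zero_d_gives_indistinguishable_groups(self):
        inds = tuple(
            IndicatorSpec(f"v{i}", 0.0, 1.0, 5.0, 2.0, (0.0, 30.0))
            for i in range(3)
        )
        sample = make_taxonic(ScenarioSpec("null", 900, 0.1, inds, 0.2), seed=4)
        for ind in inds:
            assert abs(_true_d(sample, ind.name)) < 0.15

    def test_values_respect_stated_ranges(self, anbp_taxonic, bn_taxonic):
        for sample in (anbp_taxonic, bn_taxonic):
            m = sample.matrix
            for j, ind in enumerate(sample.spec.indicators):
                if ind.value_range is not None:
                    assert m.scores[:, j].min() >= ind.value_range[0]
                    assert m.scores[:, j].max() <= ind.value_range[1]

    def test_skew_sign_and_moderate_targets(self, bn_taxonic):
        """Moderate-skew margins land near target; heavy-tailed margins
        keep the right sign (their sample skewness is biased low)."""
        m = bn_taxonic.matrix
        for j, ind in enumerate(bn_taxonic.spec.indicators):
            g = stats.skew(m.scores[:, j], bias=False)
            assert np.sign(g) == np.sign(ind.skew)
            if abs(ind.skew) <= 2.0:
                assert g == pytest.approx(ind.skew, abs=0.5)

    def test_negative_d_indicator_is_reflected(self, anbp_taxonic):
        # the BMI z-score: clinical group LOW, left-skewed
        d = _true_d(anbp_taxonic, "bmi_z")
        g = stats.skew(anbp_taxonic.matrix.column("bmi_z"), bias=False)
        assert d < -1.5
        assert g < 0

    def test_infeasible_skew_rejected(self):
        inds = (IndicatorSpec("a", 1.5, 40.0, 1.0, 2.0, (0.0, 30.0)),
                IndicatorSpec("b", 1.5, 1.0, 1.0, 2.0, (0.0, 30.0)))
        with pytest.raises(ValueError, match="skew"):
            make_taxonic(ScenarioSpec("bad", 900, 0.1, inds, 0.2), seed=0)

    def test_screening_selects_all_indicators_across_seeds(self):
        sc = anbp_scenario()
        hits = 0
        n_seeds = 20
        for s in range(1, n_seeds + 1):
            rep = screen(make_taxonic(sc, s).matrix)
            hits += len(rep.selected) == sc.k
        assert hits / n_seeds >= 0.95


class TestMakeDimensional:
    def test_matches_mixture_implied_correlations(self, anbp_dimensional):
        target = mixture_implied_correlation(anbp_scenario())
        real = np.corrcoef(anbp_dimensional.matrix.scores, rowvar=False)
        iu = np.triu_indices(4, 1)
        rmsr = np.sqrt(np.mean((real - target)[iu] ** 2))
        assert rmsr <= 0.05

    def test_matches_paired_taxonic_mean_correlation(self, anbp_taxonic,
                                                     anbp_dimensional):
        def mean_r(m):
            r = np.corrcoef(m.scores, rowvar=False)
            return np.abs(r[np.triu_indices_from(r, 1)]).mean()

        assert mean_r(anbp_dimensional.matrix) == pytest.approx(
            mean_r(anbp_taxonic.matrix), abs=0.05)

    def test_zero_factor_limit_is_uncorrelated(self):
        inds = tuple(
            IndicatorSpec(f"v{i}", 0.0, 1.0, 5.0, 2.0, (0.0, 30.0))
            for i in range(3)
        )
        spec = ScenarioSpec("indep", 900, 0.1, inds, 0.0, structure="dimensional")
        sample = make_dimensional(spec, seed=6)
        r = np.corrcoef(sample.matrix.scores, rowvar=False)
        assert np.abs(r[np.triu_indices(3, 1)]).mean() < 0.05

    def test_no_genuine_bimodality(self, anbp_dimensional):
        from taxometrics.curves import lmode_scores, estimate_base_rate
        res = lmode_scores(anbp_dimensional.matrix)
        br = estimate_base_rate(res)
        assert not br.reliable

    def test_deterministic(self):
        a = make_dimensional(anbp_scenario(), seed=3)
        b = make_dimensional(anbp_scenario(), seed=3)
        np.testing.assert_array_equal(a.matrix.scores, b.matrix.scores)

    def test_mixture_implied_correlation_signs(self):
        r = mixture_implied_correlation(anbp_scenario())
        # the reflected BMI indicator correlates negatively with the rest
        assert np.all(r[3, :3] < 0)
        assert np.all(r[np.triu_indices(3, 1)] > 0)
        np.testing.assert_allclose(np.diag(r), 1.0)
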