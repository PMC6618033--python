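import numpy as np
import pytest

from taxometrics.io import IndicatorMatrix
from taxometrics.curves import (
    estimate_base_rate,
    lmode_scores,
    mambac_averaged,
    mambac_curve,
    maxeig_averaged,
    maxeig_curve,
    maxeig_window_geometry,
)


def _unlabeled(scores, names=None):
    scores = np.asarray(scores, dtype=float)
    names = names or [f"v{i}" for i in range(scores.shape[1])]
    return IndicatorMatrix(scores, names)


class TestMambac:
    def test_half_split_means_oracle(self):
        """Single mid cut on 1..100: brute-force means of the two halves."""
        x = np.arange(1, 101, dtype=float)
        m = _unlabeled(np.column_stack([x, x]))
        c = mambac_curve(m, 0, 1, n_cuts=1, trim=49, seed=0)
        below = x[:50].mean()  # ranks 1..50
        above = x[50:].mean()  # ranks 51..100
        assert c.y[0] == pytest.approx(above - below)  # = 50
        assert c.y[0] == pytest.approx(50.0)

    def test_arbitrary_cut_matches_brute_force(self):
        rng = np.random.default_rng(5)
        out = rng.normal(size=200)
        inp = rng.normal(size=200)
        m = _unlabeled(np.column_stack([inp, out]))
        c = mambac_curve(m, 0, 1, n_cuts=10, trim=25, seed=3)
        # brute force means above/below each of the curve's own cut ranks,
        # reproducing the seeded tie-break order
        srt = out[np.lexsort((np.random.default_rng(3).permutation(200), inp))]
        for xi, yi in zip(c.x.astype(int), c.y):
            assert yi == pytest.approx(srt[xi:].mean() - srt[:xi].mean())

    def test_member_count_is_all_ordered_pairs(self, anbp_taxonic):
        avg = mambac_averaged(anbp_taxonic.matrix, seed=0)
        assert len(avg.member_curves) == 4 * 3  # the 12 separate curves

    def test_independent_output_gives_flat_curve(self):
        rng = np.random.default_rng(17)
        n = 1000
        m = _unlabeled(rng.normal(size=(n, 2)))
        c = mambac_curve(m, 0, 1, n_cuts=50, trim=25, seed=1)
        cuts = c.x.astype(int)
        se = np.sqrt(1.0 / cuts + 1.0 / (n - cuts))
        assert np.all(np.abs(c.y) < 3 * se)

    def test_constant_output_gives_zero_curve(self):
        m = _unlabeled(np.column_stack([np.arange(100.0), np.ones(100)]))
        c = mambac_curve(m, 0, 1, n_cuts=5, trim=10, seed=0)
        assert np.allclose(c.y, 0.0)

    def test_too_small_sample_rejected(self):
        m = _unlabeled(np.arange(40, dtype=float).reshape(20, 2))
        with pytest.raises(ValueError, match="trim"):
            mambac_curve(m, 0, 1, trim=25, seed=0)

    def test_input_rank_invariance(self):
        """Any strictly increasing transform of the input leaves y unchanged."""
        rng = np.random.default_rng(23)
        scores = rng.normal(size=(300, 2))
        a = mambac_curve(_unlabeled(scores), 0, 1, seed=9)
        transformed = scores.copy()
        transformed[:, 0] = np.exp(transformed[:, 0])
        b = mambac_curve(_unlabeled(transformed), 0, 1, seed=9)
        np.testing.assert_allclose(a.y, b.y)


class TestMaxeig:
    def test_window_geometry(self):
        w, step = maxeig_window_geometry(945, 50, 0.90)
        assert w == int(np.floor(945 / (1 + 49 * 0.1)))
        assert step == int(np.floor(w * 0.1))

    def test_single_window_equals_zero_diagonal_eigenvalue(self):
        """2 outputs: largest eigenvalue of [[0,c],[c,0]] is |c| (closed form)."""
        rng = np.random.default_rng(2)
        z = rng.normal(size=(400, 1))
        out1 = z[:, 0] + 0.3 * rng.normal(size=400)
        out2 = -z[:, 0] + 0.3 * rng.normal(size=400)  # negative covariance
        m = _unlabeled(np.column_stack([rng.normal(size=400), out1, out2]))
        c = maxeig_curve(m, 0, n_windows=2, overlap=0.0, seed=0)
        for i, sl in enumerate((slice(0, 200), slice(200, 400))):
            order = np.lexsort(
                (np.random.default_rng([0, 0]).permutation(400), m.scores[:, 0]))
            block = m.scores[order][sl][:, 1:]
            cov = np.cov(block, rowvar=False)
            assert c.y[i] == pytest.approx(abs(cov[0, 1]))

    def test_independent_outputs_give_near_zero_curve(self):
        rng = np.random.default_rng(31)
        n = 1000
        m = _unlabeled(rng.normal(size=(n, 3)))
        c = maxeig_curve(m, 0, n_windows=20, overlap=0.5, seed=4)
        w, _ = maxeig_window_geometry(n, 20, 0.5)
        # the largest eigenvalue of a noise covariance is positively biased
        # and this checks the max over 20 windows, so allow 4 SE
        assert np.all(np.abs(c.y) < 4.0 / np.sqrt(w))

    def test_window_count_for_exact_division(self):
        m = _unlabeled(np.random.default_rng(0).normal(size=(1000, 3)))
        c = maxeig_curve(m, 0, n_windows=10, overlap=0.5, seed=0)
        assert len(c) == 10

    def test_too_many_windows_rejected_with_suggestion(self):
        m = _unlabeled(np.random.default_rng(0).normal(size=(60, 3)))
        with pytest.raises(ValueError, match="n_windows <="):
            maxeig_curve(m, 0, n_windows=30, overlap=0.0, seed=0)

    def test_requires_three_indicators(self):
        m = _unlabeled(np.random.default_rng(0).normal(size=(100, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            maxeig_curve(m, 0, seed=0)

    def test_averaged_uses_each_indicator_once_as_input(self, anbp_taxonic):
        avg = maxeig_averaged(anbp_taxonic.matrix, seed=0)
        assert len(avg.member_curves) == anbp_taxonic.matrix.n_indicators


class TestLMode:
    def test_well_separated_mixture_has_opposite_sign_modes(self):
        rng = np.random.default_rng(8)
        comp = rng.normal(0, 1, size=(500, 4))
        tax = rng.normal(3, 1, size=(500, 4))
        res = lmode_scores(_unlabeled(np.vstack([comp, tax])))
        assert res.left_mode < 0 < res.right_mode
        assert res.antimode is not None

    def test_single_population_is_unimodal(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(1000, 1))
        scores = 0.7 * z + 0.7 * rng.normal(size=(1000, 4))
        res = lmode_scores(_unlabeled(scores))
        assert abs(res.right_mode - res.left_mode) < 0.5

    def test_one_score_per_case(self, anbp_taxonic):
        res = lmode_scores(anbp_taxonic.matrix)
        assert len(res.scores) == anbp_taxonic.matrix.n_cases

    def test_density_integrates_to_one(self, anbp_taxonic):
        res = lmode_scores(anbp_taxonic.matrix)
        mass = np.trapezoid(res.curve.y, res.curve.x)
        assert mass == pytest.approx(1.0, abs=0.05)

    def test_collinear_indicators_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=500)
        scores = np.column_stack([x, x + 1e-9 * rng.normal(size=500),
                                  x + 1e-9 * rng.normal(size=500)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            lmode_scores(_unlabeled(scores))


class TestBaseRates:
    def test_symmetric_mixture_splits_at_half(self):
        rng = np.random.default_rng(12)
        comp = rng.normal(0, 1, size=(500, 4))
        tax = rng.normal(3, 1, size=(500, 4))
        res = lmode_scores(_unlabeled(np.vstack([comp, tax])))
        br = estimate_base_rate(res)
        assert br.estimates[0] == pytest.approx(0.5, abs=0.05)
        assert br.estimates[1] == pytest.approx(0.5, abs=0.05)

    def test_small_taxon_recovered_from_antimode(self, anbp_taxonic):
        res = lmode_scores(anbp_taxonic.matrix)
        br = estimate_base_rate(res)
        assert br.methods == ("antimode-above", "antimode-below")
        assert br.estimates[0] == pytest.approx(0.101, abs=0.05)

    def test_estimates_lie_in_unit_interval(self, anbp_taxonic, anbp_dimensional):
        for sample in (anbp_taxonic, anbp_dimensional):
            for maker in (mambac_averaged, maxeig_averaged):
                avg = maker(sample.matrix, seed=2)
                br = estimate_base_rate(avg)
                assert all(0.0 <= e <= 1.0 for e in br.estimates)

    def test_dimensional_data_flagged_unreliable(self, anbp_dimensional):
        """A dish-shaped MAMBAC curve and a unimodal score density both
        signal that no taxon boundary exists to estimate."""
        avg = mambac_averaged(anbp_dimensional.matrix, seed=2)
        assert not estimate_base_rate(avg).reliable
        res = lmode_scores(anbp_dimensional.matrix)
        assert not estimate_base_rate(res).reliable

    def test_flat_curve_flagged(self):
        from taxometrics.curves import TaxometricCurve
        flat = TaxometricCurve("MAMBAC", np.arange(10.0), np.zeros(10))
        br = estimate_base_rate(flat)
        assert not br.reliable
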