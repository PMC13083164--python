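import numpy as np
import pytest
from scipy.special import expit

from clinens import (
    SplineConfig,
    candidate_cutpoints,
    cutpoint_scan,
    fit_interaction,
    rcs_basis,
    rcs_knots,
)
from clinens.age import _logistic_irls


def _truncated_ages(rng, n, mean=66.63, sd=9.3, lo=35, hi=83):
    out = []
    while len(out) < n:
        a = rng.normal(mean, sd)
        if lo <= a <= hi:
            out.append(a)
    return np.array(out)


class TestCandidateCutpoints:
    def test_counting_oracle_two_blocks(self):
        ages = list(range(30, 40)) + list(range(50, 60))  # 10 below 50, 10 at/above
        got = candidate_cutpoints(ages, min_n=10)
        oracle = [
            c for c in range(31, 60)
            if sum(a < c for a in ages) >= 10 and sum(a >= c for a in ages) >= 10
        ]
        assert got == oracle
        assert got == list(range(40, 51))

    def test_min_n_too_large_gives_empty(self):
        assert candidate_cutpoints([1, 2, 3, 4], min_n=3) == []

    def test_constant_ages_give_empty(self):
        assert candidate_cutpoints([60.0] * 30, min_n=5) == []


class TestCutpointScan:
    def test_p_floor_convention(self):
        rng = np.random.default_rng(0)
        ages = np.concatenate([rng.uniform(40, 60, 100), rng.uniform(70, 82, 100)])
        y = rng.integers(0, 2, 200)
        y[:4] = [0, 1, 0, 1]
        # score is a strong predictor only below age 65
        s = np.where(ages < 65, y + 0.1 * rng.random(200), rng.random(200))
        res = cutpoint_scan(s, y, ages, min_n=10, B=199, seed=1)
        floored = [r for r in res if r.below_floor]
        assert floored, "expected at least one zero-exceedance cut-point"
        for r in floored:
            assert r.p_raw == pytest.approx(1 / 200)
        for r in res:
            assert r.p_holm >= r.p_raw - 1e-15
            assert r.ci[0] <= r.delta_auc <= r.ci[1] or not r.below_floor

    def test_small_b_warns(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(40, 80, 60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        with pytest.warns(UserWarning, match="unstable"):
            cutpoint_scan(rng.random(60), y, ages, min_n=10, B=50, seed=2)

    def test_point_estimate_inside_its_bootstrap_interval(self):
        rng = np.random.default_rng(2)
        hits = 0
        for i in range(20):
            ages = _truncated_ages(rng, 150)
            y = rng.integers(0, 2, 150)
            y[:4] = [0, 1, 0, 1]
            s = np.where(rng.random(150) < 0.8, y, rng.random(150))
            res = cutpoint_scan(s, y, ages, min_n=30, B=300, seed=100 + i)
            if all(r.ci[0] - 1e-12 <= r.delta_auc <= r.ci[1] + 1e-12 for r in res):
                hits += 1
        assert hits >= 19


class TestRcsBasis:
    def test_dimensions_and_knots(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(40, 80, 200)
        knots = rcs_knots(ages, SplineConfig(df=4))
        assert len(knots) == 5
        B = rcs_basis(ages, knots)
        assert B.shape == (200, 4)

    def test_linear_below_first_knot(self):
        knots = np.array([50.0, 58.0, 66.0, 72.0, 80.0])
        x = np.linspace(30, 49.9, 50)
        B = rcs_basis(x, knots)
        assert np.allclose(B[:, 1:], 0.0)

    def test_linear_beyond_last_knot(self):
        knots = np.array([50.0, 58.0, 66.0, 72.0, 80.0])
        x = np.linspace(80.5, 120, 400)
        B = rcs_basis(x, knots)
        h = x[1] - x[0]
        second = np.diff(B, n=2, axis=0) / h**2
        assert np.abs(second).max() < 1e-8

    def test_smooth_at_interior_knots(self):
        knots = np.array([50.0, 58.0, 66.0, 72.0, 80.0])
        x = np.linspace(40, 90, 20001)
        B = rcs_basis(x, knots)
        h = x[1] - x[0]
        second = np.diff(B, n=2, axis=0) / h**2
        # second differences change continuously: no jumps beyond O(h)
        assert np.abs(np.diff(second, axis=0)).max() < 0.05

    def test_tied_knots_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            rcs_knots(np.array([60.0] * 50 + [61.0] * 5), SplineConfig(df=4))


class TestLogisticIrls:
    def test_matches_statsmodels_loglik(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 3))])
        beta_true = np.array([-0.5, 1.0, -0.7, 0.3])
        y = (rng.random(300) < expit(X @ beta_true)).astype(int)
        beta, ll = _logistic_irls(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert ll == pytest.approx(ref.llf, abs=1e-6)
        assert np.allclose(beta, ref.params, atol=1e-4)


class TestInteraction:
    @staticmethod
    def _simulate(rng, n, interaction):
        ages = _truncated_ages(rng, n)
        s = rng.random(n)
        slope = 3.0 + interaction * (ages - 66.0)
        y = (rng.random(n) < expit(-1.0 + slope * s + 0.02 * (ages - 66.0))).astype(int)
        return s, ages, y

    def test_lrt_nonnegative_and_df(self):
        rng = np.random.default_rng(5)
        s, ages, y = self._simulate(rng, 400, 0.0)
        res = fit_interaction(s, ages, y)
        assert res.lrt_stat >= 0
        assert res.lrt_df == 4
        assert res.loglik_full >= res.loglik_reduced

    def test_detects_strong_interaction(self):
        rng = np.random.default_rng(6)
        s, ages, y = self._simulate(rng, 500, -0.2)
        res = fit_interaction(s, ages, y)
        assert res.p < 0.01

    def test_probability_curves_and_half_crossing(self):
        rng = np.random.default_rng(7)
        s, ages, y = self._simulate(rng, 500, 0.0)
        res = fit_interaction(s, ages, y)
        assert set(res.curves) == {"p25", "p50", "p75"}
        for label, (grid, pq) in res.curves.items():
            assert len(grid) == len(pq) == 101
            t = res.score_at_half[label]
            if t is not None:
                assert pq[np.searchsorted(grid, t)] >= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_interaction([0.1, 0.9], [60, 70], [1, 1])
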