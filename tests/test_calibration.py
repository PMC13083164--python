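import numpy as np
import pytest
from scipy.special import expit

from clinens import (
    calibration_report,
    decision_curve,
    fit_calibrator,
    fit_isotonic,
    fit_platt,
    select_calibrator,
)
from clinens.calibration import brier


class TestPlatt:
    def test_separable_scores_calibrate_to_extremes(self):
        y = np.repeat([0, 1], 100)
        s = y.astype(float)
        cal = fit_platt(s, y)
        assert cal.predict([1.0])[0] > 0.9
        assert cal.predict([0.0])[0] < 0.1

    def test_uninformative_scores_fit_near_prevalence(self):
        rng = np.random.default_rng(0)
        s = rng.random(2000)
        y = (rng.random(2000) < 0.4).astype(int)
        cal = fit_platt(s, y)
        p = cal.predict(s)
        assert np.abs(p - 0.4).max() < 0.1

    def test_output_strictly_inside_unit_interval(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        cal = fit_platt([0.1, 0.9, 0.2, 0.8, 0.7, 0.3], y)
        p = cal.predict(np.array([-1.0, 0.0, 0.5, 1.0, 2.0]))
        assert ((p > 0) & (p < 1)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_platt([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1])


class TestIsotonic:
    def test_already_monotone_data_fits_exactly(self):
        cal = fit_isotonic([1, 2, 3], [0, 1, 1])
        fitted = cal.predict([1, 2, 3])
        assert np.allclose(fitted, [0, 1, 1])
        assert brier(fitted, [0, 1, 1]) == 0.0

    def test_single_violation_pools_to_half(self):
        cal = fit_isotonic([1, 2], [1, 0])
        assert np.allclose(cal.predict([1, 2]), [0.5, 0.5])

    def test_output_monotone_and_clamped(self):
        rng = np.random.default_rng(1)
        s = rng.random(100)
        y = (rng.random(100) < expit(3 * (s - 0.5))).astype(int)
        y[:2] = [0, 1]
        cal = fit_isotonic(s, y)
        grid = np.linspace(-0.5, 1.5, 200)
        p = cal.predict(grid)
        assert (np.diff(p) >= -1e-12).all()
        assert p[0] == p[p == p[0]].min() and 0 <= p.min() <= p.max() <= 1

    def test_projection_never_hurts_training_brier(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.random(80)
            y = rng.integers(0, 2, 80)
            y[:2] = [0, 1]
            cal = fit_isotonic(s, y)
            assert brier(cal.predict(s), y) <= brier(np.clip(s, 0, 1), y) + 1e-12


class TestCalibrationReport:
    def test_perfect_probabilities(self):
        rep = calibration_report([0, 1, 0, 1], [0, 1, 0, 1])
        assert rep.brier == 0 and rep.ece == 0 and rep.mce == 0

    def test_constant_half_balanced(self):
        rep = calibration_report([0.5] * 10, [0, 1] * 5)
        assert rep.brier == pytest.approx(0.25)
        assert rep.ece == pytest.approx(0.0)
        assert rep.mce == pytest.approx(0.0)

    def test_confident_and_wrong(self):
        rep = calibration_report([0.9] * 8, [0] * 8)
        assert rep.brier == pytest.approx(0.81)
        assert rep.ece == pytest.approx(0.9)
        assert rep.mce == pytest.approx(0.9)

    def test_ece_bounded_by_mce_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = rng.random(60)
            y = rng.integers(0, 2, 60)
            rep = calibration_report(p, y)
            assert rep.mce >= rep.ece >= 0

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            calibration_report([1.2], [1])


class TestDecisionCurve:
    def test_treat_none_reference_is_zero(self):
        nb = decision_curve([0.4, 0.6], [0, 1], [0.1, 0.3])
        assert np.allclose(nb.treat_none, 0.0)

    def test_treat_all_closed_form(self):
        y = np.array([1] * 681 + [0] * 319)
        nb = decision_curve(np.ones(1000), y, [0.25])
        assert nb.net_benefit[0] == pytest.approx(0.681 - 0.319 * (0.25 / 0.75), abs=1e-12)
        assert nb.treat_all[0] == pytest.approx(nb.net_benefit[0], abs=1e-12)

    def test_perfect_classifier_attains_prevalence_everywhere(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        nb = decision_curve(y.astype(float), y, np.arange(0.05, 0.96, 0.05))
        assert np.allclose(nb.net_benefit, y.mean(), atol=1e-12)

    def test_never_beats_the_perfect_classifier(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        p = rng.random(300)
        nb = decision_curve(p, y, np.arange(0.05, 0.51, 0.05))
        assert (nb.net_benefit <= y.mean() + 1e-12).all()

    def test_boundary_thresholds_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            decision_curve([0.5], [1], [0.0])


class TestSelectCalibrator:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        s = rng.random(200)
        y = (rng.random(200) < expit(6 * (s - 0.5))).astype(int)
        y[:2] = [0, 1]
        assert select_calibrator(s, y, seed=3) == select_calibrator(s, y, seed=3)

    def test_unsplittable_sample_falls_back_to_platt(self):
        # a class with a single member cannot be stratified into inner folds
        assert select_calibrator([0.1, 0.9, 0.2], [0, 1, 0], seed=0) == "platt"

    def test_fit_calibrator_dispatch(self):
        y = np.repeat([0, 1], 20)
        s = np.linspace(0, 1, 40)
        for kind in ("platt", "isotonic", "identity"):
            cal = fit_calibrator(kind, s, y)
            assert cal.kind == kind
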