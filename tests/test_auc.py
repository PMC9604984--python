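"""AUC quadrature, contribution regression and apoptosis calibration."""

import numpy as np
import pandas as pd
import pytest

from tnfnet.auc import (
    auc,
    auc_records,
    fit_calibration,
    fit_contributions,
    predict_apoptosis,
    sensitivity_ratio,
)


class TestAUC:
    def test_rectangle(self):
        t = np.linspace(0, 8, 9)
        assert auc(t, np.ones_like(t), (0, 8)) == pytest.approx(8.0)

    def test_triangle(self):
        t = np.linspace(0, 24, 25)
        assert auc(t, t, (0, 24)) == pytest.approx(288.0)

    def test_sine_against_closed_form(self):
        t = np.linspace(0, 12, 1000)
        y = np.sin(t) + 2
        exact = (1 - np.cos(12.0)) + 24.0
        assert auc(t, y, (0, 12)) == pytest.approx(exact, abs=1e-4)

    def test_additivity_of_windows(self, trajectories):
        traj = trajectories["TPL"]
        t = traj.time
        fc = traj.markers["Casp3"]
        upper = np.trapezoid(fc[t >= 12.0], t[t >= 12.0])
        assert auc(t, fc, (0, 24)) == pytest.approx(auc(t, fc, (0, 12)) + upper)

    def test_window_beyond_grid_rejected(self):
        with pytest.raises(ValueError):
            auc([0.0, 1.0], [1.0, 1.0], (0, 2))


def _records_from_rule(a, b, n_reps=5, windows=(8.0, 12.0, 24.0), noise=0.0,
                       seed=0, condition="TNFa"):
    rng = np.random.default_rng(seed)
    rows = []
    for w in windows:
        for r in range(n_reps):
            jnk, akt = rng.uniform(2, 30, 2)
            casp = a * jnk + b * akt
            if noise:
                casp *= 1 + rng.normal(0, noise)
            rows += [("pJNK", condition, w, f"r{r}", jnk),
                     ("pAKT", condition, w, f"r{r}", akt),
                     ("Casp3", condition, w, f"r{r}", casp)]
    return pd.DataFrame(rows, columns=["marker", "condition", "window_h", "id", "auc"])


class TestContributionRegression:
    def test_exact_linear_recovery(self):
        rec = _records_from_rule(2.0, 0.5)
        fit = fit_contributions(rec)
        assert fit.a == pytest.approx(2.0, abs=1e-10)
        assert fit.b == pytest.approx(0.5, abs=1e-10)

    def test_contributions_sum_to_one(self):
        for seed in range(5):
            rec = _records_from_rule(1.5, -0.4, noise=0.05, seed=seed)
            fit = fit_contributions(rec)
            total = fit.contributions["A_pJNK"] + fit.contributions["A_pAKT"]
            assert np.allclose(total, 1.0, atol=1e-12)

    def test_per_window_mode_also_normalised(self):
        rec = _records_from_rule(1.0, 1.0, noise=0.03, seed=3)
        fit = fit_contributions(rec, per_window=True)
        total = fit.contributions["A_pJNK"] + fit.contributions["A_pAKT"]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        """1% multiplicative noise, 15 observations, 100 seeds: recovered
        coefficients within 5% of truth."""
        a_true, b_true = 1.6, 0.9
        for seed in range(100):
            rec = _records_from_rule(a_true, b_true, n_reps=5, noise=0.01, seed=seed)
            fit = fit_contributions(rec)
            assert fit.a == pytest.approx(a_true, rel=0.05)
            assert fit.b == pytest.approx(b_true, rel=0.05)

    def test_collinear_regressors_rejected(self):
        rows = []
        for r in range(4):
            jnk = 2.0 * (r + 1)
            rows += [("pJNK", "c", 8.0, f"r{r}", jnk),
                     ("pAKT", "c", 8.0, f"r{r}", 3 * jnk),
                     ("Casp3", "c", 8.0, f"r{r}", jnk)]
        rec = pd.DataFrame(rows, columns=["marker", "condition", "window_h", "id",
                                          "auc"])
        with pytest.raises(np.linalg.LinAlgError):
            fit_contributions(rec)

    def test_mixed_conditions_rejected(self):
        rec = pd.concat([_records_from_rule(1, 1, condition="TNFa"),
                         _records_from_rule(1, 1, condition="TPL")])
        with pytest.raises(ValueError):
            fit_contributions(rec)

    def test_ensemble_records_from_simulations(self, trajectories):
        per_rep = {"p0": trajectories["TNFa"].markers,
                   "p1": {m: v * 1.01 for m, v in trajectories["TNFa"].markers.items()}}
        rec = auc_records(per_rep, trajectories["TNFa"].time, "TNFa")
        assert set(rec["window_h"]) == {8.0, 12.0, 24.0}
        assert (rec["auc"] > 0).all()
        fit = fit_contributions(rec)
        total = fit.contributions["A_pJNK"] + fit.contributions["A_pAKT"]
        assert np.allclose(total, 1.0, atol=1e-12)


class TestCalibration:
    def test_exact_quartic_recovery(self):
        coeffs = np.array([3.0, -0.5, 0.02, 1e-3, -2e-5])
        x = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        y = np.polynomial.polynomial.polyval(x, coeffs)
        curve = fit_calibration(x, y, degree=4)
        assert np.allclose(curve.coefficients, coeffs, atol=1e-8)

    def test_degree_one_exact_line(self):
        curve = fit_calibration([1.0, 3.0], [10.0, 30.0], degree=1)
        assert np.allclose(curve.coefficients, [0.0, 10.0], atol=1e-10)

    def test_noisy_quartic_residual_bounded(self):
        rng = np.random.default_rng(0)
        coeffs = np.array([5.0, 2.0, -0.1, 2e-3, -1e-5])
        x = np.linspace(2, 30, 12)
        sigma = 0.5
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.polynomial.polynomial.polyval(x, coeffs) + rng.normal(0, sigma, 12)
            curve = fit_calibration(x, y, degree=4)
            rms = curve.residual_norm / np.sqrt(len(x))
            assert rms <= 2 * sigma

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([1, 2, 3, 4], [1, 2, 3, 4], degree=4)

    def test_round_trip_within_residual_norm(self):
        rng = np.random.default_rng(5)
        x = np.linspace(1, 20, 10)
        y = 2 + 3 * x - 0.05 * x**2 + rng.normal(0, 1.0, 10)
        curve = fit_calibration(x, y, degree=4)
        pred = np.array([predict_apoptosis(curve, xi)["raw"] for xi in x])
        assert np.linalg.norm(pred - y) <= curve.residual_norm + 1e-9


class TestPrediction:
    def _curve(self):
        return fit_calibration([1.0, 2.0, 3.0, 4.0, 5.0],
                               [10.0, 20.0, 35.0, 60.0, 90.0], degree=4)

    def test_fitted_abscissa_within_residual(self):
        curve = self._curve()
        out = predict_apoptosis(curve, 3.0)
        assert abs(out["apoptosis_pct"] - 35.0) <= curve.residual_norm + 1e-9
        assert not out["extrapolated"]

    def test_clipping_flagged(self):
        curve = fit_calibration([0.0, 1.0], [50.0, 150.0], degree=1)
        out = predict_apoptosis(curve, 1.0)
        assert out["apoptosis_pct"] == 100.0
        assert out["clipped"]

    def test_extrapolation_flagged(self):
        out = predict_apoptosis(self._curve(), 9.0)
        assert out["extrapolated"]


class TestSensitivityRatio:
    def test_identity(self):
        t = np.linspace(0, 10, 11)
        y = np.cos(t) + 2
        assert sensitivity_ratio(y, y, t) == pytest.approx(1.0)

    def test_doubling(self):
        t = np.linspace(0, 10, 11)
        y = np.cos(t) + 2
        assert sensitivity_ratio(2 * y, y, t) == pytest.approx(2.0)

    def test_parameter_bump_matches_direct_quotient(self, reduced_net, reduced_truth):
        from tnfnet import assemble_odes, run_protocol, StimulationProtocol
        proto = StimulationProtocol("TNFa", tnf_dose=50.0, horizon=12.0)
        grid = np.linspace(0, 12, 25)
        ref_sys = assemble_odes(reduced_net, reduced_truth)
        bumped = assemble_odes(reduced_net,
                               reduced_truth.replace({"k_A_B": 1.2 * reduced_truth["k_A_B"]}))
        ref = run_protocol(ref_sys, proto, grid).markers["B"]
        per = run_protocol(bumped, proto, grid).markers["B"]
        assert sensitivity_ratio(per, ref, grid) == pytest.approx(
            auc(grid, per, (0, 12)) / auc(grid, ref, (0, 12)))

    def test_zero_reference_rejected(self):
        t = np.linspace(0, 2, 3)
        with pytest.raises(ZeroDivisionError):
            sensitivity_ratio(np.ones(3), np.zeros(3), t)
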