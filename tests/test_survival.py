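"""Parametric survival curves, censored MLE, model selection, KM round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbc_cea.survival import (
    FitResult,
    KMCurvePoints,
    ParametricSurvival,
    PseudoIPD,
    SurvivalValidationError,
    _loglik,
    fit_all_families,
    fit_mle,
    km_estimator,
    reconstruct_pseudo_ipd,
    select_model,
    survival_at,
)
from tnbc_cea.synthetic import SimulationSpec, simulate_ipd

from conftest import fisher_se

LOGNORMAL_PFS = ParametricSurvival("lognormal", (2.3487, 1.2258))
LOGLOGISTIC_PFS = ParametricSurvival("loglogistic", (1.763, 6.618))


class TestSurvivalAt:
    @pytest.mark.parametrize(
        "model,t,expected",
        [
            # medians: exp(meanlog) for log-normal, scale for log-logistic
            (LOGNORMAL_PFS, math.exp(2.3487), 0.5),
            (LOGLOGISTIC_PFS, 6.618, 0.5),
            (ParametricSurvival("lognormal", (3.1454, 1.1058)), math.exp(3.1454), 0.5),
            (ParametricSurvival("loglogistic", (1.702, 16.631)), 16.631, 0.5),
            # independent normal-CDF oracle: 1 - Phi((ln 12 - 2.3487)/1.2258)
            (LOGNORMAL_PFS, 12.0, 0.455772),
        ],
    )
    def test_reference_values(self, model, t, expected):
        assert survival_at(model, t) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "model",
        [
            ParametricSurvival("exponential", (0.1,)),
            ParametricSurvival("weibull", (1.5, 10.0)),
            ParametricSurvival("gamma", (2.0, 5.0)),
            LOGNORMAL_PFS,
            LOGLOGISTIC_PFS,
            ParametricSurvival("gompertz", (0.05, 0.08)),
            ParametricSurvival("gompertz", (-0.05, 0.02)),
        ],
        ids=lambda m: f"{m.family}{m.params}",
    )
    def test_s0_is_one_and_monotone(self, model):
        t = np.linspace(0, 300, 400)
        s = model.sf(t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_tail_vanishes_except_negative_gompertz_plateau(self):
        for model in [
            ParametricSurvival("weibull", (1.5, 10.0)),
            LOGNORMAL_PFS,
            LOGLOGISTIC_PFS,
        ]:
            assert survival_at(model, 1e5) < 1e-3
        plateau = ParametricSurvival("gompertz", (-0.05, 0.02))
        a, b = plateau.params
        assert survival_at(plateau, 1e5) == pytest.approx(math.exp(b / a), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(SurvivalValidationError):
            LOGNORMAL_PFS.sf(-1.0)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("lognormal", (2.0, -1.0)),
            ("weibull", (0.0, 10.0)),
            ("loglogistic", (1.5, -2.0)),
            ("exponential", (-0.1,)),
            ("gompertz", (0.0, 0.1)),
            ("notafamily", (1.0,)),
        ],
    )
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(SurvivalValidationError):
            ParametricSurvival(family, params)

    @given(
        shape=st.floats(0.3, 5.0),
        scale=st.floats(0.5, 50.0),
        t1=st.floats(0.0, 200.0),
        t2=st.floats(0.0, 200.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_property_loglogistic(self, shape, scale, t1, t2):
        model = ParametricSurvival("loglogistic", (shape, scale))
        lo, hi = sorted((t1, t2))
        assert survival_at(model, lo) >= survival_at(model, hi) - 1e-12


class TestFitMLE:
    def test_exponential_closed_form(self):
        ipd = PseudoIPD(np.array([2.0, 5.0, 1.5, 8.0]), np.ones(4, dtype=int))
        fit = fit_mle(ipd, "exponential")
        assert fit.model.params[0] == pytest.approx(4 / 16.5, rel=1e-12)
        assert fit.converged

    def test_lognormal_meanlog_matches_log_mean_oracle(self):
        # uncensored MLE of meanlog is exactly the sample mean of log-times
        ipd = simulate_ipd(
            SimulationSpec(LOGNORMAL_PFS, 5000, censor_rate=0.0, seed=7)
        )
        fit = fit_mle(ipd, "lognormal")
        assert fit.model.params[0] == pytest.approx(np.log(ipd.time).mean(), abs=1e-4)
        assert fit.model.params[0] == pytest.approx(2.3487, abs=0.05)

    def test_no_events_rejected(self):
        with pytest.raises(SurvivalValidationError):
            fit_mle(PseudoIPD(np.array([1.0, 2.0]), np.array([0, 0])), "weibull")
        with pytest.raises(SurvivalValidationError):
            PseudoIPD(np.array([]), np.array([]))

    def test_aic_bic_identities(self):
        ipd = simulate_ipd(
            SimulationSpec(LOGNORMAL_PFS, 200, censor_rate=0.02, seed=3)
        )
        for fit in fit_all_families(ipd):
            k = len(fit.model.params)
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, rel=1e-12)
            assert fit.bic == pytest.approx(
                -2 * fit.loglik + k * math.log(fit.n), rel=1e-12
            )

    @pytest.mark.parametrize(
        "truth",
        [
            ParametricSurvival("weibull", (1.5, 10.0)),
            ParametricSurvival("gamma", (1.6, 7.0)),
            LOGNORMAL_PFS,
            LOGLOGISTIC_PFS,
            ParametricSurvival("gompertz", (0.06, 0.05)),
        ],
        ids=lambda m: m.family,
    )
    def test_parameter_recovery_within_3se(self, truth):
        """Seeded censored fit recovers the generating parameters within
        3 standard errors (observed information from a numeric Hessian)."""
        ipd = simulate_ipd(
            SimulationSpec(truth, 5000, censor_rate=0.016, admin_cutoff=120, seed=11)
        )
        fit = fit_mle(ipd, truth.family)
        assert fit.converged

        def nll(x):
            return -_loglik(ParametricSurvival(truth.family, tuple(x)),
                            np.maximum(ipd.time, 1e-8), ipd.event)

        se = fisher_se(nll, fit.model.params)
        for est, true, s in zip(fit.model.params, truth.params, se):
            assert abs(est - true) < 3 * s, (est, true, s)

    def test_cross_check_against_lifelines(self):
        """Independent oracle: lifelines' univariate fitters find the same
        optimum on censored data (within optimizer tolerance)."""
        from lifelines import LogNormalFitter, WeibullFitter

        ipd = simulate_ipd(
            SimulationSpec(LOGNORMAL_PFS, 1500, censor_rate=0.03, seed=5)
        )
        ln = fit_mle(ipd, "lognormal")
        llf = LogNormalFitter().fit(ipd.time, ipd.event)
        assert ln.model.params[0] == pytest.approx(llf.mu_, abs=1e-3)
        assert ln.model.params[1] == pytest.approx(llf.sigma_, abs=1e-3)

        wb = fit_mle(ipd, "weibull")
        wbf = WeibullFitter().fit(ipd.time, ipd.event)
        assert wb.model.params[0] == pytest.approx(wbf.rho_, rel=1e-3)
        assert wb.model.params[1] == pytest.approx(wbf.lambda_, rel=1e-3)


class TestSelectModel:
    def _fit(self, family, aic, bic):
        model = ParametricSurvival(family, (1.0, 1.0)) \
            if family != "exponential" else ParametricSurvival(family, (1.0,))
        return FitResult(model, 0.0, aic, bic, 10, True)

    def test_min_aic_wins(self):
        fits = [self._fit("weibull", 100, 90), self._fit("gamma", 90, 95)]
        assert select_model(fits).model.family == "gamma"

    def test_aic_tie_broken_by_bic(self):
        fits = [self._fit("weibull", 90, 85), self._fit("gamma", 90, 80)]
        assert select_model(fits).model.family == "gamma"

    def test_full_tie_broken_by_family_order(self):
        fits = [self._fit("gompertz", 90, 80), self._fit("weibull", 90, 80)]
        assert select_model(fits).model.family == "weibull"

    def test_empty_list_rejected(self):
        with pytest.raises(SurvivalValidationError):
            select_model([])

    def test_weibull_truth_beats_exponential(self):
        """Misspecified exponential loses the AIC contest in >=80% of
        seeded replicates at n=2000."""
        truth = ParametricSurvival("weibull", (1.5, 10.0))
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            ipd = simulate_ipd(SimulationSpec(truth, 2000, seed=seed))
            best = select_model([fit_mle(ipd, "exponential"), fit_mle(ipd, "weibull")])
            wins += best.model.family == "weibull"
        assert wins >= 0.8 * n_rep


class TestKaplanMeier:
    def test_two_event_product_limit(self):
        km = km_estimator(PseudoIPD(np.array([1.0, 2.0]), np.array([1, 1])))
        assert km.time.tolist() == [0.0, 1.0, 2.0]
        assert km.survival.tolist() == [1.0, 0.5, 0.0]

    def test_all_censored_is_flat_one(self):
        km = km_estimator(PseudoIPD(np.array([1.0, 2.0, 3.0]), np.zeros(3, int)))
        assert np.all(km.survival == 1.0)

    def test_matches_hand_computed_table(self):
        # events at 1, 2, 3, 5; censored at 2 and 4:
        # S = 5/6, 2/3, 4/9, 0 (censoring at a tie leaves the subject at risk)
        ipd = PseudoIPD(np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0]),
                        np.array([1, 0, 1, 1, 0, 1]))
        km = km_estimator(ipd)
        assert km.time.tolist() == [0.0, 1.0, 2.0, 3.0, 5.0]
        np.testing.assert_allclose(
            km.survival, [1.0, 5 / 6, 2 / 3, 4 / 9, 0.0], atol=1e-12
        )


class TestReconstruction:
    def test_round_trip_matches_input_curve(self):
        curve = KMCurvePoints(
            np.array([0.0, 3.0, 6.0, 12.0, 24.0]),
            np.array([1.0, 0.8, 0.55, 0.3, 0.12]),
        )
        n = 250
        km = km_estimator(reconstruct_pseudo_ipd(curve, n))
        recon = km.step_interp(curve.time)
        np.testing.assert_allclose(recon, curve.survival, atol=1 / (2 * n))

    def test_event_count_tracks_curve_level(self):
        curve = KMCurvePoints(np.array([0.0, 10.0]), np.array([1.0, 0.5]))
        ipd = reconstruct_pseudo_ipd(curve, 200)
        assert ipd.n_events == 100
        assert len(ipd) == 200

    def test_increasing_survival_rejected(self):
        with pytest.raises(SurvivalValidationError):
            KMCurvePoints(np.array([1.0, 2.0]), np.array([0.5, 0.6]))

    def test_at_risk_counts_drive_interior_censoring(self):
        curve = KMCurvePoints(np.array([0.0, 6.0, 12.0]), np.array([1.0, 0.7, 0.5]))
        ipd = reconstruct_pseudo_ipd(curve, 100, at_risk=[100, 70, 40])
        censored_inside = np.sum((ipd.event == 0) & (ipd.time < 12.0))
        assert censored_inside > 0
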