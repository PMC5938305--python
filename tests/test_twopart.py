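"""Two-part model: likelihood oracles, properties, fitting contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

import gambrct as g
from gambrct import tlfb
from gambrct.twopart import ModelError, TwoPartParams, twopart_loglik


def single_row_design():
    weekly = pd.DataFrame(
        {"participant_id": ["a", "a", "a", "a"], "rater": "gambler",
         "week": [0, 1, 2, 3], "avg_daily_loss": 0.0, "n_days_observed": 7}
    )
    return tlfb.build_design(weekly, {"a": "bct"}, knots=(0.5, 1.5, 2.5))


def params_with(p, mean, shape, n_coef=7):
    """Intercept-only params hitting occurrence p and amount mean."""
    beta_occ = np.zeros(n_coef)
    beta_amt = np.zeros(n_coef)
    beta_occ[0] = special.logit(p)
    beta_amt[0] = np.log(mean)
    return TwoPartParams(beta_occ, beta_amt, shape, 1.0, 1.0, 0.0)


class TestLoglikOracles:
    def test_zero_week_contributes_log_one_minus_p(self):
        params = params_with(0.5, 100.0, 1.0)
        X = np.zeros((1, 7)); X[0, 0] = 1.0
        ll = twopart_loglik([0.0], X, params)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_exponential_special_case(self):
        # shape 1 => exponential: log p + log(1/100) - y/100 at y = mean = 100
        params = params_with(0.5, 100.0, 1.0)
        X = np.zeros((1, 7)); X[0, 0] = 1.0
        ll = twopart_loglik([100.0], X, params)
        assert ll == pytest.approx(np.log(0.5) - np.log(100.0) - 1.0, abs=1e-10)

    def test_matches_scipy_gamma_density(self):
        params = params_with(0.7, 250.0, 2.5)
        X = np.zeros((1, 7)); X[0, 0] = 1.0
        y = 180.0
        expected = np.log(0.7) + stats.gamma.logpdf(y, a=2.5, scale=250.0 / 2.5)
        assert twopart_loglik([y], X, params) == pytest.approx(expected, abs=1e-10)

    def test_empty_observations_give_zero(self):
        params = params_with(0.5, 100.0, 1.0)
        assert twopart_loglik([], np.zeros((0, 7)), params) == 0.0

    def test_negative_loss_rejected(self):
        params = params_with(0.5, 100.0, 1.0)
        with pytest.raises(ModelError):
            twopart_loglik([-1.0], np.zeros((1, 7)), params)


class TestDensityProperties:
    def test_density_integrates_to_one(self):
        """Point mass at zero plus gamma mass over (0, inf) totals 1."""
        for p, mean, shape in [(0.3, 50.0, 0.7), (0.8, 1500.0, 2.0)]:
            mass, err = integrate.quad(
                lambda y: p * stats.gamma.pdf(y, a=shape, scale=mean / shape),
                0, np.inf, limit=200,
            )
            total = (1 - p) + mass
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_marginal_mean_matches_simulation(self):
        """p * mu equals the Monte Carlo mean of two-part outcomes."""
        rng = np.random.default_rng(5)
        p, mean, shape = 0.55, 300.0, 0.9
        n = 10**6
        z = rng.uniform(size=n) < p
        y = np.where(z, rng.gamma(shape, mean / shape, size=n), 0.0)
        assert y.mean() == pytest.approx(p * mean, rel=0.01)

    def test_loglik_peaks_at_generating_parameters(self, truth):
        """At large n the likelihood at truth beats single-coordinate
        perturbations of +-0.5."""
        weekly, design, info = g.generate_from_model(truth, g.TrialShape(150, 14), seed=9)
        y = weekly["avg_daily_loss"].to_numpy()
        sub_idx = pd.factorize(weekly["participant_id"])[0]
        base = twopart_loglik(y, design, truth, info["intercepts"], sub_idx)
        for j in [0, 1, 2, 7, 8]:
            for delta in (-0.5, 0.5):
                occ = truth.beta_occ.copy()
                amt = truth.beta_amt.copy()
                if j < 7:
                    occ[j] += delta
                else:
                    amt[j - 7] += delta
                pert = TwoPartParams(occ, amt, truth.shape, truth.sd_occ,
                                     truth.sd_amt, truth.rho)
                assert twopart_loglik(y, design, pert, info["intercepts"], sub_idx) < base


class TestParamValidation:
    def test_invalid_shape(self):
        with pytest.raises(ModelError):
            TwoPartParams(np.zeros(2), np.zeros(2), -1.0, 1.0, 1.0, 0.0)

    def test_invalid_rho(self):
        with pytest.raises(ModelError):
            TwoPartParams(np.zeros(2), np.zeros(2), 1.0, 1.0, 1.0, 1.5)


class TestFit:
    def test_seed_determinism(self, small_model_data):
        weekly, design, _ = small_model_data
        cfg = g.McmcConfig(n_ensembles=1, n_warmup=30, n_steps=30, max_draws=500)
        a = g.fit_twopart(weekly, design, config=cfg, seed=5)
        b = g.fit_twopart(weekly, design, config=cfg, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.intercepts, b.intercepts)

    def test_all_zero_losses_rejected(self, small_model_data):
        weekly, design, _ = small_model_data
        zero = weekly.copy()
        zero["avg_daily_loss"] = 0.0
        with pytest.raises(ModelError, match="unidentified"):
            g.fit_twopart(zero, design, seed=1)

    def test_seed_required(self, small_model_data):
        weekly, design, _ = small_model_data
        with pytest.raises(ModelError, match="seed"):
            g.fit_twopart(weekly, design)

    def test_posterior_near_truth(self, small_fit, truth):
        """On one 18-subject dataset most 95% CIs cover the generating fixed
        effects and the medians stay within gross sampling error."""
        tv = np.concatenate([truth.beta_occ, truth.beta_amt])
        names = small_fit.param_names[: tv.size]
        covered = sum(
            lo <= t <= hi
            for (lo, hi), t in ((small_fit.ci(n), t) for n, t in zip(names, tv))
        )
        assert covered >= len(names) - 3
        med = np.array([small_fit.table[n].median() for n in names])
        assert np.max(np.abs(med - tv)) < 2.0

    def test_diagnostics_present(self, small_fit):
        d = small_fit.diagnostics
        assert set(d) >= {"rhat", "ess", "acceptance_rate", "divergences", "warnings"}
        assert d["divergences"] is None
        assert all(v > 0 for v in d["ess"].values())
        assert small_fit.n_draws >= 1000


class TestMarginals:
    def test_p_times_mu_closed_form(self, small_fit):
        row = small_fit.design.row(0.0, "bct")
        vals = g.twopart.__dict__["_draw_marginals"](small_fit, row)
        names = small_fit.param_names
        K = small_fit.design.X.shape[1]
        p = special.expit(small_fit.params(names[:K]) @ row)
        mu = np.exp(small_fit.params(names[K : 2 * K]) @ row)
        np.testing.assert_allclose(vals, p * mu, rtol=1e-12)

    def test_baseline_contrast_identically_zero(self, small_fit):
        out = g.arm_contrast(small_fit, [0.0])
        es = out["week 0"]["diff"]
        assert es.estimate == 0.0 and es.ci_low == 0.0 and es.ci_high == 0.0

    def test_extrapolation_warning(self, small_fit):
        out = g.arm_contrast(small_fit, [99.0])
        assert any("extrapolat" in w for w in out["week 99"]["diff"].warnings)

    def test_summary_orders(self, small_fit):
        es = g.marginal_daily_loss(small_fit, small_fit.design.row(1.0, "cbt"))
        assert es.ci_low <= es.estimate <= es.ci_high
        assert es.scale == "SEK/day"
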