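"""Drift-diffusion machinery: renewal solver vs closed forms and Monte Carlo,
likelihoods, maximum-likelihood recovery, and BIC model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from urgeflow import (
    DDMParams,
    UrgencyParams,
    compare_models,
    fit_mle,
    fpt_density,
    loglik_dataset,
    simulate_ddm,
)
from urgeflow.urgency import collapse_urgency


def p_upper_closed_form(v, a, z, s):
    """Absorption probability at the upper bound of a constant-bound DDM."""
    if v == 0:
        return z / a
    return (math.exp(-2 * v * z / s**2) - 1) / (math.exp(-2 * v * a / s**2) - 1)


def constant_bound_density(t, v, a, z, s, which="lower", n_terms=50):
    """Series solution for the defect FPT density of a constant-bound DDM
    (unit-variance rescaling), used as an independent analytic oracle."""
    t = np.asarray(t, dtype=float)
    av, zv, vv = a / s, z / s, v / s
    w = zv / av if which == "lower" else 1.0 - zv / av
    vv = vv if which == "lower" else -vv
    k = np.arange(1, n_terms + 1)[:, None]
    series = k * np.sin(k * np.pi * w) * np.exp(-0.5 * (k * np.pi / av) ** 2 * t)
    dens = (np.pi / av**2) * np.exp(-vv * av * w - 0.5 * vv**2 * t) * series.sum(axis=0)
    return np.maximum(dens, 0.0)


class TestRenewalSolver:
    def test_zero_drift_symmetric(self):
        g = fpt_density(DDMParams(v=0.0, a=0.2), None, dt=1e-3, t_max=6.0)
        assert g.p_correct == pytest.approx(0.5, abs=1e-9)
        np.testing.assert_allclose(g.g_correct, g.g_error, atol=1e-12)

    @pytest.mark.parametrize("v,a", [(0.15, 0.2), (0.08, 0.12), (-0.1, 0.25)])
    def test_accuracy_matches_closed_form(self, v, a):
        g = fpt_density(DDMParams(v=v, a=a), None, dt=1e-3, t_max=8.0)
        expected = p_upper_closed_form(v, a, a / 2, 0.1)
        pc = g.dt * g.g_correct.sum()
        assert pc == pytest.approx(expected, abs=1e-3)

    def test_density_matches_series_solution(self):
        """Defect densities agree pointwise with the analytic series."""
        p = DDMParams(v=0.15, a=0.2)
        g = fpt_density(p, None, dt=1e-3, t_max=6.0)
        keep = g.t > 0.02  # series converges slowly at tiny t
        upper = constant_bound_density(g.t[keep], p.v, p.a, p.a / 2, p.s, "upper")
        lower = constant_bound_density(g.t[keep], p.v, p.a, p.a / 2, p.s, "lower")
        assert np.max(np.abs(g.g_correct[keep] - upper)) < 1e-3 * upper.max()
        assert np.max(np.abs(g.g_error[keep] - lower)) < 1e-2 * lower.max()

    def test_flat_urgency_equals_rescaled_constant_bound(self):
        """u = flat u0 is a standard DDM with a = 2(1-u0), z = a/2."""
        u = UrgencyParams.flat(0.3)
        p = DDMParams(v=0.1)
        g_urg = fpt_density(p, u, dt=1e-3, t_max=6.0)
        g_std = fpt_density(DDMParams(v=0.1, a=2 * 0.7), None, dt=1e-3, t_max=6.0)
        assert np.max(np.abs(g_urg.g_correct - g_std.g_correct)) < 1e-3
        assert np.max(np.abs(g_urg.g_error - g_std.g_error)) < 1e-3

    def test_mass_conservation_random_draws(self):
        """Absorbed mass + survival = 1 within 1e-3 over random parameters."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = DDMParams(v=rng.uniform(-0.2, 0.3), eta=rng.uniform(0, 0.08),
                          t_er=0.3)
            u = UrgencyParams(u0=rng.uniform(0, 0.6), k=rng.uniform(0.05, 0.8),
                              lam=rng.uniform(0.1, 1.5),
                              ceiling=rng.uniform(1.0, 1.5))
            g = fpt_density(p, u, dt=1e-3, t_max=3.0)
            total = g.dt * np.sum(g.g_correct + g.g_error) + g.survival
            assert total == pytest.approx(1.0, abs=1e-3)
            assert g.g_correct.min() >= 0 and g.g_error.min() >= 0

    def test_full_collapse_forces_absorption(self):
        """A bound reaching 0 at 1.1 s leaves < 1e-6 survival at 1.3 s."""
        u = collapse_urgency(u0=0.2, t_collapse=1.1)
        g = fpt_density(DDMParams(v=0.1), u, dt=1e-3, t_max=1.3)
        assert g.survival < 1e-6

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            fpt_density(DDMParams(v=0.1), None, dt=5e-3)


class TestSimulatorVsSolver:
    """The Monte-Carlo oracle and the renewal solver must agree (KS < 0.01)."""

    @pytest.mark.parametrize(
        "urgency",
        [
            None,  # flat (standard DDM bounds)
            UrgencyParams(u0=0.2, k=0.35, lam=0.9),  # asymptotic logistic collapse
            collapse_urgency(0.3, 1.1),  # full collapse (deadline regime)
        ],
        ids=["flat", "logistic", "full-collapse"],
    )
    def test_ks_distance(self, urgency):
        p = DDMParams(v=0.12, eta=0.0, a=0.2, t_er=0.3)
        t_max = 6.0 if urgency is None else 2.0
        df = simulate_ddm(p, urgency, 100_000, dt=1e-3, t_max=t_max, seed=5)
        g = fpt_density(p, urgency, dt=1e-3, t_max=t_max)
        rts = np.sort(df.loc[df["censored"] == 0, "rt"].to_numpy() - p.t_er)
        cdf = g.dt * np.cumsum(g.g_correct + g.g_error)
        cdf /= cdf[-1]
        emp = np.searchsorted(rts, g.t, side="right") / rts.size
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_accuracy_matches_solver(self):
        u = UrgencyParams(u0=0.3, k=0.33, lam=0.88, ceiling=1.4)
        p = DDMParams(v=0.12, eta=0.05, t_er=0.3)
        df = simulate_ddm(p, u, 50_000, dt=1e-3, t_max=2.0, seed=9)
        g = fpt_density(p, u, dt=1e-3, t_max=2.0)
        assert df["accuracy"].mean() == pytest.approx(g.p_correct, abs=0.01)

    def test_determinism(self):
        p = DDMParams(v=0.1, t_er=0.3)
        a = simulate_ddm(p, None, 500, seed=11, t_max=2.0)
        b = simulate_ddm(p, None, 500, seed=11, t_max=2.0)
        pd.testing.assert_frame_equal(a, b)

    def test_collapse_caps_all_rts(self):
        """Urgency reaching the bound at (1.4 - t_er) leaves no RT beyond 1.41."""
        u = collapse_urgency(0.3, 1.1)
        p = DDMParams(v=0.12, eta=0.05, t_er=0.3)
        df = simulate_ddm(p, u, 20_000, dt=1e-3, t_max=2.0, seed=3,
                          regime="DL", deadline=1.4)
        assert df["censored"].sum() == 0
        assert df["rt"].max() <= 1.4 + 2e-3 + 1e-9
        assert df["missed"].mean() <= 1e-3


class TestLikelihoodAndFitting:
    def test_single_trial_scores_grid_density(self):
        p = DDMParams(v=0.12, t_er=0.3)
        u = UrgencyParams(u0=0.2, k=0.35, lam=0.9)
        g = fpt_density(p, u, dt=2e-3, t_max=2.0)
        i_mode = int(np.argmax(g.g_correct))
        rt = g.t[i_mode] + p.t_er
        df = pd.DataFrame({"regime": ["DL"], "rt": [rt], "accuracy": [1],
                           "censored": [0], "missed": [0]})
        ll = loglik_dataset(df, p, u, dt=2e-3)
        assert ll == pytest.approx(np.log(g.g_correct[i_mode]), abs=1e-6)

    def test_rt_below_nondecision_time_floored(self):
        p = DDMParams(v=0.12, t_er=0.9)
        df = pd.DataFrame({"regime": ["DL"] * 3, "rt": [0.4, 0.5, 0.6],
                           "accuracy": [1, 0, 1], "censored": [0] * 3,
                           "missed": [0] * 3})
        ll = loglik_dataset(df, p, UrgencyParams(0.2, 0.35, 0.9), dt=2e-3)
        assert ll == pytest.approx(3 * np.log(1e-10))

    def test_true_parameters_beat_perturbed(self):
        """Data generated from (p, u) scores higher likelihood under the
        generating drift than under +/-30% perturbations of it."""
        p = DDMParams(v=0.15, eta=0.0, t_er=0.3)
        u = UrgencyParams(u0=0.25, k=0.3, lam=0.6, ceiling=1.3)
        wins = 0
        n_rep = 12
        for s in range(n_rep):
            df = simulate_ddm(p, u, 400, dt=1e-3, t_max=2.0, seed=300 + s,
                              regime="DL", deadline=1.4)
            ll_true = loglik_dataset(df, p, u, dt=2e-3)
            ll_lo = loglik_dataset(df, DDMParams(v=0.7 * p.v, t_er=0.3), u, dt=2e-3)
            ll_hi = loglik_dataset(df, DDMParams(v=1.3 * p.v, t_er=0.3), u, dt=2e-3)
            wins += ll_true > max(ll_lo, ll_hi)
        assert wins >= n_rep - 1

    def test_fixed_point_spec_returns_loglik_without_search(self):
        p = DDMParams(v=0.12, t_er=0.3)
        u = UrgencyParams(u0=0.25, k=0.3, lam=0.6, ceiling=1.3)
        df = simulate_ddm(p, u, 300, dt=1e-3, t_max=2.0, seed=1,
                          regime="DL", deadline=1.4)
        fit = fit_mle(df, model="urgency", free={},
                      fixed={"v": 0.12, "eta": 0.0, "u0": 0.25, "k": 0.3,
                             "lam": 0.6, "ceiling": 1.3, "t_er": 0.3})
        assert fit.n_free == 0
        assert fit.loglik == pytest.approx(loglik_dataset(df, p, u, dt=2e-3), abs=1e-9)
        assert fit.bic == pytest.approx(-2 * fit.loglik, abs=1e-9)

    def test_parameter_recovery_urgency_model(self):
        """v and u0 recovered within +/-15% (median over seeded replicates)
        at the per-subject trial count of 1,440."""
        true_p = DDMParams(v=0.12, eta=0.0, t_er=0.3)
        true_u = UrgencyParams(u0=0.25, k=0.3, lam=0.6, ceiling=1.3)
        v_err, u0_err = [], []
        for s in range(5):
            df = simulate_ddm(true_p, true_u, 1440, dt=1e-3, t_max=2.5,
                              seed=500 + s, regime="DL", deadline=1.4)
            fit = fit_mle(
                df, model="urgency",
                free={"v": (0.1, -1, 1), "u0": (0.3, 0, 0.999),
                      "k": (0.2, 1e-3, np.inf), "lam": (0.5, 1e-3, np.inf),
                      "t_er": (0.25, 0.05, 0.6)},
                fixed={"eta": 0.0, "ceiling": 1.3},
                seed=s, dt=2e-3, n_starts=4, maxfev=600,
            )
            u_fit = fit.urgency["DL"]
            v_err.append(abs(fit.params.v / true_p.v - 1))
            u0_err.append(abs(u_fit.u0 / true_u.u0 - 1))
        assert np.median(v_err) < 0.15
        assert np.median(u0_err) < 0.15

    def test_standard_data_fit_by_urgency_model_looks_flat(self):
        """Fitting the urgency model to flat-bound data recovers a nearly
        flat urgency signal (u(1.4) - u0 small)."""
        from urgeflow.urgency import urgency_value

        df = simulate_ddm(DDMParams(v=0.25, eta=0.0, a=0.16, t_er=0.3), None,
                          600, dt=1e-3, t_max=2.0, seed=77, regime="DL",
                          deadline=1.4)
        fit = fit_mle(
            df, model="urgency",
            free={"v": (0.5, -4, 4), "u0": (0.9, 0, 0.999),
                  "k": (0.3, 1e-3, np.inf), "lam": (0.6, 1e-3, np.inf),
                  "t_er": (0.25, 0.05, 0.6)},
            fixed={"eta": 0.0}, seed=1, dt=2e-3, n_starts=3, maxfev=350,
        )
        u_fit = fit.urgency["DL"]
        rise = urgency_value(u_fit, 1.4) - u_fit.u0
        assert rise < 0.25 * (1 - u_fit.u0) + 0.05


class TestModelComparison:
    def _fit_both(self, df, seed):
        fu = fit_mle(df, model="urgency",
                     free={"v": (0.1, -1, 1), "u0": (0.3, 0, 0.999),
                           "k": (0.2, 1e-3, np.inf), "lam": (0.5, 1e-3, np.inf),
                           "t_er": (0.25, 0.05, 0.6)},
                     fixed={"eta": 0.0, "ceiling": 1.3},
                     seed=seed, dt=2e-3, n_starts=2, maxfev=300)
        fs = fit_mle(df, model="standard",
                     free={"v": (0.1, -1, 1), "a": (0.15, 0.02, 1.0),
                           "t_er": (0.25, 0.05, 0.6)},
                     fixed={"eta": 0.0},
                     seed=seed, dt=2e-3, n_starts=2, maxfev=300)
        return fu, fs

    def test_identical_fit_lists_give_p_one(self):
        df = simulate_ddm(DDMParams(v=0.12, t_er=0.3),
                          UrgencyParams(0.25, 0.3, 0.6, 1.3), 300,
                          seed=4, t_max=2.0, regime="DL", deadline=1.4)
        fits = [fit_mle(df, model="urgency", free={},
                        fixed={"v": 0.12, "u0": 0.25, "k": 0.3, "lam": 0.6,
                               "ceiling": 1.3, "t_er": 0.3})] * 6
        rep = compare_models(fits, list(fits))
        assert rep["p_value"] == 1.0
        assert np.all(rep["delta_bic"] == 0)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            compare_models([], [None])

    def test_model_recovery_both_directions(self):
        """Urgency model wins by BIC on urgency-generated cohorts and is not
        preferred on cohorts generated without urgency."""
        n_subj = 6
        true_u = UrgencyParams(u0=0.25, k=0.3, lam=0.6, ceiling=1.3)
        fus, fss = [], []
        for s in range(n_subj):
            df = simulate_ddm(DDMParams(v=0.12, eta=0.0, t_er=0.3), true_u,
                              400, seed=100 + s, t_max=2.5, regime="DL",
                              deadline=1.4)
            fu, fs = self._fit_both(df, s)
            fus.append(fu)
            fss.append(fs)
        rep = compare_models(fus, fss)
        assert rep["median_delta_bic"] < 0
        assert rep["p_value"] < 0.05

        fus, fss = [], []
        for s in range(n_subj):
            df = simulate_ddm(DDMParams(v=0.25, eta=0.0, a=0.16, t_er=0.3),
                              None, 400, seed=200 + s, t_max=2.0, regime="DL",
                              deadline=1.4)
            fu, fs = self._fit_both(df, s)
            fus.append(fu)
            fss.append(fs)
        rep = compare_models(fus, fss)
        assert rep["median_delta_bic"] >= 0

    def test_bic_definition(self):
        df = simulate_ddm(DDMParams(v=0.12, t_er=0.3),
                          UrgencyParams(0.25, 0.3, 0.6, 1.3), 200,
                          seed=8, t_max=2.0, regime="DL", deadline=1.4)
        fit = fit_mle(df, model="urgency",
                      free={"v": (0.1, -1, 1)},
                      fixed={"u0": 0.25, "k": 0.3, "lam": 0.6, "ceiling": 1.3,
                             "t_er": 0.3},
                      seed=0, n_starts=2, maxfev=100)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 1 * np.log(200))
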