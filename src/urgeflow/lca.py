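"""Gain-modulated leaky competing accumulator (LCA).

A two-layer network: two input units (activations I1, I2 for the correct and
incorrect alternatives) feed two accumulator units x1, x2 that compete via
lateral inhibition and self-excite. Per finite-difference step,

    dx_i = -leak * x_i + excit * f(x_i) - inhib * f(x_j) + f(I_i) + noise,
    x_i  = max(x_i + dx_i, 0),

where every term except the leak passes through the sigmoidal transfer
function

    f(x) = theta * (2 * Phi(x; 0, 1/g) - 1),

Phi the normal CDF; the gain g sets the steepness of the non-linearity
(linear near 0 as g -> 0, step-like as g -> inf) and theta the symmetric
output bounds. A decision is made when an accumulator's activation exceeds
the bound A; RT = commitment time + t_er.

Global gain modulation implements urgency: gain is flat within-trial in the
free-response regime and has both a higher baseline and a linear within-trial
ramp under deadline. With recurrent excitation stronger than lateral
inhibition, a rising gain drives building common activation of both
accumulators — the signature of time-dependent urgency: losing-accumulator
activation at commitment grows with commitment time under deadline but not
under free response, and pre-motion baseline activation is elevated under
deadline.

Default network constants were calibrated once to reproduce those
qualitative deadline signatures (faster, less accurate DL responding with
negligible missed deadlines); they are package defaults, not estimates of
any empirical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "LCAParams",
    "GainSchedule",
    "AccumulatorTrace",
    "transfer",
    "simulate_lca_trial",
    "simulate_lca_trials",
    "dynamics_summaries",
    "fit_lca_behavior",
    "effective_time_constant",
]


@dataclass(frozen=True)
class LCAParams:
    """Network constants (per-step units at integration step ``dt``).

    leak : activation decay per step.
    excit / inhib : recurrent excitation and lateral inhibition weights;
        excitation must dominate inhibition for the urgency signatures.
    noise_sd : per-step Gaussian noise s.d. (dt-specific, finite-difference
        form).
    bound : decision bound A on activation.
    theta : symmetric output bound of the transfer function.
    inputs : (I1, I2) input-unit activations; I1 is the correct alternative.
    dt : integration step (s).
    t_er : non-decision time (s).
    premotion : pre-motion period (s) simulated with the input units off.
    """

    leak: float = 0.06
    excit: float = 0.07
    inhib: float = 0.05
    noise_sd: float = 0.03
    bound: float = 1.0
    theta: float = 1.0
    inputs: tuple[float, float] = (0.033, 0.026)
    dt: float = 0.01
    t_er: float = 0.3
    premotion: float = 0.3

    def __post_init__(self) -> None:
        if self.excit <= self.inhib:
            raise ValueError("recurrent excitation must exceed lateral inhibition")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bound <= 0 or self.theta <= 0:
            raise ValueError("bound and theta must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class GainSchedule:
    """Regime-specific gain trajectories.

    FR gain is flat at ``g_FR``; DL gain is ``g0_DL + slope_DL * t`` with t
    the time since motion onset (the static offset also applies during the
    pre-motion period).
    """

    g_FR: float = 0.85
    g0_DL: float = 1.5
    slope_DL: float = 2.2

    def __post_init__(self) -> None:
        if self.g_FR <= 0 or self.g0_DL <= 0:
            raise ValueError("gains must be positive everywhere")
        if self.slope_DL < 0:
            raise ValueError("DL gain trajectory must be non-decreasing")

    def gain(self, regime: str, t_since_onset) -> np.ndarray:
        t = np.asarray(t_since_onset, dtype=float)
        if regime == "FR":
            return np.broadcast_to(self.g_FR, t.shape).copy() if t.ndim else self.g_FR
        g = self.g0_DL + self.slope_DL * np.maximum(t, 0.0)
        return g


@dataclass
class AccumulatorTrace:
    """One simulated trial's activation time courses.

    ``t`` runs from -premotion (inputs off) through commitment; ``winner``
    is 1 or 2 (or 0 if censored: no commitment within t_max).
    """

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    commit_time: float | None
    winner: int


def transfer(x, g: float, theta: float = 1.0):
    """Sigmoidal activation-to-output function theta*(2*Phi(x; 0, 1/g) - 1).

    Odd in x, range (-theta, theta); approximately linear with slope
    theta*g*sqrt(2/pi) near 0; step-like as g -> inf.
    """
    if g <= 0:
        raise ValueError("gain must be positive")
    return theta * (2.0 * norm.cdf(np.asarray(x, dtype=float) * g) - 1.0)


def _transfer_prime0(g: float, theta: float) -> float:
    """Slope of the transfer function at x = 0."""
    return theta * g * math.sqrt(2.0 / math.pi)


def _simulate_batch(
    p: LCAParams,
    gains: GainSchedule,
    regime: str,
    n: int,
    rng: np.random.Generator,
    t_max: float = 5.0,
    keep_traces: bool = False,
):
    """Vectorized Euler simulation of ``n`` trials; see simulate_lca_trial."""
    n_pre = int(round(p.premotion / p.dt))
    n_post = int(round(t_max / p.dt))
    steps = n_pre + n_post
    t_grid = p.dt * (np.arange(steps) - n_pre + 1)

    x1 = np.zeros(n)
    x2 = np.zeros(n)
    active = np.ones(n, dtype=bool)
    commit = np.full(n, np.nan)
    winner = np.zeros(n, dtype=int)
    pre_sum = np.zeros(n)
    x_lose = np.full(n, np.nan)
    x_win = np.full(n, np.nan)
    traces = ([], [])
    f0 = lambda x, g: p.theta * (2.0 * norm.cdf(x * g) - 1.0)

    for k in range(steps):
        t = t_grid[k]
        g = gains.gain(regime, max(t, 0.0)) if regime == "DL" else gains.g_FR
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        i1 = p.inputs[0] if t > 0 else 0.0
        i2 = p.inputs[1] if t > 0 else 0.0
        a, b = x1[idx], x2[idx]
        fa, fb = f0(a, g), f0(b, g)
        # full-width draws keep the noise stream aligned across parameter
        # values (common random numbers for simulation-based fitting)
        noise1 = rng.normal(0.0, p.noise_sd, n)[idx]
        noise2 = rng.normal(0.0, p.noise_sd, n)[idx]
        a_new = np.maximum(a + (-p.leak * a + p.excit * fa - p.inhib * fb + f0(i1, g)) + noise1, 0.0)
        b_new = np.maximum(b + (-p.leak * b + p.excit * fb - p.inhib * fa + f0(i2, g)) + noise2, 0.0)
        x1[idx], x2[idx] = a_new, b_new
        if keep_traces:
            traces[0].append(x1.copy())
            traces[1].append(x2.copy())
        if t <= 0:
            pre_sum[idx] += 0.5 * (a_new + b_new)
        else:
            hit1 = a_new >= p.bound
            hit2 = b_new >= p.bound
            hit = hit1 | hit2
            if np.any(hit):
                hidx = idx[hit]
                both = hit1 & hit2
                w = np.where(hit1, 1, 2)
                if np.any(both):
                    w[both] = np.where(a_new[both] >= b_new[both], 1, 2)
                winner[hidx] = w[hit]
                commit[hidx] = t
                x_win[hidx] = np.where(w[hit] == 1, a_new[hit], b_new[hit])
                x_lose[hidx] = np.where(w[hit] == 1, b_new[hit], a_new[hit])
                active[hidx] = False

    out = {
        "commit_time": commit,
        "winner": winner,
        "pre_motion_mean": pre_sum / max(n_pre, 1),
        "x_lose": x_lose,
        "x_win": x_win,
        "censored": active,
        "t_grid": t_grid,
    }
    if keep_traces:
        out["x1"] = np.array(traces[0])
        out["x2"] = np.array(traces[1])
    return out


def simulate_lca_trial(
    p: LCAParams,
    gains: GainSchedule,
    regime: str = "FR",
    seed: int = 0,
    t_max: float = 5.0,
):
    """Simulate one trial; returns (AccumulatorTrace, TrialRecord row dict).

    Inputs are off during the pre-motion period (baseline dynamics driven by
    leak, recurrence and gain alone); activations are floored at 0 each
    step; the trial ends at the first bound crossing, with
    RT = commitment time + t_er. No crossing within ``t_max`` gives a
    censored record.
    """
    rng = np.random.default_rng(seed)
    res = _simulate_batch(p, gains, regime, 1, rng, t_max=t_max, keep_traces=True)
    ct = res["commit_time"][0]
    censored = bool(res["censored"][0])
    if not censored:
        n_keep = int(np.searchsorted(res["t_grid"], ct, side="right"))
    else:
        n_keep = len(res["t_grid"])
    trace = AccumulatorTrace(
        t=res["t_grid"][:n_keep],
        x1=res["x1"][:n_keep, 0],
        x2=res["x2"][:n_keep, 0],
        commit_time=None if censored else float(ct),
        winner=int(res["winner"][0]),
    )
    record = {
        "regime": regime,
        "rt": np.nan if censored else float(ct) + p.t_er,
        "accuracy": int(res["winner"][0] == 1),
        "censored": int(censored),
        "missed": int((regime == "DL") and (not censored) and (ct + p.t_er > 1.4)),
    }
    return trace, record


def simulate_lca_trials(
    p: LCAParams,
    gains: GainSchedule,
    regime: str,
    n: int,
    seed: int = 0,
    t_max: float = 5.0,
    deadline: float = 1.4,
) -> pd.DataFrame:
    """Vectorized simulation of ``n`` trials; returns a trial table with the
    per-trial dynamics summaries (pre-motion mean activation, winner and
    loser activation at commitment) attached as extra columns."""
    rng = np.random.default_rng(seed)
    res = _simulate_batch(p, gains, regime, n, rng, t_max=t_max)
    rt = res["commit_time"] + p.t_er
    df = pd.DataFrame(
        {
            "subject_id": "lca",
            "regime": regime,
            "rt": rt,
            "accuracy": (res["winner"] == 1).astype(int),
            "censored": res["censored"].astype(int),
            "pre_motion": res["pre_motion_mean"],
            "x_lose": res["x_lose"],
            "x_win": res["x_win"],
        }
    )
    df["missed"] = ((df["regime"] == "DL") & (df["rt"] > deadline)).astype(int)
    return df


def dynamics_summaries(trials: pd.DataFrame, n_rt_bins: int = 3) -> dict[str, object]:
    """Accumulator-dynamics summaries per regime.

    For each regime: (i) mean pre-motion activation; (ii) mean
    losing-accumulator activation at commitment per equal-count RT bin;
    (iii) mean winner-minus-loser activation difference at commitment per RT
    bin. Needs >= 500 committed trials per regime; empty bins are reported
    as NaN.
    """
    out = {}
    for regime, sub in trials.groupby("regime", sort=True):
        done = sub[(sub["censored"] == 0) & np.isfinite(sub["rt"])]
        if len(done) < 500:
            raise ValueError(f"need >= 500 committed traces in regime {regime}, got {len(done)}")
        order = np.argsort(done["rt"].to_numpy(), kind="stable")
        lose = done["x_lose"].to_numpy()[order]
        win = done["x_win"].to_numpy()[order]
        rts = done["rt"].to_numpy()[order]
        lose_b, diff_b, rt_b = [], [], []
        for chunk in np.array_split(np.arange(len(done)), n_rt_bins):
            if chunk.size == 0:
                lose_b.append(np.nan)
                diff_b.append(np.nan)
                rt_b.append(np.nan)
                continue
            lose_b.append(float(lose[chunk].mean()))
            diff_b.append(float((win[chunk] - lose[chunk]).mean()))
            rt_b.append(float(rts[chunk].mean()))
        out[regime] = {
            "pre_motion": float(done["pre_motion"].mean()),
            "rt_bin_mean": rt_b,
            "loser_at_commit": lose_b,
            "winner_minus_loser": diff_b,
        }
    return out


def effective_time_constant(p: LCAParams, g: float) -> float:
    """Effective accumulation time constant (s) from linearizing the noise-
    free baseline dynamics around the pre-motion fixed point x* = 0:

        tau = dt / (leak - (excit - inhib) * f'(x*; g)).

    Diagnostic only; a non-positive denominator (runaway regime) returns
    inf with a warning.
    """
    denom = p.leak - (p.excit - p.inhib) * _transfer_prime0(g, p.theta)
    if denom <= 0:
        import warnings

        warnings.warn("effective time constant is unbounded (runaway regime)")
        return math.inf
    return p.dt / denom


def fit_lca_behavior(
    trials: pd.DataFrame,
    fixed: LCAParams,
    init: GainSchedule = GainSchedule(),
    seed: int = 0,
    n_sim: int = 2000,
    n_starts: int = 3,
    maxfev: int = 100,
    deadline: float = 1.4,
) -> dict[str, object]:
    """Fit the gain schedule (g_FR, g0_DL, slope_DL) to pooled behaviour.

    Minimizes a quantile-based chi-square — observed vs simulated RT deciles
    plus accuracy, per regime — over the gain-schedule parameters by seeded
    multistart Nelder-Mead, using a fixed simulation seed per evaluation
    (common random numbers). All other network constants stay fixed.

    Requires both regimes in ``trials``; a missing regime raises, since its
    gain parameters would be unidentifiable.
    """
    regimes = set(trials["regime"].unique())
    missing = {"FR", "DL"} - regimes
    if missing:
        raise ValueError(
            f"regime(s) {sorted(missing)} absent: gain parameters unidentifiable"
        )
    obs = {}
    qs = np.arange(0.1, 1.0, 0.1)
    for regime, sub in trials.groupby("regime"):
        done = sub[(sub["censored"] == 0) & np.isfinite(sub["rt"])]
        obs[regime] = (np.quantile(done["rt"], qs), done["accuracy"].mean())

    def objective(x):
        g_fr, g0, slope = np.exp(x[0]), np.exp(x[1]), np.exp(x[2])
        try:
            sched = GainSchedule(g_FR=g_fr, g0_DL=g0, slope_DL=slope)
        except ValueError:
            return 1e9
        total = 0.0
        for regime in ("FR", "DL"):
            sim = simulate_lca_trials(fixed, sched, regime, n_sim, seed=seed + 17)
            done = sim[sim["censored"] == 0]
            if len(done) < n_sim * 0.5:
                return 1e6 + (n_sim - len(done))  # penalized: too few commits
            sq = np.quantile(done["rt"], qs)
            oq, oacc = obs[regime]
            total += float(np.sum((sq - oq) ** 2)) + 10.0 * (done["accuracy"].mean() - oacc) ** 2
        return total

    rng = np.random.default_rng(seed)
    x0 = np.log([init.g_FR, init.g0_DL, init.slope_DL])
    best = None
    for i in range(n_starts):
        start = x0 if i == 0 else x0 + rng.normal(0, 0.2, 3)
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-4})
        if best is None or res.fun < best.fun:
            best = res
    sched = GainSchedule(*np.exp(best.x))
    return {"schedule": sched, "objective": float(best.fun), "n_eval": int(best.nfev)}
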