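"""Drift diffusion models with and without time-dependent urgency.

Two model classes are supported, both expressed internally as a single
diffusion started at 0 between symmetric bounds +/- b(t):

* the *standard DDM*: noisy evidence accumulated from z = a/2 at drift v
  between bounds 0 and a, i.e. b(t) = a/2 constant;
* the *urgency DDM*: two perfectly anti-correlated accumulators with a common
  additive logistic urgency signal and a fixed unit bound, equivalent to
  b(t) = 1 - u(t).

First-passage-time (FPT) densities through the (continuously differentiable)
time-varying bounds are computed with the renewal integral-equation method:
the defect densities g+/g- of first crossing the upper/lower boundary satisfy
a system of Volterra equations of the second kind in the free-diffusion
transition density, which is discretized on a uniform grid. Between-trial
drift variability (drift ~ N(v, eta^2)) is marginalized by Gauss-Hermite
quadrature.

Likelihoods interpolate the FPT grid at (RT - t_er); trials censored at the
response deadline contribute the survival mass beyond it. Fitting is
multistart Nelder-Mead maximum likelihood; model comparison uses
BIC = -2 lnL + k ln n with Wilcoxon signed-rank tests on paired BIC
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import wilcoxon

from .urgency import (
    BOUND_FLOOR,
    UrgencyParams,
    effective_bound,
    urgency_slope,
)

__all__ = [
    "DDMParams",
    "FPTGrid",
    "FitResult",
    "fpt_density",
    "simulate_ddm",
    "loglik_dataset",
    "fit_mle",
    "compare_models",
]

#: Floor density (1/s) for trials outside the support of the model.
DENSITY_FLOOR = 1e-10

#: Gauss-Hermite node count for marginalizing drift variability.
GH_NODES = 7


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters.

    v : mean drift rate (evidence units / s).
    eta : s.d. of between-trial drift variability (>= 0).
    a : boundary separation of the standard DDM. For the urgency DDM the
        bound is fixed at 1 and ``a`` is ignored.
    s : within-trial noise s.d.; fixed at 0.1 to scale all other parameters.
    t_er : non-decision time (s), added to the decision time to give RT.

    The start point z is always a/2 (unbiased), so the equivalent symmetric
    diffusion starts at 0.
    """

    v: float
    eta: float = 0.0
    a: float = 1.0
    s: float = 0.1
    t_er: float = 0.3

    def __post_init__(self) -> None:
        for name in ("v", "eta", "a", "s", "t_er"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"DDM parameter {name!r} must be finite, got {val!r}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if self.t_er < 0:
            raise ValueError(f"t_er must be >= 0, got {self.t_er}")


@dataclass
class FPTGrid:
    """Discretized defect first-passage densities.

    t : time grid (s), uniform step dt, starting at dt.
    g_correct / g_error : densities (1/s) of first crossing the correct
        (upper, drift-congruent) and error (lower) bounds.
    survival : probability mass not yet absorbed at the end of the grid.
    """

    t: np.ndarray
    g_correct: np.ndarray
    g_error: np.ndarray
    survival: float

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def p_correct(self) -> float:
        """Probability of a correct response among absorbed mass."""
        pc = self.dt * float(np.sum(self.g_correct))
        pe = self.dt * float(np.sum(self.g_error))
        return pc / (pc + pe)

    def survival_at(self, t: float) -> float:
        """P(no crossing by decision time t)."""
        absorbed = self.dt * np.cumsum(self.g_correct + self.g_error)
        surv = 1.0 - absorbed
        return float(np.interp(t, self.t, surv, left=1.0, right=surv[-1]))


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: DDMParams
    urgency: dict[str, UrgencyParams] | None
    loglik: float
    n_free: int
    n_trials: int
    bic: float = field(init=False)
    starts: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bic = -2.0 * self.loglik + self.n_free * math.log(self.n_trials)


# ----------------------------------------------------------------------------
# Renewal (Volterra) solver
# ----------------------------------------------------------------------------

_SQRT2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _renewal_core(t, b, bp, mu, s, kc):  # pragma: no cover - jitted
    """Solve the two-boundary Volterra system for symmetric bounds +/- b(t).

    t, b, bp : grid times, bound values and bound derivatives (len N).
    mu : drift; s : diffusion s.d.; kc : first index with a collapsed bound
        (N if none). Returns (g_up, g_lo) defect densities on the grid.
    """
    n = t.shape[0]
    g1 = np.zeros(n)
    g2 = np.zeros(n)
    s2 = s * s
    step = t[1] - t[0] if n > 1 else t[0]
    for k in range(min(kc, n)):
        tk = t[k]
        bk = b[k]
        bpk = bp[k]
        # kernel against the initial condition (x0 = 0 at time 0)
        var0 = s2 * tk
        d1 = bk - mu * tk
        f1 = math.exp(-0.5 * d1 * d1 / var0) / (_SQRT2PI * math.sqrt(var0))
        psi1_0 = f1 * 0.5 * (bpk - mu - d1 / tk)
        d2 = -bk - mu * tk
        f2 = math.exp(-0.5 * d2 * d2 / var0) / (_SQRT2PI * math.sqrt(var0))
        psi2_0 = f2 * 0.5 * (-bpk - mu - d2 / tk)
        acc1 = -2.0 * psi1_0
        acc2 = 2.0 * psi2_0
        for j in range(k):
            dtau = tk - t[j]
            var = s2 * dtau
            inv2v = 0.5 / var
            # upper boundary kernel, sources at +b_j and -b_j
            du = bk - b[j] - mu * dtau
            fu = math.exp(-du * du * inv2v) / (_SQRT2PI * math.sqrt(var))
            psi1_u = fu * 0.5 * (bpk - mu - du / dtau)
            dl = bk + b[j] - mu * dtau
            fl = math.exp(-dl * dl * inv2v) / (_SQRT2PI * math.sqrt(var))
            psi1_l = fl * 0.5 * (bpk - mu - dl / dtau)
            # lower boundary kernel
            eu = -bk - b[j] - mu * dtau
            gu = math.exp(-eu * eu * inv2v) / (_SQRT2PI * math.sqrt(var))
            psi2_u = gu * 0.5 * (-bpk - mu - eu / dtau)
            el = -bk + b[j] - mu * dtau
            gl = math.exp(-el * el * inv2v) / (_SQRT2PI * math.sqrt(var))
            psi2_l = gl * 0.5 * (-bpk - mu - el / dtau)
            acc1 += 2.0 * (g1[j] * psi1_u + g2[j] * psi1_l) * step
            acc2 -= 2.0 * (g1[j] * psi2_u + g2[j] * psi2_l) * step
        g1[k] = acc1
        g2[k] = acc2
    return g1, g2


def _bound_arrays(p: DDMParams, u: UrgencyParams | None, t: np.ndarray):
    if u is None:
        b = np.full_like(t, p.a / 2.0)
        bp = np.zeros_like(t)
    else:
        b = np.asarray(effective_bound(u, t), dtype=float)
        bp = -np.asarray(urgency_slope(u, t), dtype=float)
    return b, bp


def _gh_drifts(p: DDMParams):
    """Gauss-Hermite nodes/weights for drift ~ N(v, eta^2)."""
    if p.eta == 0.0:
        return np.array([p.v]), np.array([1.0])
    x, w = np.polynomial.hermite.hermgauss(GH_NODES)
    drifts = p.v + math.sqrt(2.0) * p.eta * x
    weights = w / math.sqrt(math.pi)
    return drifts, weights


def fpt_density(
    p: DDMParams,
    u: UrgencyParams | None = None,
    dt: float = 1e-3,
    t_max: float = 6.0,
) -> FPTGrid:
    """First-passage densities of the diffusion through +/- b(t).

    ``u=None`` gives the standard DDM (flat bounds +/- a/2); otherwise
    b(t) = 1 - u(t). When the bound collapses to the floor, all surviving
    mass is absorbed over the next step, split evenly between the two bounds
    (chance accuracy at full collapse).

    Raises if ``dt`` > 2 ms or if the discretization produces negative
    density / mass-conservation violations beyond 1e-3.
    """
    if dt > 2e-3 + 1e-12:
        raise ValueError("dt must be <= 2 ms for the renewal discretization")
    n = int(round(t_max / dt))
    t = dt * np.arange(1, n + 1)
    b, bp = _bound_arrays(p, u, t)

    collapsed = np.nonzero(b <= BOUND_FLOOR)[0]
    kc = int(collapsed[0]) if collapsed.size else n
    b = np.maximum(b, BOUND_FLOOR)  # solver stability below the floor

    drifts, weights = _gh_drifts(p)
    g_up = np.zeros(n)
    g_lo = np.zeros(n)
    for mu, w in zip(drifts, weights):
        g1, g2 = _renewal_core(t, b, bp, float(mu), p.s, kc)
        g_up += w * g1
        g_lo += w * g2

    neg_mass = -dt * (np.sum(np.minimum(g_up, 0.0)) + np.sum(np.minimum(g_lo, 0.0)))
    if neg_mass > 1e-3:
        raise RuntimeError(
            "renewal solver produced substantially negative density mass; use a smaller dt"
        )
    g_up = np.maximum(g_up, 0.0)
    g_lo = np.maximum(g_lo, 0.0)

    absorbed = dt * float(np.sum(g_up + g_lo))
    if absorbed > 1.0 + 1e-3:
        raise RuntimeError(
            f"mass conservation violated (absorbed {absorbed:.4f} > 1); use a smaller dt"
        )
    survival = max(1.0 - absorbed, 0.0)
    if kc < n:
        # full collapse: dump surviving mass at the collapse step, 50/50
        g_up[kc] += survival / (2.0 * dt)
        g_lo[kc] += survival / (2.0 * dt)
        survival = 0.0
    return FPTGrid(t=t, g_correct=g_up, g_error=g_lo, survival=survival)


# ----------------------------------------------------------------------------
# Monte-Carlo simulation (Euler-Maruyama oracle and behaviour generator)
# ----------------------------------------------------------------------------

def simulate_ddm(
    p: DDMParams,
    u: UrgencyParams | None,
    n: int,
    dt: float = 1e-3,
    t_max: float = 6.0,
    seed: int | np.random.Generator = 0,
    regime: str = "FR",
    deadline: float | None = None,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Forward-simulate the diffusion and return a trial table.

    Euler-Maruyama paths with step ``dt`` (noise increments scaled by
    sqrt(dt)); the first crossing of +/- b(t) sets the choice and decision
    time; RT = decision time + t_er. A Brownian-bridge correction accounts
    for within-step boundary excursions that discrete sampling would miss.
    When the bound is fully collapsed all still-active paths are absorbed
    immediately, the choice taken from the sign of the diffusion state (ties
    broken at random). Paths that never cross within ``t_max`` are returned
    with ``censored=1`` and rt = NaN.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(t_max / dt))
    t = dt * np.arange(1, n_steps + 1)
    b, _ = _bound_arrays(p, u, t)

    drift = np.full(n, p.v)
    if p.eta > 0:
        drift = rng.normal(p.v, p.eta, size=n)

    x = np.zeros(n)
    active = np.ones(n, dtype=bool)
    dec_time = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    sqdt = math.sqrt(dt)
    var = p.s * p.s * dt
    b_prev = b[0]
    for k in range(n_steps):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        x_old = x[idx].copy()
        x[idx] += drift[idx] * dt + p.s * sqdt * rng.standard_normal(idx.size)
        bk = b[k]
        if bk <= BOUND_FLOOR:
            # full collapse: absorb everything still active
            sign = np.sign(x[idx])
            zero = sign == 0
            if np.any(zero):
                sign[zero] = rng.choice([-1.0, 1.0], size=int(zero.sum()))
            upper[idx] = sign > 0
            dec_time[idx] = t[k]
            active[idx] = False
            break
        x_new = x[idx]
        hit_up = x_new >= bk
        hit_lo = x_new <= -bk
        # Brownian-bridge probability of an unobserved within-step excursion
        inside = ~(hit_up | hit_lo)
        if np.any(inside):
            xo, xn = x_old[inside], x_new[inside]
            p_up = np.exp(-2.0 * np.maximum(b_prev - xo, 0.0)
                          * np.maximum(bk - xn, 0.0) / var)
            p_lo = np.exp(-2.0 * np.maximum(b_prev + xo, 0.0)
                          * np.maximum(bk + xn, 0.0) / var)
            draw = rng.random(int(inside.sum()))
            bridge_up = draw < p_up
            bridge_lo = (~bridge_up) & (draw < p_up + p_lo)
            hit_up[inside] |= bridge_up
            hit_lo[inside] |= bridge_lo
        hit = hit_up | hit_lo
        if np.any(hit):
            hidx = idx[hit]
            upper[hidx] = hit_up[hit]
            dec_time[hidx] = t[k]
            active[hidx] = False
        b_prev = bk

    censored = active.copy()
    rt = dec_time + p.t_er
    accuracy = upper.astype(int)
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "regime": regime,
            "rt": rt,
            "accuracy": accuracy,
            "censored": censored.astype(int),
        }
    )
    dl = deadline if deadline is not None else np.inf
    df["missed"] = ((df["regime"] == "DL") & (df["rt"] > dl)).astype(int)
    df.loc[censored, "accuracy"] = 0
    return df


# ----------------------------------------------------------------------------
# Likelihood, fitting, model comparison
# ----------------------------------------------------------------------------

def loglik_dataset(
    trials: pd.DataFrame,
    p: DDMParams,
    urgency: dict[str, UrgencyParams] | UrgencyParams | None,
    dt: float = 2e-3,
    deadline: float = 1.4,
    t_er: dict[str, float] | None = None,
    rt_ceiling: float = 5.0,
) -> float:
    """Log-likelihood of a trial table under a (standard or urgency) DDM.

    ``urgency`` may be a single UrgencyParams, a dict keyed by regime, or
    None (standard DDM). ``t_er`` optionally overrides the non-decision time
    per regime. Correct trials score the correct-bound density at
    (rt - t_er), errors the error-bound density, with linear interpolation on
    the grid; censored or missed-deadline trials contribute the log survival
    mass beyond the deadline. Trials with rt < t_er contribute a floor
    density. FR trials with rt > ``rt_ceiling`` are excluded.
    """
    total = 0.0
    for regime, sub in trials.groupby("regime", sort=True):
        if regime == "FR":
            keep = sub["censored"].astype(bool) | (sub["rt"] <= rt_ceiling)
            sub = sub[keep]
        u_reg = urgency.get(regime) if isinstance(urgency, dict) else urgency
        ter = t_er.get(regime, p.t_er) if t_er is not None else p.t_er
        preg = replace(p, t_er=ter)
        cens = sub["censored"].astype(bool).to_numpy() | sub["missed"].astype(bool).to_numpy()
        obs_rt = sub["rt"].to_numpy()
        finite = np.isfinite(obs_rt)
        t_need = (np.max(obs_rt[finite]) if finite.any() else deadline) - ter
        t_max = max(t_need + 0.1, deadline - ter + 0.1, 0.2)
        grid = fpt_density(preg, u_reg, dt=dt, t_max=t_max)
        acc = sub["accuracy"].to_numpy()

        dec_t = obs_rt - ter
        g_c = np.interp(dec_t, grid.t, grid.g_correct, left=0.0, right=0.0)
        g_e = np.interp(dec_t, grid.t, grid.g_error, left=0.0, right=0.0)
        dens = np.where(acc == 1, g_c, g_e)
        dens = np.where(np.isfinite(dec_t) & (dec_t > 0), dens, 0.0)
        dens = np.maximum(dens, DENSITY_FLOOR)

        ll = np.where(cens, 0.0, np.log(dens))
        if cens.any():
            surv = max(grid.survival_at(deadline - ter), DENSITY_FLOOR)
            ll = ll + cens * math.log(surv)
        total += float(np.sum(ll))
    return total


class _ParamCodec:
    """Bijective map between named, bounded parameters and R^n."""

    def __init__(self, spec: dict[str, tuple[float, float, float]]):
        # spec: name -> (init, lo, hi); hi may be inf (log-scale from lo)
        self.names = list(spec)
        self.spec = spec

    def encode(self, values: dict[str, float]) -> np.ndarray:
        out = []
        for name in self.names:
            _, lo, hi = self.spec[name]
            v = values[name]
            if np.isinf(hi):
                out.append(math.log(max(v - lo, 1e-12)))
            else:
                frac = (v - lo) / (hi - lo)
                out.append(float(logit(np.clip(frac, 1e-9, 1 - 1e-9))))
        return np.array(out)

    def decode(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for name, xi in zip(self.names, x):
            _, lo, hi = self.spec[name]
            if np.isinf(hi):
                out[name] = lo + math.exp(min(xi, 50.0))
            else:
                out[name] = lo + (hi - lo) * float(expit(xi))
        return out


def _default_spec(model: str, trials: pd.DataFrame) -> dict[str, tuple[float, float, float]]:
    rt = trials.loc[trials["censored"] == 0, "rt"]
    min_rt = float(rt.min()) if len(rt) else 0.3
    if model == "standard":
        return {
            "v": (0.1, -1.0, 1.0),
            "a": (0.15, 0.02, 1.0),
            "t_er": (0.8 * min_rt, 0.05, max(min_rt, 0.06)),
        }
    return {
        "v": (0.1, -1.0, 1.0),
        "u0": (0.3, 0.0, 0.999),
        "k": (0.1, 1e-3, np.inf),
        "lam": (0.5, 1e-3, np.inf),
        "t_er": (0.8 * min_rt, 0.05, max(min_rt, 0.06)),
    }


def fit_mle(
    trials: pd.DataFrame,
    model: str = "urgency",
    free: dict[str, tuple[float, float, float]] | None = None,
    fixed: dict[str, float] | None = None,
    per_regime: tuple[str, ...] = (),
    seed: int = 0,
    dt: float = 2e-3,
    deadline: float = 1.4,
    n_starts: int = 5,
    maxfev: int = 400,
) -> FitResult:
    """Multistart Nelder-Mead maximum-likelihood fit of one model class.

    ``free`` maps parameter names (standard: v, eta, a, t_er; urgency: v,
    eta, u0, k, lam, t_er, ceiling) to (init, lo, hi) tuples; omitted
    parameters take the values in ``fixed`` (or the class defaults). Names
    listed in ``per_regime`` get an independent copy per regime present in
    the data (e.g. urgency shape and t_er varying across speed regimes while
    v and eta are shared). ``n_starts`` seeded Nelder-Mead restarts run from
    jittered starts and the best is retained (all starts recorded). With an
    empty ``free`` the log-likelihood of the fixed point is returned without
    any search.
    """
    if model not in ("standard", "urgency"):
        raise ValueError(f"unknown model class {model!r}")
    fixed = dict(fixed or {})
    base_spec = _default_spec(model, trials) if free is None else dict(free)
    regimes = sorted(trials["regime"].unique())
    per_regime = tuple(p for p in per_regime if p in base_spec)
    if per_regime and len(regimes) < 2:
        per_regime = ()
    spec: dict[str, tuple[float, float, float]] = {}
    for name, tpl in base_spec.items():
        if name in per_regime:
            for reg in regimes:
                spec[f"{name}@{reg}"] = tpl
        else:
            spec[name] = tpl
    codec = _ParamCodec(spec)

    def build(values: dict[str, float]):
        merged = {**fixed, **values}

        def get(name, reg, default):
            if f"{name}@{reg}" in merged:
                return merged[f"{name}@{reg}"]
            return merged.get(name, default)

        # shared diffusion parameters (per-regime t_er handled separately)
        p = DDMParams(
            v=merged.get("v", 0.1),
            eta=merged.get("eta", 0.0),
            a=merged.get("a", merged.get(f"a@{regimes[0]}", 1.0)),
            t_er=get("t_er", regimes[0], 0.3),
        )
        t_er = {reg: get("t_er", reg, 0.3) for reg in regimes}
        if model == "standard":
            return p, None, t_er
        urg = {
            reg: UrgencyParams(
                u0=get("u0", reg, 0.0),
                k=get("k", reg, np.inf),
                lam=get("lam", reg, 0.0),
                ceiling=get("ceiling", reg, 1.0),
            )
            for reg in regimes
        }
        return p, urg, t_er

    def negll(x: np.ndarray) -> float:
        try:
            p, u, t_er = build(codec.decode(x))
            return -loglik_dataset(trials, p, u, dt=dt, deadline=deadline, t_er=t_er)
        except (ValueError, RuntimeError):
            return 1e12

    n_trials = int(len(trials))
    if not spec:
        p, u, t_er = build({})
        ll = loglik_dataset(trials, p, u, dt=dt, deadline=deadline, t_er=t_er)
        return FitResult(params=p, urgency=u, loglik=ll, n_free=0, n_trials=n_trials)

    rng = np.random.default_rng(seed)
    x0 = codec.encode({k: v[0] for k, v in spec.items()})
    starts = [x0] + [x0 + rng.normal(0, 0.5, size=x0.size) for _ in range(n_starts - 1)]
    records: list[tuple[float, np.ndarray]] = []
    best = None
    for s0 in starts:
        res = minimize(negll, s0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-4})
        records.append((float(res.fun), res.x.copy()))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("all optimization starts failed")
    values = codec.decode(best.x)
    p, u, _ = build(values)
    fit = FitResult(
        params=p,
        urgency=u,
        loglik=-float(best.fun),
        n_free=len(spec),
        n_trials=n_trials,
    )
    fit.starts = records
    return fit


def compare_models(
    fits_a: list[FitResult], fits_b: list[FitResult]
) -> dict[str, object]:
    """Per-subject BIC comparison of two model classes (paired).

    Returns the per-subject delta-BIC vector (model A minus model B; negative
    values favour A), its median, and the two-sided Wilcoxon signed-rank
    p-value. All-zero differences give p = 1.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("paired fit lists must have equal length")
    delta = np.array([fa.bic - fb.bic for fa, fb in zip(fits_a, fits_b)])
    if np.allclose(delta, 0.0):
        stat, pval = 0.0, 1.0
    else:
        stat, pval = wilcoxon(delta)
    return {
        "delta_bic": delta,
        "median_delta_bic": float(np.median(delta)),
        "wilcoxon_stat": float(stat),
        "p_value": float(pval),
    }
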