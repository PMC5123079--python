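"""Piece-wise logistic conditional accuracy functions (CAFs).

The CAF relates single-trial accuracy (1 = correct, 0 = error) to RT. To
capture both an initial rising portion (fast premature errors) and the
dominant declining portion, accuracy is regressed onto RT with a piece-wise
logistic model split at an inflection point alpha:

    p(rt) = logistic(beta0 + beta1 * (rt - alpha))   for rt <  alpha
    p(rt) = logistic(beta0 + beta2 * (rt - alpha))   for rt >= alpha

beta0 is the (logit) accuracy at alpha, beta1 (constrained >= 0) the
pre-alpha slope, beta2 the post-alpha slope. Parameters minimize the
combined sum of squared errors (SSE); alpha is found by exhaustive grid
search (10 ms steps ending at 1 s). Because whichever segment is fit first
determines beta0, the inner fits are run in both orders (left-first and
right-first) and the lower-SSE solution kept.

Accuracy at the response deadline is read off the fitted curve at
RT = 1.4 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "CAFFit",
    "fit_piecewise_caf",
    "caf_predict",
    "accuracy_at_deadline",
    "binned_caf",
]

_P_CLIP = 1e-9  # keep SSE finite under extreme logits


@dataclass
class CAFFit:
    """Fitted piece-wise logistic CAF."""

    alpha: float
    beta0: float
    beta1: float
    beta2: float
    sse: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.beta1 < 0:
            raise ValueError("beta1 must be >= 0")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


def _predict(rt, alpha, beta0, beta1, beta2):
    rt = np.asarray(rt, dtype=float)
    slope = np.where(rt < alpha, beta1, beta2)
    p = expit(beta0 + slope * (rt - alpha))
    return np.clip(p, _P_CLIP, 1.0 - _P_CLIP)


def caf_predict(fit: CAFFit, rt):
    """Predicted accuracy at RT(s) > 0; continuous at alpha."""
    rt_arr = np.asarray(rt, dtype=float)
    if np.any(rt_arr <= 0):
        raise ValueError("rt must be > 0")
    out = _predict(rt_arr, fit.alpha, fit.beta0, fit.beta1, fit.beta2)
    return out if rt_arr.ndim else float(out)


def accuracy_at_deadline(fit: CAFFit, deadline: float = 1.4) -> float:
    """Fitted accuracy at the deadline, as a percentage."""
    return 100.0 * float(caf_predict(fit, deadline))


def _sse_segment(y, x, beta0, slope):
    p = np.clip(expit(beta0 + slope * x), _P_CLIP, 1.0 - _P_CLIP)
    return float(np.sum((y - p) ** 2))


def _fit_alpha(rt, acc, alpha, rng, n_restarts=3, warm=None):
    """Best (beta0, beta1, beta2, sse) at one alpha over both fit orders.

    ``warm`` optionally carries the previous alpha's solutions per order;
    because the SSE surface changes slowly along the alpha grid, warm starts
    both speed up and stabilize the inner Nelder-Mead runs.
    """
    left = rt < alpha
    xl, yl = rt[left] - alpha, acc[left]
    xr, yr = rt[~left] - alpha, acc[~left]
    if xr.size == 0:
        return None
    warm = warm or {}
    if xl.size == 0:
        # no trials before alpha (no premature responses): the left segment
        # is vacuous; fit a single declining logistic with beta1 = 0
        w = warm.get("right")

        def f1(th):
            return _sse_segment(yr, xr, th[0], th[1])

        x0 = np.array([w[0], w[2]]) if w else np.array([0.5, -1.0])
        th1 = _nm(f1, x0, rng, n_restarts)
        b0, b2 = th1[0], th1[1]
        sse = _sse_segment(yr, xr, b0, b2)
        sol = (b0, 0.0, b2, sse)
        return sol, {"left": sol, "right": sol}

    def run(order):
        # first-fit segment determines beta0; the other segment's slope is
        # then fit with beta0 held fixed
        w = warm.get(order)
        if order == "left":
            def f1(th):
                return _sse_segment(yl, xl, th[0], abs(th[1]))
            x0 = np.array([w[0], w[1]]) if w else np.array([0.5, 0.5])
            th1 = _nm(f1, x0, rng, n_restarts)
            b0, b1 = th1[0], abs(th1[1])

            def f2(th):
                return _sse_segment(yr, xr, b0, th[0])
            th2 = _nm(f2, np.array([w[2] if w else -1.0]), rng, n_restarts)
            b2 = th2[0]
        else:
            def f1(th):
                return _sse_segment(yr, xr, th[0], th[1])
            x0 = np.array([w[0], w[2]]) if w else np.array([0.5, -1.0])
            th1 = _nm(f1, x0, rng, n_restarts)
            b0, b2 = th1[0], th1[1]

            def f2(th):
                return _sse_segment(yl, xl, b0, abs(th[0]))
            th2 = _nm(f2, np.array([w[1] if w else 0.5]), rng, n_restarts)
            b1 = abs(th2[0])
        sse = _sse_segment(yl, xl, b0, b1) + _sse_segment(yr, xr, b0, b2)
        return b0, b1, b2, sse

    sols = {order: run(order) for order in ("left", "right")}
    order = min(sols, key=lambda o: sols[o][3])
    return sols[order], sols


def _nm(fun, x0, rng, n_restarts):
    best_x, best_f = None, np.inf
    starts = [x0] + [x0 + rng.normal(0, 0.5, size=x0.size) for _ in range(n_restarts - 1)]
    for s in starts:
        res = minimize(fun, s, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxfev": 400})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    return best_x


def fit_piecewise_caf(
    trials: pd.DataFrame,
    rt_ceiling: float = 5.0,
    alpha_grid: np.ndarray | None = None,
    seed: int = 0,
) -> CAFFit:
    """Fit the piece-wise logistic CAF to a trial table.

    Trials with RT above ``rt_ceiling`` (default 5 s, the free-response
    exclusion rule) or without a finite RT are dropped. The alpha grid
    defaults to 0.15..1.0 s in 10 ms steps; alphas leaving an empty segment
    are skipped; SSE ties break toward smaller alpha. Requires >= 50 trials
    containing both correct and error outcomes.
    """
    df = trials
    keep = df["rt"].notna() & (df["rt"] <= rt_ceiling)
    if "censored" in df.columns:
        keep &= df["censored"] == 0
    rt = df.loc[keep, "rt"].to_numpy(dtype=float)
    acc = df.loc[keep, "accuracy"].to_numpy(dtype=float)
    if rt.size < 50:
        raise ValueError(f"need >= 50 usable trials, got {rt.size}")
    if acc.min() == acc.max():
        raise ValueError("all-correct or all-error data: logit accuracy unidentifiable")

    if alpha_grid is None:
        alpha_grid = np.arange(0.15, 1.0 + 1e-9, 0.01)
    rng = np.random.default_rng(seed)
    best = None
    warm = None
    for i, alpha in enumerate(alpha_grid):
        # continuation along the grid: 1 warm-started run per alpha, full
        # 3-restart fits at the first alpha and (below) at the winner
        n_restarts = 3 if i == 0 else 1
        res = _fit_alpha(rt, acc, float(alpha),
                         np.random.default_rng(rng.integers(2**31)),
                         n_restarts=n_restarts, warm=warm)
        if res is None:
            continue
        (b0, b1, b2, sse), warm = res
        if best is None or sse < best[4] - 1e-12:  # strict: ties keep smaller alpha
            best = (float(alpha), b0, b1, b2, sse)
    if best is not None:
        # polish the winning alpha with the full restart budget
        res = _fit_alpha(rt, acc, best[0], np.random.default_rng(seed + 1),
                         n_restarts=3, warm={"left": best[1:4], "right": best[1:4]})
        if res is not None and res[0][3] < best[4]:
            b0, b1, b2, sse = res[0]
            best = (best[0], b0, b1, b2, sse)
    if best is None:
        raise ValueError("no alpha in the grid produced two non-empty segments")
    alpha, b0, b1, b2, sse = best
    return CAFFit(alpha=alpha, beta0=float(b0), beta1=float(b1), beta2=float(b2),
                  sse=float(sse), n_trials=int(rt.size))


def binned_caf(trials: pd.DataFrame, n_bins: int = 25) -> pd.DataFrame:
    """Equal-count RT bins with per-bin mean RT, mean accuracy, and s.e.m.

    Ties across bin edges are broken by a stable sort on RT.
    """
    df = trials
    keep = df["rt"].notna()
    if "censored" in df.columns:
        keep &= df["censored"] == 0
    rt = df.loc[keep, "rt"].to_numpy(dtype=float)
    acc = df.loc[keep, "accuracy"].to_numpy(dtype=float)
    if rt.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} trials, got {rt.size}")
    order = np.argsort(rt, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        a = acc[chunk]
        sem = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
        rows.append({"rt": rt[chunk].mean(), "accuracy": a.mean(),
                     "sem": sem, "n": a.size})
    return pd.DataFrame(rows)
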