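"""Linear-systems analysis of task-evoked pupil dilation.

The phasic neural input to the peripheral pupil system during a trial is
modelled as a linear combination of three temporal components — a transient
at stimulus onset, a sustained component spanning the decision interval, and
a transient at response — each convolved with a canonical pupil impulse
response function (IRF)

    h(t) = t^w * exp(-w * t / t_max),

rescaled to unit peak, with shape w = 10.1 and time-to-peak
t_max = 930 ms. Eight candidate shapes of the sustained component are
compared by ordinary least squares and the least-squares form of the BIC,

    BIC = n * ln(SSR / n) + k * ln(n),

with group-level comparison of paired BIC differences by Wilcoxon
signed-rank tests. A monotone up-ramp winning over the boxcar diagnoses a
time-dependent increase in the input to the pupil system (urgency via gain).

Sustained-component geometries (unit height pre-convolution; regression betas
carry all scaling; D = decision interval duration = RT):

1. boxcar: constant 1 over the decision interval;
2. up-ramp: 0 at onset rising linearly to 1 at response;
3. ramp-to-threshold: fixed shared slope, terminating at a common peak of 1
   at response (clipped at 0 early in slow trials);
4. linear decay, RT-scaled start: starts at D / median(D), decays to 0 at
   response (larger start for slower trials);
5. decay-to-threshold: starts at fixed 1, decays to 0 at response;
6-8. the boxcar, up-ramp and down-ramp (shape 5 geometry) divided by the
   number of samples in the trial's decision interval (negative RT
   modulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

__all__ = [
    "IRFParams",
    "pupil_irf",
    "trial_components",
    "build_design",
    "fit_glm",
    "select_model",
    "GLMFit",
    "SUSTAINED_SHAPES",
]

SUSTAINED_SHAPES = {
    1: "boxcar",
    2: "up-ramp",
    3: "ramp-to-threshold",
    4: "linear decay (RT-scaled start)",
    5: "decay-to-threshold",
    6: "RT-normalized boxcar",
    7: "RT-normalized up-ramp",
    8: "RT-normalized down-ramp",
}

#: IRF support truncation (s) for convolution.
IRF_SUPPORT = 4.0


@dataclass(frozen=True)
class IRFParams:
    """Canonical pupil IRF parameters: shape ``w`` (dimensionless) and
    time-to-peak ``t_max`` in milliseconds."""

    w: float = 10.1
    t_max: float = 930.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.t_max <= 0:
            raise ValueError("IRF parameters w and t_max must be positive")


def pupil_irf(p: IRFParams, t_ms) -> np.ndarray:
    """Evaluate the unit-peak IRF at times ``t_ms`` (milliseconds, >= 0).

    The unnormalized kernel t^w exp(-w t / t_max) peaks analytically at
    t = t_max; the returned amplitudes are rescaled so that peak is 1.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(over="ignore"):
        h = t**p.w * np.exp(-p.w * t / p.t_max)
    peak = p.t_max**p.w * np.exp(-p.w)
    return h / peak


def _irf_kernel(irf: IRFParams, fs: float) -> np.ndarray:
    t_ms = 1000.0 * np.arange(0, IRF_SUPPORT, 1.0 / fs)
    return pupil_irf(irf, t_ms)


def _sustained_profile(shape_id: int, n_dec: int, rt: float, ref_rt: float) -> np.ndarray:
    """Pre-convolution amplitude profile over the decision interval."""
    ramp_up = np.linspace(0.0, 1.0, n_dec)
    if shape_id == 1:
        prof = np.ones(n_dec)
    elif shape_id == 2:
        prof = ramp_up
    elif shape_id == 3:
        # fixed shared slope 1/ref_rt, common peak 1 at response
        t_before_resp = rt * (1.0 - np.linspace(0.0, 1.0, n_dec))
        prof = np.clip(1.0 - t_before_resp / ref_rt, 0.0, None)
    elif shape_id == 4:
        prof = (rt / ref_rt) * ramp_up[::-1]
    elif shape_id == 5:
        prof = ramp_up[::-1]
    elif shape_id == 6:
        prof = np.ones(n_dec) / n_dec
    elif shape_id == 7:
        prof = ramp_up / n_dec
    elif shape_id == 8:
        prof = ramp_up[::-1] / n_dec
    else:
        raise ValueError(f"shape_id must be in 1..8, got {shape_id}")
    return prof


def trial_components(
    rt: float,
    shape_id: int,
    irf: IRFParams,
    fs: float = 50.0,
    ref_rt: float | None = None,
    pre: float = 0.2,
    post: float = 2.5,
) -> np.ndarray:
    """IRF-convolved (onset, sustained, response) regressor block for one
    trial, shape (n_epoch_samples, 3), on the epoch clock [-pre, rt + post].
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    if ref_rt is None:
        ref_rt = rt
    n_epoch = int(round((pre + rt + post) * fs)) + 1
    i_on = int(round(pre * fs))
    i_resp = int(round((pre + rt) * fs))
    kern = _irf_kernel(irf, fs)

    onset = np.zeros(n_epoch)
    onset[i_on] = 1.0
    response = np.zeros(n_epoch)
    response[i_resp] = 1.0
    sustained = np.zeros(n_epoch)
    n_dec = i_resp - i_on + 1
    sustained[i_on : i_resp + 1] = _sustained_profile(int(shape_id), n_dec, rt, ref_rt)

    cols = [np.convolve(c, kern)[:n_epoch] for c in (onset, sustained, response)]
    return np.column_stack(cols)


def build_design(
    traces,
    shape_id: int,
    irf: IRFParams,
    modulate_rt: bool = False,
):
    """Concatenated GLM design matrix and response vector for one session.

    Per-trial component time courses are built on the trial clock, convolved
    with the IRF, truncated to the epoch, and concatenated trial-major
    (epochs only; no inter-trial gaps). Columns: intercept, onset, sustained,
    response, and — with ``modulate_rt`` — copies of the onset and response
    components weighted by the trial's mean-centred RT.

    Trials with non-positive RT are rejected.
    """
    fs_set = {tr.fs for tr in traces}
    if len(fs_set) != 1:
        raise ValueError("all traces must share the same sampling rate")
    rts = np.array([tr.rt for tr in traces], dtype=float)
    if np.any(rts <= 0):
        bad = np.nonzero(rts <= 0)[0].tolist()
        raise ValueError(f"non-positive RT in trial(s) {bad}")
    ref_rt = float(np.median(rts))
    rt_c = rts - rts.mean()

    blocks, ys = [], []
    for i, tr in enumerate(traces):
        comps = trial_components(tr.rt, shape_id, irf, fs=tr.fs, ref_rt=ref_rt)
        n = min(len(tr.samples), comps.shape[0])
        comps = comps[:n]
        cols = [np.ones(n), comps[:, 0], comps[:, 1], comps[:, 2]]
        if modulate_rt:
            cols += [rt_c[i] * comps[:, 0], rt_c[i] * comps[:, 2]]
        blocks.append(np.column_stack(cols))
        ys.append(np.asarray(tr.samples[:n], dtype=float))
    return np.vstack(blocks), np.concatenate(ys)


@dataclass
class GLMFit:
    """Ordinary-least-squares fit with least-squares BIC."""

    betas: np.ndarray
    ssr: float
    n: int
    k: int
    bic: float
    se: np.ndarray | None = None


def fit_glm(design: np.ndarray, response: np.ndarray) -> GLMFit:
    """OLS fit; BIC = n ln(SSR/n) + k ln(n) with k = number of columns.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    n, k = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < k:
        # identify offending columns by QR pivoting on the gram matrix
        _, r = np.linalg.qr(design)
        bad = np.nonzero(np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max())[0]
        raise ValueError(f"design is rank deficient (collinear column(s) {bad.tolist()})")
    betas, _, _, _ = np.linalg.lstsq(design, response, rcond=None)
    resid = response - design @ betas
    ssr = float(resid @ resid)
    bic = n * np.log(max(ssr, 1e-300) / n) + k * np.log(n)
    sigma2 = ssr / max(n - k, 1)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return GLMFit(betas=betas, ssr=ssr, n=n, k=k, bic=float(bic),
                  se=np.sqrt(np.diag(cov)))


def select_model(
    sessions,
    irf: IRFParams = IRFParams(),
    shapes=tuple(range(1, 9)),
) -> dict[str, object]:
    """Model selection over sustained-component shapes across subjects.

    ``sessions`` is a list (one per subject) of lists of PupilTrialTrace.
    Returns per-subject BIC per shape, the winning shape (lowest summed BIC),
    a delta-BIC table relative to the winner, and Wilcoxon signed-rank
    p-values of each shape against the winner. Shapes failing to fit for a
    subject are excluded with a log entry in the report.
    """
    shapes = tuple(shapes)
    if len(shapes) < 2:
        raise ValueError("need at least 2 candidate shapes")
    bics = np.full((len(sessions), len(shapes)), np.nan)
    failures = []
    for si, traces in enumerate(sessions):
        for mi, shape in enumerate(shapes):
            try:
                X, y = build_design(traces, shape, irf)
                bics[si, mi] = fit_glm(X, y).bic
            except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
                failures.append((si, shape, str(exc)))
    ok = ~np.any(np.isnan(bics), axis=0)
    totals = np.where(ok, np.nansum(bics, axis=0), np.inf)
    win_idx = int(np.argmin(totals))
    winner = shapes[win_idx]
    delta = bics - bics[:, [win_idx]]
    pvals = {}
    for mi, shape in enumerate(shapes):
        if mi == win_idx or not ok[mi]:
            continue
        diff = delta[:, mi]
        pvals[shape] = 1.0 if np.allclose(diff, 0) else float(wilcoxon(diff).pvalue)
    return {
        "winner": winner,
        "shapes": shapes,
        "bic": bics,
        "delta_bic": delta,
        "p_vs_winner": pvals,
        "failures": failures,
    }
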