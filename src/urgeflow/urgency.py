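"""Logistic urgency signals and their equivalent collapsing decision bounds.

An urgency signal u(t) is an evidence-independent quantity, expressed in units
of the (fixed, unit) decision bound, that is added to both accumulators of a
two-alternative race. Because the two accumulators are perfectly
anti-correlated, the race is mathematically identical to a single diffusion
started at 0 between symmetric time-varying bounds +/- b(t) with
b(t) = 1 - u(t).

The time course of u is parameterized by a logistic function

    u(t) = min(u0 + (c - u0) * (L(t) - L(0)) / (1 - L(0)), 1),
    L(t) = 1 / (1 + exp(-(t - lam) / k)),

which guarantees u(0) = u0 exactly and monotone growth. With ceiling c = 1
(the default) u asymptotes at the bound; with c > 1 the logistic is clipped
where it would exceed the bound, so u *reaches* the bound — full collapse of
the effective bound, forcing commitment of all surviving trials — at a
finite time with non-vanishing slope. Depending on (k, lam) the shape is
concave, convex, approximately linear, or flat (k -> inf).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "UrgencyParams",
    "urgency_value",
    "effective_bound",
    "collapse_urgency",
    "BOUND_FLOOR",
]

#: Effective bounds below this value are treated as fully collapsed: all
#: surviving probability mass is absorbed (chance accuracy at full collapse).
BOUND_FLOOR = 1e-4


@dataclass(frozen=True)
class UrgencyParams:
    """Parameters of the logistic urgency signal.

    Attributes
    ----------
    u0 : float
        Static component of urgency, in bound units; the value of u at t=0.
        Must lie in [0, 1).
    k : float
        Shape parameter (seconds). Small k gives a step-like rise, large k a
        flat signal. ``k = inf`` is the exactly-flat limit u(t) = u0.
    lam : float
        Scale / latency parameter (seconds): the latency of the logistic's
        inflection point.
    ceiling : float
        Asymptote of the unclipped logistic. 1.0 (default) approaches the
        bound asymptotically; values > 1 make the clipped signal reach the
        bound at a finite time (full collapse).
    """

    u0: float
    k: float
    lam: float
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.u0) or not (0.0 <= self.u0 < 1.0):
            raise ValueError(f"u0 must be in [0, 1), got {self.u0!r}")
        if np.isnan(self.k) or self.k <= 0:
            raise ValueError(f"k must be positive (inf allowed), got {self.k!r}")
        if not np.isfinite(self.lam):
            raise ValueError(f"lam must be finite, got {self.lam!r}")
        if not np.isfinite(self.ceiling) or self.ceiling <= self.u0:
            raise ValueError(f"ceiling must be finite and > u0, got {self.ceiling!r}")

    @staticmethod
    def flat(u0: float) -> "UrgencyParams":
        """A time-invariant urgency signal u(t) = u0."""
        return UrgencyParams(u0=u0, k=np.inf, lam=0.0)

    @property
    def is_flat(self) -> bool:
        return np.isinf(self.k)


def urgency_value(u: UrgencyParams, t):
    """Evaluate the urgency signal u(t) at time(s) ``t`` (seconds, >= 0).

    Returns values in [u0, 1); vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if u.is_flat:
        return np.full_like(t, u.u0) if t.ndim else float(u.u0)
    lam0 = expit(-u.lam / u.k)  # L(0)
    lam_t = expit((t - u.lam) / u.k)
    out = np.minimum(u.u0 + (u.ceiling - u.u0) * (lam_t - lam0) / (1.0 - lam0), 1.0)
    return out if t.ndim else float(out)


def effective_bound(u: UrgencyParams, t):
    """Effective symmetric half-bound b(t) = 1 - u(t) of the equivalent
    single-diffusion representation. Never negative."""
    b = 1.0 - urgency_value(u, t)
    return np.maximum(b, 0.0) if np.ndim(b) else max(b, 0.0)


def urgency_slope(u: UrgencyParams, t):
    """Analytic derivative du/dt; b'(t) = -du/dt. Vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    if u.is_flat:
        return np.zeros_like(t) if t.ndim else 0.0
    lam0 = expit(-u.lam / u.k)
    lam_t = expit((t - u.lam) / u.k)
    d = (u.ceiling - u.u0) / (1.0 - lam0) * lam_t * (1.0 - lam_t) / u.k
    unclipped = u.u0 + (u.ceiling - u.u0) * (lam_t - lam0) / (1.0 - lam0)
    d = np.where(unclipped >= 1.0, 0.0, d)
    return d if t.ndim else float(d)


def collapse_urgency(
    u0: float,
    t_collapse: float,
    lam: float | None = None,
    k: float | None = None,
) -> UrgencyParams:
    """Construct a logistic urgency signal that reaches the decision bound
    exactly at decision time ``t_collapse``.

    The logistic's ceiling is solved so that the clipped signal hits 1 at
    ``t_collapse`` with non-vanishing slope: the effective bound collapses
    fully there, all surviving trials commit, and commitment at full
    collapse is at chance. Used for deadline-regime configurations in which
    misses are structurally negligible and accuracy at the deadline is at
    chance.

    Parameters
    ----------
    u0 : static urgency at t=0.
    t_collapse : decision time (s) of full collapse.
    lam : logistic latency; defaults to ``0.8 * t_collapse``.
    k : logistic shape (s); defaults to ``0.3 * t_collapse``.
    """
    if t_collapse <= 0:
        raise ValueError("t_collapse must be positive")
    if lam is None:
        lam = 0.8 * t_collapse
    if k is None:
        k = 0.3 * t_collapse
    lam0 = expit(-lam / k)
    lam_c = expit((t_collapse - lam) / k)
    if lam_c <= lam0:
        raise ValueError("t_collapse too small for the requested (k, lam)")
    ceiling = u0 + (1.0 - u0) * (1.0 - lam0) / (lam_c - lam0)
    return UrgencyParams(u0=u0, k=float(k), lam=float(lam), ceiling=float(ceiling))
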