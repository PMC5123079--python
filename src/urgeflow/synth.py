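"""Synthetic behavioural and pupillometric data generators.

The behavioural generator forward-simulates the urgency drift-diffusion
model under two speed-emphasis regimes: free response (FR) and deadline (DL,
with a 1.4 s response deadline). The default parameters define the study
conditions emulated throughout the package:

* shared diffusion parameters v = 0.12, eta = 0.05, s = 0.1, t_er = 0.3 s,
  fixed unit bound;
* DL urgency: u0 = 0.3 with a logistic rise that reaches the bound exactly
  at (deadline - t_er) = 1.1 s of decision time, making deadline misses
  structurally negligible and accuracy at the deadline chance;
* FR urgency: lower static component (u0 = 0.2) and a slower, asymptotic
  rise, giving slower, more accurate responding, many responses beyond
  1.4 s, and a much shallower conditional-accuracy decline than under
  deadline.

The pupil generator emulates per-trial pupil diameter traces as a linear
combination of three IRF-convolved temporal components (onset transient,
sustained decisional component of a chosen shape, response transient) plus
Gaussian noise, on epochs spanning 0.2 s pre-stimulus to 2.5 s
post-response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate_ddm
from .urgency import UrgencyParams, collapse_urgency

__all__ = [
    "GeneratorConfig",
    "PupilTrialTrace",
    "default_config",
    "generate_behavior",
    "generate_pupil_session",
    "read_trials",
    "write_trials",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ("subject_id", "regime", "rt", "accuracy", "missed")

#: Frozen study-condition defaults (see module docstring).
DEFAULT_DDM = DDMParams(v=0.12, eta=0.05, s=0.1, t_er=0.3)
DEFAULT_URGENCY_FR = UrgencyParams(u0=0.2, k=0.35, lam=0.9)


def _default_dl_urgency() -> UrgencyParams:
    return collapse_urgency(u0=0.3, t_collapse=1.1)


@dataclass
class GeneratorConfig:
    """Configuration of the behavioural generator.

    ``n_trials`` trials are simulated per regime; the deadline applies to the
    DL regime only. Seeds make runs byte-identical.
    """

    ddm: DDMParams = DEFAULT_DDM
    urgency_FR: UrgencyParams = DEFAULT_URGENCY_FR
    urgency_DL: UrgencyParams = field(default_factory=_default_dl_urgency)
    deadline: float = 1.4
    n_trials: int = 1000
    seed: int = 0
    dt: float = 1e-3
    t_max: float = 6.0
    subject_id: str = "s01"

    def __post_init__(self) -> None:
        if self.deadline <= 0:
            raise ValueError(f"deadline must be > 0, got {self.deadline}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")


def default_config(**overrides) -> GeneratorConfig:
    """The frozen study conditions, with optional field overrides."""
    return GeneratorConfig(**overrides)


def generate_behavior(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate FR and DL trial tables under the configured urgency DDM.

    Returns a table with columns (subject_id, regime, rt, accuracy, missed,
    censored): ``n_trials`` records per regime, RT = decision time + t_er,
    accuracy from the first bound crossed, ``missed`` flagging DL responses
    beyond the deadline. Identical config + seed gives identical tables.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for regime, urg in (("FR", config.urgency_FR), ("DL", config.urgency_DL)):
        df = simulate_ddm(
            config.ddm,
            urg,
            config.n_trials,
            dt=config.dt,
            t_max=config.t_max,
            seed=rng,
            regime=regime,
            deadline=config.deadline,
            subject_id=config.subject_id,
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------------
# Pupil session generator
# ----------------------------------------------------------------------------

@dataclass
class PupilTrialTrace:
    """One baselined pupil epoch.

    samples : diameter samples (arbitrary units), spanning exactly
        [-0.2 s pre-stimulus, +2.5 s post-response].
    fs : sampling rate (Hz).
    t_onset, t_response : event latencies (s) on the epoch clock.
    rt : response time (s) = t_response - t_onset.
    """

    samples: np.ndarray
    fs: float
    t_onset: float
    t_response: float
    rt: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rt <= 0:
            raise ValueError("rt must be positive")


def generate_pupil_session(
    shape_id: int,
    betas: tuple[float, float, float],
    irf,
    rts: np.ndarray,
    noise_sd: float = 1.0,
    fs: float = 50.0,
    seed: int = 0,
) -> list[PupilTrialTrace]:
    """Generate one subject's pupil epochs from the linear-systems model.

    Each trace is the design row for that trial (onset, sustained of shape
    ``shape_id``, response, each convolved with the pupil IRF) weighted by
    ``betas`` plus Gaussian noise of s.d. ``noise_sd``.

    ``irf`` is an :class:`urgeflow.pupil.IRFParams`. ``fs`` below 10 Hz is
    rejected (cannot resolve the IRF).
    """
    from .pupil import trial_components  # local import to avoid a cycle

    if not (1 <= int(shape_id) <= 8):
        raise ValueError(f"shape_id must be in 1..8, got {shape_id}")
    if fs < 10.0:
        raise ValueError(f"fs={fs} Hz is too low to resolve the pupil IRF (< 10 Hz)")
    rts = np.asarray(rts, dtype=float)
    if np.any(rts <= 0):
        raise ValueError("all rts must be positive")
    betas = np.asarray(betas, dtype=float)
    rng = np.random.default_rng(seed)
    ref_rt = float(np.median(rts))
    traces = []
    for rt in rts:
        comps = trial_components(rt, int(shape_id), irf, fs=fs, ref_rt=ref_rt)
        clean = comps @ betas
        samples = clean + rng.normal(0.0, noise_sd, size=clean.size)
        traces.append(
            PupilTrialTrace(
                samples=samples, fs=fs, t_onset=0.2, t_response=0.2 + rt, rt=float(rt)
            )
        )
    return traces


# ----------------------------------------------------------------------------
# Trial table I/O
# ----------------------------------------------------------------------------

def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (header: subject_id, regime, rt, accuracy,
    missed, plus any extra columns)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table lacks required column(s): {', '.join(missing)}")
    table.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`.

    Unknown columns are preserved. Raises on a missing required column, and
    on invalid rows (non-positive RT, accuracy outside {0, 1}), naming them.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} lacks required column(s): {', '.join(missing)}")
    finite = df["rt"].notna()
    bad_rt = df.index[finite & (df["rt"] <= 0)].tolist()
    if bad_rt:
        raise ValueError(f"non-positive rt in row(s) {bad_rt}")
    bad_acc = df.index[~df["accuracy"].isin([0, 1])].tolist()
    if bad_acc:
        raise ValueError(f"accuracy outside {{0,1}} in row(s) {bad_acc}")
    return df
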