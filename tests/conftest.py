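import numpy as np
import pandas as pd
import pytest

from urgeflow import DDMParams, UrgencyParams, default_config, generate_behavior
from urgeflow.urgency import collapse_urgency


@pytest.fixture(scope="session")
def dl_trials_medium():
    """12k deadline-regime trials from the frozen study-condition generator."""
    cfg = default_config(n_trials=12000, seed=42)
    trials = generate_behavior(cfg)
    return trials[trials["regime"] == "DL"].reset_index(drop=True)


@pytest.fixture(scope="session")
def fr_trials_medium():
    cfg = default_config(n_trials=12000, seed=42)
    trials = generate_behavior(cfg)
    return trials[trials["regime"] == "FR"].reset_index(drop=True)


@pytest.fixture(scope="session")
def dl_urgency():
    """The frozen deadline urgency signal (full collapse at 1.1 s)."""
    return collapse_urgency(u0=0.3, t_collapse=1.1)


@pytest.fixture(scope="session")
def base_params():
    return DDMParams(v=0.12, eta=0.05, t_er=0.3)


def make_piecewise_logistic_trials(seed, n=20000, alpha=0.4, b0=1.5, b1=2.0, b2=-3.0):
    """Generate-and-refit oracle data for the piece-wise logistic CAF."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    n_left = int(0.4 * n)
    rt = np.concatenate(
        [rng.uniform(0.1, alpha, n_left), rng.uniform(alpha, 1.2, n - n_left)]
    )
    slope = np.where(rt < alpha, b1, b2)
    p = expit(b0 + slope * (rt - alpha))
    acc = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"rt": rt, "accuracy": acc})
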