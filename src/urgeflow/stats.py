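"""Small group-level statistics helper.

Group-level significance of per-subject effects is tested with a one-sample
t-test (H0: effect = 0) or, for paired model-comparison differences, a
Wilcoxon signed-rank test. All tests are two-tailed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

__all__ = ["group_stats"]


def group_stats(values_by_subject, test: str = "t_one_sample") -> dict[str, float]:
    """Two-tailed group test on one value per subject.

    ``test`` is ``"t_one_sample"`` (H0: mean = 0) or ``"wilcoxon_paired"``
    (H0: symmetric differences around 0; pass per-subject differences).
    Requires >= 5 subjects. An all-identical vector under Wilcoxon returns
    p = 1 with a warning.
    """
    x = np.asarray(values_by_subject, dtype=float)
    if x.ndim != 1:
        raise ValueError("values_by_subject must be one value per subject")
    if x.size < 5:
        raise ValueError(f"need >= 5 subjects, got {x.size}")
    if test == "t_one_sample":
        res = sps.ttest_1samp(x, 0.0)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n": x.size}
    if test == "wilcoxon_paired":
        if np.ptp(x) == 0:
            warnings.warn("all differences identical; Wilcoxon uninformative, p = 1")
            return {"statistic": 0.0, "p_value": 1.0, "n": x.size}
        res = sps.wilcoxon(x)
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n": x.size}
    raise ValueError(f"unknown test {test!r}")
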