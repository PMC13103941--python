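"""Signature-score survival stratification.

Patients are dichotomized at the median of a per-patient signature score
(computed with the same module-score procedure used on single cells) and the
two arms are compared with the Kaplan-Meier product-limit estimator and the
log-rank test.  Estimation and testing delegate to ``lifelines``; events
precede censoring at tied times (the standard convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


def stratify_by_score(scores: pd.Series) -> pd.Series:
    """'high' iff score strictly above the median of all scored patients."""
    if len(scores) < 2:
        raise ValueError("need at least 2 patients")
    median = float(scores.median())
    return pd.Series(np.where(scores > median, "high", "low"),
                     index=scores.index, name="group")


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> time, survival, at_risk
    chi2: float | None = None
    p: float | None = None


def km_estimate(times, events, groups) -> KMResult:
    """Kaplan-Meier product-limit curves per group.

    S(t) is the product over event times <= t of (1 - d_i / n_i); censored
    subjects leave the risk set after their time.
    """
    times = np.asarray(times, float)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        curves[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
            "at_risk": at_risk.to_numpy(float),
        }).reset_index(drop=True)
    return KMResult(curves)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test: chi-square (1 df) and its upper-tail p.

    With zero events overall the test is undefined; p = 1 with a warning.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank p = 1")
        return 0.0, 1.0
    a = groups == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def km_by_score(
    scores: pd.Series, clinical: pd.DataFrame
) -> tuple[pd.Series, KMResult]:
    """Median-dichotomize scores and run KM + log-rank on the two strata."""
    strata = stratify_by_score(scores.loc[clinical.index])
    result = km_estimate(clinical["time"], clinical["event"], strata.to_numpy())
    chi2, p = logrank_test(clinical["time"], clinical["event"], strata.to_numpy())
    result.chi2, result.p = chi2, p
    return strata, result
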