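"""Kaplan-Meier estimation and log-rank stratification.

Thin, validated wrappers around lifelines, returning a
:class:`SurvivalResult` that exposes the per-group product-limit step
functions (with at-risk bookkeeping) plus the log-rank chi-square and
p-value for two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .bulk import BulkCohort, quantile_stratify, signature_score
from .matrix import GeneSet, ValidationError


@dataclass
class GroupCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int


@dataclass
class SurvivalResult:
    curves: dict[str, GroupCurve] = field(default_factory=dict)
    statistic: float | None = None
    df: int | None = None
    p_value: float | None = None
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "group_sizes": self.group_sizes,
        }
        d["curves"] = {
            str(g): {"times": c.times.tolist(),
                     "survival": c.survival.tolist(),
                     "at_risk": c.at_risk.tolist(),
                     "n": c.n}
            for g, c in self.curves.items()
        }
        return d


def _check_times(times: np.ndarray) -> None:
    if (times <= 0).any():
        raise ValidationError("survival times must be positive")


def km_estimate(times, events, groups) -> SurvivalResult:
    """Product-limit survival curve per group, with at-risk counts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    _check_times(times)

    result = SurvivalResult()
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValidationError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        result.curves[str(g)] = GroupCurve(
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            at_risk=tab["at_risk"].to_numpy(dtype=float),
            n=int(mask.sum()),
        )
        result.group_sizes[str(g)] = int(mask.sum())
    return result


def logrank_test(times, events, groups) -> SurvivalResult:
    """Two-group log-rank chi-square (1 df): observed minus expected events
    under hypergeometric at-risk allocation, squared over its variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    _check_times(times)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    m0, m1 = groups == labels[0], groups == labels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValidationError("empty group")

    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    out = km_estimate(times, events, groups)
    out.statistic = float(res.test_statistic)
    out.df = 1
    out.p_value = float(res.p_value)
    return out


def survival_by_signature(cohort: BulkCohort, sig: GeneSet,
                          low_q: float = 0.20,
                          drop_middle: bool = False) -> SurvivalResult:
    """Score the cohort, split at the ``low_q`` score quantile, and compare
    the two strata by Kaplan-Meier / log-rank."""
    table = signature_score(cohort, sig)
    strata = quantile_stratify(table.scores.astype(float), low_q=low_q,
                               drop_middle=drop_middle)
    keep = strata.notna()
    strata = strata[keep]
    meta = cohort.meta.loc[strata.index]
    return logrank_test(meta["time"].to_numpy(dtype=float),
                        meta["event"].to_numpy(dtype=int),
                        strata.to_numpy())
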