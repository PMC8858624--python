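"""±1 median-dichotomized signature scoring of bulk cohorts and the
metastasis-group comparison.

For each signature gene, a sample scores +1 when its expression is strictly
above the cohort median of that gene and -1 otherwise (ties score -1); the
per-sample sum over covered signature genes is the signature score.  With a
20-gene signature the score therefore lies in {-20, -18, ..., +20} and has
the same parity as the number of covered genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GeneSet, ValidationError

LN_MET = "LN_met"
NON_LN_MET = "non_LN_met"


@dataclass
class BulkCohort:
    """Normalized bulk expression (genes x samples) with per-sample metadata.

    ``meta`` is indexed by sample id and carries ``metastasis_group``
    (:data:`LN_MET` / :data:`NON_LN_MET`), ``time`` (survival time, unit in
    ``time_unit``), ``event`` (1 = death observed) and optionally
    ``histology``.
    """

    expr: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if "sample" in self.meta.columns:
            self.meta = self.meta.set_index("sample")
        missing = set(self.expr.columns) - set(self.meta.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} expression samples lack metadata"
            )
        self.meta = self.meta.loc[list(self.expr.columns)]
        if (pd.to_numeric(self.meta["time"]) <= 0).any():
            raise ValidationError("survival times must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    def filter_histology(self, keep: list[str]) -> "BulkCohort":
        """Restrict to samples whose histology is in ``keep`` (e.g.
        intestinal and mixed types)."""
        if "histology" not in self.meta.columns:
            raise ValidationError("cohort has no histology annotation")
        samples = self.meta.index[self.meta["histology"].isin(keep)]
        return BulkCohort(expr=self.expr[list(samples)],
                          meta=self.meta.loc[list(samples)].reset_index()
                          .rename(columns={"index": "sample"}),
                          time_unit=self.time_unit)


@dataclass
class SignatureScoreTable:
    scores: pd.Series          # sample id -> integer score
    coverage: int              # signature genes found in the cohort

    def __post_init__(self) -> None:
        if (self.scores.abs() > self.coverage).any():
            raise ValidationError("|score| cannot exceed coverage")


def signature_score(cohort: BulkCohort, sig: GeneSet) -> SignatureScoreTable:
    """Sum of per-gene ±1 votes over the covered signature genes.

    Per gene the median is taken across the cohort's samples (median of an
    even count = mean of the two central order statistics); a sample votes
    +1 when strictly above it, -1 otherwise.
    """
    present = [g for g in sig.genes if g in cohort.expr.index]
    if not present:
        raise ValidationError(
            f"no gene of signature {sig.name!r} present in cohort"
        )
    sub = cohort.expr.loc[present]                       # genes x samples
    medians = sub.median(axis=1)
    votes = np.where(sub.gt(medians, axis=0), 1, -1)
    scores = pd.Series(votes.sum(axis=0), index=sub.columns, dtype=int,
                       name=sig.name)
    return SignatureScoreTable(scores=scores, coverage=len(present))


def compare_score_groups(table: SignatureScoreTable,
                         meta: pd.DataFrame) -> dict:
    """Welch two-sample t-test of signature scores by metastasis group."""
    groups = meta.loc[table.scores.index, "metastasis_group"]
    a = table.scores[groups == LN_MET].to_numpy(dtype=float)
    b = table.scores[groups == NON_LN_MET].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each metastasis group needs >= 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no variance anywhere
        t, p = (np.inf, 0.0) if a.mean() != b.mean() else (0.0, 1.0)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_LN_met": float(a.mean()),
        "mean_non_LN_met": float(b.mean()),
        "n_LN_met": int(len(a)),
        "n_non_LN_met": int(len(b)),
        "t_statistic": t,
        "p_value": p,
    }


def quantile_stratify(values: pd.Series, low_q: float = 0.25,
                      drop_middle: bool = False) -> pd.Series:
    """Label samples ``low`` / ``high`` at the ``low_q`` empirical quantile.

    Samples at or below the quantile are low, the rest high.  With
    ``drop_middle`` the split becomes bottom ``low_q`` vs top ``low_q`` and
    the middle samples are dropped (returned as NaN).
    """
    values = pd.Series(values).astype(float)
    if len(values) < 4:
        raise ValidationError("need at least 4 samples to stratify")
    if values.nunique() == 1:
        raise ValidationError("all values equal; cannot stratify")
    lo_cut = float(np.quantile(values.to_numpy(), low_q))
    out = pd.Series(np.where(values <= lo_cut, "low", "high"),
                    index=values.index, dtype=object)
    if drop_middle:
        hi_cut = float(np.quantile(values.to_numpy(), 1 - low_q))
        out[(values > lo_cut) & (values < hi_cut)] = np.nan
    return out
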