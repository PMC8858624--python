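"""Iterative malignant / non-malignant division of epithelial cells.

Each epithelial cell is scored against a malignant and a non-malignant
reference gene set (control-matched module scores); the per-cell score
difference (malignant minus non-malignant), sorted ascending, forms a growth
curve.  The split threshold is the midpoint of the largest consecutive gap
near the curve's inflection point.  After labelling, both reference sets are
refreshed from the data (top upregulated markers of each putative class) and
the procedure repeats until the labels stop changing.

The classifier is agnostic to where the initial reference sets come from —
bulk tumour/normal markers, curated lists, or planted truth sets in
simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg import DEGConfig, extract_signature, wilcoxon_deg
from .matrix import ExpressionMatrix, GeneSet, ValidationError
from .scoring import ModuleScoreConfig, module_score

logger = logging.getLogger(__name__)

MALIGNANT = "malignant"
NON_MALIGNANT = "non_malignant"


class DegenerateInputError(ValueError):
    """Curve unusable for threshold finding (constant or too short)."""


@dataclass
class SplitCurve:
    """Score differences sorted ascending, with the cell order retained."""

    values: np.ndarray
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cells = np.asarray(self.cells, dtype=object)
        if np.any(np.diff(self.values) < 0):
            raise ValidationError("split curve must be non-decreasing")
        if len(self.values) != len(self.cells):
            raise ValidationError("values/cells length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DivisionConfig:
    top_n_refresh: int = 50
    alpha_refresh: float = 0.01
    max_iter: int = 20
    initial_threshold: float | None = None   # -0.02 preset available
    gap_window_frac: float = 0.2
    smooth_window: int = 5
    min_smooth_n: int = 25                   # no smoothing for tiny curves
    tail_trim_frac: float = 0.05             # exclude tails from inflection search
    adjust_method: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.top_n_refresh < 1:
            raise ValidationError("top_n_refresh must be >= 1")
        if not (0 < self.alpha_refresh < 1):
            raise ValidationError("alpha_refresh must be in (0,1)")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class MalignancyState:
    labels: pd.Series
    threshold: float
    malignant_set: GeneSet
    nonmalignant_set: GeneSet
    iteration: int
    converged: bool
    history: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "iteration": self.iteration,
            "converged": self.converged,
            "history": list(self.history),
            "n_malignant": int((self.labels == MALIGNANT).sum()),
            "n_non_malignant": int((self.labels == NON_MALIGNANT).sum()),
            "malignant_set": list(self.malignant_set.genes),
            "nonmalignant_set": list(self.nonmalignant_set.genes),
        }


def score_difference(mal: pd.Series, nonmal: pd.Series) -> SplitCurve:
    """Per-cell malignant-minus-non-malignant score, sorted ascending."""
    if set(mal.index) != set(nonmal.index):
        raise ValidationError("score vectors cover different cells")
    diff = mal - nonmal.reindex(mal.index)
    order = np.argsort(diff.to_numpy(), kind="stable")
    return SplitCurve(values=diff.to_numpy()[order],
                      cells=diff.index.to_numpy()[order])


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    return (pd.Series(y)
            .rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def find_split_threshold(curve: SplitCurve,
                         cfg: DivisionConfig | None = None) -> float:
    """Largest consecutive gap near the inflection of the sorted curve.

    The inflection index is the maximum discrete second difference of the
    (lightly smoothed, for long curves) sorted values; the search for the
    widest gap is restricted to ``±gap_window_frac * n`` positions around it
    so isolated tail outliers cannot hijack the split.  The threshold is the
    midpoint of the winning gap; cells strictly above it are malignant.
    """
    cfg = cfg or DivisionConfig()
    y = curve.values
    n = len(y)
    if n < 4:
        raise DegenerateInputError("need at least 4 cells to place a split")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant score-difference curve")

    ys = _smooth(y, cfg.smooth_window if n >= cfg.min_smooth_n else 1)
    d2 = ys[2:] - 2 * ys[1:-1] + ys[:-2]          # second difference at 1..n-2
    # the inflection is an interior feature; the curvature at the extreme
    # order statistics is dominated by tail noise, so trim 5% each side
    trim = int(round(cfg.tail_trim_frac * n))
    d2_t = d2[trim:len(d2) - trim] if 2 * trim < len(d2) else d2
    inflection = int(np.argmax(d2_t)) + 1 + (trim if 2 * trim < len(d2) else 0)

    w = max(1, int(round(cfg.gap_window_frac * n)))
    lo = max(0, inflection - w)
    hi = min(n - 2, inflection + w)
    gaps = np.diff(y)
    window_gaps = gaps[lo:hi + 1]
    if window_gaps.max() <= 0:
        # degenerate flat window; fall back to the global largest gap
        lo, hi = 0, n - 2
        window_gaps = gaps
    k = lo + int(np.argmax(window_gaps))
    return float((y[k] + y[k + 1]) / 2.0)


def classify_by_threshold(curve: SplitCurve, threshold: float) -> pd.Series:
    """Cells with score difference strictly above the threshold are malignant."""
    lab = np.where(curve.values > threshold, MALIGNANT, NON_MALIGNANT)
    return pd.Series(lab, index=curve.cells)


def derive_reference_sets(m: ExpressionMatrix, labels: pd.Series,
                          cfg: DivisionConfig | None = None):
    """Refresh the reference sets from the current putative labels.

    Rank-sum markers of each class versus the other; genes upregulated at
    adjusted p < ``alpha_refresh``, ranked by (adjusted p, log fold change,
    gene id); the top ``top_n_refresh`` per class are returned.
    """
    cfg = cfg or DivisionConfig()
    labels = pd.Series(labels)
    counts = labels.value_counts()
    for cls in (MALIGNANT, NON_MALIGNANT):
        if counts.get(cls, 0) < 3:
            raise ValidationError(
                f"class {cls!r} has {counts.get(cls, 0)} cells; "
                "need at least 3 for the rank-sum refresh"
            )
    deg_cfg = DEGConfig(alpha=cfg.alpha_refresh, only_pos=True,
                        adjust_method=cfg.adjust_method)
    sets = []
    for cls in (MALIGNANT, NON_MALIGNANT):
        deg = wilcoxon_deg(m, labels, cls, deg_cfg)
        try:
            sets.append(extract_signature(deg, top_n=cfg.top_n_refresh,
                                          name=f"{cls}_markers"))
        except ValidationError as e:
            raise ValidationError(
                f"no gene passes adjusted p < {cfg.alpha_refresh} for class "
                f"{cls!r}; increase the planted effect or alpha_refresh"
            ) from e
    return sets[0], sets[1]


def iterate_division(m: ExpressionMatrix, epithelial_cells,
                     init_mal: GeneSet, init_nonmal: GeneSet,
                     cfg: DivisionConfig | None = None,
                     score_cfg: ModuleScoreConfig | None = None) -> MalignancyState:
    """Run the score / split / refresh loop to a fixed point.

    ``cfg.initial_threshold`` (the -0.02 preset of the original analysis)
    overrides gap-finding in the first iteration only.  Non-convergence
    within ``max_iter`` returns ``converged=False`` rather than raising.
    """
    cfg = cfg or DivisionConfig()
    score_cfg = score_cfg or ModuleScoreConfig()
    sub = m.subset_cells(list(epithelial_cells))
    if not init_mal.present_in(sub) or not init_nonmal.present_in(sub):
        raise ValidationError("initial reference sets share no gene with matrix")

    mal_set, nonmal_set = init_mal, init_nonmal
    prev_labels: pd.Series | None = None
    labels = pd.Series(dtype=object)
    threshold = float("nan")
    history: list[int] = []
    converged = False
    iteration = 0

    for iteration in range(1, cfg.max_iter + 1):
        mal_scores = module_score(sub, mal_set, score_cfg)
        nonmal_scores = module_score(sub, nonmal_set, score_cfg)
        curve = score_difference(mal_scores, nonmal_scores)
        if iteration == 1 and cfg.initial_threshold is not None:
            threshold = float(cfg.initial_threshold)
        else:
            threshold = find_split_threshold(curve, cfg)
        labels = classify_by_threshold(curve, threshold)

        if prev_labels is None:
            changes = len(labels)
        else:
            changes = int((labels.reindex(prev_labels.index)
                           != prev_labels).sum())
        history.append(changes)
        logger.info("iteration %d: threshold %.4f, %d label changes",
                    iteration, threshold, changes)
        if prev_labels is not None and changes == 0:
            converged = True
            break
        prev_labels = labels
        mal_set, nonmal_set = derive_reference_sets(sub, labels, cfg)

    if not converged:
        logger.warning("division did not converge within %d iterations",
                       cfg.max_iter)
    return MalignancyState(labels=labels, threshold=threshold,
                           malignant_set=mal_set, nonmalignant_set=nonmal_set,
                           iteration=iteration, converged=converged,
                           history=history)
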