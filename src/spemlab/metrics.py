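"""Classification metrics, likelihood ratios, correlations, and reports.

Positive class throughout is *psychosis*: sensitivity is the probability
that a proband is called a proband, specificity that a control is called
a control.  Balanced accuracy is their arithmetic mean, robust to the
imbalanced group sizes typical of case-control cohorts.  Likelihood
ratios quantify the diagnostic evidence of a positive / negative test:
LR+ = sens / (1 - spec), LR- = (1 - sens) / spec.

Internally everything is kept at full precision; values are rounded
half-up to two decimals only when formatted for a report, and fold-wise
likelihood ratios are averaged per fold (not recomputed from mean
sensitivity/specificity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "CorrelationResult",
    "round_half_up",
    "classification_metrics",
    "mean_fold_metrics",
    "group_classification_report",
    "kendall_tau",
    "holm_adjust",
    "cohort_descriptives",
    "format_table3_row",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed tables use."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts; positive class = psychosis."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    """Percent-scale metrics plus likelihood ratios."""

    balanced_accuracy: float
    sensitivity: float
    specificity: float
    lr_positive: float
    lr_negative: float

    def rounded(self, ndigits: int = 2) -> "ClassificationMetrics":
        return ClassificationMetrics(
            *(round_half_up(v, ndigits) for v in (
                self.balanced_accuracy,
                self.sensitivity,
                self.specificity,
                self.lr_positive,
                self.lr_negative,
            ))
        )


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p: float
    n: int
    rejected: bool | None = None  # set by holm_adjust


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Sensitivity, specificity, balanced accuracy (percent) and LRs."""
    if c.n_positive < 1 or c.n_negative < 1:
        raise ValueError("both classes need at least one subject")
    sens = 100.0 * c.tp / c.n_positive
    spec = 100.0 * c.tn / c.n_negative
    bac = (sens + spec) / 2.0
    lr_pos = sens / (100.0 - spec) if spec < 100.0 else math.inf
    lr_neg = (100.0 - sens) / spec if spec > 0.0 else math.inf
    return ClassificationMetrics(bac, sens, spec, lr_pos, lr_neg)


def mean_fold_metrics(folds: list[ClassificationMetrics]) -> ClassificationMetrics:
    """Arithmetic mean of each metric across folds (LRs averaged per fold)."""
    if not folds:
        raise ValueError("at least one fold required")
    return ClassificationMetrics(
        balanced_accuracy=float(np.mean([f.balanced_accuracy for f in folds])),
        sensitivity=float(np.mean([f.sensitivity for f in folds])),
        specificity=float(np.mean([f.specificity for f in folds])),
        lr_positive=float(np.mean([f.lr_positive for f in folds])),
        lr_negative=float(np.mean([f.lr_negative for f in folds])),
    )


def group_classification_report(
    true_groups: "pd.Series | np.ndarray | list",
    predicted_labels: "pd.Series | np.ndarray | list",
    positive: str = "psychosis",
    negative: str = "control",
) -> pd.DataFrame:
    """Per-group predicted-label counts and percentages.

    For every true group, counts how many members were predicted into the
    psychosis vs control class, with percentages formatted ``"n (xx.xx%)"``
    as in published cross-cohort tables.
    """
    df = pd.DataFrame({"group": list(true_groups), "pred": list(predicted_labels)})
    rows = []
    for group, sub in df.groupby("group", sort=False):
        n = len(sub)
        n_pos = int((sub["pred"] == positive).sum())
        n_neg = n - n_pos
        rows.append(
            {
                "group": group,
                "n": n,
                "n_psychosis": n_pos,
                "n_control": n_neg,
                "pct_psychosis": round_half_up(100.0 * n_pos / n),
                "pct_control": round_half_up(100.0 * n_neg / n),
                "psychosis": f"{n_pos} ({round_half_up(100.0 * n_pos / n):.2f}%)",
                "control": f"{n_neg} ({round_half_up(100.0 * n_neg / n):.2f}%)",
            }
        )
    return pd.DataFrame(rows)


def kendall_tau(x, y) -> CorrelationResult:
    """Tie-corrected Kendall tau-b with two-sided p, pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(tau=math.nan, p=math.nan, n=len(x))
    res = stats.kendalltau(x, y, variant="b")
    return CorrelationResult(tau=float(res.statistic), p=float(res.pvalue), n=len(x))


def holm_adjust(pvals: list[float], alpha: float = 0.05) -> list[bool]:
    """Step-down Holm decisions for a family of tests."""
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(arr, alpha=alpha, method="holm")
    return [bool(r) for r in reject]


def cohort_descriptives(
    table: pd.DataFrame,
    features: tuple[str, ...] = ("gain_pred", "gain_early", "accel", "latency"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group n / mean / SD of each measure on available (non-missing) values."""
    rows = []
    for group, sub in table.groupby(group_col, sort=False):
        row: dict = {"group": group, "n": len(sub)}
        for f in features:
            vals = sub[f].dropna()
            row[f"{f}_mean"] = round_half_up(float(vals.mean()), 2) if len(vals) else None
            row[f"{f}_sd"] = round_half_up(float(vals.std(ddof=1)), 2) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


def format_table3_row(label: str, n: int, n_psych: int) -> str:
    """Render ``"label (n = N) count (xx.xx%)"`` like the published table."""
    pct = round_half_up(100.0 * n_psych / n)
    return f"{label} (n = {n}) {n_psych} ({pct:.2f}%)"
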