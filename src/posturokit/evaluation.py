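"""Cohort-level statistics for deployed balance assessments.

Covers the study-style analysis of a table of assessments: single-pass
mu +/- 2 sigma outlier rejection, per-phone averaging, risk-factor
prevalence summaries, one-way ANOVA and two-sample z-tests of association,
and 2-/3-class classification of risk categories against self-reported
falls history (accuracy, per-class sensitivity and predictivity).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES
from .io_formats import RISK_FACTOR_ITEMS, ValidationError

THREE_CLASS = ("low", "medium", "high")
TWO_CLASS = ("non-faller", "faller")


@dataclass
class ConfusionMatrix:
    """KxK counts, rows = true falls-history class, columns = predicted."""

    counts: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be KxK matching class_labels")
        if np.any(self.counts < 0) or self.counts.sum() == 0:
            raise ValidationError("counts must be nonnegative with total > 0")


@dataclass
class MetricsReport:
    """Accuracy and per-class sensitivity/predictivity, in percent.

    A class absent from the truth (sensitivity) or never predicted
    (predictivity) yields NaN -- undefined, never 0.
    """

    accuracy: float
    sensitivity: dict[str, float]
    predictivity: dict[str, float]


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: dict


@dataclass
class OutlierReport:
    """Per-feature mean/SD and removed row indices from outlier rejection."""

    mu: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    removed: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


def remove_outliers(table: pd.DataFrame,
                    columns: Optional[Sequence[str]] = None
                    ) -> tuple[pd.DataFrame, OutlierReport]:
    """Single-pass mu +/- 2 sigma outlier rejection on feature columns.

    Mean and SD are computed once per column from all non-missing values
    (outliers included; no re-estimation); values strictly outside
    mu +/- 2 sigma are set to missing.  Existing missing values stay
    missing and are excluded from mu and sigma.
    """
    if columns is None:
        columns = [c for c in FEATURE_NAMES if c in table.columns]
    out = table.copy()
    report = OutlierReport()
    for col in columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.notna().sum() < 3:
            warnings.warn(f"column {col!r} has < 3 values; skipped")
            continue
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=1))
        report.mu[col] = mu
        report.sigma[col] = sigma
        mask = vals.notna() & (np.abs(vals - mu) > 2 * sigma)
        report.removed[col] = list(out.index[mask])
        out.loc[mask, col] = np.nan
    return out, report


def per_phone_average(assessments: pd.DataFrame,
                      feature_columns: Optional[Sequence[str]] = None
                      ) -> pd.DataFrame:
    """Average assessments per phone (one participant surrogate per phone).

    Feature columns are averaged over each phone's assessments (missing
    values skipped); phones whose recorded gender or age changes between
    assessments are excluded.
    """
    if feature_columns is None:
        feature_columns = [c for c in assessments.columns
                           if c in FEATURE_NAMES
                           or c in ("balance_score", "fre_percent")]
    df = assessments
    consistent = df.groupby("phone_id").agg(
        {c: "nunique" for c in ("gender", "age") if c in df.columns})
    bad = consistent.index[(consistent > 1).any(axis=1)]
    df = df[~df["phone_id"].isin(bad)]
    agg = {c: "mean" for c in feature_columns}
    for c in df.columns:
        if c not in agg and c != "phone_id":
            agg[c] = "first"
    return df.groupby("phone_id", as_index=False).agg(agg)


def prevalence_summary(questionnaires: pd.DataFrame,
                       items: Sequence[str] = RISK_FACTOR_ITEMS
                       ) -> pd.DataFrame:
    """Risk-factor prevalence: count and percent of all responses.

    The denominator is the full number of responses (missing items are not
    excluded from it), and percentages are reported to one decimal.
    """
    n = len(questionnaires)
    if n == 0:
        raise ValidationError("no questionnaire responses")
    rows = []
    for item in items:
        if item not in questionnaires.columns:
            continue
        count = int((questionnaires[item] == True).sum())  # noqa: E712
        rows.append({"factor": item, "count": count,
                     "percent": round(100.0 * count / n, 1)})
    return pd.DataFrame(rows).set_index("factor")


def anova_oneway(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """One-way fixed-effects ANOVA of ``values`` across group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*samples)
    return AnovaResult(F=float(f), p=float(p),
                       group_means={g: float(s.mean())
                                    for g, s in zip(labels, samples)})


@dataclass
class ZTestResult:
    z: float
    p: float
    significant: bool
    approximate: bool = False


def two_sample_ztest(sample_a: np.ndarray, sample_b: np.ndarray,
                     alpha: float = 0.05) -> ZTestResult:
    """Two-sided unequal-variance z-test of two sample means.

    z = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with sample
    variances (ddof=1); samples under 30 trigger a warning and the result
    is flagged approximate.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    approximate = False
    if min(a.size, b.size) < 30:
        warnings.warn("z-test on < 30 samples: normal approximation is weak")
        approximate = True
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se == 0:
        z = 0.0
    else:
        z = float((a.mean() - b.mean()) / se)
    p = float(2 * stats.norm.sf(abs(z)))
    return ZTestResult(z=z, p=p, significant=p < alpha, approximate=approximate)


def falls_history_to_class(falls_12m: int, k: int) -> str:
    """Map a 12-month falls count to a history class.

    k=3: 0 falls -> 'low', 1 fall -> 'medium', >= 2 (recurrent) -> 'high';
    k=2: 0 falls -> 'non-faller', >= 1 -> 'faller'.
    """
    if falls_12m < 0:
        raise ValidationError("falls count must be >= 0")
    if k == 3:
        return THREE_CLASS[min(int(falls_12m), 2)]
    if k == 2:
        return TWO_CLASS[int(falls_12m >= 1)]
    raise ValidationError("k must be 2 or 3")


def classification_metrics(confusion: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class sensitivity and predictivity from a confusion matrix.

    Sensitivity is the percentage of each true class classified correctly;
    predictivity the percentage of each predicted class that is correct.
    Empty rows/columns give NaN (undefined).
    """
    c = confusion.counts
    total = c.sum()
    accuracy = 100.0 * np.trace(c) / total
    sens, pred = {}, {}
    for i, label in enumerate(confusion.class_labels):
        row, col = c[i].sum(), c[:, i].sum()
        sens[label] = 100.0 * c[i, i] / row if row else float("nan")
        pred[label] = 100.0 * c[i, i] / col if col else float("nan")
    return MetricsReport(accuracy=float(accuracy), sensitivity=sens,
                         predictivity=pred)


def _category_to_class(category: str, k: int) -> str:
    if k == 3:
        return category
    # binary: the low-risk category predicts non-faller, medium/high faller
    return TWO_CLASS[int(category in ("medium", "high"))]


def evaluate_risk_vs_history(assessments: pd.DataFrame, k: int,
                             risk: str = "fre"
                             ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Cross-tabulate a risk category against self-reported falls history.

    ``risk`` selects the predicted column: 'fre' -> ``fre_category``,
    'balance' -> ``balance_category``.  Rows lacking either the category or
    the falls count are dropped.
    """
    col = {"fre": "fre_category", "balance": "balance_category"}[risk]
    df = assessments[[col, "falls_12m"]].dropna()
    if df.empty:
        raise ValidationError("no complete (risk, falls history) pairs")
    labels = THREE_CLASS if k == 3 else TWO_CLASS
    truth = df["falls_12m"].map(lambda v: falls_history_to_class(int(v), k))
    predicted = df[col].map(lambda cat: _category_to_class(cat, k))
    counts = np.zeros((k, k), dtype=int)
    index = {lab: i for i, lab in enumerate(labels)}
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(counts=counts, class_labels=tuple(labels))
    return cm, classification_metrics(cm)
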