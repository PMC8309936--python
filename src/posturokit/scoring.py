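"""Percentile balance scoring and classifier-fusion falls-risk estimation.

Two estimators implement the clinical outputs:

* :class:`BalanceScorer` -- a percentile-based balance impairment score.
  Each sway feature is ranked against a reference cohort, oriented so that
  the direction more common among cohort fallers counts as worse; the mean
  per-feature percentile is then itself rank-normalised against the
  cohort's own scores, so subjects drawn from the reference population
  score uniformly on [0, 100].

* :class:`FallsRiskEstimator` -- the fused falls-risk estimate: two
  maximum-likelihood logistic classifiers (sensor features and
  questionnaire risk factors, each against 12-month falls history) whose
  posterior probabilities are combined with weight ``lambda`` (default 0.5,
  an arithmetic mean).  The estimate is only defined for subjects aged 60
  or over.

Scores map to risk categories low (< 50), medium ([50, 70)) and
high (>= 70).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .features import FEATURE_NAMES, SwayFeatures
from .io_formats import RISK_FACTOR_ITEMS, QuestionnaireResponse, ValidationError

logger = logging.getLogger("posturokit")

MIN_COHORT_SCORING = 20
MIN_COHORT_TRAINING = 50
FRE_MIN_AGE = 60.0
RIDGE_ALPHA = 1e-2  # L2 strength of the separation fallback, standardized scale

CATEGORIES = ("low", "medium", "high")


@dataclass
class ReferenceCohort:
    """Per-subject sway features, demographics and 12-month falls label.

    ``data`` holds one row per subject with the 14 feature columns plus
    ``age``, ``gender``, ``height``, ``weight`` and boolean ``faller_12m``.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in (*FEATURE_NAMES, "faller_12m")
                   if c not in self.data.columns]
        if missing:
            raise ValidationError(f"cohort table missing column(s): {missing}")
        feats = self.data[list(FEATURE_NAMES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(feats)):
            raise ValidationError("cohort features must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "ReferenceCohort":
        return cls(pd.read_csv(path), provenance=provenance or str(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class BalanceScore:
    """Percentile balance score with its per-feature breakdown."""

    overall: float
    per_feature: dict[str, float]
    category: str

    def __post_init__(self) -> None:
        if not 0 <= self.overall <= 100:
            raise ValidationError("balance score must lie in [0, 100]")


@dataclass
class FreResult:
    """Fused falls-risk posterior (percent) with its risk category.

    ``defined`` is False below the age gate; the posterior is then None and
    no category is assigned.
    """

    defined: bool
    posterior: Optional[float]
    category: Optional[str]
    components: tuple[float, float] = (float("nan"), float("nan"))
    notes: list[str] = field(default_factory=list)


def categorize(score_percent: float,
               thresholds: tuple[float, float] = (50.0, 70.0)) -> str:
    """Map a 0-100 score to low / medium / high risk.

    ``< thresholds[0]`` is low, ``[thresholds[0], thresholds[1])`` medium,
    ``>= thresholds[1]`` high; the partition covers [0, 100] exactly.
    """
    if not 0 <= score_percent <= 100:
        raise ValidationError(f"score {score_percent} outside [0, 100]")
    lo, hi = thresholds
    if score_percent < lo:
        return "low"
    if score_percent < hi:
        return "medium"
    return "high"


class BalanceScorer(BaseEstimator):
    """Percentile balance score against a reference cohort.

    Parameters
    ----------
    feature_names : sequence of str
        Feature columns used for scoring (default: all 14 sway features).
    thresholds : (float, float)
        Risk-category boundaries on the 0-100 scale.

    Attributes
    ----------
    orientation_ : ndarray of {+1, -1}
        Per-feature sign such that larger oriented values are "worse";
        learned from the faller/non-faller cohort means.
    reference_ : ndarray (n_subjects, n_features)
        Oriented cohort feature values.
    reference_scores_ : ndarray (n_subjects,)
        The cohort's own mean per-feature percentiles, used to
        rank-normalise the overall score.
    """

    def __init__(self, feature_names: Sequence[str] = FEATURE_NAMES,
                 thresholds: tuple[float, float] = (50.0, 70.0)):
        self.feature_names = feature_names
        self.thresholds = thresholds

    def fit(self, X, y) -> "BalanceScorer":
        """Learn orientations and reference ranks from cohort features.

        ``X`` is (n_subjects, n_features); ``y`` the boolean faller label.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"X must be (n, {len(self.feature_names)})")
        if X.shape[0] < MIN_COHORT_SCORING:
            raise ValidationError(
                f"reference cohort needs >= {MIN_COHORT_SCORING} subjects, "
                f"got {X.shape[0]}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("cohort features must be finite")
        if y.any() and (~y).any():
            diff = X[y].mean(axis=0) - X[~y].mean(axis=0)
            self.orientation_ = np.where(diff >= 0, 1.0, -1.0)
        else:  # single-class cohort: larger raw value counts as worse
            self.orientation_ = np.ones(X.shape[1])
        self.reference_ = X * self.orientation_
        self.n_features_in_ = X.shape[1]
        self.reference_scores_ = np.array(
            [self._raw_score(row)[0] for row in self.reference_])
        return self

    def _raw_score(self, oriented: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean per-feature percentile of one oriented feature vector."""
        valid = np.isfinite(oriented)
        per = np.full(oriented.size, np.nan)
        per[valid] = 100.0 * (self.reference_[:, valid] <=
                              oriented[valid]).mean(axis=0)
        if not valid.any():
            raise ValidationError("no usable features for balance scoring")
        if not valid.all():
            logger.info("balance score: %d missing feature(s) excluded",
                        int((~valid).sum()))
        return float(np.nanmean(per)), per

    def transform(self, X) -> np.ndarray:
        """Overall balance scores (0-100) for each row of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            raw, _ = self._raw_score(row * self.orientation_)
            out[i] = 100.0 * (self.reference_scores_ <= raw).mean()
        return out

    def score_one(self, features: SwayFeatures | Mapping[str, float]) -> BalanceScore:
        """Full :class:`BalanceScore` (overall, per-feature map, category)."""
        if isinstance(features, SwayFeatures):
            features = features.to_dict()
        vec = np.array([features.get(name, np.nan) for name in self.feature_names],
                       dtype=float)
        raw, per = self._raw_score(vec * self.orientation_)
        overall = 100.0 * float((self.reference_scores_ <= raw).mean())
        per_map = {name: p for name, p in zip(self.feature_names, per)
                   if np.isfinite(p)}
        return BalanceScore(overall=overall, per_feature=per_map,
                            category=categorize(overall, self.thresholds))


class FallsRiskEstimator(BaseEstimator):
    """Fused falls-risk estimate from sensor and questionnaire classifiers.

    Two logistic regressions are fitted against the 12-month falls label:
    one on standardized sway features, one on the binary questionnaire risk
    factors.  Prediction fuses the two posteriors with weight
    ``fusion_weight`` on the sensor posterior.  Perfectly separable fits
    fall back to a light L2 ridge (logged).

    Attributes (after fit)
    ----------------------
    sensor_coef_, sensor_intercept_ : logistic weights on standardized features
    quest_coef_, quest_intercept_ : logistic weights on questionnaire items
    center_, scale_ : per-feature standardisation from the training cohort
    quest_fill_ : training prevalence used for missing questionnaire items
    """

    def __init__(self,
                 sensor_features: Sequence[str] = FEATURE_NAMES,
                 questionnaire_items: Sequence[str] = RISK_FACTOR_ITEMS,
                 fusion_weight: float = 0.5,
                 min_age: float = FRE_MIN_AGE,
                 thresholds: tuple[float, float] = (50.0, 70.0)):
        self.sensor_features = sensor_features
        self.questionnaire_items = questionnaire_items
        self.fusion_weight = fusion_weight
        self.min_age = min_age
        self.thresholds = thresholds

    # -- fitting -------------------------------------------------------
    def _fit_logistic(self, X: np.ndarray, y: np.ndarray,
                      label: str) -> tuple[np.ndarray, float]:
        clf = LogisticRegression(C=np.inf, max_iter=5000)
        clf.fit(X, y)
        if np.max(np.abs(clf.coef_)) > 30:  # quasi-separation: unbounded MLE
            logger.warning("%s classifier is separable; refitting with "
                           "ridge alpha=%.0e", label, RIDGE_ALPHA)
            clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, max_iter=5000)
            clf.fit(X, y)
        return clf.coef_[0].copy(), float(clf.intercept_[0])

    def fit(self, X: pd.DataFrame, y=None) -> "FallsRiskEstimator":
        """Fit both classifiers on a cohort table.

        ``X`` must hold the sensor feature columns and questionnaire item
        columns; ``y`` is the boolean faller label (or ``X['faller_12m']``).
        """
        if y is None:
            if "faller_12m" not in X.columns:
                raise ValidationError("no faller_12m label available")
            y = X["faller_12m"]
        y = np.asarray(y, dtype=bool)
        if len(X) < MIN_COHORT_TRAINING:
            raise ValidationError(
                f"training needs >= {MIN_COHORT_TRAINING} subjects")
        if not (y.any() and (~y).any()):
            raise ValidationError("training needs both fallers and non-fallers")
        if not 0 <= self.fusion_weight <= 1:
            raise ValidationError("fusion_weight must be in [0, 1]")

        S = X[list(self.sensor_features)].to_numpy(dtype=float)
        self.center_ = S.mean(axis=0)
        self.scale_ = S.std(axis=0, ddof=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (S - self.center_) / self.scale_
        self.sensor_coef_, self.sensor_intercept_ = self._fit_logistic(
            Z, y, "sensor")

        Q = X[list(self.questionnaire_items)].astype(float).to_numpy()
        self.quest_fill_ = np.nanmean(
            np.where(np.isnan(Q), np.nan, Q), axis=0)
        self.quest_fill_ = np.nan_to_num(self.quest_fill_, nan=0.0)
        Q = np.where(np.isnan(Q), self.quest_fill_, Q)
        self.quest_coef_, self.quest_intercept_ = self._fit_logistic(
            Q, y, "questionnaire")
        self.n_features_in_ = len(self.sensor_features)
        return self

    # -- prediction ----------------------------------------------------
    def _sensor_posterior(self, features: Mapping[str, float]) -> float:
        vec = np.array([features[name] for name in self.sensor_features],
                       dtype=float)
        z = (vec - self.center_) / self.scale_
        return float(_sigmoid(self.sensor_coef_ @ z + self.sensor_intercept_))

    def _quest_posterior(self, items: Mapping[str, Optional[bool]]
                         ) -> Optional[float]:
        raw = [items.get(name) for name in self.questionnaire_items]
        if all(v is None for v in raw):
            return None
        vec = np.array([self.quest_fill_[i] if v is None else float(v)
                        for i, v in enumerate(raw)])
        return float(_sigmoid(self.quest_coef_ @ vec + self.quest_intercept_))

    def predict_one(self, features: SwayFeatures | Mapping[str, float],
                    questionnaire: QuestionnaireResponse | Mapping,
                    age: Optional[float] = None) -> FreResult:
        """Fused falls-risk estimate for one subject.

        Undefined (``defined=False``) below the age gate.  If every
        questionnaire item is missing the sensor posterior is used alone,
        flagged in ``notes``.
        """
        if isinstance(questionnaire, QuestionnaireResponse):
            if age is None:
                age = questionnaire.age
            items: Mapping = questionnaire.items()
        else:
            items = questionnaire
        if age is None or age < self.min_age:
            return FreResult(defined=False, posterior=None, category=None,
                             notes=[f"undefined below age {self.min_age:.0f}"])
        if isinstance(features, SwayFeatures):
            features = features.to_dict()
        p_sensor = self._sensor_posterior(features)
        p_quest = self._quest_posterior(items)
        notes: list[str] = []
        lam = self.fusion_weight
        if p_quest is None:
            logger.info("all questionnaire items missing; sensor-only posterior")
            notes.append("questionnaire missing: sensor-only posterior")
            fused = p_sensor
            p_quest = float("nan")
        else:
            fused = lam * p_sensor + (1.0 - lam) * p_quest
        posterior = 100.0 * fused
        return FreResult(defined=True, posterior=posterior,
                         category=categorize(posterior, self.thresholds),
                         components=(p_sensor, p_quest), notes=notes)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Fused faller probability per row (sklearn-style, both classes)."""
        p = np.array([
            self.predict_one(row[list(self.sensor_features)].to_dict(),
                             {k: row.get(k) for k in self.questionnaire_items},
                             age=row.get("age", self.min_age)).posterior / 100.0
            for _, row in X.iterrows()])
        return np.column_stack([1 - p, p])

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sensor_features": list(self.sensor_features),
            "questionnaire_items": list(self.questionnaire_items),
            "fusion_weight": self.fusion_weight,
            "min_age": self.min_age,
            "thresholds": list(self.thresholds),
            "sensor_coef": self.sensor_coef_.tolist(),
            "sensor_intercept": self.sensor_intercept_,
            "quest_coef": self.quest_coef_.tolist(),
            "quest_intercept": self.quest_intercept_,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "quest_fill": self.quest_fill_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FallsRiskEstimator":
        est = cls(sensor_features=d["sensor_features"],
                  questionnaire_items=d["questionnaire_items"],
                  fusion_weight=d["fusion_weight"], min_age=d["min_age"],
                  thresholds=tuple(d["thresholds"]))
        est.sensor_coef_ = np.asarray(d["sensor_coef"], dtype=float)
        est.sensor_intercept_ = float(d["sensor_intercept"])
        est.quest_coef_ = np.asarray(d["quest_coef"], dtype=float)
        est.quest_intercept_ = float(d["quest_intercept"])
        est.center_ = np.asarray(d["center"], dtype=float)
        est.scale_ = np.asarray(d["scale"], dtype=float)
        est.quest_fill_ = np.asarray(d["quest_fill"], dtype=float)
        est.n_features_in_ = len(est.sensor_features)
        return est

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FallsRiskEstimator":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def balance_score(features: SwayFeatures, cohort: ReferenceCohort,
                  thresholds: tuple[float, float] = (50.0, 70.0)) -> BalanceScore:
    """Percentile balance score of one subject against a reference cohort."""
    scorer = BalanceScorer(thresholds=thresholds).fit(
        cohort.data[list(FEATURE_NAMES)], cohort.data["faller_12m"])
    return scorer.score_one(features)


def train_fre(cohort: ReferenceCohort,
              questionnaires: Optional[pd.DataFrame] = None,
              fusion_weight: float = 0.5) -> FallsRiskEstimator:
    """Train the fused falls-risk model on a reference cohort.

    ``questionnaires`` supplies the risk-factor columns when the cohort
    table does not already carry them (rows aligned with cohort subjects).
    """
    df = cohort.data
    if questionnaires is not None:
        if len(questionnaires) != len(df):
            raise ValidationError("questionnaire table must align with cohort")
        df = pd.concat([df.reset_index(drop=True),
                        questionnaires.reset_index(drop=True)[
                            [c for c in questionnaires.columns
                             if c not in df.columns]]], axis=1)
    return FallsRiskEstimator(fusion_weight=fusion_weight).fit(
        df, df["faller_12m"])


def predict_fre(model: FallsRiskEstimator, features, questionnaire,
                age: Optional[float] = None) -> FreResult:
    """Fused falls-risk estimate for one subject (see ``predict_one``)."""
    return model.predict_one(features, questionnaire, age=age)
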