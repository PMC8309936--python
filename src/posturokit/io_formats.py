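"""Domain types and file formats for smartphone balance assessments.

The package works with four kinds of records:

* raw IMU recordings from a 30 s standing balance test (CSV, one row per
  sample: ``t,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z``, seconds, m/s^2 and
  deg/s, comma separated, dot decimal);
* questionnaire responses on clinical falls-risk factors (CSV or JSON);
* assessment records joining one questionnaire with one balance test's
  features and scores (CSV);
* reference cohorts used for percentile scoring and falls-risk training
  (CSV, handled by :mod:`posturokit.scoring`).

Readers never drop data silently: every rejected row is counted in the
:class:`ReadReport` available from each reader.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("posturokit")

IMU_COLUMNS = ("t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

#: Tri-state clinical risk-factor items captured by the questionnaire.
RISK_FACTOR_ITEMS = (
    "polypharmacy",
    "mobility_problems",
    "orthostatic_hypotension",
    "foot_problems",
    "vision_problems",
    "adl_change",
    "dizziness",
    "walking_aid",
    "parkinsons",
    "stroke",
)


class FormatError(ValueError):
    """A file does not match the expected dialect/schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class ReadReport:
    """Row/field rejection bookkeeping for one read operation."""

    n_read: int = 0
    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)


@dataclass
class ImuRecording:
    """One balance test's raw tri-axial accelerometer + gyroscope trace.

    Timestamps are seconds since test start and may be irregular; the
    accelerometer is in m/s^2 (gravity included) and the gyroscope in deg/s.
    """

    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    device_id: str = ""
    nominal_rate: Optional[float] = None

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, name), dtype=float) for name in IMU_COLUMNS]
        n = arrays[0].shape[0]
        for name, arr in zip(IMU_COLUMNS, arrays):
            if arr.ndim != 1 or arr.shape[0] != n:
                raise ValidationError(f"channel {name!r} must be 1-D of common length")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
            setattr(self, name, arr)
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Time span between first and last sample, seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def acc(self) -> np.ndarray:
        """Acceleration as a 3xN array (x, y, z rows)."""
        return np.vstack([self.acc_x, self.acc_y, self.acc_z])

    @property
    def gyro(self) -> np.ndarray:
        """Angular velocity as a 3xN array (x, y, z rows)."""
        return np.vstack([self.gyro_x, self.gyro_y, self.gyro_z])

    def replace_channels(self, acc: np.ndarray, gyro: np.ndarray,
                         t: Optional[np.ndarray] = None) -> "ImuRecording":
        t = self.t if t is None else t
        return ImuRecording(
            t=t, acc_x=acc[0], acc_y=acc[1], acc_z=acc[2],
            gyro_x=gyro[0], gyro_y=gyro[1], gyro_z=gyro[2],
            device_id=self.device_id, nominal_rate=self.nominal_rate,
        )


@dataclass
class QuestionnaireResponse:
    """One self-reported falls-risk questionnaire.

    Risk-factor items are tri-state: ``True`` / ``False`` / ``None``
    (missing).  Missing items are never imputed at read time.
    """

    age: Optional[float] = None
    gender: Optional[str] = None  # 'male' / 'female' / 'other'
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    falls_12m: Optional[int] = None
    polypharmacy: Optional[bool] = None
    mobility_problems: Optional[bool] = None
    orthostatic_hypotension: Optional[bool] = None
    foot_problems: Optional[bool] = None
    vision_problems: Optional[bool] = None
    adl_change: Optional[bool] = None
    dizziness: Optional[bool] = None
    walking_aid: Optional[bool] = None
    parkinsons: Optional[bool] = None
    stroke: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValidationError("age must be >= 0")
        for name in ("height", "weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.falls_12m is not None and self.falls_12m < 0:
            raise ValidationError("falls_12m must be >= 0")

    def items(self) -> dict[str, Optional[bool]]:
        """The tri-state risk-factor items as a dict."""
        return {k: getattr(self, k) for k in RISK_FACTOR_ITEMS}


@dataclass
class AssessmentRecord:
    """One questionnaire response joined with one balance test's outputs."""

    phone_id: str
    timestamp: str
    questionnaire: QuestionnaireResponse
    features: Optional[Any] = None       # SwayFeatures
    balance_score: Optional[Any] = None  # BalanceScore
    fre: Optional[Any] = None            # FreResult
    qc_status: str = "ok"

    def __post_init__(self) -> None:
        if self.qc_status != "ok" and self.features is not None:
            raise ValidationError("rejected assessments cannot carry features")
        if self.fre is not None and getattr(self.fre, "defined", True):
            age = self.questionnaire.age
            if age is not None and age < 60:
                raise ValidationError("falls-risk estimate is undefined below age 60")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_imu_csv(path: str | Path, device_id: str = "",
                 return_report: bool = False):
    """Read a raw IMU recording from its canonical 7-column CSV.

    Rows with non-finite values are rejected and counted in the report.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If timestamps are not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IMU CSV {path.name} is missing column(s): "
                          + ", ".join(missing))
    report = ReadReport(n_read=len(df))
    values = df[list(IMU_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(values.to_numpy(dtype=float)).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        report.n_rejected = n_bad
        report.reasons.append(f"{n_bad} rows with non-finite values rejected")
        logger.warning("%s: %s", path.name, report.reasons[-1])
        values = values.loc[finite]
    rec = ImuRecording(device_id=device_id,
                       **{c: values[c].to_numpy(dtype=float) for c in IMU_COLUMNS})
    return (rec, report) if return_report else rec


def write_imu_csv(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording in the canonical dialect (time to 1 ms, signals 1e-6)."""
    df = pd.DataFrame({c: getattr(rec, c) for c in IMU_COLUMNS})
    df["t"] = df["t"].round(3)
    for c in IMU_COLUMNS[1:]:
        df[c] = df[c].round(6)
    df.to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s == "" or s == "nan":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a tri-state boolean")


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    v = float(value)
    if math.isnan(v):
        return None
    return v


def read_questionnaire(path: str | Path, return_report: bool = False):
    """Read questionnaire responses from CSV or JSON (list of objects).

    Unknown fields are ignored with a warning; rows whose age/height/weight/
    falls count cannot be parsed are skipped and counted in the report.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise FormatError("questionnaire JSON must be a list of objects")
    else:
        rows = pd.read_csv(path).to_dict(orient="records")

    known = {f.name for f in fields(QuestionnaireResponse)}
    report = ReadReport(n_read=len(rows))
    unknown_seen: set[str] = set()
    responses: list[QuestionnaireResponse] = []
    for i, row in enumerate(rows):
        unknown_seen |= set(row) - known
        try:
            falls = _parse_optional_float(row.get("falls_12m"))
            resp = QuestionnaireResponse(
                age=_parse_optional_float(row.get("age")),
                gender=(str(row["gender"]).strip().lower() or None)
                if row.get("gender") not in (None, "") and
                not (isinstance(row.get("gender"), float) and math.isnan(row["gender"]))
                else None,
                height=_parse_optional_float(row.get("height")),
                weight=_parse_optional_float(row.get("weight")),
                falls_12m=None if falls is None else int(falls),
                **{k: _parse_bool(row.get(k)) for k in RISK_FACTOR_ITEMS},
            )
        except (ValueError, TypeError) as exc:
            report.n_rejected += 1
            report.reasons.append(f"row {i}: {exc}")
            continue
        responses.append(resp)
    if unknown_seen:
        logger.warning("questionnaire %s: ignoring unknown field(s) %s",
                       path.name, sorted(unknown_seen))
    if report.n_rejected:
        logger.warning("questionnaire %s: %d row(s) rejected",
                       path.name, report.n_rejected)
    return (responses, report) if return_report else responses


_FEATURE_PREFIX = "feat_"


def write_assessments(records: list[AssessmentRecord], path: str | Path) -> None:
    """Write assessment records to a flat CSV (one row per assessment).

    Missing features/scores are written as empty cells, never as 0.
    """
    from .features import FEATURE_NAMES  # local import avoids a cycle

    rows = []
    for rec in records:
        row: dict[str, Any] = {"phone_id": rec.phone_id, "timestamp": rec.timestamp,
                               "qc_status": rec.qc_status}
        q = rec.questionnaire
        row.update(age=q.age, gender=q.gender, height=q.height, weight=q.weight,
                   falls_12m=q.falls_12m)
        row.update(q.items())
        if rec.features is not None:
            row.update({_FEATURE_PREFIX + k: v
                        for k, v in rec.features.to_dict().items()})
        if rec.balance_score is not None:
            row["balance_score"] = rec.balance_score.overall
            row["balance_category"] = rec.balance_score.category
        if rec.fre is not None and rec.fre.defined:
            row["fre_percent"] = rec.fre.posterior
            row["fre_category"] = rec.fre.category
        rows.append(row)
    cols = ["phone_id", "timestamp", "qc_status", "age", "gender", "height",
            "weight", "falls_12m", *RISK_FACTOR_ITEMS,
            *[_FEATURE_PREFIX + k for k in FEATURE_NAMES],
            "balance_score", "balance_category", "fre_percent", "fre_category"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_assessments(path: str | Path) -> list[AssessmentRecord]:
    """Read back a CSV written by :func:`write_assessments`."""
    from .features import FEATURE_NAMES, SwayFeatures
    from .scoring import BalanceScore, FreResult, categorize

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        falls = _parse_optional_float(row.get("falls_12m"))
        q = QuestionnaireResponse(
            age=_parse_optional_float(row.get("age")),
            gender=None if pd.isna(row.get("gender")) else str(row["gender"]),
            height=_parse_optional_float(row.get("height")),
            weight=_parse_optional_float(row.get("weight")),
            falls_12m=None if falls is None else int(falls),
            **{k: _parse_bool(row.get(k)) for k in RISK_FACTOR_ITEMS},
        )
        feat = None
        fvals = {k: row.get(_FEATURE_PREFIX + k) for k in FEATURE_NAMES}
        if any(pd.notna(v) for v in fvals.values()):
            feat = SwayFeatures(**{k: float(v) if pd.notna(v) else float("nan")
                                   for k, v in fvals.items()})
        score = None
        if pd.notna(row.get("balance_score")):
            score = BalanceScore(overall=float(row["balance_score"]),
                                 per_feature={},
                                 category=str(row["balance_category"]))
        fre = None
        if pd.notna(row.get("fre_percent")):
            p = float(row["fre_percent"])
            fre = FreResult(defined=True, posterior=p,
                            category=str(row["fre_category"]),
                            components=(float("nan"), float("nan")))
        records.append(AssessmentRecord(
            phone_id=str(row["phone_id"]), timestamp=str(row["timestamp"]),
            questionnaire=q, features=feat, balance_score=score, fre=fre,
            qc_status=str(row["qc_status"])))
    return records
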