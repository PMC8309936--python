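"""Seeded generators for sway recordings, reference cohorts and assessments.

Everything downstream is testable without any real deployment data:

* :func:`simulate_sway_recording` -- quiet-stance IMU traces: gravity on
  the nominal vertical axis plus band-limited Gaussian sway noise scaled
  to per-axis RMS targets, with optional timestamp jitter and injected
  artifacts (pulse / drift / tilt);
* :func:`simulate_reference_cohort` -- a clinical reference cohort (277
  subjects, 100 fallers by default) with features drawn per class from
  zero-truncated Gaussians;
* :func:`simulate_assessment_table` -- a deployment sample (594 assessments
  over 147 phones by default) with over-dispersed per-phone assessment
  counts, questionnaire items at configurable prevalences coupled to faller
  status through odds ratios, and risk categories drawn from an explicit
  confusion kernel so expected classification metrics are known by
  construction.

The sway model is noise shaped in the frequency domain, not a biomechanical
inverted-pendulum model; it is sufficient to exercise every pipeline
operation.  All generators are deterministic given (params, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .features import FEATURE_NAMES
from .io_formats import RISK_FACTOR_ITEMS, ImuRecording
from .preprocess import GRAVITY
from .scoring import ReferenceCohort

#: Reference-cohort feature means/SDs for non-fallers (lumbar-sensor
#: normative context).  The gyro Z-axis entry is synthetic: it is chosen so
#: the per-axis values close the resultant identity, which the printed
#: per-axis means do not satisfy (a population mean of resultants is not
#: the resultant of means).
REFERENCE_FEATURE_STATS: dict[str, tuple[float, float]] = {
    "rms_acc_x": (0.10, 0.05),
    "rms_acc_y": (0.09, 0.04),
    "rms_acc_z": (0.10, 0.04),
    "rms_acc_res": (0.22, 0.10),
    "rms_gyro_x": (0.91, 0.56),
    "rms_gyro_y": (0.72, 0.43),
    "rms_gyro_z": (1.21, 0.70),  # synthetic (no published value)
    "rms_gyro_res": (1.68, 1.01),
    "medf_acc": (5.32, 1.72),
    "sef_acc": (4.14, 0.46),
    "h_acc": (0.76, 0.07),
    "medf_gyro": (2.87, 1.17),
    "sef_gyro": (3.64, 0.50),
    "h_gyro": (0.75, 0.06),
}

#: Standardized faller - non-faller feature shifts (invented: fallers sway
#: more and show slightly less complex spectra).
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    **{k: 0.4 for k in FEATURE_NAMES if k.startswith("rms_")},
    "medf_acc": 0.0, "sef_acc": 0.0, "medf_gyro": 0.0, "sef_gyro": 0.0,
    "h_acc": -0.3, "h_gyro": -0.3,
}

#: Deployment-sample risk-factor prevalences.  Dizziness and foot problems
#: have no published prevalence; those two values are invented.
DEFAULT_PREVALENCES: dict[str, float] = {
    "polypharmacy": 0.283,
    "mobility_problems": 0.246,
    "vision_problems": 0.199,
    "orthostatic_hypotension": 0.071,
    "adl_change": 0.153,
    "walking_aid": 0.146,
    "parkinsons": 0.008,
    "stroke": 0.032,
    "dizziness": 0.20,    # invented
    "foot_problems": 0.15,  # invented
}

#: Faller vs non-faller odds ratios for the questionnaire items (invented,
#: so association tests have signal to detect).
DEFAULT_ODDS_RATIOS: dict[str, float] = {
    **{k: 1.0 for k in RISK_FACTOR_ITEMS},
    "mobility_problems": 2.0, "polypharmacy": 2.0, "dizziness": 2.0,
}

#: Falls-history class probabilities (no falls / one fall / recurrent) for
#: the deployment sample: 388, 72 and 134 of 594 responses.
DEFAULT_FALLS_CLASS_PROBS = (388 / 594, 72 / 594, 134 / 594)

#: Row-stochastic kernel P(predicted risk category | true history class)
#: used to draw risk categories; invented so the expected accuracy of the
#: evaluation module is known analytically.
DEFAULT_RISK_KERNEL = np.array([
    [0.85, 0.12, 0.03],
    [0.30, 0.45, 0.25],
    [0.10, 0.25, 0.65],
])

_CATEGORY_RANGES = {"low": (0.0, 50.0), "medium": (50.0, 70.0),
                    "high": (70.0, 100.0)}


@dataclass
class ArtifactSpec:
    """One injected disturbance: 'pulse' (m/s^2 step on the X axis),
    'drift' (linear ramp to ``magnitude``) or 'tilt' (degrees of gravity
    rotation from ``onset`` onward)."""

    kind: str
    onset: float
    magnitude: float
    duration: float = 0.0


@dataclass
class SwaySimParams:
    """Quiet-stance sway signal generator settings.

    Default per-axis RMS targets are scaled so the acceleration and
    angular-velocity resultants hit the reference normative means of
    0.22 m/s^2 and 1.68 deg/s.
    """

    duration: float = 30.0
    rate: float = 100.0
    acc_rms: tuple[float, float, float] = (0.131, 0.118, 0.131)
    gyro_rms: tuple[float, float, float] = (0.91, 0.72, 1.21)
    band: tuple[float, float] = (0.3, 3.0)
    slope: float = 0.0
    gravity_axis: str = "z"
    tilt_deg: float = 0.0
    jitter: float = 0.0
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if any(v < 0 for v in (*self.acc_rms, *self.gyro_rms)):
            raise ValueError("RMS targets must be >= 0")
        if any(v > 0.5 * GRAVITY for v in self.acc_rms):
            raise ValueError("acceleration RMS target above 0.5 g is infeasible")
        low, high = self.band
        if not 0 < low < high < self.rate / 2:
            raise ValueError("band must lie inside (0, Nyquist)")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter fraction must be in [0, 1)")


def _band_noise(n: int, rate: float, band: tuple[float, float], slope: float,
                target_rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power confined to ``band``, scaled to target RMS."""
    if target_rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    amp = np.zeros_like(freqs)
    amp[mask] = np.where(freqs[mask] > 0, freqs[mask], 1.0) ** (slope / 2.0)
    coeff = amp * (rng.standard_normal(freqs.size)
                   + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(coeff, n=n)
    return x * (target_rms / np.sqrt(np.mean(x ** 2)))


def simulate_sway_recording(params: SwaySimParams,
                            seed: Optional[int] = None) -> ImuRecording:
    """Generate one quiet-stance IMU recording.

    Accelerometer channels carry the gravity projection plus band-limited
    sway noise hitting the per-axis RMS targets (exactly on the full
    record, hence within a few percent after the analysis pipeline);
    gyroscope channels carry sway noise only.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(params.duration * params.rate))
    axis = {"x": 0, "y": 1, "z": 2}[params.gravity_axis]
    gravity_dir = np.zeros(3)
    gravity_dir[axis] = 1.0
    if params.tilt_deg:
        gravity_dir = _tilt(gravity_dir, params.tilt_deg)

    acc = np.vstack([
        _band_noise(n, params.rate, params.band, params.slope, r, rng)
        for r in params.acc_rms])
    gyro = np.vstack([
        _band_noise(n, params.rate, params.band, params.slope, r, rng)
        for r in params.gyro_rms])
    acc = acc + GRAVITY * gravity_dir[:, None]

    t_grid = np.arange(n) / params.rate
    for art in params.artifacts:
        sel = (t_grid >= art.onset) & (t_grid < art.onset + art.duration)
        if art.kind == "pulse":
            acc[0, sel] += art.magnitude
        elif art.kind == "drift":
            ramp = np.linspace(0, art.magnitude, int(sel.sum()))
            acc[0, sel] += ramp
        elif art.kind == "tilt":
            tilted = GRAVITY * _tilt(gravity_dir, art.magnitude)
            acc[:, sel] += (tilted - GRAVITY * gravity_dir)[:, None]
        else:
            raise ValueError(f"unknown artifact kind {art.kind!r}")

    if params.jitter > 0:
        offsets = params.jitter * rng.uniform(-0.49, 0.49, size=n) / params.rate
        t = t_grid + offsets
        t[0] = 0.0
        acc = np.vstack([np.interp(t, t_grid, ch) for ch in acc])
        gyro = np.vstack([np.interp(t, t_grid, ch) for ch in gyro])
    else:
        t = t_grid
    return ImuRecording(t=t, acc_x=acc[0], acc_y=acc[1], acc_z=acc[2],
                        gyro_x=gyro[0], gyro_y=gyro[1], gyro_z=gyro[2],
                        device_id="sim", nominal_rate=params.rate)


def _tilt(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a unit vector by ``angle_deg`` within a fixed plane."""
    perp = np.eye(3)[int(np.argmin(np.abs(direction)))]
    perp = perp - perp @ direction * direction
    perp /= np.linalg.norm(perp)
    a = np.radians(angle_deg)
    return np.cos(a) * direction + np.sin(a) * perp


# ---------------------------------------------------------------------------
# Reference cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Reference-cohort generator settings (defaults: 277 subjects with 100
    fallers, normative feature means/SDs, invented effect sizes)."""

    n: int = 277
    faller_fraction: float = 100 / 277
    feature_stats: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_FEATURE_STATS))
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    odds_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ODDS_RATIOS))
    age: tuple[float, float] = (74.7, 6.6)
    height: tuple[float, float] = (164.35, 9.22)
    weight: tuple[float, float] = (74.57, 13.69)
    female_fraction: float = 178 / 277
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs n >= 2")
        if not 0 <= self.faller_fraction <= 1:
            raise ValueError("faller_fraction must be in [0, 1]")
        for name, p in self.prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {name} must be in [0, 1]")
        for name, (mu, sd) in self.feature_stats.items():
            if sd <= 0:
                raise ValueError(f"SD for {name} must be > 0")


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator,
                      upper: float = np.inf) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_features(labels: np.ndarray, params: CohortSimParams,
                   rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name in FEATURE_NAMES:
        mean, sd = params.feature_stats[name]
        shift = params.effect_sizes.get(name, 0.0) * sd
        upper = 1.0 if name.startswith("h_") else np.inf
        vals = np.empty(labels.size)
        for is_faller in (False, True):
            mask = labels == is_faller
            if mask.any():
                vals[mask] = _truncated_normal(
                    mean + (shift if is_faller else 0.0), sd,
                    int(mask.sum()), rng, upper=upper)
        cols[name] = vals
    return pd.DataFrame(cols)


def simulate_reference_cohort(params: Optional[CohortSimParams] = None,
                              seed: Optional[int] = None) -> ReferenceCohort:
    """Generate a reference cohort with exact faller allocation.

    The number of fallers is ``round(faller_fraction * n)`` exactly (not
    binomial), matching how a recruited clinical cohort reports its counts.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_fallers = int(round(params.faller_fraction * params.n))
    labels = np.zeros(params.n, dtype=bool)
    labels[:n_fallers] = True
    rng.shuffle(labels)
    df = _draw_features(labels, params, rng)
    df["age"] = _truncated_normal(*params.age, params.n, rng)
    df["gender"] = np.where(rng.uniform(size=params.n) < params.female_fraction,
                            "female", "male")
    df["height"] = _truncated_normal(*params.height, params.n, rng)
    df["weight"] = _truncated_normal(*params.weight, params.n, rng)
    for item in RISK_FACTOR_ITEMS:
        p = params.prevalences.get(item, 0.0)
        p0, p1 = _class_prevalences(p, n_fallers / params.n,
                                    params.odds_ratios.get(item, 1.0))
        probs = np.where(labels, p1, p0)
        df[item] = rng.uniform(size=params.n) < probs
    df["faller_12m"] = labels
    return ReferenceCohort(df, provenance="synthetic")


def _class_prevalences(p_overall: float, faller_frac: float,
                       odds_ratio: float) -> tuple[float, float]:
    """Split an overall prevalence into per-class values at a given OR."""
    if p_overall in (0.0, 1.0) or odds_ratio == 1.0 or faller_frac in (0.0, 1.0):
        return p_overall, p_overall

    def gap(p0: float) -> float:
        odds1 = odds_ratio * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        return (1 - faller_frac) * p0 + faller_frac * p1 - p_overall

    p0 = brentq(gap, 1e-12, 1 - 1e-12)
    odds1 = odds_ratio * p0 / (1 - p0)
    return p0, odds1 / (1 + odds1)


# ---------------------------------------------------------------------------
# Deployment assessment table
# ---------------------------------------------------------------------------

def expected_accuracy(k: int,
                      kernel: np.ndarray = DEFAULT_RISK_KERNEL,
                      priors: Sequence[float] = DEFAULT_FALLS_CLASS_PROBS
                      ) -> float:
    """Analytic expected accuracy (%) of kernel-drawn risk categories.

    For the binary problem the medium and high categories both predict
    'faller', mirroring the evaluation module's merge rule.
    """
    kernel = np.asarray(kernel, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if k == 3:
        acc = float(priors @ np.diag(kernel))
    elif k == 2:
        acc = float(priors[0] * kernel[0, 0]
                    + priors[1] * kernel[1, 1:].sum()
                    + priors[2] * kernel[2, 1:].sum())
    else:
        raise ValueError("k must be 2 or 3")
    return 100.0 * acc


def _phone_counts(n_assessments: int, n_phones: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated geometric assessment counts repaired to the exact total."""
    if n_assessments < n_phones or n_phones < 1:
        raise ValueError("need n_assessments >= n_phones >= 1")
    p = min(1.0, n_phones / n_assessments)
    counts = rng.geometric(p, size=n_phones)  # support {1, 2, ...}
    while counts.sum() > n_assessments:
        i = rng.integers(n_phones)
        if counts[i] > 1:
            counts[i] -= 1
    while counts.sum() < n_assessments:
        counts[rng.integers(n_phones)] += 1
    return counts


def simulate_assessment_table(params: Optional[CohortSimParams] = None,
                              n_assessments: int = 594,
                              n_phones: int = 147,
                              falls_class_probs: Sequence[float] = DEFAULT_FALLS_CLASS_PROBS,
                              risk_kernel: np.ndarray = DEFAULT_RISK_KERNEL,
                              age: tuple[float, float] = (56.5, 17.0),
                              height: tuple[float, float] = (167.4, 10.8),
                              weight: tuple[float, float] = (78.2, 20.0),
                              seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a deployment-style assessment table.

    One row per assessment with phone_id, demographics (constant per
    phone), falls history, questionnaire items, sway features, and balance
    / falls-risk categories drawn from ``risk_kernel`` given the true
    history class.  Falls-risk columns are missing below age 60.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = _phone_counts(n_assessments, n_phones, rng)
    falls_class_probs = np.asarray(falls_class_probs, dtype=float)
    faller_frac = float(falls_class_probs[1:].sum())

    rows = []
    for phone in range(n_phones):
        history = int(rng.choice(3, p=falls_class_probs))
        falls = [0, 1, 2][history] + (int(rng.poisson(2.0)) if history == 2 else 0)
        demo = {
            "phone_id": f"phone-{phone:04d}",
            "age": float(np.clip(rng.normal(*age), 18.0, 100.0)),
            "gender": "male" if rng.uniform() < 0.5 else "female",
            "height": float(max(rng.normal(*height), 120.0)),
            "weight": float(max(rng.normal(*weight), 35.0)),
            "falls_12m": falls,
        }
        for j in range(counts[phone]):
            items = {}
            for item in RISK_FACTOR_ITEMS:
                p = params.prevalences.get(item, 0.0)
                p0, p1 = _class_prevalences(p, faller_frac,
                                            params.odds_ratios.get(item, 1.0))
                items[item] = bool(rng.uniform() < (p1 if history > 0 else p0))
            cat_b = ("low", "medium", "high")[
                int(rng.choice(3, p=risk_kernel[history]))]
            cat_f = ("low", "medium", "high")[
                int(rng.choice(3, p=risk_kernel[history]))]
            feats = _draw_features(np.array([falls > 0]), params, rng).iloc[0]
            row = {**demo, **items, **feats.to_dict(),
                   "timestamp": f"2020-09-{(j % 28) + 1:02d}T10:00:00",
                   "balance_score": float(rng.uniform(*_CATEGORY_RANGES[cat_b])),
                   "balance_category": cat_b}
            if demo["age"] >= 60.0:
                row["fre_percent"] = float(rng.uniform(*_CATEGORY_RANGES[cat_f]))
                row["fre_category"] = cat_f
            else:
                row["fre_percent"] = np.nan
                row["fre_category"] = None
            rows.append(row)
    return pd.DataFrame(rows)


def questionnaire_counts_table(counts: dict[str, int], n: int) -> pd.DataFrame:
    """Deterministic questionnaire table with exact per-item positive counts.

    Useful for reproducing printed prevalence summaries: item ``k`` is True
    in the first ``counts[k]`` rows and False elsewhere.
    """
    data = {}
    for item in RISK_FACTOR_ITEMS:
        c = counts.get(item)
        if c is None:
            data[item] = [None] * n
        else:
            if not 0 <= c <= n:
                raise ValueError(f"count for {item} outside [0, {n}]")
            data[item] = [True] * c + [False] * (n - c)
    return pd.DataFrame(data)
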