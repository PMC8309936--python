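"""Turn a raw IMU trace into analysis-ready sway signals.

The pipeline is fixed: linear resampling to a uniform grid (100 Hz by
default), gravity alignment of the device frame, zero-phase Butterworth
band-pass filtering (0.1-5 Hz), and removal of the first and last five
seconds of the test so that only steady quiet stance remains.  Quality
control checks phone orientation against a gravity cone and flags windows
with implausible movement.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .io_formats import ImuRecording, ValidationError

GRAVITY = 9.81  # m/s^2

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class QualityError(ValueError):
    """Recording fails a quality-control contract (test rejected)."""


@dataclass
class QcReport:
    """Outcome of the data-quality checks for one recording."""

    orientation_ok: bool = True
    reposition_artifact_removed: bool = False
    movement_flag: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.orientation_ok and not self.movement_flag


@dataclass
class SwaySignal:
    """Uniformly sampled, calibrated, band-limited, trimmed sway signals.

    ``acc`` and ``gyro`` are 3xN arrays; each channel is mean-free after
    filtering and trimming.
    """

    rate: float
    acc: np.ndarray
    gyro: np.ndarray
    t0_offset: float
    qc: QcReport

    def __post_init__(self) -> None:
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.acc.shape[0] != 3 or self.gyro.shape[0] != 3:
            raise ValidationError("acc and gyro must be 3xN arrays")
        if self.acc.shape != self.gyro.shape:
            raise ValidationError("acc and gyro must have equal shapes")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def resample_uniform(rec: ImuRecording, target_rate: float) -> ImuRecording:
    """Linearly interpolate a recording onto a uniform grid.

    The output grid is ``0, 1/rate, 2/rate, ...`` relative to the first
    timestamp and never extrapolates beyond the original endpoints.
    """
    if rec.duration < 2.0 / target_rate:
        raise ValidationError(
            f"recording of {rec.duration:.3f} s too short to resample at "
            f"{target_rate} Hz")
    n = int(np.floor(rec.duration * target_rate)) + 1
    t_new = np.arange(n) / target_rate
    t_query = rec.t[0] + t_new
    acc = np.vstack([np.interp(t_query, rec.t, ch) for ch in rec.acc])
    gyro = np.vstack([np.interp(t_query, rec.t, ch) for ch in rec.gyro])
    out = rec.replace_channels(acc, gyro, t=t_new)
    out.nominal_rate = target_rate
    return out


def _rotation_to_vertical(mean_acc: np.ndarray, vertical: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping ``mean_acc`` direction onto ``vertical``."""
    u = mean_acc / np.linalg.norm(mean_acc)
    v = vertical / np.linalg.norm(vertical)
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to u
        perp = np.eye(3)[np.argmin(np.abs(u))]
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, np.pi)
    return _axis_angle(axis / s, float(np.arctan2(s, c)))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def gravity_align(rec: ImuRecording, vertical_axis: str = "z") -> ImuRecording:
    """Rotate the device frame so mean gravity lies on the nominal vertical.

    The mean acceleration over the middle 50% of the test estimates the
    gravity direction; the same rotation is applied to the gyroscope so the
    two sensor frames stay consistent.  Gravity magnitude is preserved.

    Raises
    ------
    QualityError
        If the mean acceleration magnitude is below 2 m/s^2 (sensor fault).
    """
    n = len(rec)
    mid = slice(n // 4, n - n // 4)
    mean_acc = rec.acc[:, mid].mean(axis=1)
    if np.linalg.norm(mean_acc) < 2.0:
        raise QualityError("implausible gravity")
    vertical = np.zeros(3)
    vertical[_AXIS_INDEX[vertical_axis]] = 1.0
    rot = _rotation_to_vertical(mean_acc, vertical)
    return rec.replace_channels(rot @ rec.acc, rot @ rec.gyro)


def bandpass(channel: np.ndarray, band: tuple[float, float],
             rate: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass of one channel.

    Applied forward-backward (``sosfiltfilt``) so sway phase is preserved;
    DC is fully removed.
    """
    low, high = band
    if not 0 < low < high < rate / 2:
        raise ValueError(f"band {band} must lie strictly inside (0, {rate / 2})")
    sos = sps.butter(2, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(channel, dtype=float))


def trim_settle(arr: np.ndarray, trim_seconds: float, rate: float) -> np.ndarray:
    """Drop ``trim_seconds`` from each end of a uniformly sampled array.

    The retained support is ``[trim, duration - trim)`` where the duration
    counts one sample interval past the last sample, so a 30 s test at
    100 Hz keeps exactly 2000 samples.
    """
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    n = arr.shape[-1]
    k = int(round(trim_seconds * rate))
    if n - 2 * k < 1:
        raise QualityError("test too short")
    out = arr[..., k:n - k]
    return out


def quality_check(rec: ImuRecording, config: AnalysisConfig) -> QcReport:
    """Run the data-quality checks on a resampled recording.

    * orientation: mean gravity within ``qc_cone_deg`` of nominal vertical;
    * repositioning transients: 1-s windows in the settling interval whose
      acceleration RMS exceeds ``qc_rms_ratio`` x the median window RMS
      (noted; the trim already excises them);
    * movement: any retained window breaching the same RMS ratio, or with
      gyroscope RMS above ``qc_gyro_rms`` deg/s.
    """
    report = QcReport()
    rate = config.target_rate
    n = len(rec)

    mean_acc = rec.acc.mean(axis=1)
    vertical = np.zeros(3)
    vertical[_AXIS_INDEX[config.vertical_axis]] = 1.0
    norm = np.linalg.norm(mean_acc)
    if norm < 2.0:
        report.orientation_ok = False
        report.reasons.append("implausible gravity")
    else:
        cos_tilt = float(np.dot(mean_acc / norm, vertical))
        tilt = np.degrees(np.arccos(np.clip(cos_tilt, -1.0, 1.0)))
        if tilt > config.qc_cone_deg:
            report.orientation_ok = False
            report.reasons.append(
                f"phone tilted {tilt:.0f} deg from vertical "
                f"(> {config.qc_cone_deg:.0f} deg cone)")

    # window RMS on mean-free channels (gravity removed by mean subtraction)
    acc0 = rec.acc - rec.acc.mean(axis=1, keepdims=True)
    gyro0 = rec.gyro - rec.gyro.mean(axis=1, keepdims=True)
    win = max(int(round(rate)), 1)
    n_win = n // win
    if n_win >= 2:
        acc_rms = np.array([
            np.sqrt(np.mean(acc0[:, i * win:(i + 1) * win] ** 2))
            for i in range(n_win)])
        gyro_rms = np.array([
            np.sqrt(np.mean(gyro0[:, i * win:(i + 1) * win] ** 2))
            for i in range(n_win)])
        med = float(np.median(acc_rms))
        thresh = config.qc_rms_ratio * med
        k = int(round(config.trim * rate)) // win  # windows inside the trim
        settle = acc_rms[:k] > thresh
        if settle.any():
            report.reposition_artifact_removed = True
            report.reasons.append(
                f"{int(settle.sum())} repositioning window(s) removed by trim")
        retained = slice(k, max(k, n_win - k))
        moved = (acc_rms[retained] > thresh) | (gyro_rms[retained] > config.qc_gyro_rms)
        if moved.any():
            report.movement_flag = True
            report.reasons.append(
                f"movement in {int(moved.sum())} retained window(s)")
    return report


def preprocess_recording(rec: ImuRecording,
                         config: Optional[AnalysisConfig] = None) -> SwaySignal:
    """Full pipeline: resample -> QC -> gravity align -> band-pass -> trim.

    Always returns a :class:`SwaySignal`; a failed quality check is recorded
    in ``signal.qc`` and blocks feature extraction downstream.  After
    trimming, each channel's residual mean is removed so the sway channels
    are exactly mean-free.
    """
    config = config or AnalysisConfig()
    rec = resample_uniform(rec, config.target_rate)
    try:
        qc = quality_check(rec, config)
        if config.calibrate:
            rec = gravity_align(rec, config.vertical_axis)
    except QualityError as exc:
        qc = QcReport(orientation_ok=False, reasons=[str(exc)])
    acc = np.vstack([bandpass(ch, config.band, config.target_rate)
                     for ch in rec.acc])
    gyro = np.vstack([bandpass(ch, config.band, config.target_rate)
                      for ch in rec.gyro])
    acc = trim_settle(acc, config.trim, config.target_rate)
    gyro = trim_settle(gyro, config.trim, config.target_rate)
    acc = acc - acc.mean(axis=1, keepdims=True)
    gyro = gyro - gyro.mean(axis=1, keepdims=True)
    return SwaySignal(rate=config.target_rate, acc=acc, gyro=gyro,
                      t0_offset=config.trim, qc=qc)
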