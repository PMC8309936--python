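"""Quantitative postural-sway features.

Fourteen scalars summarise one balance test: per-axis and resultant RMS
amplitude of acceleration (m/s^2) and angular velocity (deg/s), and three
spectral descriptors per sensor family computed on the resultant channel
within the analysis band -- the median frequency (50% spectral power), the
spectral edge frequency (SEF, 95% spectral power) and the normalized
spectral entropy H in [0, 1].

Power spectra are Welch averaged periodograms (Hann window, 5 s segments,
50% overlap by default).  Undefined spectral features (zero band power)
propagate as NaN rather than raising.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .io_formats import ValidationError
from .preprocess import SwaySignal

FEATURE_NAMES = (
    "rms_acc_x", "rms_acc_y", "rms_acc_z", "rms_acc_res",
    "rms_gyro_x", "rms_gyro_y", "rms_gyro_z", "rms_gyro_res",
    "medf_acc", "sef_acc", "h_acc",
    "medf_gyro", "sef_gyro", "h_gyro",
)


class FeatureError(ValueError):
    """Feature extraction attempted on an unusable signal."""


@dataclass
class SwayFeatures:
    """The 14 sensor-derived sway scalars for one balance test."""

    rms_acc_x: float
    rms_acc_y: float
    rms_acc_z: float
    rms_acc_res: float
    rms_gyro_x: float
    rms_gyro_y: float
    rms_gyro_z: float
    rms_gyro_res: float
    medf_acc: float
    sef_acc: float
    h_acc: float
    medf_gyro: float
    sef_gyro: float
    h_gyro: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def rms(channel: np.ndarray) -> float:
    """Root-mean-square amplitude of a (mean-free) channel."""
    channel = np.asarray(channel, dtype=float)
    if channel.size < 2:
        raise ValidationError("rms needs at least 2 samples")
    if not np.all(np.isfinite(channel)):
        raise ValidationError("rms input must be finite")
    return float(np.sqrt(np.mean(channel ** 2)))


def resultant_rms(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """RMS of the per-sample Euclidean norm of the three axes.

    Algebraically equals sqrt(rms_x^2 + rms_y^2 + rms_z^2).
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValidationError("resultant_rms needs equal-length channels")
    return rms(np.sqrt(x ** 2 + y ** 2 + z ** 2))


def power_spectrum(channel: np.ndarray, rate: float,
                   window_seconds: float = 5.0,
                   overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (Hann window) of one channel.

    Total integrated power matches the channel variance to within the
    usual windowing tolerance (~10%).
    """
    channel = np.asarray(channel, dtype=float)
    nperseg = int(round(window_seconds * rate))
    if channel.size < nperseg:
        raise ValidationError(
            f"channel of {channel.size} samples shorter than one "
            f"{window_seconds} s window")
    freqs, psd = sps.welch(channel, fs=rate, window="hann", nperseg=nperseg,
                           noverlap=int(nperseg * overlap), detrend="constant")
    return freqs, psd


def _band_mask(freqs: np.ndarray, band: Optional[tuple[float, float]]) -> np.ndarray:
    if band is None:
        return np.ones_like(freqs, dtype=bool)
    low, high = band
    return (freqs >= low - 1e-12) & (freqs <= high + 1e-12)


def spectral_edge_frequency(freqs: np.ndarray, psd: np.ndarray,
                            edge: float = 0.95,
                            band: Optional[tuple[float, float]] = None) -> float:
    """Frequency below which ``edge`` of the band power is contained.

    Returns the smallest grid frequency whose cumulative band power reaches
    ``edge`` times the total band power; NaN if the band carries no power.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValidationError("psd must be nonnegative")
    mask = _band_mask(freqs, band)
    p = psd[mask]
    f = freqs[mask]
    total = p.sum()
    if total <= 0 or f.size == 0:
        return float("nan")
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, edge * total - 1e-12 * total))
    return float(f[min(idx, f.size - 1)])


def median_frequency(freqs: np.ndarray, psd: np.ndarray,
                     band: Optional[tuple[float, float]] = None) -> float:
    """Frequency below which half of the band power is contained."""
    return spectral_edge_frequency(freqs, psd, edge=0.50, band=band)


def spectral_entropy(freqs: np.ndarray, psd: np.ndarray,
                     band: Optional[tuple[float, float]] = None) -> float:
    """Normalized Shannon entropy of the band PSD, in [0, 1].

    H = -sum(p_i log p_i) / log(K) with p_i the PSD normalized over the K
    band bins; 0 for a single spectral line, 1 for an exactly flat band.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValidationError("psd must be nonnegative")
    mask = _band_mask(freqs, band)
    p = psd[mask]
    k = p.size
    total = p.sum()
    if total <= 0 or k < 2:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(k)) + 0.0


def extract_features(sway: SwaySignal,
                     config: Optional[AnalysisConfig] = None) -> SwayFeatures:
    """Compute all 14 sway features from a processed signal.

    Spectral features are computed on the mean-removed resultant-norm
    channel of each sensor family, restricted to the analysis band.

    Raises
    ------
    FeatureError
        If the signal failed quality control.
    """
    config = config or AnalysisConfig()
    if not sway.qc.ok:
        raise FeatureError("features unavailable for rejected test: "
                           + "; ".join(sway.qc.reasons))
    out: dict[str, float] = {}
    for fam, arr in (("acc", sway.acc), ("gyro", sway.gyro)):
        for axis, ch in zip("xyz", arr):
            out[f"rms_{fam}_{axis}"] = rms(ch)
        out[f"rms_{fam}_res"] = resultant_rms(*arr)
        norm = np.sqrt((arr ** 2).sum(axis=0))
        norm = norm - norm.mean()
        freqs, psd = power_spectrum(norm, sway.rate, config.psd_window,
                                    config.psd_overlap)
        out[f"medf_{fam}"] = median_frequency(freqs, psd, config.band)
        out[f"sef_{fam}"] = spectral_edge_frequency(freqs, psd, 0.95, config.band)
        out[f"h_{fam}"] = spectral_entropy(freqs, psd, config.band)
    return SwayFeatures(**out)
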