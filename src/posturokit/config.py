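"""Analysis configuration shared by the whole pipeline.

All tunables of the measurement pipeline live here: the resampling rate,
the band-pass corners, the settling trim, the Welch PSD settings, the
quality-control thresholds and the risk-category boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Pipeline settings with the defaults used for smartphone balance tests.

    Parameters
    ----------
    target_rate : float
        Uniform resampling rate in Hz.
    band : tuple of float
        Band-pass corner frequencies (low, high) in Hz.
    trim : float
        Seconds removed from each end of the test to allow settling.
    psd_window : float
        Welch segment length in seconds.
    psd_overlap : float
        Fractional overlap between Welch segments.
    qc_cone_deg : float
        Maximum tilt of the mean gravity vector from the nominal vertical
        before the orientation check fails.
    qc_rms_ratio : float
        A 1-s window whose acceleration RMS exceeds this multiple of the
        median window RMS is flagged as movement.
    qc_gyro_rms : float
        Absolute angular-velocity RMS (deg/s) over a 1-s window above which
        movement is flagged.
    risk_thresholds : tuple of float
        (low/medium, medium/high) boundaries on the 0-100 risk scale.
    alpha : float
        Significance level for the statistical tests.
    calibrate : bool
        Whether to apply the gravity-alignment rotation.
    vertical_axis : str
        Device axis ('x', 'y' or 'z') expected to carry gravity.
    seed : int
        Seed for any stochastic step.
    """

    target_rate: float = 100.0
    band: tuple[float, float] = (0.1, 5.0)
    trim: float = 5.0
    psd_window: float = 5.0
    psd_overlap: float = 0.5
    qc_cone_deg: float = 30.0
    qc_rms_ratio: float = 5.0
    qc_gyro_rms: float = 50.0
    risk_thresholds: tuple[float, float] = (50.0, 70.0)
    alpha: float = 0.05
    calibrate: bool = True
    vertical_axis: str = "z"
    seed: int = 0
    fusion_weight: float = 0.5

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_rate / 2):
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({self.target_rate / 2} Hz)"
            )
        if self.trim < 0:
            raise ValueError("trim must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.fusion_weight <= 1:
            raise ValueError("fusion_weight must be in [0, 1]")
        lo, hi = self.risk_thresholds
        if not 0 < lo < hi <= 100:
            raise ValueError("risk_thresholds must satisfy 0 < low < high <= 100")
        if self.vertical_axis not in ("x", "y", "z"):
            raise ValueError("vertical_axis must be one of 'x', 'y', 'z'")

    # -- flat key/value persistence ------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kwargs = {}
        known = {f.name: f for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, val = raw.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = _parse_value(key, val)
        return cls(**kwargs)


def _parse_value(key: str, val: str):
    if key in ("band", "risk_thresholds"):
        parts = [float(x) for x in val.split(",")]
        return tuple(parts)
    if key == "calibrate":
        return val.lower() in ("1", "true", "yes")
    if key == "vertical_axis":
        return val
    if key == "seed":
        return int(val)
    return float(val)
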