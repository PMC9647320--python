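"""Core domain model for GC-IMS air analysis.

A GC-IMS measurement is a rectangular intensity grid over two time axes:
the drift time (milliseconds) of a product ion through the IMS tube and the
retention time (seconds) of the analyte on the GC column.  The reactant ion
peak (RIP) forms a ridge at a fixed drift time visible at all retention
times; its drift time anchors the instrument-robust *relative* drift time
used for identification.

This module holds the shared value types (:class:`DeviceConfig`,
:class:`IMSSpectrum`, :class:`Peak`, :class:`MobilityResult`), the
ion-mobility arithmetic (drift velocity, mobility constant ``K`` and its
pressure/temperature-normalized form ``K0``) and the long-form CSV dialect
used to exchange spectra.

Unit policy: drift times in milliseconds, retention times in seconds,
intensities in volts, mobilities in cm^2 V^-1 s^-1.  All unit conversions
go through :func:`ms_to_s`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MS_PER_S",
    "STANDARD_PRESSURE_TORR",
    "STANDARD_TEMPERATURE_K",
    "DomainError",
    "ConfigurationError",
    "DeviceConfig",
    "IMSSpectrum",
    "Peak",
    "MobilityResult",
    "ms_to_s",
    "drift_velocity",
    "mobility_constant",
    "normalize_mobility",
    "relative_drift_time",
    "mobility_from_drift_time",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

MS_PER_S = 1000.0
#: Reference pressure used for mobility normalization (Torr).
STANDARD_PRESSURE_TORR = 760.0
#: Reference temperature used for mobility normalization (Kelvin).
STANDARD_TEMPERATURE_K = 273.15

SPECTRUM_COLUMNS = ("retention_time_s", "drift_time_ms", "intensity_V")


class DomainError(ValueError):
    """A physical quantity violated its domain (e.g. non-positive time)."""


class ConfigurationError(ValueError):
    """Configuration objects are internally inconsistent."""


def _check_positive(**values: float) -> None:
    """Raise :class:`DomainError` naming the first non-positive argument."""
    for name, value in values.items():
        if not math.isfinite(value) or value <= 0:
            raise DomainError(
                f"{name} must be strictly positive and finite, got {value!r}"
            )


def ms_to_s(milliseconds: float) -> float:
    """Convert milliseconds to seconds (the single unit-conversion point)."""
    return milliseconds / MS_PER_S


@dataclass(frozen=True)
class DeviceConfig:
    """Instrument geometry and operating conditions.

    Defaults describe a drift tube of 9.8 cm operated at 500 V/cm with the
    RIP at 4.889 ms; pressure and temperature default to the midpoints of
    the operating ranges (757-760 Torr, 297.15-301.15 K).

    The tabulated drift voltage (5 kV) and field strength (500 V/cm over
    9.8 cm = 4.9 kV) disagree by ~2%; the field strength is authoritative
    for mobility computations and the voltage is kept as metadata.  A
    mismatch beyond 10% is rejected.
    """

    drift_length: float = 9.8  # cm
    field_strength: float = 500.0  # V/cm
    drift_voltage: float = 5.0  # kV
    pressure: float = 758.5  # Torr
    temperature: float = 299.15  # K
    rip_drift_time: float = 4.889  # ms
    sample_loop_volume: float = 1.0  # mL
    carrier_flow: float = 10.0  # mL/min
    drift_flow: float = 150.0  # mL/min

    def __post_init__(self) -> None:
        _check_positive(
            drift_length=self.drift_length,
            field_strength=self.field_strength,
            drift_voltage=self.drift_voltage,
            pressure=self.pressure,
            temperature=self.temperature,
            rip_drift_time=self.rip_drift_time,
            sample_loop_volume=self.sample_loop_volume,
            carrier_flow=self.carrier_flow,
            drift_flow=self.drift_flow,
        )
        implied_kv = self.field_strength * self.drift_length / 1000.0
        if abs(implied_kv - self.drift_voltage) > 0.10 * self.drift_voltage:
            raise ConfigurationError(
                "field_strength x drift_length "
                f"({implied_kv:.3g} kV) inconsistent with drift_voltage "
                f"({self.drift_voltage:.3g} kV) beyond 10%"
            )


@dataclass
class IMSSpectrum:
    """A rectangular intensity grid over (retention time, drift time).

    ``intensity`` has shape ``(len(retention_axis), len(drift_axis))`` with
    rows indexed by retention time.  Axes must be strictly increasing and
    every intensity finite.
    """

    drift_axis: np.ndarray  # ms
    retention_axis: np.ndarray  # s
    intensity: np.ndarray  # V
    device: DeviceConfig = field(default_factory=DeviceConfig)

    def __post_init__(self) -> None:
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.drift_axis.ndim != 1 or self.drift_axis.size == 0:
            raise DomainError("drift_axis must be a non-empty 1-D vector")
        if self.retention_axis.ndim != 1 or self.retention_axis.size == 0:
            raise DomainError("retention_axis must be a non-empty 1-D vector")
        if np.any(np.diff(self.drift_axis) <= 0):
            raise DomainError("drift_axis must be strictly increasing")
        if np.any(np.diff(self.retention_axis) <= 0):
            raise DomainError("retention_axis must be strictly increasing")
        expected = (self.retention_axis.size, self.drift_axis.size)
        if self.intensity.shape != expected:
            raise DomainError(
                f"intensity shape {self.intensity.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise DomainError("intensity values must all be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def drift_step(self) -> float:
        """Median drift-axis spacing (ms)."""
        return float(np.median(np.diff(self.drift_axis)))

    def retention_step(self) -> float:
        """Median retention-axis spacing (s)."""
        return float(np.median(np.diff(self.retention_axis)))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form representation, row-major by retention time."""
        nr, nd = self.shape
        return pd.DataFrame(
            {
                "retention_time_s": np.repeat(self.retention_axis, nd),
                "drift_time_ms": np.tile(self.drift_axis, nr),
                "intensity_V": self.intensity.ravel(),
            }
        )


@dataclass(frozen=True)
class Peak:
    """A local intensity maximum on a spectrum.

    ``relative_drift_time`` is the drift time divided by the RIP drift
    time of the device the peak was detected on.
    """

    retention_time: float  # s
    drift_time: float  # ms
    relative_drift_time: float
    intensity: float  # V
    is_rip: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.retention_time) or self.retention_time < 0:
            raise DomainError(
                f"retention_time must be finite and >= 0, got {self.retention_time!r}"
            )
        _check_positive(
            drift_time=self.drift_time,
            relative_drift_time=self.relative_drift_time,
            intensity=self.intensity,
        )


@dataclass(frozen=True)
class MobilityResult:
    """Drift velocity with the raw and normalized mobility constants."""

    drift_velocity: float  # cm/s
    mobility_K: float  # cm^2 V^-1 s^-1
    mobility_K0: float  # cm^2 V^-1 s^-1

    def __post_init__(self) -> None:
        _check_positive(
            drift_velocity=self.drift_velocity,
            mobility_K=self.mobility_K,
            mobility_K0=self.mobility_K0,
        )


def drift_velocity(drift_length: float, drift_time: float) -> float:
    """Mean ion velocity (cm/s) over ``drift_length`` cm in ``drift_time`` ms."""
    _check_positive(drift_length=drift_length, drift_time=drift_time)
    return drift_length / ms_to_s(drift_time)


def mobility_constant(drift_velocity: float, field_strength: float) -> float:
    """Ion mobility constant K = v_d / E (cm^2 V^-1 s^-1)."""
    _check_positive(drift_velocity=drift_velocity, field_strength=field_strength)
    return drift_velocity / field_strength


def normalize_mobility(K: float, pressure: float, temperature: float) -> float:
    """Mobility normalized to 760 Torr and 273.15 K.

    ``K0 = K * (P / 760 Torr) * (273.15 K / T)``; equals ``K`` exactly at
    standard conditions.
    """
    _check_positive(K=K, pressure=pressure, temperature=temperature)
    return (
        K
        * (pressure / STANDARD_PRESSURE_TORR)
        * (STANDARD_TEMPERATURE_K / temperature)
    )


def relative_drift_time(drift_time: float, rip_drift_time: float) -> float:
    """Drift time expressed as a multiple of the RIP drift time."""
    _check_positive(drift_time=drift_time, rip_drift_time=rip_drift_time)
    return drift_time / rip_drift_time


def mobility_from_drift_time(
    device: DeviceConfig,
    drift_time: float,
    pressure: float | None = None,
    temperature: float | None = None,
) -> MobilityResult:
    """Full mobility computation for one drift time under a device config."""
    p = device.pressure if pressure is None else pressure
    t = device.temperature if temperature is None else temperature
    vd = drift_velocity(device.drift_length, drift_time)
    K = mobility_constant(vd, device.field_strength)
    return MobilityResult(vd, K, normalize_mobility(K, p, t))


# ---------------------------------------------------------------------------
# Long-form CSV dialect
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: IMSSpectrum, path: str | Path) -> None:
    """Write a spectrum as long-form CSV (retention_time_s, drift_time_ms,
    intensity_V), row-major by retention time."""
    spectrum.to_long_frame().to_csv(path, index=False, float_format="%.9g")


def read_spectrum_csv(
    path: str | Path, device: DeviceConfig | None = None
) -> IMSSpectrum:
    """Read a long-form spectrum CSV back into an :class:`IMSSpectrum`.

    Raises :class:`DomainError` naming the file and the first malformed
    data row, or on an incomplete (non-rectangular) grid.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # parser-level failure
        raise DomainError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing column(s) {missing}")
    for col in SPECTRUM_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DomainError(
                f"{path}: malformed value in column {col!r} at data row {row + 1}"
            )
        df[col] = numeric
    drift = np.unique(df["drift_time_ms"].to_numpy())
    retention = np.unique(df["retention_time_s"].to_numpy())
    if drift.size * retention.size != len(df):
        raise DomainError(f"{path}: rows do not form a complete rectangular grid")
    pivot = df.pivot(
        index="retention_time_s", columns="drift_time_ms", values="intensity_V"
    )
    pivot = pivot.reindex(index=retention, columns=drift)
    if pivot.isna().to_numpy().any():
        raise DomainError(f"{path}: rows do not form a complete rectangular grid")
    return IMSSpectrum(
        drift_axis=drift,
        retention_axis=retention,
        intensity=pivot.to_numpy(),
        device=device or DeviceConfig(),
    )
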