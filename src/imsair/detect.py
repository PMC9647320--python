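"""2D peak detection on GC-IMS spectra and replicate consensus tables.

Detection subtracts the RIP ridge (per-column median over retention),
finds strict local maxima of a lightly drift-smoothed copy of the
residual, thresholds them, excludes the RIP band, and reports the RIP
apex once as its own peak.  Consensus
tables single-linkage cluster peaks across replicate measurements and
carry per-replicate intensity series for stability analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import DomainError, IMSSpectrum, Peak

__all__ = [
    "DetectionConfig",
    "ConsensusPeak",
    "robust_noise_sd",
    "detect_peaks",
    "consensus_peaks",
    "peaks_to_frame",
    "consensus_to_frame",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for local-maximum peak picking.

    ``min_intensity`` of ``None`` selects an automatic threshold of
    ``threshold_factor`` times a robust (MAD-based) noise estimate.
    ``neighborhood`` gives the half-widths (drift ms, retention s) of the
    window a peak must dominate.  Analyte candidates within
    ``rip_exclusion_halfwidth`` of the RIP drift time are suppressed; the
    default (0.04 ms) keeps the band below the closest library analyte at
    relative drift 1.012.  ``smooth_drift`` is the sigma of a Gaussian
    pre-smoothing along drift applied before the local-maximum test
    (positions come from the smoothed surface, intensities from the raw
    one).
    """

    min_intensity: float | None = None  # V; None -> automatic
    neighborhood: tuple[float, float] = (0.016, 1.0)  # (ms, s) half-widths
    rip_exclusion_halfwidth: float = 0.04  # ms
    merge_tolerance: tuple[float, float] = (0.01, 2.0)  # (ms, s)
    smooth_drift: float = 0.003  # ms; 0 disables
    smooth_retention: float = 0.0  # s; 0 disables
    threshold_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.min_intensity is not None and self.min_intensity <= 0:
            raise DomainError("min_intensity must be > 0 when given")
        if min(self.neighborhood) <= 0 or min(self.merge_tolerance) <= 0:
            raise DomainError("neighborhood and merge_tolerance must be > 0")
        if self.rip_exclusion_halfwidth <= 0:
            raise DomainError("rip_exclusion_halfwidth must be > 0")
        if self.smooth_drift < 0 or self.smooth_retention < 0:
            raise DomainError("smoothing sigmas must be >= 0")
        if self.threshold_factor <= 0:
            raise DomainError("threshold_factor must be > 0")


def robust_noise_sd(values: np.ndarray) -> float:
    """MAD-based noise scale: 1.4826 * median(|x - median(x)|)."""
    values = np.asarray(values, dtype=float)
    return float(1.4826 * np.median(np.abs(values - np.median(values))))


def detect_peaks(
    spectrum: IMSSpectrum, config: DetectionConfig | None = None
) -> list[Peak]:
    """Locate analyte peaks and the RIP apex on one spectrum.

    Returns peaks sorted by (retention time, drift time); the RIP apex is
    included once with ``is_rip=True``.  Ties on plateaus are broken
    toward the lowest drift-time cell.
    """
    if spectrum is None:
        raise DomainError("spectrum must not be None")
    config = config or DetectionConfig()
    raw = spectrum.intensity
    drift = spectrum.drift_axis
    retention = spectrum.retention_axis
    rip = spectrum.device.rip_drift_time
    dstep = spectrum.drift_step() if drift.size > 1 else 1.0
    rstep = spectrum.retention_step() if retention.size > 1 else 1.0

    # The RIP ridge is constant along retention while analytes are local,
    # so the per-column median over retention estimates the ridge (plus
    # baseline).  Subtracting it lets analytes on the RIP shoulder stand
    # out as local maxima and unbiases their intensity readout.
    ridge_baseline = np.median(raw, axis=0)
    signal = raw - ridge_baseline[np.newaxis, :]

    smoothed = signal
    if config.smooth_drift > 0 and drift.size > 1:
        smoothed = ndimage.gaussian_filter1d(
            smoothed, sigma=config.smooth_drift / dstep, axis=1, mode="nearest"
        )
    if config.smooth_retention > 0 and retention.size > 1:
        smoothed = ndimage.gaussian_filter1d(
            smoothed, sigma=config.smooth_retention / rstep, axis=0, mode="nearest"
        )

    if config.min_intensity is not None:
        threshold = config.min_intensity
    else:
        threshold = config.threshold_factor * robust_noise_sd(signal)
    # Floor excludes flat (all-zero) plateaus on noise-free spectra.
    peak_signal = float(np.max(signal))
    floor = max(threshold, 1e-9 * peak_signal) if peak_signal > 0 else np.inf

    # epsilon guards against float noise in the axis step inflating the
    # window by a full cell (e.g. 0.02 / 0.00399999... -> 6 instead of 5)
    kd = max(1, math.ceil(config.neighborhood[0] / dstep - 1e-6))
    kr = max(1, math.ceil(config.neighborhood[1] / rstep - 1e-6))
    local_max = smoothed == ndimage.maximum_filter(
        smoothed, size=(2 * kr + 1, 2 * kd + 1), mode="nearest"
    )

    in_rip_band = np.abs(drift - rip) <= config.rip_exclusion_halfwidth
    candidates = local_max & (signal >= floor) & ~in_rip_band[np.newaxis, :]

    rows, cols = np.nonzero(candidates)
    # Non-maximum suppression with deterministic tie-breaking: strongest
    # first, then lowest drift, then lowest retention.
    order = np.lexsort((rows, cols, -smoothed[rows, cols]))
    kept_rows: list[int] = []
    kept_cols: list[int] = []
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if any(
            abs(r - kr_) <= kr and abs(c - kc_) <= kd
            for kr_, kc_ in zip(kept_rows, kept_cols)
        ):
            continue
        kept_rows.append(r)
        kept_cols.append(c)

    peaks = [
        Peak(
            retention_time=float(retention[r]),
            drift_time=float(drift[c]),
            relative_drift_time=float(drift[c] / rip),
            intensity=float(signal[r, c]),
            is_rip=False,
        )
        for r, c in zip(kept_rows, kept_cols)
    ]

    rip_peak = _rip_apex(raw, drift, retention, rip, config.rip_exclusion_halfwidth)
    if rip_peak is not None:
        peaks.append(rip_peak)
    peaks.sort(key=lambda p: (p.retention_time, p.drift_time))
    return peaks


def _rip_apex(
    raw: np.ndarray,
    drift: np.ndarray,
    retention: np.ndarray,
    rip: float,
    halfwidth: float,
) -> Peak | None:
    band = np.flatnonzero(np.abs(drift - rip) <= halfwidth)
    if band.size == 0:
        return None
    ridge = raw[:, band].mean(axis=0)
    apex_col = int(band[np.argmax(ridge)])
    apex_row = int(np.argmax(raw[:, apex_col]))
    intensity = float(raw[apex_row, apex_col])
    if intensity <= 0:
        return None
    return Peak(
        retention_time=float(retention[apex_row]),
        drift_time=float(drift[apex_col]),
        relative_drift_time=float(drift[apex_col] / rip),
        intensity=intensity,
        is_rip=True,
    )


@dataclass(frozen=True)
class ConsensusPeak:
    """A peak cluster across replicates, with replicate statistics.

    ``intensities`` holds one slot per replicate (NaN where the peak was
    not observed); ``intensity`` is the mean over observed replicates.
    """

    retention_time: float  # mean, s
    drift_time: float  # mean, ms
    relative_drift_time: float
    intensity: float  # mean over occurrences, V
    occurrence: int
    intensities: np.ndarray

    @property
    def n_replicates(self) -> int:
        return int(self.intensities.size)


def consensus_peaks(
    replicate_peak_lists: Sequence[Sequence[Peak]],
    config: DetectionConfig | None = None,
) -> list[ConsensusPeak]:
    """Single-linkage clustering of analyte peaks across replicates.

    Two peaks link when both coordinate differences fall within
    ``config.merge_tolerance``.  RIP peaks are dropped (the RIP is not an
    analyte).  The result is invariant to the order of replicate lists up
    to the ordering inside the per-replicate intensity series.
    """
    if len(replicate_peak_lists) == 0:
        raise DomainError("need at least one replicate peak list")
    config = config or DetectionConfig()
    tol_d, tol_r = config.merge_tolerance

    rep_idx: list[int] = []
    flat: list[Peak] = []
    for i, peak_list in enumerate(replicate_peak_lists):
        for peak in peak_list:
            if peak.is_rip:
                continue
            rep_idx.append(i)
            flat.append(peak)
    n_reps = len(replicate_peak_lists)
    if not flat:
        return []

    dt = np.array([p.drift_time for p in flat])
    rt = np.array([p.retention_time for p in flat])
    adjacency = (np.abs(dt[:, None] - dt[None, :]) <= tol_d) & (
        np.abs(rt[:, None] - rt[None, :]) <= tol_r
    )
    n_clusters, labels = connected_components(
        csr_matrix(adjacency), directed=False
    )

    consensus: list[ConsensusPeak] = []
    for label in range(n_clusters):
        members = np.flatnonzero(labels == label)
        series = np.full(n_reps, np.nan)
        for m in members:
            i = rep_idx[m]
            value = flat[m].intensity
            if np.isnan(series[i]) or value > series[i]:
                series[i] = value
        occurrence = int(np.sum(~np.isnan(series)))
        consensus.append(
            ConsensusPeak(
                retention_time=float(rt[members].mean()),
                drift_time=float(dt[members].mean()),
                relative_drift_time=float(
                    np.mean([flat[m].relative_drift_time for m in members])
                ),
                intensity=float(np.nanmean(series)),
                occurrence=occurrence,
                intensities=series,
            )
        )
    consensus.sort(key=lambda p: (p.retention_time, p.drift_time))
    return consensus


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Peak table as a DataFrame (the peak-table CSV dialect)."""
    return pd.DataFrame(
        {
            "retention_time_s": [p.retention_time for p in peaks],
            "drift_time_ms": [p.drift_time for p in peaks],
            "relative_drift_time": [p.relative_drift_time for p in peaks],
            "intensity_V": [p.intensity for p in peaks],
            "is_rip": [p.is_rip for p in peaks],
        }
    )


def consensus_to_frame(consensus: Sequence[ConsensusPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "retention_time_s": [p.retention_time for p in consensus],
            "drift_time_ms": [p.drift_time for p in consensus],
            "relative_drift_time": [p.relative_drift_time for p in consensus],
            "intensity_V": [p.intensity for p in consensus],
            "occurrence": [p.occurrence for p in consensus],
        }
    )
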