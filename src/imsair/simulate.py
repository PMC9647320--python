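"""Synthetic GC-IMS spectra and whole multi-location studies.

Spectra are rendered as a RIP ridge (Gaussian in drift, constant along
retention) plus separable 2D Gaussian analyte peaks at library
coordinates, plus optional white noise.  Studies draw one amplitude per
(location, replicate, compound group): the group base amplitude times the
location's fold ratio versus outdoor times a unit-mean lognormal replicate
multiplier.  Every random stream is derived deterministically from the
design seed and the (location, replicate, group) coordinates, so studies
are reproducible element-wise.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .core import ConfigurationError, DeviceConfig, DomainError, IMSSpectrum
from .library import LibraryEntry, ReferenceLibrary

__all__ = [
    "DEFAULT_SIGMA_DRIFT",
    "DEFAULT_SIGMA_RETENTION",
    "DEFAULT_RIP_AMPLITUDE",
    "DEFAULT_RIP_SIGMA",
    "INDOOR_LOCATIONS",
    "OUTDOOR_LOCATION",
    "MATERIALS_LAB_FOLDS",
    "ELECTRONIC_ENGINEERING_FOLDS",
    "GridSpec",
    "DEFAULT_GRID",
    "STUDY_GRID",
    "PeakSpec",
    "StudyDesign",
    "StudySpectrum",
    "specs_from_library",
    "generate_spectrum",
    "amplitude_multiplier",
    "replicate_amplitudes",
    "generate_study",
]

# Peak-shape defaults, chosen so that every pair of library entries is
# separated by >= ~3 combined widths and remains resolvable as two strict
# local maxima (the tightest pairs sit at retention gaps of 1-3 s and
# relative-drift gaps of 0.002-0.006).
DEFAULT_SIGMA_DRIFT = 0.010  # ms
DEFAULT_SIGMA_RETENTION = 1.0  # s
DEFAULT_RIP_AMPLITUDE = 5.0  # V
DEFAULT_RIP_SIGMA = 0.025  # ms

#: The fifteen indoor sampling sites plus the outdoor baseline site.
INDOOR_LOCATIONS = (
    "administration_building",
    "mechanical_engineering_building",
    "electronic_engineering_building",
    "atomic_molecular_physics_lab",
    "biomedical_engineering_lab",
    "chemistry_lab",
    "analytical_instrumentation_lab",
    "electronics_lab",
    "materials_engineering_lab",
    "conservation_restoration_lab",
    "fablab",
    "canteen",
    "bathroom",
    "workshop",
    "storeroom",
)
OUTDOOR_LOCATION = "outdoor"

#: Scenario: butanal (group 7), pentanal (17) and butanol (15) elevated
#: roughly 5x, 10x and 15x over outdoor in the materials engineering lab.
MATERIALS_LAB_FOLDS: Mapping[str, Mapping[int, float]] = {
    "materials_engineering_lab": {7: 5.0, 17: 10.0, 15: 15.0}
}
#: Scenario: butanol (group 15) roughly 3x over outdoor.
ELECTRONIC_ENGINEERING_FOLDS: Mapping[str, Mapping[int, float]] = {
    "electronic_engineering_building": {15: 3.0}
}

_AMPLITUDE_STREAM = 1
_NOISE_STREAM = 2


@dataclass(frozen=True)
class GridSpec:
    """Axis specification for rendered spectra.

    The drift axis is anchored at the device RIP drift time so that the
    RIP always falls exactly on a grid node regardless of the step.
    """

    drift_start: float = 4.0  # ms
    drift_stop: float = 7.0  # ms
    drift_step: float = 0.001  # ms
    retention_start: float = 0.0  # s
    retention_stop: float = 300.0  # s
    retention_step: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.drift_step <= 0 or self.retention_step <= 0:
            raise ConfigurationError("grid steps must be strictly positive")
        if self.drift_stop <= self.drift_start:
            raise ConfigurationError("drift_stop must exceed drift_start")
        if self.retention_stop <= self.retention_start:
            raise ConfigurationError("retention_stop must exceed retention_start")

    def axes(self, device: DeviceConfig) -> tuple[np.ndarray, np.ndarray]:
        rip = device.rip_drift_time
        if not self.drift_start <= rip <= self.drift_stop:
            raise ConfigurationError(
                f"grid drift range [{self.drift_start}, {self.drift_stop}] ms "
                f"does not contain the RIP drift time {rip} ms"
            )
        k_lo = math.ceil((self.drift_start - rip) / self.drift_step - 1e-9)
        k_hi = math.floor((self.drift_stop - rip) / self.drift_step + 1e-9)
        drift = rip + self.drift_step * np.arange(k_lo, k_hi + 1)
        n = math.floor(
            (self.retention_stop - self.retention_start) / self.retention_step + 1e-9
        )
        retention = self.retention_start + self.retention_step * np.arange(n + 1)
        return drift, retention


DEFAULT_GRID = GridSpec()
#: Coarser grid used for whole-study runs (16 x 31 spectra).
STUDY_GRID = GridSpec(4.6, 6.6, 0.004, 40.0, 280.0, 1.0)


@dataclass(frozen=True)
class PeakSpec:
    """Placement and shape of one synthetic analyte peak."""

    library_entry: LibraryEntry
    amplitude: float = 1.0  # V
    sigma_drift: float = DEFAULT_SIGMA_DRIFT  # ms
    sigma_retention: float = DEFAULT_SIGMA_RETENTION  # s

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise DomainError("amplitude must be > 0")
        if self.sigma_drift <= 0 or self.sigma_retention <= 0:
            raise DomainError("peak widths must be > 0")


def specs_from_library(
    library: ReferenceLibrary,
    amplitudes: Mapping[int, float] | float = 1.0,
    sigma_drift: float = DEFAULT_SIGMA_DRIFT,
    sigma_retention: float = DEFAULT_SIGMA_RETENTION,
) -> list[PeakSpec]:
    """One :class:`PeakSpec` per library entry.

    ``amplitudes`` is either a single amplitude for every entry or a
    mapping from group id to amplitude (groups absent default to 1 V).
    """
    specs = []
    for entry in library:
        if isinstance(amplitudes, Mapping):
            amp = float(amplitudes.get(entry.group_id, 1.0))
        else:
            amp = float(amplitudes)
        specs.append(PeakSpec(entry, amp, sigma_drift, sigma_retention))
    return specs


def _add_gaussian_2d(
    out: np.ndarray,
    drift: np.ndarray,
    retention: np.ndarray,
    center_drift: float,
    center_retention: float,
    amplitude: float,
    sigma_drift: float,
    sigma_retention: float,
    cutoff_sigmas: float = 6.0,
) -> None:
    """Accumulate a separable 2D Gaussian, truncated at ``cutoff_sigmas``."""
    j = np.searchsorted(
        drift,
        [center_drift - cutoff_sigmas * sigma_drift,
         center_drift + cutoff_sigmas * sigma_drift],
    )
    i = np.searchsorted(
        retention,
        [center_retention - cutoff_sigmas * sigma_retention,
         center_retention + cutoff_sigmas * sigma_retention],
    )
    j0, j1 = int(j[0]), int(j[1])
    i0, i1 = int(i[0]), int(i[1])
    if j0 >= j1 or i0 >= i1:
        return
    gd = np.exp(-0.5 * ((drift[j0:j1] - center_drift) / sigma_drift) ** 2)
    gr = np.exp(-0.5 * ((retention[i0:i1] - center_retention) / sigma_retention) ** 2)
    out[i0:i1, j0:j1] += amplitude * np.outer(gr, gd)


def generate_spectrum(
    peak_specs: Sequence[PeakSpec],
    device: DeviceConfig | None = None,
    noise_sd: float = 0.0,
    grid: GridSpec | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    *,
    rip_amplitude: float = DEFAULT_RIP_AMPLITUDE,
    rip_sigma: float = DEFAULT_RIP_SIGMA,
) -> IMSSpectrum:
    """Render one spectrum: RIP ridge + analyte Gaussians + white noise.

    Deterministic for a fixed seed.  Raises :class:`ConfigurationError`
    when the grid does not contain the device RIP drift time.
    """
    device = device or DeviceConfig()
    grid = grid or DEFAULT_GRID
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if rip_amplitude < 0 or rip_sigma <= 0:
        raise DomainError("RIP amplitude must be >= 0 and RIP width > 0")
    drift, retention = grid.axes(device)
    intensity = np.zeros((retention.size, drift.size))

    if rip_amplitude > 0:
        ridge = rip_amplitude * np.exp(
            -0.5 * ((drift - device.rip_drift_time) / rip_sigma) ** 2
        )
        ridge[np.abs(drift - device.rip_drift_time) > 6.0 * rip_sigma] = 0.0
        intensity += ridge[np.newaxis, :]

    for spec in peak_specs:
        _add_gaussian_2d(
            intensity,
            drift,
            retention,
            spec.library_entry.drift_time(device),
            spec.library_entry.retention_time,
            spec.amplitude,
            spec.sigma_drift,
            spec.sigma_retention,
        )

    if noise_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        intensity += rng.normal(0.0, noise_sd, intensity.shape)

    return IMSSpectrum(drift, retention, intensity, device)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a multi-location study.

    ``fold_map`` maps location name to ``{group_id: fold ratio}`` versus
    the outdoor baseline; groups and locations not listed default to a
    fold of 1.  The outdoor location always has all folds equal to 1.
    """

    location_names: tuple[str, ...] = INDOOR_LOCATIONS + (OUTDOOR_LOCATION,)
    replicates_per_location: int = 31
    fold_map: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    replicate_cv: float = 0.2
    seed: int = 0
    outdoor_name: str = OUTDOOR_LOCATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "location_names", tuple(self.location_names))
        if len(self.location_names) == 0:
            raise ConfigurationError("design needs at least one location")
        if len(set(self.location_names)) != len(self.location_names):
            raise ConfigurationError("location names must be unique")
        if self.replicates_per_location < 1:
            raise ConfigurationError("replicates_per_location must be >= 1")
        if self.replicate_cv < 0:
            raise ConfigurationError("replicate_cv must be >= 0")
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        for location, folds in self.fold_map.items():
            for group_id, fold in folds.items():
                if fold <= 0:
                    raise ConfigurationError(
                        f"fold for group {group_id} at {location!r} must be > 0"
                    )

    def fold(self, location: str, group_id: int) -> float:
        if location == self.outdoor_name:
            return 1.0
        return float(self.fold_map.get(location, {}).get(group_id, 1.0))

    @property
    def n_spectra(self) -> int:
        return len(self.location_names) * self.replicates_per_location


@dataclass(frozen=True)
class StudySpectrum:
    """One generated measurement with its ground-truth amplitudes."""

    location: str
    replicate: int
    spectrum: IMSSpectrum
    amplitudes: Mapping[int, float]  # group_id -> true amplitude (V)


def _location_key(location: str) -> int:
    return zlib.crc32(location.encode("utf-8"))


def amplitude_multiplier(
    seed: int, location: str, replicate: int, group_id: int, cv: float
) -> float:
    """Unit-mean lognormal replicate multiplier, deterministically seeded.

    ``cv`` is the lognormal coefficient of variation; ``cv == 0`` yields
    exactly 1.
    """
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [seed, _location_key(location), replicate, _AMPLITUDE_STREAM, group_id]
        )
    )
    return float(np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2))))


def replicate_amplitudes(
    design: StudyDesign,
    location: str,
    replicate: int,
    group_ids: Iterable[int],
    base_amplitudes: Mapping[int, float] | None = None,
) -> dict[int, float]:
    """True amplitude per group for one (location, replicate)."""
    base = base_amplitudes or {}
    return {
        gid: float(base.get(gid, 1.0))
        * design.fold(location, gid)
        * amplitude_multiplier(
            design.seed, location, replicate, gid, design.replicate_cv
        )
        for gid in group_ids
    }


def generate_study(
    design: StudyDesign,
    library: ReferenceLibrary,
    base_amplitudes: Mapping[int, float] | None = None,
    device: DeviceConfig | None = None,
    grid: GridSpec | None = None,
    noise_sd: float = 0.01,
    sigma_drift: float = DEFAULT_SIGMA_DRIFT,
    sigma_retention: float = DEFAULT_SIGMA_RETENTION,
    rip_amplitude: float = DEFAULT_RIP_AMPLITUDE,
    rip_sigma: float = DEFAULT_RIP_SIGMA,
) -> Iterator[StudySpectrum]:
    """Lazily generate every (location, replicate) spectrum of a study.

    Yields ``len(design.location_names) * design.replicates_per_location``
    spectra.  Raises :class:`ConfigurationError` when ``fold_map``
    references a group id absent from the library.
    """
    device = device or DeviceConfig()
    grid = grid or STUDY_GRID
    known_groups = set(library.group_ids)
    for location, folds in design.fold_map.items():
        unknown = sorted(set(folds) - known_groups)
        if unknown:
            raise ConfigurationError(
                f"fold_map for {location!r} references unknown group id(s) {unknown}"
            )

    for location in design.location_names:
        for replicate in range(design.replicates_per_location):
            amplitudes = replicate_amplitudes(
                design, location, replicate, library.group_ids, base_amplitudes
            )
            specs = [
                PeakSpec(
                    entry, amplitudes[entry.group_id], sigma_drift, sigma_retention
                )
                for entry in library
            ]
            noise_seed = np.random.SeedSequence(
                [design.seed, _location_key(location), replicate, _NOISE_STREAM]
            )
            spectrum = generate_spectrum(
                specs,
                device,
                noise_sd,
                grid,
                noise_seed,
                rip_amplitude=rip_amplitude,
                rip_sigma=rip_sigma,
            )
            yield StudySpectrum(location, replicate, spectrum, amplitudes)
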