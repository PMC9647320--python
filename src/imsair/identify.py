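"""Compound identification by cross-checking peak coordinates.

Peaks are matched to reference-library entries when both the retention
time and the RIP-relative drift time fall within tolerance; ties are
resolved by a scaled Euclidean distance and assignment is greedy
one-to-one (each entry claimed by at most one peak), so a monomer and a
dimer can never collapse onto the same library row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .core import ConfigurationError, DomainError, Peak
from .detect import ConsensusPeak
from .library import LibraryEntry, ReferenceLibrary

__all__ = [
    "MatchConfig",
    "GROUP_ASSIGNMENT_CONFIG",
    "Identification",
    "IdentificationSummary",
    "match_peaks",
    "summarize_identifications",
    "identifications_to_frame",
]

AnyPeak = Union[Peak, ConsensusPeak]

IDENTIFIED = "identified"
NOT_IDENTIFIED_STATUS = "not_identified"


@dataclass(frozen=True)
class MatchConfig:
    """Matching tolerances; ``distance_scale`` defaults to the tolerances."""

    tol_retention: float = 3.0  # s
    tol_relative_drift: float = 0.01
    distance_scale: tuple[float, float] | None = None  # (s, dimensionless)

    def __post_init__(self) -> None:
        if self.tol_retention <= 0 or self.tol_relative_drift <= 0:
            raise DomainError("matching tolerances must be > 0")
        if self.distance_scale is not None and min(self.distance_scale) <= 0:
            raise DomainError("distance_scale components must be > 0")

    @property
    def scales(self) -> tuple[float, float]:
        return self.distance_scale or (self.tol_retention, self.tol_relative_drift)


#: Tighter tolerances used when assigning group ids against the *full*
#: library (including N.I. entries), whose closest pair sits at
#: (1 s, 0.006) in (retention, relative drift).
GROUP_ASSIGNMENT_CONFIG = MatchConfig(tol_retention=2.5, tol_relative_drift=0.005)


@dataclass(frozen=True)
class Identification:
    peak: AnyPeak
    entry: LibraryEntry | None
    status: str
    distance: float

    def __post_init__(self) -> None:
        if (self.status == IDENTIFIED) != (self.entry is not None):
            raise DomainError("status 'identified' requires a library entry")


@dataclass(frozen=True)
class IdentificationSummary:
    n_detected: int
    n_identified: int
    n_distinct_compounds: int
    forms_by_compound: dict[str, tuple[str, ...]]


def _check_library_unique(library: ReferenceLibrary, config: MatchConfig) -> None:
    collisions = library.find_collisions(
        config.tol_retention, config.tol_relative_drift
    )
    if collisions:
        listing = "; ".join(
            f"group {a.group_id} {a.form} ({a.retention_time:g} s, "
            f"{a.relative_drift_time:g}) vs group {b.group_id} {b.form} "
            f"({b.retention_time:g} s, {b.relative_drift_time:g})"
            for a, b in collisions
        )
        raise ConfigurationError(
            f"library entries collide under tolerances "
            f"({config.tol_retention} s, {config.tol_relative_drift}): {listing}"
        )


def match_peaks(
    peaks: Sequence[AnyPeak],
    library: ReferenceLibrary,
    config: MatchConfig | None = None,
) -> list[Identification]:
    """Assign library entries to peaks, greedy by ascending distance.

    RIP peaks are skipped.  Raises :class:`ConfigurationError` when the
    library violates the uniqueness invariant under the tolerances.
    """
    config = config or MatchConfig()
    _check_library_unique(library, config)
    scale_rt, scale_rdt = config.scales

    analyte_peaks = [p for p in peaks if not getattr(p, "is_rip", False)]
    candidates: list[tuple[float, int, int]] = []
    for i, peak in enumerate(analyte_peaks):
        for j, entry in enumerate(library):
            d_rt = peak.retention_time - entry.retention_time
            d_rdt = peak.relative_drift_time - entry.relative_drift_time
            if (
                abs(d_rt) <= config.tol_retention
                and abs(d_rdt) <= config.tol_relative_drift
            ):
                distance = math.hypot(d_rt / scale_rt, d_rdt / scale_rdt)
                candidates.append((distance, i, j))
    candidates.sort()

    peak_entry: dict[int, tuple[int, float]] = {}
    claimed_entries: set[int] = set()
    for distance, i, j in candidates:
        if i in peak_entry or j in claimed_entries:
            continue
        peak_entry[i] = (j, distance)
        claimed_entries.add(j)

    result = []
    for i, peak in enumerate(analyte_peaks):
        if i in peak_entry:
            j, distance = peak_entry[i]
            result.append(
                Identification(peak, library.entries[j], IDENTIFIED, distance)
            )
        else:
            result.append(
                Identification(peak, None, NOT_IDENTIFIED_STATUS, math.inf)
            )
    return result


def summarize_identifications(
    idents: Sequence[Identification],
) -> IdentificationSummary:
    """Counts of detected peaks, identified peaks and distinct compounds."""
    forms: dict[str, list[str]] = {}
    n_identified = 0
    for ident in idents:
        if ident.entry is None:
            continue
        n_identified += 1
        if ident.entry.is_named:
            forms.setdefault(ident.entry.compound_name, []).append(ident.entry.form)
    return IdentificationSummary(
        n_detected=len(idents),
        n_identified=n_identified,
        n_distinct_compounds=len(forms),
        forms_by_compound={name: tuple(f) for name, f in sorted(forms.items())},
    )


def identifications_to_frame(idents: Sequence[Identification]) -> pd.DataFrame:
    """Identification table (the identification CSV dialect)."""
    rows = []
    for ident in idents:
        entry = ident.entry
        rows.append(
            {
                "retention_time_s": ident.peak.retention_time,
                "drift_time_ms": ident.peak.drift_time,
                "relative_drift_time": ident.peak.relative_drift_time,
                "intensity_V": ident.peak.intensity,
                "status": ident.status,
                "group_id": entry.group_id if entry else pd.NA,
                "compound_name": entry.compound_name if entry else "",
                "form": entry.form if entry else "",
                "cas_number": entry.cas_number if entry else "",
                "distance": ident.distance if entry else float("nan"),
            }
        )
    return pd.DataFrame(rows)
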