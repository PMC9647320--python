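"""Reference library of VOC coordinates used for identification.

The packaged library holds 31 entries in 20 compound groups.  Each entry
records the group number, compound name (or the sentinel ``N.I.`` for
peaks that could not be identified), CAS number, product-ion form
(monomer/dimer/trimer), retention time in seconds and the RIP-relative
drift time.  Relative drift times are dimensionless ratios; the absolute
drift time is reconstructed as ``ratio * rip_drift_time``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .core import ConfigurationError, DeviceConfig, DomainError

__all__ = ["NOT_IDENTIFIED", "FORMS", "LibraryEntry", "ReferenceLibrary"]

NOT_IDENTIFIED = "N.I."
FORMS = ("monomer", "dimer", "trimer")

_TSV_COLUMNS = (
    "group_id",
    "compound_name",
    "cas_number",
    "form",
    "retention_time_s",
    "relative_drift_time",
)


@dataclass(frozen=True)
class LibraryEntry:
    """One registered product ion: a (group, form) at fixed coordinates."""

    group_id: int
    compound_name: str
    cas_number: str
    form: str
    retention_time: float  # s
    relative_drift_time: float  # ratio to RIP drift time
    annotation: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.group_id <= 20:
            raise DomainError(f"group_id must be in [1, 20], got {self.group_id}")
        if self.form not in FORMS:
            raise DomainError(f"form must be one of {FORMS}, got {self.form!r}")
        if self.retention_time <= 0:
            raise DomainError("retention_time must be > 0")
        if self.relative_drift_time <= 0:
            raise DomainError("relative_drift_time must be > 0")

    @property
    def is_named(self) -> bool:
        return self.compound_name != NOT_IDENTIFIED

    def drift_time(self, device: DeviceConfig) -> float:
        """Absolute drift time (ms) reconstructed on a device."""
        return self.relative_drift_time * device.rip_drift_time


@dataclass(frozen=True)
class ReferenceLibrary:
    """An ordered collection of :class:`LibraryEntry`."""

    entries: tuple[LibraryEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    @property
    def group_ids(self) -> tuple[int, ...]:
        """Distinct group ids in first-appearance order."""
        seen: dict[int, None] = {}
        for entry in self.entries:
            seen.setdefault(entry.group_id, None)
        return tuple(seen)

    @property
    def compound_names(self) -> tuple[str, ...]:
        """Distinct compound names (excluding the N.I. sentinel)."""
        seen: dict[str, None] = {}
        for entry in self.entries:
            if entry.is_named:
                seen.setdefault(entry.compound_name, None)
        return tuple(seen)

    def named(self) -> "ReferenceLibrary":
        """Sub-library of identified entries only (the matching library)."""
        return ReferenceLibrary(tuple(e for e in self.entries if e.is_named))

    def group_name(self, group_id: int) -> str:
        for entry in self.entries:
            if entry.group_id == group_id:
                return entry.compound_name
        raise KeyError(group_id)

    def find_collisions(
        self, tol_retention: float, tol_relative_drift: float
    ) -> list[tuple[LibraryEntry, LibraryEntry]]:
        """Pairs of entries inside each other's matching tolerance box.

        Two entries collide when both coordinate differences are within
        tolerance, making them indistinguishable to the matcher.
        """
        collisions = []
        for i, a in enumerate(self.entries):
            for b in self.entries[i + 1 :]:
                if (
                    abs(a.retention_time - b.retention_time) <= tol_retention
                    and abs(a.relative_drift_time - b.relative_drift_time)
                    <= tol_relative_drift
                ):
                    collisions.append((a, b))
        return collisions

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "ReferenceLibrary":
        entries = []
        for row in rows:
            entries.append(
                LibraryEntry(
                    group_id=int(row["group_id"]),
                    compound_name=str(row["compound_name"]),
                    cas_number=str(row.get("cas_number") or ""),
                    form=str(row["form"]),
                    retention_time=float(row["retention_time_s"]),
                    relative_drift_time=float(row["relative_drift_time"]),
                    annotation=str(row.get("annotation") or ""),
                )
            )
        return cls(tuple(entries))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceLibrary":
        path = Path(path)
        with open(path, encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            header = reader.fieldnames or ()
            missing = [c for c in _TSV_COLUMNS if c not in header]
            if missing:
                raise ConfigurationError(
                    f"{path}: reference library missing column(s) {missing}"
                )
            return cls.from_rows(reader)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(_TSV_COLUMNS + ("annotation",))
            for e in self.entries:
                writer.writerow(
                    [
                        e.group_id,
                        e.compound_name,
                        e.cas_number,
                        e.form,
                        f"{e.retention_time:g}",
                        f"{e.relative_drift_time:g}",
                        e.annotation,
                    ]
                )

    @classmethod
    def load_default(cls) -> "ReferenceLibrary":
        """Load the packaged 31-entry reference library."""
        source = resources.files("imsair.data").joinpath("reference_library.tsv")
        with resources.as_file(source) as path:
            return cls.from_tsv(path)
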