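"""Outdoor-normalized relative-intensity profiles and replicate stability.

Per location, the mean intensity of every identified (group, form) over
its replicates is divided by the outdoor mean of the same (group, form),
giving a fold ratio.  The displayed score is zero-centred: a fold of 1
(indoor equals outdoor) scores 0, a fold of 4 scores +3 and a fold of
1/4 scores -3.  Fold ratios are reported alongside so a plain-ratio
reading of the profiles is also recoverable.  Scores of the monomer,
dimer and trimer of one group are added to give the group score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DomainError
from .identify import Identification
from .library import ReferenceLibrary

__all__ = [
    "LocationProfile",
    "StabilityReport",
    "mean_group_intensity",
    "relative_score",
    "aggregate_forms",
    "build_profiles",
    "stability_report",
    "profiles_to_frame",
    "plot_radar",
    "plot_stability",
]

GroupForm = tuple[int, str]


@dataclass(frozen=True)
class LocationProfile:
    """Per-group relative-intensity scores for one location."""

    location: str
    scores: Mapping[int, float]  # group_id -> signed zero-centred score
    folds: Mapping[int, float]  # group_id -> raw indoor/outdoor fold
    censored: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for gid, fold in self.folds.items():
            if fold <= 0:
                raise DomainError(f"fold for group {gid} must be > 0")


@dataclass(frozen=True)
class StabilityReport:
    """Replicate intensity series and CVs per (location, group, form)."""

    series: Mapping[tuple[str, int, str], np.ndarray]
    means: Mapping[tuple[str, int, str], float]
    cvs: Mapping[tuple[str, int, str], float]
    median_cv_by_location: Mapping[str, float]
    ranking: tuple[str, ...]  # most stable first

    @property
    def most_stable(self) -> str:
        return self.ranking[0]

    @property
    def least_stable(self) -> str:
        return self.ranking[-1]


def mean_group_intensity(
    idents: Sequence[Identification],
) -> dict[GroupForm, float]:
    """Mean replicate intensity per identified (group, form).

    Consensus peaks carry per-replicate series; the mean is taken over
    the replicates in which the peak occurred.  Plain peaks contribute
    their single intensity.
    """
    means: dict[GroupForm, float] = {}
    for ident in idents:
        if ident.entry is None:
            continue
        key = (ident.entry.group_id, ident.entry.form)
        series = getattr(ident.peak, "intensities", None)
        if series is not None:
            means[key] = float(np.nanmean(series))
        else:
            means[key] = float(ident.peak.intensity)
    return means


def relative_score(indoor_mean: float, outdoor_mean: float) -> tuple[float, float]:
    """Fold ratio and zero-centred signed score for one (group, form).

    ``fold = indoor / outdoor``; ``score = fold - 1`` for fold >= 1 and
    ``-(1/fold - 1)`` otherwise, so score(f) = -score(1/f).
    """
    if indoor_mean <= 0 or outdoor_mean <= 0:
        raise DomainError(
            f"means must be > 0, got indoor={indoor_mean!r} outdoor={outdoor_mean!r}"
        )
    fold = indoor_mean / outdoor_mean
    score = fold - 1.0 if fold >= 1.0 else -(1.0 / fold - 1.0)
    return fold, score


def aggregate_forms(form_scores: Mapping[GroupForm, float]) -> dict[int, float]:
    """Sum scores over the forms present for each group."""
    totals: dict[int, float] = {}
    for (group_id, _form), score in form_scores.items():
        totals[group_id] = totals.get(group_id, 0.0) + score
    return totals


def build_profiles(
    location_tables: Mapping[str, Sequence[Identification]],
    outdoor_name: str,
    group_ids: Sequence[int] | None = None,
    outdoor_floor: float | None = None,
) -> list[LocationProfile]:
    """One profile per indoor location versus the outdoor baseline.

    ``location_tables`` maps location name to the identified consensus
    peaks of that location.  Groups undetected indoors get fold 1 and
    score 0.  A (group, form) present indoors but missing outdoors is
    scored against ``outdoor_floor`` (typically the detection threshold)
    and the group is flagged censored; with no floor configured this is
    an error, since a ratio to nothing is undefined.
    """
    if outdoor_name not in location_tables:
        raise DomainError(f"outdoor location {outdoor_name!r} missing from tables")
    outdoor_means = mean_group_intensity(location_tables[outdoor_name])

    if group_ids is None:
        seen: dict[int, None] = {}
        for table in location_tables.values():
            for ident in table:
                if ident.entry is not None:
                    seen.setdefault(ident.entry.group_id, None)
        group_ids = tuple(seen)

    profiles = []
    for location in location_tables:
        if location == outdoor_name:
            continue
        indoor_means = mean_group_intensity(location_tables[location])
        form_scores: dict[GroupForm, float] = {}
        group_numer: dict[int, float] = {}
        group_denom: dict[int, float] = {}
        censored: set[int] = set()
        for key, indoor_mean in indoor_means.items():
            outdoor_mean = outdoor_means.get(key)
            if outdoor_mean is None:
                if outdoor_floor is None:
                    raise DomainError(
                        f"(group, form) {key} at {location!r} absent from outdoor "
                        "baseline and no outdoor_floor configured"
                    )
                outdoor_mean = outdoor_floor
                censored.add(key[0])
            _fold, score = relative_score(indoor_mean, outdoor_mean)
            form_scores[key] = score
            group_numer[key[0]] = group_numer.get(key[0], 0.0) + indoor_mean
            group_denom[key[0]] = group_denom.get(key[0], 0.0) + outdoor_mean
        group_scores = aggregate_forms(form_scores)
        scores = {gid: group_scores.get(gid, 0.0) for gid in group_ids}
        folds = {
            gid: (group_numer[gid] / group_denom[gid] if gid in group_numer else 1.0)
            for gid in group_ids
        }
        profiles.append(
            LocationProfile(location, scores, folds, frozenset(censored))
        )
    return profiles


def stability_report(
    location_tables: Mapping[str, Sequence[Identification]],
) -> StabilityReport:
    """Replicate-to-replicate intensity variability per analyte and site.

    Locations are ranked by the median coefficient of variation of their
    analytes (sample standard deviation, ddof=1), most stable first; ties
    break by location name.  Requires at least two replicates.
    """
    series: dict[tuple[str, int, str], np.ndarray] = {}
    means: dict[tuple[str, int, str], float] = {}
    cvs: dict[tuple[str, int, str], float] = {}
    per_location: dict[str, list[float]] = {}
    max_replicates = 0
    for location, table in location_tables.items():
        per_location.setdefault(location, [])
        for ident in table:
            if ident.entry is None:
                continue
            values = getattr(ident.peak, "intensities", None)
            if values is None:
                values = np.array([ident.peak.intensity])
            values = np.asarray(values, dtype=float)
            max_replicates = max(max_replicates, values.size)
            key = (location, ident.entry.group_id, ident.entry.form)
            observed = values[~np.isnan(values)]
            mean = float(observed.mean()) if observed.size else float("nan")
            if observed.size >= 2 and mean > 0:
                cv = float(observed.std(ddof=1) / mean)
            else:
                cv = float("nan")
            series[key] = values
            means[key] = mean
            if np.isfinite(cv):
                cvs[key] = cv
                per_location[location].append(cv)
    if max_replicates < 2:
        raise DomainError("stability analysis requires at least 2 replicates")
    median_cv = {
        location: (float(np.median(values)) if values else float("nan"))
        for location, values in per_location.items()
    }
    ranking = tuple(
        sorted(median_cv, key=lambda loc: (median_cv[loc], loc))
    )
    return StabilityReport(series, means, cvs, median_cv, ranking)


def profiles_to_frame(
    profiles: Sequence[LocationProfile], library: ReferenceLibrary | None = None
) -> pd.DataFrame:
    """Profile table (the profile CSV dialect)."""
    rows = []
    for profile in profiles:
        for gid in profile.scores:
            rows.append(
                {
                    "location": profile.location,
                    "group_id": gid,
                    "compound_name": library.group_name(gid) if library else "",
                    "fold": profile.folds.get(gid, 1.0),
                    "score": profile.scores[gid],
                    "censored": gid in profile.censored,
                }
            )
    return pd.DataFrame(rows)


def plot_radar(
    profile: LocationProfile, path: str | Path, library: ReferenceLibrary | None = None
) -> None:
    """Radar chart of one location profile (circular axis = group ids)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group_ids = sorted(profile.scores)
    values = [profile.scores[g] for g in group_ids]
    theta = np.linspace(0.0, 2.0 * np.pi, len(group_ids), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.plot(np.r_[theta, theta[:1]], np.r_[values, values[:1]], marker="o")
    ax.fill(np.r_[theta, theta[:1]], np.r_[values, values[:1]], alpha=0.25)
    ax.set_xticks(theta)
    ax.set_xticklabels([str(g) for g in group_ids])
    ax.set_title(f"Relative intensity profile: {profile.location}")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stability(
    report: StabilityReport,
    location: str,
    group_id: int,
    path: str | Path,
) -> None:
    """Replicate intensity series for one analyte at one location."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    plotted = False
    for (loc, gid, form), values in report.series.items():
        if loc == location and gid == group_id:
            ax.plot(
                np.arange(1, values.size + 1), values, marker="o", label=form
            )
            plotted = True
    if not plotted:
        plt.close(fig)
        raise DomainError(
            f"no series for group {group_id} at location {location!r}"
        )
    ax.set_xlabel("measurement")
    ax.set_ylabel("intensity (V)")
    ax.set_title(f"{location}: group {group_id}")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)
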