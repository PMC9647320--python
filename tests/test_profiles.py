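import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imsair.core import DomainError
from imsair.detect import ConsensusPeak, DetectionConfig, consensus_peaks, detect_peaks
from imsair.identify import GROUP_ASSIGNMENT_CONFIG, Identification, match_peaks
from imsair.profiles import (
    aggregate_forms,
    build_profiles,
    mean_group_intensity,
    plot_radar,
    plot_stability,
    profiles_to_frame,
    relative_score,
    stability_report,
)
from imsair.simulate import (
    MATERIALS_LAB_FOLDS,
    OUTDOOR_LOCATION,
    StudyDesign,
    generate_study,
)


def run_small_study(library, design, noise_sd=0.005):
    """Generate -> detect -> consensus -> group assignment, per location."""
    spectra = {}
    for item in generate_study(design, library, noise_sd=noise_sd):
        spectra.setdefault(item.location, []).append(item.spectrum)
    config = DetectionConfig()
    tables = {}
    for location, replicates in spectra.items():
        lists = [detect_peaks(s, config) for s in replicates]
        consensus = consensus_peaks(lists, config)
        tables[location] = match_peaks(consensus, library, GROUP_ASSIGNMENT_CONFIG)
    return tables


def fake_consensus(rt, dt, series):
    series = np.asarray(series, dtype=float)
    return ConsensusPeak(
        retention_time=rt,
        drift_time=dt,
        relative_drift_time=dt / 4.889,
        intensity=float(np.nanmean(series)),
        occurrence=int(np.sum(~np.isnan(series))),
        intensities=series,
    )


def identified(entry, series):
    peak = fake_consensus(entry.retention_time, entry.relative_drift_time * 4.889, series)
    return Identification(peak, entry, "identified", 0.0)


class TestRelativeScore:
    def test_outdoor_baseline_is_zero(self):
        assert relative_score(2.0, 2.0) == (1.0, 0.0)

    def test_fourfold_excess(self):
        fold, score = relative_score(8.0, 2.0)
        assert fold == pytest.approx(4.0)
        assert score == pytest.approx(3.0)

    def test_symmetric_depletion(self):
        fold, score = relative_score(1.0, 4.0)
        assert fold == pytest.approx(0.25)
        assert score == pytest.approx(-3.0)

    def test_non_positive_rejected(self):
        with pytest.raises(DomainError):
            relative_score(0.0, 1.0)
        with pytest.raises(DomainError):
            relative_score(1.0, -1.0)

    @given(f=st.floats(min_value=0.01, max_value=100.0))
    def test_odd_symmetry_around_unity(self, f):
        _, up = relative_score(f, 1.0)
        _, down = relative_score(1.0, f)
        assert up == pytest.approx(-down, rel=1e-9, abs=1e-12)


class TestAggregateForms:
    def test_monomer_plus_dimer(self):
        scores = {(7, "monomer"): 1.2, (7, "dimer"): 0.8}
        assert aggregate_forms(scores) == {7: pytest.approx(2.0)}

    def test_monomer_only_unchanged(self):
        assert aggregate_forms({(15, "monomer"): 0.4}) == {15: pytest.approx(0.4)}

    def test_ethanol_both_forms_at_fold_two(self):
        # fold 2 on both forms -> group score 2 x (2 - 1) = 2
        scores = {}
        for form in ("monomer", "dimer"):
            _, s = relative_score(2.0, 1.0)
            scores[(1, form)] = s
        assert aggregate_forms(scores) == {1: pytest.approx(2.0)}


class TestMeanGroupIntensity:
    def test_constant_series(self, library):
        entry = library.entries[0]
        means = mean_group_intensity([identified(entry, [2.0, 2.0, 2.0])])
        assert means == {(1, "monomer"): pytest.approx(2.0)}

    def test_noiseless_generator_amplitude(self, library):
        entry = library.entries[0]
        means = mean_group_intensity([identified(entry, [1.0] * 31)])
        assert means[(1, "monomer")] == pytest.approx(1.0)

    def test_lognormal_series_mean(self, library):
        # oracle: direct simulation of unit-mean lognormal means
        entry = library.entries[0]
        cv = 0.2
        sigma = np.sqrt(np.log1p(cv * cv))
        rng = np.random.default_rng(11)
        series = np.exp(rng.normal(-sigma * sigma / 2, sigma, 31))
        means = mean_group_intensity([identified(entry, series)])
        assert means[(1, "monomer")] == pytest.approx(1.0, abs=0.11)

    def test_missing_replicates_ignored(self, library):
        entry = library.entries[0]
        means = mean_group_intensity(
            [identified(entry, [2.0, np.nan, 4.0])]
        )
        assert means[(1, "monomer")] == pytest.approx(3.0)


class TestBuildProfiles:
    def test_materials_lab_scenario_exact_at_zero_cv(self, library):
        design = StudyDesign(
            location_names=("materials_engineering_lab", OUTDOOR_LOCATION),
            replicates_per_location=2,
            fold_map=MATERIALS_LAB_FOLDS,
            replicate_cv=0.0,
        )
        tables = run_small_study(library, design, noise_sd=0.0)
        profiles = build_profiles(
            tables, OUTDOOR_LOCATION, group_ids=library.group_ids
        )
        profile = profiles[0]
        assert profile.folds[7] == pytest.approx(5.0, rel=1e-6)
        assert profile.folds[17] == pytest.approx(10.0, rel=1e-6)
        assert profile.folds[15] == pytest.approx(15.0, rel=1e-6)
        # butanal has two forms: group score = 2 x (5 - 1)
        assert profile.scores[7] == pytest.approx(8.0, rel=1e-6)
        assert profile.scores[17] == pytest.approx(9.0, rel=1e-6)

    def test_equal_folds_give_zero_profiles(self, library):
        design = StudyDesign(
            location_names=("canteen", OUTDOOR_LOCATION),
            replicates_per_location=2,
            replicate_cv=0.0,
        )
        tables = run_small_study(library, design, noise_sd=0.0)
        profiles = build_profiles(
            tables, OUTDOOR_LOCATION, group_ids=library.group_ids
        )
        for gid, score in profiles[0].scores.items():
            assert score == pytest.approx(0.0, abs=1e-9)
            assert profiles[0].folds[gid] == pytest.approx(1.0, abs=1e-9)

    def test_electronic_engineering_scenario(self, library):
        design = StudyDesign(
            location_names=("electronic_engineering_building", OUTDOOR_LOCATION),
            replicates_per_location=31,
            fold_map={"electronic_engineering_building": {15: 3.0}},
            replicate_cv=0.2,
            seed=7,
        )
        tables = run_small_study(library, design)
        profiles = build_profiles(
            tables, OUTDOOR_LOCATION, group_ids=library.group_ids
        )
        assert 2.7 <= profiles[0].folds[15] <= 3.3

    def test_missing_outdoor_rejected(self, library):
        entry = library.entries[0]
        tables = {"a": [identified(entry, [1.0, 1.0])]}
        with pytest.raises(DomainError, match="outdoor"):
            build_profiles(tables, OUTDOOR_LOCATION)

    def test_group_absent_outdoors_censored_against_floor(self, library):
        entry = library.entries[0]
        other = library.entries[5]  # propanal, group 3
        tables = {
            OUTDOOR_LOCATION: [identified(other, [1.0, 1.0])],
            "a": [identified(entry, [0.5, 0.5]), identified(other, [1.0, 1.0])],
        }
        profiles = build_profiles(
            tables, OUTDOOR_LOCATION, group_ids=(1, 3), outdoor_floor=0.05
        )
        profile = profiles[0]
        assert profile.censored == frozenset({1})
        assert profile.folds[1] == pytest.approx(10.0)
        assert profile.folds[3] == pytest.approx(1.0)

    def test_group_absent_outdoors_without_floor_rejected(self, library):
        entry = library.entries[0]
        tables = {
            OUTDOOR_LOCATION: [],
            "a": [identified(entry, [0.5, 0.5])],
        }
        with pytest.raises(DomainError, match="floor"):
            build_profiles(tables, OUTDOOR_LOCATION, group_ids=(1,))

    def test_groups_absent_indoors_default_to_unity(self, library):
        entry = library.entries[0]
        tables = {
            OUTDOOR_LOCATION: [identified(entry, [1.0, 1.0])],
            "a": [],
        }
        profiles = build_profiles(tables, OUTDOOR_LOCATION, group_ids=(1, 2))
        assert profiles[0].folds == {1: 1.0, 2: 1.0}
        assert profiles[0].scores == {1: 0.0, 2: 0.0}


class TestStabilityReport:
    def test_zero_cv_all_zero_with_name_tiebreak(self, library):
        entry = library.entries[0]
        tables = {
            "b_site": [identified(entry, [1.0, 1.0, 1.0])],
            "a_site": [identified(entry, [2.0, 2.0, 2.0])],
        }
        report = stability_report(tables)
        assert all(cv == 0.0 for cv in report.cvs.values())
        assert report.ranking == ("a_site", "b_site")
        assert report.most_stable == "a_site"

    def test_low_cv_location_ranked_most_stable(self, library):
        rng = np.random.default_rng(5)
        entry = library.entries[0]
        tables = {}
        for location, cv in (("electronics_lab", 0.05), ("workshop", 0.4)):
            sigma = np.sqrt(np.log1p(cv * cv))
            series = np.exp(rng.normal(-sigma * sigma / 2, sigma, 31))
            tables[location] = [identified(entry, series)]
        report = stability_report(tables)
        assert report.most_stable == "electronics_lab"
        assert report.least_stable == "workshop"

    def test_single_replicate_rejected(self, library):
        entry = library.entries[0]
        tables = {"a": [identified(entry, [1.0])]}
        with pytest.raises(DomainError, match="2 replicates"):
            stability_report(tables)

    def test_cv_uses_sample_standard_deviation(self, library):
        entry = library.entries[0]
        series = [1.0, 2.0, 3.0]
        tables = {"a": [identified(entry, series)], "b": [identified(entry, series)]}
        report = stability_report(tables)
        expected = np.std(series, ddof=1) / np.mean(series)
        assert report.cvs[("a", 1, "monomer")] == pytest.approx(expected)


class TestProfileOutputs:
    def test_profiles_frame_columns(self, library):
        entry = library.entries[0]
        tables = {
            OUTDOOR_LOCATION: [identified(entry, [1.0, 1.0])],
            "a": [identified(entry, [2.0, 2.0])],
        }
        profiles = build_profiles(tables, OUTDOOR_LOCATION, group_ids=(1,))
        frame = profiles_to_frame(profiles, library)
        assert list(frame.columns) == [
            "location",
            "group_id",
            "compound_name",
            "fold",
            "score",
            "censored",
        ]
        assert frame.iloc[0]["compound_name"] == "Ethanol"
        assert frame.iloc[0]["fold"] == pytest.approx(2.0)

    def test_plots_write_png(self, tmp_path, library):
        entry = library.entries[0]
        tables = {
            OUTDOOR_LOCATION: [identified(entry, [1.0, 1.0])],
            "a": [identified(entry, [2.0, 2.0])],
        }
        profiles = build_profiles(tables, OUTDOOR_LOCATION, group_ids=(1,))
        report = stability_report(tables)
        radar = tmp_path / "radar.png"
        stability = tmp_path / "stability.png"
        plot_radar(profiles[0], radar, library)
        plot_stability(report, "a", 1, stability)
        assert radar.stat().st_size > 0
        assert stability.stat().st_size > 0

    def test_plot_stability_unknown_series_rejected(self, library):
        entry = library.entries[0]
        report = stability_report(
            {"a": [identified(entry, [1.0, 2.0])], "b": [identified(entry, [1.0, 2.0])]}
        )
        with pytest.raises(DomainError):
            plot_stability(report, "a", 19, "unused.png")
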