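"""Session reductions, rates, location grouping, facility aggregation."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

import epumine as em
from epumine.analytics import AnalyticsError, freedman_diaconis_bins


def entry_at(ts, mic="m", square="GridSquare_1", hole="FoilHole_1"):
    return em.JoinedMicrograph(record=em.AcquisitionRecord(
        micrograph_id=mic, square_id=square, hole_id=hole,
        acquisition_area_id=None, timestamp=ts))


PRESET = em.OpticsPreset(preset_name="acquisition", pixel_size=2.3,
                         sensor_pixels=(5760, 4092))


class TestSummarizeSession:
    def test_rate_is_span_based(self):
        t0 = datetime(2023, 6, 1, tzinfo=timezone.utc)
        entries = [entry_at(t0 + timedelta(hours=i / 100), mic=f"m{i}")
                   for i in range(101)]
        summary = em.summarize_session(entries, em.SessionConfig(), PRESET)
        # 101 micrographs spanning exactly one hour -> 100 per hour
        assert summary.rate_micrographs_per_hour == pytest.approx(100.0)

    def test_area_rate_is_rate_times_field_of_view(self):
        t0 = datetime(2023, 6, 1, tzinfo=timezone.utc)
        entries = [entry_at(t0 + timedelta(minutes=i), mic=f"m{i}")
                   for i in range(7)]
        summary = em.summarize_session(entries, em.SessionConfig(), PRESET)
        fov = PRESET.field_of_view_um2()
        assert summary.rate_area_per_hour == pytest.approx(
            summary.rate_micrographs_per_hour * fov)
        assert summary.collected_area == pytest.approx(7 * fov)

    def test_single_micrograph_has_no_rates(self):
        entries = [entry_at(datetime(2023, 6, 1, tzinfo=timezone.utc))]
        summary = em.summarize_session(entries, em.SessionConfig(), PRESET)
        assert summary.rate_micrographs_per_hour is None
        assert summary.n_micrographs == 1

    def test_zero_span_with_multiple_micrographs_is_pathological(self):
        t = datetime(2023, 6, 1, tzinfo=timezone.utc)
        entries = [entry_at(t, mic="a"), entry_at(t, mic="b")]
        with pytest.raises(AnalyticsError, match="zero"):
            em.summarize_session(entries, em.SessionConfig(), PRESET)

    def test_average_foils_per_square_division_rule(self):
        config = em.SessionConfig(n_squares_collected=3)
        summary = em.summarize_session([], config, PRESET, n_targeted_holes=420)
        assert summary.average_foils_per_square == 140

    def test_session_reduction_matches_hand_means(self, analysis):
        qualities = list(analysis.qualities.values())
        mean, lo, hi = analysis.summary.reductions["ctf_max_resolution"]
        values = [q.ctf_max_resolution for q in qualities]
        assert mean == pytest.approx(np.mean(values))
        assert (lo, hi) == (min(values), max(values))


class TestGroupByLocation:
    def test_partition_counts_sum_to_session_count(self, analysis):
        for grouping in ("atlas", "grid_square", "hole_position"):
            groups = em.group_by_location(
                analysis.entries, grouping, analysis.qualities,
                shots_per_hole=analysis.session.config.shots_per_hole)
            assert sum(g.n_micrographs for g in groups) == len(analysis.entries)

    def test_two_shots_yield_top_and_bottom_groups(self, analysis):
        groups = em.group_by_location(analysis.entries, "hole_position",
                                      analysis.qualities, shots_per_hole=2)
        assert sorted(g.group_key for g in groups) == ["bottom", "top"]

    def test_whole_session_mean_is_count_weighted_group_mean(self, analysis):
        groups = em.group_by_location(analysis.entries, "grid_square",
                                      analysis.qualities)
        whole = analysis.summary.reductions["density"][0]
        weighted = sum(g.reductions["density"][0] * g.n_micrographs
                       for g in groups) / len(analysis.entries)
        assert whole == pytest.approx(weighted, rel=1e-9)

    def test_single_square_group_equals_session_reduction(self, tmp_path):
        sc = em.example_scenario(seed=11, n_micrographs=6, n_squares_collected=1,
                                 foils_per_square=(3,),
                                 picks_per_micrograph=(30.0, 3.0))
        root = em.generate_session_tree(sc, tmp_path)
        em.generate_preprocessing_tree(sc, root)
        a = em.analyze_session(root)
        groups = em.group_by_location(a.entries, "grid_square", a.qualities)
        assert len(groups) == 1
        assert groups[0].reductions["density"] == pytest.approx(
            a.summary.reductions["density"])

    def test_denser_bottom_shots_recovered_by_grouping(self, tmp_path):
        sc = em.example_scenario(
            seed=13, n_micrographs=40, n_squares_collected=2,
            foils_per_square=(10, 10), shots_per_hole=2,
            picks_per_micrograph=(60.0, 4.0),
            shot_density_factors=(1.0, 2.0),  # shot 1 (bottom) twice as dense
            clustered_fraction_true=0.0)
        root = em.generate_session_tree(sc, tmp_path)
        em.generate_preprocessing_tree(sc, root)
        a = em.analyze_session(root)
        groups = {g.group_key: g for g in em.group_by_location(
            a.entries, "hole_position", a.qualities, shots_per_hole=2)}
        ratio = (groups["bottom"].reductions["density"][0]
                 / groups["top"].reductions["density"][0])
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_unknown_grouping_rejected(self, analysis):
        with pytest.raises(ValueError, match="grouping"):
            em.group_by_location(analysis.entries, "nebula", analysis.qualities)


@pytest.fixture(scope="module")
def facility(tmp_path_factory):
    scenarios = [
        em.example_scenario(seed=i, session_id=f"bi900-{i}",
                            instrument_id="KRIOS1" if i < 2 else "KRIOS2",
                            n_micrographs=4, n_squares_collected=1,
                            foils_per_square=(2,),
                            picks_per_micrograph=(20.0, 2.0),
                            ctf_resolution=(3.0 + i, 0.001))
        for i in range(3)
    ]
    root = em.generate_facility_tree(scenarios,
                                     tmp_path_factory.mktemp("facility"))
    return root, scenarios


class TestAggregateVisits:
    def test_one_row_per_visit(self, facility):
        root, scenarios = facility
        result = em.aggregate_visits(root)
        assert len(result.table) == 3
        assert result.failures == []
        assert set(result.table["visit"]) == {s.session_id for s in scenarios}

    def test_instrument_filter(self, facility):
        root, _ = facility
        result = em.aggregate_visits(root, {"instrument": "KRIOS1"})
        assert set(result.table["instrument"]) == {"KRIOS1"}
        assert len(result.table) == 2

    def test_distinct_ctf_means_preserved(self, facility, tmp_path):
        root, _ = facility
        result = em.aggregate_visits(root, out_dir=tmp_path / "hists")
        by_visit = result.table.set_index("visit")["ctf_max_resolution_mean"]
        # near-degenerate generating distributions -> distinguishable means
        assert by_visit["bi900-0"] == pytest.approx(3.0, abs=0.1)
        assert by_visit["bi900-2"] == pytest.approx(5.0, abs=0.1)
        assert result.histogram_paths  # PNGs written

    def test_empty_root_is_an_error(self, tmp_path):
        (tmp_path / "nothing").mkdir()
        with pytest.raises(AnalyticsError, match="instrument"):
            em.aggregate_visits(tmp_path / "nothing")

    def test_aggregation_is_pure(self, facility):
        root, _ = facility
        t1 = em.aggregate_visits(root).table
        t2 = em.aggregate_visits(root).table
        assert t1.equals(t2)


def test_freedman_diaconis_bins_reasonable():
    rng = np.random.default_rng(0)
    assert freedman_diaconis_bins(rng.normal(size=1000)) > 5
    assert freedman_diaconis_bins(np.array([1.0])) == 1
    assert freedman_diaconis_bins(np.full(50, 3.3)) == 1
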