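"""Event processing: independence merging, day/night, effort, rates, bootstrap."""

import math
from datetime import datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remcam.events import (
    bootstrap_rate_variance,
    classify_night,
    collapse_to_independent_events,
    encounter_rate,
    enumerate_rate_variance,
    stratum_effort,
    tally,
)
from remcam.types import CameraTally, Deployment, EventRecord, ValidationError

T0 = datetime(2010, 8, 1, 12, 0)


def _ev(minutes, camera="c1", count=1):
    return EventRecord(camera, T0 + timedelta(minutes=minutes), count=count)


class TestCollapse:
    def test_gap_separates_events(self):
        evs = [_ev(0), _ev(0.5), _ev(20)]
        out = collapse_to_independent_events(evs, gap_min=10)
        assert len(out) == 2
        assert out[0].timestamp == evs[0].timestamp
        assert out[1].timestamp == evs[2].timestamp

    def test_single_trigger(self):
        assert len(collapse_to_independent_events([_ev(0)])) == 1

    def test_chained_merging_spans_beyond_gap(self):
        # each inter-trigger gap < 10 min, total span 18 min: still one event
        evs = [_ev(0), _ev(9), _ev(18)]
        assert len(collapse_to_independent_events(evs, gap_min=10)) == 1

    def test_merged_event_keeps_max_count(self):
        evs = [_ev(0, count=1), _ev(5, count=3), _ev(8, count=2)]
        out = collapse_to_independent_events(evs, gap_min=10)
        assert out[0].count == 3

    def test_cameras_do_not_merge_together(self):
        evs = sorted(
            [_ev(0, "a"), _ev(1, "b")], key=lambda e: (e.camera_id, e.timestamp)
        )
        assert len(collapse_to_independent_events(evs, gap_min=10)) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValidationError, match="sorted"):
            collapse_to_independent_events([_ev(5), _ev(0)])

    @given(
        gaps=st.lists(st.floats(min_value=0.01, max_value=120), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent(self, gaps):
        times = np.cumsum(gaps)
        evs = [_ev(m) for m in times]
        once = collapse_to_independent_events(evs, gap_min=15)
        twice = collapse_to_independent_events(once, gap_min=15)
        assert once == twice


class TestNightWindow:
    @pytest.mark.parametrize(
        "hh,mm,expected",
        [(17, 59, False), (18, 0, True), (0, 30, True), (6, 0, False), (5, 59, True), (12, 0, False)],
    )
    def test_boundaries_half_open(self, hh, mm, expected):
        assert classify_night(datetime(2010, 8, 1, hh, mm)) is expected

    def test_day_night_partition_is_exhaustive(self):
        ts = [datetime(2010, 8, 1) + timedelta(minutes=7 * k) for k in range(300)]
        night = sum(classify_night(t) for t in ts)
        day = sum(not classify_night(t) for t in ts)
        assert night + day == len(ts)


class TestEffort:
    def test_all_hours_ten_days(self, small_deployments):
        assert stratum_effort(small_deployments[:1]) == pytest.approx(240.0)

    def test_night_window_is_12h_per_day(self, small_deployments):
        assert stratum_effort(small_deployments[:1], window="night") == pytest.approx(120.0)

    def test_partial_day_overlap(self):
        d = Deployment("c", 0, 0, datetime(2010, 8, 1, 12), datetime(2010, 8, 1, 20))
        assert stratum_effort([d], window="night") == pytest.approx(2.0)

    def test_habitat_restriction(self, small_deployments, split_habitat_map):
        eff = stratum_effort(
            small_deployments, habitat="grassland", habitat_map=split_habitat_map
        )
        assert eff == pytest.approx(240.0)

    def test_camera_outside_all_polygons_excluded(self, split_habitat_map):
        d = Deployment("far", 100.0, 100.0, datetime(2010, 8, 1), datetime(2010, 8, 2))
        assert stratum_effort([d], habitat="grassland", habitat_map=split_habitat_map) == 0.0


class TestEncounterRate:
    def test_ratio_of_totals(self):
        r = encounter_rate([CameraTally("a", 5, 1200.0)])
        assert r.rate == pytest.approx(5 / 1200)

    def test_zero_events(self):
        assert encounter_rate([CameraTally("a", 0, 10), CameraTally("b", 0, 10)]).rate == 0.0

    def test_pooled_not_mean_of_rates(self):
        r = encounter_rate([CameraTally("a", 0, 240.0), CameraTally("b", 10, 240.0)])
        assert r.rate == pytest.approx(10 / 480)

    def test_zero_effort_rejected(self):
        with pytest.raises(ValidationError):
            encounter_rate([CameraTally("a", 0, 0.0)])

    def test_invariant_to_splitting_a_camera(self):
        whole = encounter_rate([CameraTally("a", 4, 100.0), CameraTally("b", 2, 50.0)])
        split = encounter_rate(
            [CameraTally("a1", 1, 25.0), CameraTally("a2", 3, 75.0), CameraTally("b", 2, 50.0)]
        )
        assert whole.rate == pytest.approx(split.rate)

    def test_tally_windows_partition_counts(self, small_deployments):
        evs = sorted(
            [
                EventRecord("c1", datetime(2010, 8, 2, 3, 0)),
                EventRecord("c1", datetime(2010, 8, 2, 12, 0)),
                EventRecord("c2", datetime(2010, 8, 3, 19, 0)),
            ],
            key=lambda e: (e.camera_id, e.timestamp),
        )
        y = lambda w: sum(t.y for t in tally(small_deployments, evs, window=w))
        assert y("night") + y("day") == y("all") == 3

    def test_per_individual_counts_group_size(self, small_deployments):
        evs = [EventRecord("c1", datetime(2010, 8, 2, 12, 0), count=4)]
        assert sum(t.y for t in tally(small_deployments, evs)) == 1
        assert sum(t.y for t in tally(small_deployments, evs, per_individual=True)) == 4


class TestBootstrap:
    def test_identical_cameras_zero_variance(self):
        tallies = [CameraTally(f"c{i}", 3, 100.0) for i in range(4)]
        r = bootstrap_rate_variance(tallies, n_boot=200, seed=0)
        assert r.var_boot == pytest.approx(0.0, abs=1e-20)

    def test_two_camera_exhaustive_oracle(self):
        # resamples {AA, AB, BA, BB} -> rates {0, .5, .5, 1}, variance 0.125
        tallies = [CameraTally("a", 0, 10.0), CameraTally("b", 10, 10.0)]
        assert enumerate_rate_variance(tallies) == pytest.approx(0.125)
        r = bootstrap_rate_variance(tallies, n_boot=100_000, seed=1)
        # 3 sigma of the sampling variance of the variance estimator
        assert abs(r.var_boot - 0.125) < 1.3e-3
        assert r.seed == 1 and r.n_boot == 100_000

    def test_three_camera_enumeration_oracle(self):
        tallies = [CameraTally("a", 0, 10.0), CameraTally("b", 5, 10.0), CameraTally("c", 10, 20.0)]
        exact = enumerate_rate_variance(tallies)
        r = bootstrap_rate_variance(tallies, n_boot=100_000, seed=2)
        assert r.var_boot == pytest.approx(exact, rel=0.05)

    def test_single_camera_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_rate_variance([CameraTally("a", 1, 10.0)], n_boot=10, seed=0)

    def test_seed_reproducible(self):
        tallies = [CameraTally("a", 0, 10.0), CameraTally("b", 10, 10.0)]
        r1 = bootstrap_rate_variance(tallies, n_boot=500, seed=7)
        r2 = bootstrap_rate_variance(tallies, n_boot=500, seed=7)
        assert r1.var_boot == r2.var_boot
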