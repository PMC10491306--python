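"""Orientation angles and the buffered two-threshold event detector."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scramblescan as ss
from scramblescan.detector import _split_replicas
from conftest import brute_force_events, make_trace, write_gro


def _frame_from(points, box=(10.0, 10.0, 10.0)):
    return ss.Frame(time_ns=0.0, positions=np.asarray(points, float), box=np.asarray(box))


def _selection(n=1):
    return ss.LipidSelection(
        lipid_ids=np.arange(n),
        resids=np.arange(1, n + 1),
        head=np.arange(n) * 3,
        tails=np.stack([np.arange(n) * 3 + 1, np.arange(n) * 3 + 2], axis=1),
    )


class TestLipidAngle:
    @pytest.mark.parametrize(
        "head,expected",
        [((0, 0, 1.0), 0.0), ((0, 0, -1.0), 180.0), ((1.0, 0, 0), 90.0)],
    )
    def test_axis_aligned(self, head, expected):
        frame = _frame_from([head, (0, 0, 0), (0, 0, 0.0)])
        # avoid coincident tails: offset the second tail along y
        frame.positions[2] = [0, 1e-9, 0]
        angle = ss.lipid_angle(frame, _selection(), 0)
        assert angle == pytest.approx(expected, abs=1e-5)

    def test_vector_mean_matches_explicit_arithmetic(self):
        head = np.array([0.0, 0.0, 0.5])
        t1 = np.array([0.1, 0.0, 0.0])
        t2 = np.array([0.3, 0.2, 0.0])
        frame = _frame_from([head, t1, t2])
        angle = ss.lipid_angle(frame, _selection(), 0)
        # independent oracle: explicit unit-vector mean
        v1 = (head - t1) / np.linalg.norm(head - t1)
        v2 = (head - t2) / np.linalg.norm(head - t2)
        m = v1 + v2
        expected = np.degrees(np.arccos(m[2] / np.linalg.norm(m)))
        assert angle == pytest.approx(expected, abs=1e-9)

    def test_angle_mean_method_differs_in_general(self):
        frame = _frame_from([(0.0, 0.0, 0.5), (0.4, 0.0, 0.0), (-0.1, 0.0, 0.0)])
        vm = ss.lipid_angle(frame, _selection(), 0, method="vector-mean")
        am = ss.lipid_angle(frame, _selection(), 0, method="angle-mean")
        assert vm != pytest.approx(am, abs=1e-6)

    def test_coincident_beads_raise(self):
        frame = _frame_from([(0, 0, 0.5), (0, 0, 0.5), (0.1, 0, 0)])
        with pytest.raises(ss.GeometryError, match="0"):
            ss.lipid_angle(frame, _selection(), 0)


class TestBuildTraces:
    def _frames(self, times, n_lipids=2, replica=0):
        sel = _selection(n_lipids)
        for t in times:
            pos = np.zeros((3 * n_lipids, 3))
            pos[sel.head, 2] = 1.0  # all heads straight up
            pos[sel.tails[:, 1], 1] = 1e-9
            yield ss.Frame(time_ns=t, positions=pos, box=np.array([5.0, 5.0, 5.0]), replica=replica)

    def test_one_trace_per_lipid(self):
        traces = ss.build_traces(self._frames(np.arange(10.0)), _selection(2))
        assert len(traces) == 2
        assert all(len(tr.times) == 10 for tr in traces)
        assert traces[0].angles == pytest.approx(np.zeros(10), abs=1e-5)

    def test_exact_subsampling_takes_grid_frames(self):
        traces = ss.build_traces(self._frames(np.arange(0, 5, 0.5)), _selection(1), stride_ns=1.0)
        assert traces[0].times == pytest.approx([0, 1, 2, 3, 4])

    def test_nearest_frame_resampling_warns(self):
        times = np.arange(0, 4, 0.4)
        with pytest.warns(UserWarning, match="nearest-frame"):
            traces = ss.build_traces(self._frames(times), _selection(1), stride_ns=1.0)
        # each grid point must be served by the closest available frame
        assert len(traces[0].times) >= 3

    def test_empty_trajectory_errors(self):
        with pytest.raises(ss.AnalysisError, match="empty"):
            ss.build_traces(iter([]), _selection(1))

    def test_replica_split_preserves_order(self):
        frames = list(self._frames([0.0, 1.0], replica=0)) + list(
            self._frames([0.0, 1.0], replica=1)
        )
        groups = [(r, len(list(g))) for r, g in _split_replicas(iter(frames))]
        assert groups == [(0, 2), (1, 2)]


class TestDetectEvents:
    def test_single_clean_flip(self):
        events, states = ss.detect_events(make_trace([10, 30, 170, 175]), ss.Leaflet.UPPER)
        assert len(events) == 1
        assert events[0].event_time_ns == 2.0
        assert events[0].direction is ss.Direction.UPPER_TO_LOWER
        assert list(states) == [ss.Leaflet.UPPER] * 2 + [ss.Leaflet.LOWER] * 2

    def test_buffer_oscillation_counts_nothing(self):
        events, _ = ss.detect_events(make_trace([40, 100, 40, 100, 40]), ss.Leaflet.UPPER)
        assert events == []

    def test_alternating_full_crossings(self):
        events, _ = ss.detect_events(make_trace([10, 170, 10, 170]), ss.Leaflet.UPPER)
        assert [e.direction.value for e in events] == [
            "UPPER->LOWER",
            "LOWER->UPPER",
            "UPPER->LOWER",
        ]

    def test_threshold_equality_is_inside_buffer(self):
        events, _ = ss.detect_events(make_trace([10, 125.0, 55.0, 125.0]), ss.Leaflet.UPPER)
        assert events == []

    def test_inconsistent_initial_state_corrected_with_warning(self):
        with pytest.warns(UserWarning, match="corrected"):
            events, states = ss.detect_events(make_trace([170, 160]), ss.Leaflet.UPPER)
        assert events == []
        assert states[0] is ss.Leaflet.LOWER

    def test_transit_window_tracks_buffer_entry(self):
        trace = make_trace([10, 40, 60, 100, 130])
        events, _ = ss.detect_events(trace, ss.Leaflet.UPPER)
        assert len(events) == 1
        assert events[0].buffer_entry_ns == 2.0  # first buffer sample of the run
        assert events[0].event_time_ns == 4.0

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            ss.detect_events(make_trace([10.0]), ss.Leaflet.UPPER, 125, 55)


class TestDetectorProperties:
    """The implementation must agree with a naive sample-by-sample oracle."""

    @given(
        st.lists(st.floats(min_value=0.0, max_value=180.0), min_size=1, max_size=300),
        st.sampled_from(["UPPER", "LOWER"]),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, angles, initial):
        expected = brute_force_events(angles, initial)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events, _ = ss.detect_events(make_trace(angles), ss.Leaflet(initial))
        got = [(int(e.event_time_ns), e.direction.value) for e in events]
        assert got == expected

    @given(
        st.lists(st.floats(min_value=0.0, max_value=180.0), min_size=1, max_size=200),
        st.sampled_from(["UPPER", "LOWER"]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_mirror_symmetry(self, angles, initial):
        """Thresholds are symmetric about 90 deg: mirroring a trace and
        swapping the initial leaflet mirrors the event list."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev, _ = ss.detect_events(make_trace(angles), ss.Leaflet(initial))
            mirrored = [180.0 - a for a in angles]
            other = ss.Leaflet.LOWER if initial == "UPPER" else ss.Leaflet.UPPER
            ev_m, _ = ss.detect_events(make_trace(mirrored), other)
        assert [e.event_time_ns for e in ev] == [e.event_time_ns for e in ev_m]
        assert all(
            a.direction != b.direction for a, b in zip(ev, ev_m)
        )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=180.0), min_size=2, max_size=200),
        st.integers(min_value=1, max_value=199),
        st.sampled_from(["UPPER", "LOWER"]),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_concatenation_consistency(self, angles, cut, initial):
        """events(A) + events(B | end state of A) == events(A + B)."""
        cut = min(cut, len(angles) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev_all, _ = ss.detect_events(make_trace(angles), ss.Leaflet(initial))
            ev_a, states_a = ss.detect_events(make_trace(angles[:cut]), ss.Leaflet(initial))
            end_state = states_a[-1]
            tail = make_trace(angles[cut:])
            # continuation: the tail's first sample may legitimately complete a
            # crossing, so no initial-state correction applies if consistent
            ev_b, _ = ss.detect_events(tail, end_state)
        # compare counts with the tail's correction caveat: a tail starting
        # beyond the opposite threshold is corrected silently, losing the
        # crossing event the full trace counts at the junction
        junction_crossing = (
            (end_state is ss.Leaflet.UPPER and angles[cut] > 125.0)
            or (end_state is ss.Leaflet.LOWER and angles[cut] < 55.0)
        )
        assert len(ev_all) == len(ev_a) + len(ev_b) + (1 if junction_crossing else 0)

    def test_consecutive_events_alternate_direction(self, small_scrambler):
        _, traces, ledger = small_scrambler
        for trace in traces:
            events, _ = ss.detect_events(trace, ledger.initial_leaflets[trace.lipid_id])
            for a, b in zip(events, events[1:]):
                assert a.direction != b.direction

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_confined_traces_never_fire(self, seed):
        """Any trace confined to the buffer band after the first sample
        yields zero events, regardless of noise amplitude."""
        rng = np.random.default_rng(seed)
        angles = np.concatenate([[10.0], rng.uniform(55.0, 125.0, 500)])
        events, _ = ss.detect_events(make_trace(angles), ss.Leaflet.UPPER)
        assert events == []


def test_events_table_is_deterministically_ordered(small_scrambler):
    _, traces, ledger = small_scrambler
    events = ss.detect_all(traces, ledger.initial_leaflets)
    df = ss.events_to_table(events)
    assert list(df.columns) == [
        "replica",
        "lipid_id",
        "event_time_ns",
        "direction",
        "buffer_entry_ns",
    ]
    key = df[["replica", "event_time_ns", "lipid_id"]].apply(tuple, axis=1).tolist()
    assert key == sorted(key)
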