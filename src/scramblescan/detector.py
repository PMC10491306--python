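"""Orientation angles and buffered two-threshold scrambling-event detection.

The orientation of each lipid is the angle between its tail-to-head vector
and the +z axis: lipids in the upper leaflet sit near 0 deg, lipids in the
lower leaflet near 180 deg.  Two vectors are available per lipid (each
tail-terminal bead to the headgroup bead); by default the lipid orientation
is the mean of the two unit vectors, which is robust to chain splay.

Event counting uses a hysteresis state machine with a buffer band between
55 and 125 deg: a lipid in the upper leaflet is counted as having scrambled
at the first sample with angle > 125 deg, a lipid in the lower leaflet at
the first sample with angle < 55 deg.  Samples inside the closed buffer
band never change leaflet state, so within-leaflet wobble is not counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import AnalysisError, GeometryError
from .topology import Frame, Leaflet, LipidSelection

logger = logging.getLogger(__name__)

DEFAULT_STRIDE_NS = 1.0
DEFAULT_BUFFER_LOW_DEG = 55.0
DEFAULT_BUFFER_HIGH_DEG = 125.0


class Direction(str, Enum):
    UPPER_TO_LOWER = "UPPER->LOWER"
    LOWER_TO_UPPER = "LOWER->UPPER"


@dataclass(frozen=True)
class OrientationTrace:
    """Per-lipid orientation-angle time series at a fixed stride."""

    lipid_id: int
    replica: int
    times: np.ndarray   # ns
    angles: np.ndarray  # degrees in [0, 180]

    def __post_init__(self):
        if len(self.times) != len(self.angles):
            raise ValueError("times and angles must have equal length")


@dataclass(frozen=True)
class ScramblingEvent:
    """One counted leaflet crossing.

    ``event_time_ns`` is the time of the sample that completed the crossing;
    ``buffer_entry_ns`` starts the contiguous buffer-resident interval that
    ended in the crossing (equal to ``event_time_ns`` for an instantaneous
    jump across the whole buffer).
    """

    lipid_id: int
    replica: int
    event_time_ns: float
    direction: Direction
    buffer_entry_ns: float

    @property
    def transit_window(self) -> Tuple[float, float]:
        return (self.buffer_entry_ns, self.event_time_ns)


def _orientation_vectors(positions: np.ndarray, selection: LipidSelection) -> np.ndarray:
    """Unit tail->head vectors, shape (n_lipids, 2, 3)."""
    head = positions[selection.head]                      # (n, 3)
    tails = positions[selection.tails]                    # (n, 2, 3)
    vec = head[:, None, :] - tails                        # tail -> head
    norm = np.linalg.norm(vec, axis=2)
    bad = np.flatnonzero((norm == 0).any(axis=1))
    if len(bad):
        raise GeometryError(
            f"zero-length orientation vector (coincident beads) for lipid id(s) {bad.tolist()}"
        )
    return vec / norm[:, :, None]


def lipid_angles(
    positions: np.ndarray,
    selection: LipidSelection,
    method: str = "vector-mean",
) -> np.ndarray:
    """Orientation angle versus +z in degrees for every selected lipid.

    ``method='vector-mean'`` (default) takes the angle of the mean of the two
    unit tail->head vectors; ``method='angle-mean'`` averages the two angles
    instead.  Both are exposed because either convention is defensible for
    two-chain lipids.
    """
    unit = _orientation_vectors(positions, selection)
    if method == "vector-mean":
        mean = unit.sum(axis=1)
        norm = np.linalg.norm(mean, axis=1)
        bad = np.flatnonzero(norm == 0)
        if len(bad):
            raise GeometryError(
                f"anti-parallel chain vectors give a zero mean orientation for "
                f"lipid id(s) {bad.tolist()}"
            )
        cosz = np.clip(mean[:, 2] / norm, -1.0, 1.0)
        return np.degrees(np.arccos(cosz))
    if method == "angle-mean":
        cosz = np.clip(unit[:, :, 2], -1.0, 1.0)
        return np.degrees(np.arccos(cosz)).mean(axis=1)
    raise ValueError(f"unknown angle method {method!r}")


def lipid_angle(
    frame: Frame, selection: LipidSelection, lipid_id: int, method: str = "vector-mean"
) -> float:
    """Orientation angle of a single lipid in one frame (degrees)."""
    sub = LipidSelection(
        lipid_ids=np.array([0]),
        resids=selection.resids[[lipid_id]],
        head=selection.head[[lipid_id]],
        tails=selection.tails[[lipid_id]],
        residue_name=selection.residue_name,
    )
    try:
        return float(lipid_angles(frame.positions, sub, method=method)[0])
    except GeometryError as exc:
        raise GeometryError(f"lipid {lipid_id}: {exc}") from exc


def _split_replicas(frames: Iterable[Frame]) -> Iterator[Tuple[int, Iterator[Frame]]]:
    """Lazily group a time-ordered frame stream by its replica tag."""
    import itertools

    for replica, group in itertools.groupby(frames, key=lambda f: f.replica):
        yield replica, group


def build_traces(
    frames: Iterable[Frame],
    selection: LipidSelection,
    stride_ns: float = DEFAULT_STRIDE_NS,
    method: str = "vector-mean",
) -> List[OrientationTrace]:
    """Compute orientation-angle traces for every lipid at a fixed stride.

    Frames are consumed lazily.  If the trajectory's sampling interval does
    not hit the stride grid exactly, the nearest frame to each grid point is
    used and a warning is emitted once per replica.
    """
    traces: List[OrientationTrace] = []
    n_replicas = 0
    for replica, rep_frames in _split_replicas(frames):
        n_replicas += 1
        times, angle_rows = _sample_replica(rep_frames, selection, stride_ns, method, replica)
        if len(times) == 0:
            continue
        angles = np.vstack(angle_rows)  # (n_samples, n_lipids)
        for lid in selection.lipid_ids:
            traces.append(
                OrientationTrace(
                    lipid_id=int(lid),
                    replica=int(replica),
                    times=times.copy(),
                    angles=angles[:, lid].copy(),
                )
            )
    if n_replicas == 0:
        raise AnalysisError("empty trajectory: no frames to build traces from")
    return traces


def _sample_replica(rep_frames, selection, stride_ns, method, replica):
    times: List[float] = []
    rows: List[np.ndarray] = []
    t0 = None
    prev = None
    k = 0
    warned = False

    def take(frame):
        nonlocal warned, k
        dev = abs(frame.time_ns - (t0 + k * stride_ns))
        if dev > 1e-6 * max(1.0, stride_ns) and not warned:
            warnings.warn(
                f"replica {replica}: frame times do not hit the {stride_ns} ns stride "
                f"grid; using nearest-frame resampling",
                stacklevel=2,
            )
            warned = True
        times.append(t0 + k * stride_ns)
        rows.append(lipid_angles(frame.positions, selection, method=method))
        k += 1

    for frame in rep_frames:
        if t0 is None:
            t0 = frame.time_ns
        target = t0 + k * stride_ns
        while frame.time_ns >= target - 1e-9:
            if prev is not None and abs(prev.time_ns - target) < abs(frame.time_ns - target):
                take(prev)
            else:
                take(frame)
            target = t0 + k * stride_ns
        prev = frame
    return np.asarray(times), rows


def detect_events(
    trace: OrientationTrace,
    initial_state: Leaflet,
    lower_threshold: float = DEFAULT_BUFFER_LOW_DEG,
    upper_threshold: float = DEFAULT_BUFFER_HIGH_DEG,
) -> Tuple[List[ScramblingEvent], np.ndarray]:
    """Count scrambling events on one orientation trace.

    State machine semantics: a lipid in state UPPER flips to LOWER (one
    event) at the first sample with angle strictly greater than
    ``upper_threshold``; a lipid in state LOWER flips to UPPER at the first
    sample with angle strictly lower than ``lower_threshold``.  Angles inside
    the closed buffer band never change state.  Equality with a threshold
    counts as inside the buffer.

    Returns the event list and the per-sample leaflet state trace
    (post-crossing states).  If the first sample already lies beyond the
    threshold opposite to ``initial_state``, the state is corrected with a
    warning and no event is emitted for the initialization artifact.
    """
    if not (0.0 < lower_threshold < upper_threshold < 180.0):
        raise ValueError(
            f"thresholds must satisfy 0 < lower < upper < 180, got "
            f"({lower_threshold}, {upper_threshold})"
        )
    angles = np.asarray(trace.angles, dtype=float)
    times = np.asarray(trace.times, dtype=float)
    n = len(angles)
    states = np.empty(n, dtype=object)
    events: List[ScramblingEvent] = []
    if n == 0:
        return events, states

    state = initial_state
    if state is Leaflet.UPPER and angles[0] > upper_threshold:
        warnings.warn(
            f"lipid {trace.lipid_id} (replica {trace.replica}): initial angle "
            f"{angles[0]:.1f} deg contradicts initial state UPPER; state corrected",
            stacklevel=2,
        )
        state = Leaflet.LOWER
    elif state is Leaflet.LOWER and angles[0] < lower_threshold:
        warnings.warn(
            f"lipid {trace.lipid_id} (replica {trace.replica}): initial angle "
            f"{angles[0]:.1f} deg contradicts initial state LOWER; state corrected",
            stacklevel=2,
        )
        state = Leaflet.UPPER

    i = 0
    while i < n:
        if state is Leaflet.UPPER:
            beyond = angles[i:] > upper_threshold
            home_is_low = True
        else:
            beyond = angles[i:] < lower_threshold
            home_is_low = False
        if not beyond.any():
            states[i:] = state
            break
        j = i + int(np.argmax(beyond))
        states[i:j] = state
        # buffer entry: first sample of the contiguous buffer-resident run
        # immediately preceding the crossing
        seg = angles[i:j]
        if home_is_low:
            home = seg < lower_threshold
        else:
            home = seg > upper_threshold
        if home.any():
            entry_idx = i + int(len(seg) - 1 - np.argmax(home[::-1])) + 1
        else:
            entry_idx = i
        if entry_idx >= j:  # instantaneous jump across the whole buffer
            entry_idx = j
        state = state.flipped()
        states[j] = state
        events.append(
            ScramblingEvent(
                lipid_id=trace.lipid_id,
                replica=trace.replica,
                event_time_ns=float(times[j]),
                direction=(
                    Direction.UPPER_TO_LOWER if state is Leaflet.LOWER else Direction.LOWER_TO_UPPER
                ),
                buffer_entry_ns=float(times[entry_idx]),
            )
        )
        i = j + 1
    return events, states


def detect_all(
    traces: Sequence[OrientationTrace],
    assignment,
    lower_threshold: float = DEFAULT_BUFFER_LOW_DEG,
    upper_threshold: float = DEFAULT_BUFFER_HIGH_DEG,
) -> List[ScramblingEvent]:
    """Run :func:`detect_events` over all traces using initial leaflets from
    a :class:`~scramblescan.topology.LeafletAssignment` (or mapping)."""
    events: List[ScramblingEvent] = []
    for trace in traces:
        initial = assignment[trace.lipid_id]
        ev, _ = detect_events(trace, initial, lower_threshold, upper_threshold)
        events.extend(ev)
    return events


def events_to_table(events: Sequence[ScramblingEvent]) -> pd.DataFrame:
    """Deterministically ordered event table (replica, time, lipid_id)."""
    df = pd.DataFrame(
        {
            "replica": [e.replica for e in events],
            "lipid_id": [e.lipid_id for e in events],
            "event_time_ns": [e.event_time_ns for e in events],
            "direction": [e.direction.value for e in events],
            "buffer_entry_ns": [e.buffer_entry_ns for e in events],
        }
    )
    return df.sort_values(["replica", "event_time_ns", "lipid_id"], kind="stable").reset_index(
        drop=True
    )
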