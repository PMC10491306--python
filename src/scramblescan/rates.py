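"""Event-rate statistics and scrambler classification.

Events are pooled per simulated system: the first 2 us of each replicate are
discarded as equilibration, the remainder is tiled with 1 us bins, and the
per-bin event counts (events/us) across replicates form the data points for
boxplot statistics.  With the defaults and two 10 us replicates this yields
16 data points (8 per replicate).  A system is classified as a scrambler
when its mean rate reaches the cut-off of 1 event/us.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .detector import ScramblingEvent
from .errors import AnalysisError

logger = logging.getLogger(__name__)

DEFAULT_EQUILIBRATION_NS = 2000.0
DEFAULT_BIN_WIDTH_NS = 1000.0
DEFAULT_CUTOFF_PER_US = 1.0

SCRAMBLER = "SCRAMBLER"
NON_SCRAMBLER = "NON_SCRAMBLER"


@dataclass(frozen=True)
class BinnedEventCounts:
    """Per-replica event counts in half-open 1 us bins after equilibration."""

    counts: Dict[int, np.ndarray]          # replica -> per-bin counts
    bin_starts: Dict[int, np.ndarray]      # replica -> bin start times (ns)
    equilibration_ns: float = DEFAULT_EQUILIBRATION_NS
    bin_width_ns: float = DEFAULT_BIN_WIDTH_NS

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.counts[r] for r in sorted(self.counts)])

    @property
    def n_points(self) -> int:
        return int(sum(len(c) for c in self.counts.values()))


@dataclass(frozen=True)
class EventRateSummary:
    """Boxplot statistics over pooled per-bin counts plus classification."""

    data_points: np.ndarray
    n_points: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float            # Tukey: lowest point within q1 - 1.5 IQR
    whisker_high: float           # Tukey: highest point within q3 + 1.5 IQR
    whisker_min: float            # plain min/max convention
    whisker_max: float
    classification: str
    cutoff: float = DEFAULT_CUTOFF_PER_US

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "mean": self.mean,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "whisker_min": self.whisker_min,
            "whisker_max": self.whisker_max,
            "classification": self.classification,
            "cutoff": self.cutoff,
        }


def bin_events(
    events: Sequence[ScramblingEvent],
    t_end_ns,
    replicas: Sequence[int] | None = None,
    equilibration_ns: float = DEFAULT_EQUILIBRATION_NS,
    bin_width_ns: float = DEFAULT_BIN_WIDTH_NS,
) -> BinnedEventCounts:
    """Bin post-equilibration events into fixed-width bins per replica.

    Parameters
    ----------
    t_end_ns
        End time of the analyzed trajectory, either a scalar (same for all
        replicas) or a mapping ``replica -> t_end``.
    replicas
        Replica indices that exist (needed so replicas with zero events
        still contribute bins).  Defaults to the keys of ``t_end_ns`` if it
        is a mapping, else to the replicas present in ``events``.

    Events before ``equilibration_ns`` are excluded; bins are half-open
    ``[start, end)``; a trailing partial bin is dropped and logged.
    """
    if replicas is None:
        if isinstance(t_end_ns, Mapping):
            replicas = sorted(t_end_ns)
        else:
            replicas = sorted({e.replica for e in events})
            if not replicas:
                raise AnalysisError(
                    "cannot infer replicas from an empty event list; pass `replicas`"
                )
    t_end = dict(t_end_ns) if isinstance(t_end_ns, Mapping) else {r: float(t_end_ns) for r in replicas}

    counts: Dict[int, np.ndarray] = {}
    starts: Dict[int, np.ndarray] = {}
    for r in replicas:
        n_bins = int(np.floor((t_end[r] - equilibration_ns) / bin_width_ns))
        if n_bins < 1:
            raise AnalysisError(
                f"replica {r}: trajectory of {t_end[r]} ns is too short; at least "
                f"{equilibration_ns + bin_width_ns} ns (equilibration + one bin) required"
            )
        edges = equilibration_ns + bin_width_ns * np.arange(n_bins + 1)
        times = np.array([e.event_time_ns for e in events if e.replica == r])
        post_eq = times[times >= equilibration_ns]
        tail = post_eq[post_eq >= edges[-1]]
        if len(tail):
            logger.info(
                "replica %d: %d event(s) beyond the last complete bin dropped", r, len(tail)
            )
        # half-open [start, end): right edge exclusive
        hist = np.floor((post_eq[post_eq < edges[-1]] - equilibration_ns) / bin_width_ns).astype(int)
        c = np.bincount(hist, minlength=n_bins)
        counts[r] = c.astype(int)
        starts[r] = edges[:-1]
    return BinnedEventCounts(
        counts=counts,
        bin_starts=starts,
        equilibration_ns=equilibration_ns,
        bin_width_ns=bin_width_ns,
    )


def summarize(binned: BinnedEventCounts, cutoff: float = DEFAULT_CUTOFF_PER_US) -> EventRateSummary:
    """Boxplot statistics over the pooled bin counts and classification.

    Quartiles use linear interpolation between order statistics; Tukey
    whiskers extend to the most extreme data point within 1.5 IQR of the
    quartiles; a min/max whisker pair is emitted alongside.  Classification
    is SCRAMBLER iff the mean rate >= ``cutoff`` (events/us).
    """
    data = binned.pooled.astype(float)
    if len(data) == 0:
        raise AnalysisError("no bins to summarize")
    scale = binned.bin_width_ns / 1000.0  # counts per bin -> events/us
    rates = data / scale
    q1, med, q3 = np.percentile(rates, [25, 50, 75], method="linear")
    iqr = q3 - q1
    in_low = rates[rates >= q1 - 1.5 * iqr]
    in_high = rates[rates <= q3 + 1.5 * iqr]
    mean = float(rates.mean())
    return EventRateSummary(
        data_points=rates,
        n_points=len(rates),
        mean=mean,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
        whisker_min=float(rates.min()),
        whisker_max=float(rates.max()),
        classification=SCRAMBLER if mean >= cutoff else NON_SCRAMBLER,
        cutoff=float(cutoff),
    )


def compare_systems(summaries: Mapping[str, EventRateSummary]) -> pd.DataFrame:
    """Rank systems by mean event rate (descending; ties broken by name)."""
    if not summaries:
        raise AnalysisError("no system summaries to compare")
    rows = [
        {
            "system": name,
            "mean_rate_per_us": s.mean,
            "median_rate_per_us": s.median,
            "n_points": s.n_points,
            "classification": s.classification,
        }
        for name, s in summaries.items()
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_rate_per_us", "system"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


def bins_to_table(binned: BinnedEventCounts) -> pd.DataFrame:
    """Raw bin counts as a tidy table (replica, bin_start_ns, bin_end_ns, count)."""
    rows = []
    for r in sorted(binned.counts):
        for start, c in zip(binned.bin_starts[r], binned.counts[r]):
            rows.append(
                {
                    "replica": r,
                    "bin_start_ns": float(start),
                    "bin_end_ns": float(start + binned.bin_width_ns),
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows)
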