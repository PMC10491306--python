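"""Scrambling-pathway localization on the protein surface.

For each counted scrambling event the headgroup positions during the transit
window (the contiguous buffer-resident interval ending at the counted
crossing) are extracted and mapped onto protein residues: a residue scores
one contact for every (event, stride-point) pair whose transiting headgroup
lies within the contact cutoff (default 0.6 nm, a typical coarse-grained
bead-contact distance) of any of the residue's beads.  The pooled point
cloud can be written as a pseudo-atom PDB for molecular viewers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .detector import ScramblingEvent
from .errors import AnalysisError, SelectionError
from .thickness import _xy_min_image_dist2
from .topology import Frame, LipidSelection, SystemTopology

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF_NM = 0.6


@dataclass(frozen=True)
class PathwayMap:
    """Pooled transit point cloud plus per-residue contact statistics."""

    positions: np.ndarray                 # (n_points, 3) nm, pooled over events
    contacts: pd.DataFrame                # residue_id, residue_name, contact_count, normalized_frequency
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM
    per_event_positions: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.positions)


def transit_positions(
    event: ScramblingEvent,
    frames: Iterable[Frame],
    selection: LipidSelection,
    stride_ns: float = 1.0,
) -> np.ndarray:
    """Head-bead coordinates at each stride point of one event's transit.

    The window runs from buffer entry to the completing crossing, inclusive;
    the nearest frame to each stride grid point is used.  Raises
    :class:`AnalysisError` if the supplied frames do not cover the window.
    """
    t0, t1 = event.buffer_entry_ns, event.event_time_ns
    grid = np.arange(t0, t1 + stride_ns / 2, stride_ns)
    head = int(selection.head[event.lipid_id])
    best = {k: (np.inf, None) for k in range(len(grid))}
    for frame in frames:
        if frame.replica != event.replica:
            continue
        for k, tg in enumerate(grid):
            dev = abs(frame.time_ns - tg)
            if dev < best[k][0]:
                best[k] = (dev, frame.positions[head].copy())
    missing = [k for k, (dev, _) in best.items() if dev > stride_ns / 2 + 1e-9]
    if missing:
        raise AnalysisError(
            f"transit window [{t0}, {t1}] ns of lipid {event.lipid_id} is not covered "
            f"by the supplied frames ({len(missing)} of {len(grid)} stride points missing)"
        )
    return np.vstack([best[k][1] for k in range(len(grid))])


def collect_transit_positions(
    events: Sequence[ScramblingEvent],
    frames: Iterable[Frame],
    selection: LipidSelection,
    stride_ns: float = 1.0,
    equilibration_ns: float = 2000.0,
) -> Dict[ScramblingEvent, np.ndarray]:
    """Single-pass extraction of transit positions for many events.

    Only post-equilibration events (crossing time >= ``equilibration_ns``)
    contribute, mirroring the rate statistics.
    """
    kept = [e for e in events if e.event_time_ns >= equilibration_ns]
    windows = {e: [] for e in kept}
    for frame in frames:
        t = frame.time_ns
        for e in kept:
            if e.replica == frame.replica and e.buffer_entry_ns - 1e-9 <= t <= e.event_time_ns + 1e-9:
                windows[e].append(frame.positions[int(selection.head[e.lipid_id])].copy())
    return {e: np.vstack(p) for e, p in windows.items() if p}


def residue_contact_map(
    positions: np.ndarray,
    topology: SystemTopology,
    protein_positions: np.ndarray,
    box: np.ndarray,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    per_event_positions: dict | None = None,
) -> PathwayMap:
    """Count, per protein residue, the transit points within the cutoff.

    ``protein_positions`` are the coordinates (nm) of the atoms in
    ``topology.protein_indices``, typically from a reference frame (use
    :func:`map_pathway` when the protein moves).  An empty position set
    yields an empty map with a warning — no events is a legitimate outcome
    for a non-scrambler — not an error.
    """
    prot = topology.protein_indices
    if len(prot) == 0:
        raise SelectionError("protein group is empty; pathway mapping requires a protein")
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    protein_positions = np.asarray(protein_positions, dtype=float).reshape(-1, 3)
    if len(protein_positions) != len(prot):
        raise AnalysisError(
            f"protein_positions has {len(protein_positions)} rows but the protein "
            f"group has {len(prot)} atoms"
        )

    prot_resids = topology.resids[prot]
    resid_order = prot_resids[np.sort(np.unique(prot_resids, return_index=True)[1])]
    names = {int(r): str(topology.resnames[prot[prot_resids == r][0]]) for r in resid_order}

    counts = {int(r): 0 for r in resid_order}
    if len(positions) == 0:
        warnings.warn("no transit positions: pathway map is empty", stacklevel=2)
    elif contact_cutoff > 0:
        d2 = _xy_min_image_dist2(positions, protein_positions, np.asarray(box, dtype=float))
        within = d2 < contact_cutoff ** 2
        for r in resid_order:
            col = within[:, prot_resids == r]
            counts[int(r)] += int(col.any(axis=1).sum())
    df = _contacts_frame(counts, names, len(positions))
    return PathwayMap(
        positions=positions,
        contacts=df,
        contact_cutoff=contact_cutoff,
        per_event_positions=per_event_positions or {},
    )


def _contacts_frame(counts: dict, names: dict, n_points: int) -> pd.DataFrame:
    total = max(n_points, 1)
    df = pd.DataFrame(
        {
            "residue_id": list(counts.keys()),
            "residue_name": [names[r] for r in counts.keys()],
            "contact_count": list(counts.values()),
            "normalized_frequency": [c / total for c in counts.values()],
        }
    )
    return df.sort_values(
        ["contact_count", "residue_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def map_pathway(
    events: Sequence[ScramblingEvent],
    frames: Iterable[Frame],
    topology: SystemTopology,
    selection: LipidSelection,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    stride_ns: float = 1.0,
    equilibration_ns: float = 2000.0,
) -> PathwayMap:
    """Full pathway analysis in one trajectory pass.

    Extracts transiting headgroup positions for every post-equilibration
    event and accumulates residue contacts against the protein coordinates
    of the same frames.
    """
    prot = topology.protein_indices
    if len(prot) == 0:
        raise SelectionError("protein group is empty; pathway mapping requires a protein")
    kept = [e for e in events if e.event_time_ns >= equilibration_ns]
    if not kept:
        warnings.warn("no post-equilibration scrambling events: pathway map is empty", stacklevel=2)

    prot_resids = topology.resids[prot]
    resid_order = prot_resids[np.sort(np.unique(prot_resids, return_index=True)[1])]
    names = {int(r): str(topology.resnames[prot[prot_resids == r][0]]) for r in resid_order}
    counts = {int(r): 0 for r in resid_order}

    pooled: List[np.ndarray] = []
    per_event: Dict[ScramblingEvent, List[np.ndarray]] = {e: [] for e in kept}
    for frame in frames:
        t = frame.time_ns
        active = [
            e
            for e in kept
            if e.replica == frame.replica
            and e.buffer_entry_ns - 1e-9 <= t <= e.event_time_ns + 1e-9
        ]
        if not active:
            continue
        heads = np.vstack([frame.positions[int(selection.head[e.lipid_id])] for e in active])
        pooled.append(heads)
        for e, h in zip(active, heads):
            per_event[e].append(h)
        if contact_cutoff > 0:
            d2 = _xy_min_image_dist2(heads, frame.positions[prot], frame.box)
            within = d2 < contact_cutoff ** 2
            for r in resid_order:
                col = within[:, prot_resids == r]
                counts[int(r)] += int(col.any(axis=1).sum())

    positions = np.vstack(pooled) if pooled else np.empty((0, 3))
    df = _contacts_frame(counts, names, len(positions))
    return PathwayMap(
        positions=positions,
        contacts=df,
        contact_cutoff=contact_cutoff,
        per_event_positions={e: np.vstack(p) for e, p in per_event.items() if p},
    )


def write_point_cloud_pdb(positions: np.ndarray, path) -> None:
    """Write the pooled transit point cloud as pseudo-atoms (PDB, Angstrom)
    so it can be overlaid on the protein in a molecular viewer."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(positions * 10.0, start=1):
            serial = i % 100000
            fh.write(
                f"HETATM{serial:5d}  O   PTH A{(i - 1) % 9999 + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O\n"
            )
        fh.write("END\n")
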