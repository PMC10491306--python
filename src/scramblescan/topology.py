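"""System topology, lipid selection and leaflet assignment.

Reads a coarse-grained topology (GRO/PDB) plus trajectory files (XTC/TRR/DCD)
through MDAnalysis and exposes them in a uniform nm/ns coordinate model.
Lipids are resolved by residue name plus the names of the headgroup bead and
the two tail-terminal beads (Martini 3 DOPC defaults: NC3, C4A, C4B).

Internally everything is nanometres and nanoseconds (GROMACS-native units);
MDAnalysis' Angstrom/picosecond frames are converted on the fly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import GeometryError, SelectionError, TopologyError

logger = logging.getLogger(__name__)

#: residue names treated as solvent/ions and excluded from the protein group
SOLVENT_RESNAMES = frozenset(
    {"W", "WN", "SOL", "HOH", "TIP3", "ION", "NA", "CL", "NA+", "CL-", "K", "K+", "CA", "MG"}
)

DEFAULT_LIPID_RESNAME = "DOPC"
DEFAULT_HEAD_BEAD = "NC3"
DEFAULT_TAIL_BEADS = ("C4A", "C4B")


class Leaflet(str, Enum):
    UPPER = "UPPER"
    LOWER = "LOWER"

    def flipped(self) -> "Leaflet":
        return Leaflet.LOWER if self is Leaflet.UPPER else Leaflet.UPPER


@dataclass(frozen=True)
class SystemTopology:
    """Static description of the simulated system.

    Parameters
    ----------
    names, resnames, resids
        Per-atom arrays in file order (indices are 0-based and contiguous).
    box
        Box lengths in nm (orthorhombic assumed for the analyses here).
    lipid_resnames
        Residue names classified as membrane lipids; every other non-solvent
        residue is assigned to the protein group.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    box: np.ndarray
    lipid_resnames: tuple = (DEFAULT_LIPID_RESNAME,)

    def __post_init__(self):
        if len(self.names) != len(self.resnames) or len(self.names) != len(self.resids):
            raise TopologyError("per-atom arrays have inconsistent lengths")
        if np.any(np.asarray(self.box, dtype=float) <= 0):
            raise TopologyError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @cached_property
    def lipid_indices(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.resnames, list(self.lipid_resnames)))

    @cached_property
    def protein_indices(self) -> np.ndarray:
        mask = ~np.isin(self.resnames, list(self.lipid_resnames))
        mask &= ~np.isin(self.resnames, list(SOLVENT_RESNAMES))
        return np.flatnonzero(mask)

    @property
    def groups(self) -> dict:
        return {"lipids": self.lipid_indices, "protein": self.protein_indices}


@dataclass(frozen=True)
class Frame:
    """One trajectory frame in nm/ns, tagged with its replica index."""

    time_ns: float
    positions: np.ndarray  # (n_atoms, 3) nm
    box: np.ndarray        # (3,) nm
    replica: int = 0


@dataclass(frozen=True)
class LipidSelection:
    """Resolved per-lipid bead indices.

    ``lipid_ids`` are sequential (0..n-1) and used throughout the pipeline;
    ``resids`` maps back to the topology's residue numbering.
    """

    lipid_ids: np.ndarray
    resids: np.ndarray
    head: np.ndarray        # (n,) atom index of the headgroup bead
    tails: np.ndarray       # (n, 2) atom indices of the tail-terminal beads
    residue_name: str = DEFAULT_LIPID_RESNAME

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)


@dataclass(frozen=True)
class LeafletAssignment:
    leaflets: np.ndarray            # (n,) of Leaflet
    midplane_z: float               # nm
    reference_frame_time: float     # ns
    inconsistent_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __getitem__(self, lipid_id: int) -> Leaflet:
        return self.leaflets[lipid_id]


def _as_paths(paths) -> list:
    if isinstance(paths, (str, Path)):
        return [Path(paths)]
    return [Path(p) for p in paths]


def load_system(
    topology_path,
    trajectory_paths: Sequence = (),
    lipid_resnames: Sequence[str] = (DEFAULT_LIPID_RESNAME,),
):
    """Load a topology and a set of replicate trajectories.

    Returns ``(SystemTopology, frame_iterator)``.  Frames are yielded lazily
    in time order; each replicate trajectory file gets a replica index equal
    to its position in ``trajectory_paths``.  With no trajectories the
    topology's own coordinates are served as a single frame of replica 0.

    Raises
    ------
    TopologyError
        If a file is unreadable or a trajectory's atom count differs from
        the topology's (the message names both counts).
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    trajectory_paths = _as_paths(trajectory_paths)
    if not topology_path.exists():
        raise TopologyError(f"topology file not found: {topology_path}")
    for p in trajectory_paths:
        if not p.exists():
            raise TopologyError(f"trajectory file not found: {p}")
    try:
        u0 = mda.Universe(str(topology_path))
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise TopologyError(f"could not parse topology {topology_path}: {exc}") from exc

    if u0.dimensions is None or not np.all(u0.dimensions[:3] > 0):
        raise TopologyError(f"topology {topology_path} carries no valid box")
    topology = SystemTopology(
        names=u0.atoms.names.astype(str),
        resnames=u0.atoms.resnames.astype(str),
        resids=u0.atoms.resids.astype(int),
        box=u0.dimensions[:3] / 10.0,
        lipid_resnames=tuple(lipid_resnames),
    )
    n_top = topology.n_atoms

    def _frames() -> Iterator[Frame]:
        if not trajectory_paths:
            yield Frame(
                time_ns=0.0,
                positions=u0.atoms.positions / 10.0,
                box=u0.dimensions[:3] / 10.0,
                replica=0,
            )
            return
        for replica, path in enumerate(trajectory_paths):
            n_traj = _trajectory_atom_count(path)
            if n_traj is not None and n_traj != n_top:
                raise TopologyError(
                    f"atom-count mismatch: topology {topology_path} has {n_top} atoms "
                    f"but trajectory {path} has {n_traj}"
                )
            try:
                u = mda.Universe(str(topology_path), str(path))
            except Exception as exc:  # noqa: BLE001
                raise TopologyError(
                    f"could not read trajectory {path} with topology of {n_top} atoms: {exc}"
                ) from exc
            prev_t = -np.inf
            for ts in u.trajectory:
                t = float(ts.time) / 1000.0  # ps -> ns
                if t <= prev_t:
                    raise TopologyError(
                        f"non-increasing frame times in {path}: {t} ns after {prev_t} ns"
                    )
                prev_t = t
                yield Frame(
                    time_ns=t,
                    positions=ts.positions / 10.0,
                    box=ts.dimensions[:3] / 10.0,
                    replica=replica,
                )

    return topology, _frames()


def _trajectory_atom_count(path: Path):
    """Best-effort read of a trajectory file's own atom count (for clear
    mismatch messages); returns None if the format does not expose it."""
    try:
        from MDAnalysis.coordinates.core import get_reader_for

        reader_cls = get_reader_for(str(path))
        with reader_cls(str(path)) as reader:
            return int(reader.n_atoms)
    except Exception:  # noqa: BLE001 - diagnostic only
        return None


def select_lipids(
    topology: SystemTopology,
    residue_name: str = DEFAULT_LIPID_RESNAME,
    head_bead_name: str = DEFAULT_HEAD_BEAD,
    tail_bead_names: Sequence[str] = DEFAULT_TAIL_BEADS,
) -> LipidSelection:
    """Resolve one (head, tail, tail) bead triple per lipid residue.

    Raises :class:`SelectionError` if no residue matches ``residue_name`` or
    if a matching residue lacks one of the named beads.
    """
    tail_bead_names = tuple(tail_bead_names)
    if len(tail_bead_names) != 2:
        raise SelectionError(f"exactly two tail bead names required, got {tail_bead_names}")
    mask = topology.resnames == residue_name
    if not mask.any():
        raise SelectionError(f"no residue named {residue_name!r} in topology")
    atom_idx = np.flatnonzero(mask)
    resids = topology.resids[atom_idx]
    names = topology.names[atom_idx]

    heads, tails, out_resids = [], [], []
    # preserve file order of residues
    _, first_pos = np.unique(resids, return_index=True)
    for resid in resids[np.sort(first_pos)]:
        sub = atom_idx[resids == resid]
        sub_names = names[resids == resid]
        entry = []
        for bead in (head_bead_name, *tail_bead_names):
            hits = sub[sub_names == bead]
            if len(hits) != 1:
                raise SelectionError(
                    f"residue {residue_name} {int(resid)}: expected exactly one bead "
                    f"named {bead!r}, found {len(hits)}"
                )
            entry.append(int(hits[0]))
        heads.append(entry[0])
        tails.append(entry[1:])
        out_resids.append(int(resid))

    n = len(heads)
    return LipidSelection(
        lipid_ids=np.arange(n),
        resids=np.asarray(out_resids),
        head=np.asarray(heads),
        tails=np.asarray(tails),
        residue_name=residue_name,
    )


def assign_initial_leaflets(frame: Frame, selection: LipidSelection) -> LeafletAssignment:
    """Assign each lipid to the upper or lower leaflet at a reference frame.

    The bilayer midplane is the mean z of all tail-terminal beads; a lipid is
    UPPER iff its head bead sits above the midplane.  The assignment is
    cross-checked against the lipid orientation angle (UPPER lipids point
    towards +z, i.e. angle < 90 deg up to noise); inconsistent lipids are
    flagged, not reassigned.
    """
    from .detector import lipid_angles

    head_z = frame.positions[selection.head, 2]
    tail_z = frame.positions[selection.tails.ravel(), 2]
    midplane = float(tail_z.mean())

    box_z = float(frame.box[2])
    if np.any(np.abs(head_z - midplane) > box_z / 2):
        raise GeometryError(
            "bilayer appears wrapped across the z boundary "
            "(head bead further than half a box from the midplane); re-image the "
            "trajectory so the bilayer is whole along z before analysis"
        )

    upper = head_z > midplane
    if upper.all() or (~upper).all():
        raise GeometryError(
            "degenerate bilayer: all lipid heads on one side of the midplane "
            f"(z = {midplane:.3f} nm); is this a monolayer?"
        )
    leaflets = np.empty(len(upper), dtype=object)
    leaflets[upper] = Leaflet.UPPER
    leaflets[~upper] = Leaflet.LOWER

    angles = lipid_angles(frame.positions, selection)
    inconsistent = np.flatnonzero((upper & (angles > 90.0)) | (~upper & (angles < 90.0)))
    if len(inconsistent):
        logger.warning(
            "%d lipid(s) have an orientation angle inconsistent with their "
            "leaflet assignment (likely mid-flip at the reference frame): %s",
            len(inconsistent),
            inconsistent[:10],
        )
    return LeafletAssignment(
        leaflets=leaflets,
        midplane_z=midplane,
        reference_frame_time=frame.time_ns,
        inconsistent_ids=inconsistent,
    )
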