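"""Ground-truth-labeled synthetic coarse-grained bilayer trajectories.

This is a kinematic fixture generator, not an MD engine: it emulates the
statistical structure of a coarse-grained bilayer trajectory — two leaflets
of pseudo-lipids whose tail-to-head orientation angles sit near 0 deg
(upper) or 180 deg (lower) with Gaussian within-leaflet noise, Poisson
flip-flop events that sweep the angle linearly through the buffer band over
an exponential dwell, an optional cylindrical pseudo-protein, an optional
imposed local thinning, and an optional pore pathway that guides flipping
headgroups along a vertical line next to known residues.  Every trajectory
carries a ground-truth ledger (initial leaflets, true flips, thinned lipids,
pore-lining residues) so detector, rate, thickness and pathway analyses can
be validated end to end without running molecular dynamics.

Each pseudo-lipid has 10 beads (NC3, PO4, C1A..C4A, C1B..C4B).  The eight
hydrophobic beads are placed uniformly along the lipid director between the
bilayer midplane and the tail extent, so the hydrophobic z-density is a
clean slab whose FWHM is an analytically known thickness; NC3 and PO4 sit
at fixed distances beyond it.  All randomness derives from one root seed
through named substreams, so output is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .detector import Direction, OrientationTrace
from .errors import SpecError
from .topology import Frame, Leaflet, SystemTopology

logger = logging.getLogger(__name__)

# lipid internal geometry (nm along the director, measured from the midplane anchor)
S_TAIL = 1.8    # extent of the hydrophobic bead region
S_PO4 = 2.1     # phosphate bead
S_HEAD = 2.5    # headgroup (NC3) bead
PERP_OFFSET = 0.05  # lateral split of the two tail-terminal beads

BEAD_NAMES = ("NC3", "PO4", "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B")
HYDRO_COLS = (2, 3, 4, 5, 6, 7, 8, 9)   # all but NC3/PO4
C4A_COL, C4B_COL = 5, 9

BUFFER_LOW = 55.0
BUFFER_HIGH = 125.0


@dataclass(frozen=True)
class ProteinSpec:
    """Cylindrical pseudo-protein: one backbone bead per residue arranged in
    vertical columns on the cylinder surface.  With ``pore=True`` flipping
    headgroups are guided along a vertical line facing column 0, whose
    residues are recorded as the pore lining."""

    radius_nm: float = 1.0
    height_nm: float = 5.0
    n_residues: int = 40
    pore: bool = False
    n_columns: int = 8


@dataclass(frozen=True)
class SyntheticBilayerSpec:
    n_lipids_per_leaflet: int = 64
    area_per_lipid_nm2: float = 0.64
    box_z_nm: float = 10.0
    duration_ns: float = 10000.0
    frame_interval_ns: float = 1.0
    n_replicas: int = 2
    flip_rate_per_us: float = 0.0          # expected events per us per system
    transit_dwell_ns: float = 10.0         # mean buffer-resident time of a flip
    angular_noise_deg: float = 12.0        # within-leaflet angle fluctuation (1 sigma)
    base_angle_deg: float = 10.0           # mean upper-leaflet angle (lower: 180 - base)
    positional_noise_nm: float = 0.02      # isotropic bead jitter
    protein: Optional[ProteinSpec] = None
    local_thinning_nm: float = 0.0         # imposed hydrophobic thinning near protein
    thinning_radius_nm: float = 2.0        # thinned annulus width beyond protein radius
    lipid_resname: str = "DOPC"
    seed: int = 0

    def validate(self) -> None:
        if self.flip_rate_per_us < 0:
            raise SpecError("flip_rate_per_us must be >= 0")
        if self.transit_dwell_ns < self.frame_interval_ns:
            raise SpecError("transit_dwell_ns must be >= frame_interval_ns")
        if not (0 < self.base_angle_deg < BUFFER_LOW):
            raise SpecError("base_angle_deg must lie between 0 and the buffer edge")
        if self.angular_noise_deg < 0 or self.positional_noise_nm < 0:
            raise SpecError("noise amplitudes must be non-negative")
        if self.local_thinning_nm < 0:
            raise SpecError("local_thinning_nm must be >= 0")
        if self.local_thinning_nm > 0 and self.protein is None:
            raise SpecError("local thinning requires an embedded protein")
        if self.n_lipids_per_leaflet < 2:
            raise SpecError("need at least 2 lipids per leaflet")
        if self.duration_ns < self.frame_interval_ns:
            raise SpecError("duration must cover at least one frame interval")


@dataclass(frozen=True)
class TrueFlip:
    replica: int
    lipid_id: int
    start_ns: float        # buffer entry time of the sweep
    completion_ns: float   # time the far threshold is crossed (the counted event)
    direction: Direction


@dataclass
class GroundTruthLedger:
    initial_leaflets: np.ndarray              # (n_lipids,) of Leaflet
    events: List[TrueFlip]
    thinned_lipid_ids: np.ndarray
    imposed_thinning_nm: float
    pore_lining_resids: np.ndarray            # topology resids of the lining column
    pathway_line_xy: Optional[Tuple[float, float]]
    n_lipids: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_lipids": self.n_lipids,
                "initial_leaflets": [lf.value for lf in self.initial_leaflets],
                "events": [
                    {
                        "replica": e.replica,
                        "lipid_id": e.lipid_id,
                        "start_ns": e.start_ns,
                        "completion_ns": e.completion_ns,
                        "direction": e.direction.value,
                    }
                    for e in self.events
                ],
                "thinned_lipid_ids": self.thinned_lipid_ids.tolist(),
                "imposed_thinning_nm": self.imposed_thinning_nm,
                "pore_lining_resids": self.pore_lining_resids.tolist(),
                "pathway_line_xy": self.pathway_line_xy,
            },
            indent=2,
        )


@dataclass(frozen=True)
class _Sweep:
    lipid_id: int
    t0: float
    t1: float
    theta_from: float
    theta_to: float


class SyntheticSystem:
    """A realized synthetic bilayer: topology, ground truth, and on-demand
    angle traces / coordinate frames per replica."""

    def __init__(self, spec: SyntheticBilayerSpec):
        spec.validate()
        self.spec = spec
        self._geometry = _build_geometry(spec)
        root = np.random.SeedSequence(spec.seed)
        ev_root, noise_root, coord_root = root.spawn(3)
        self._noise_children = noise_root.spawn(spec.n_replicas)
        self._coord_children = coord_root.spawn(spec.n_replicas)

        n = self._geometry["n_lipids"]
        leaflet0 = np.array(
            [Leaflet.UPPER] * self._geometry["n_upper"]
            + [Leaflet.LOWER] * (n - self._geometry["n_upper"]),
            dtype=object,
        )
        self.sweeps: Dict[int, List[_Sweep]] = {}
        events: List[TrueFlip] = []
        for r, child in enumerate(ev_root.spawn(spec.n_replicas)):
            sw, ev = _draw_flips(spec, np.random.default_rng(child), leaflet0, r, n)
            self.sweeps[r] = sw
            events.extend(ev)

        self.ledger = GroundTruthLedger(
            initial_leaflets=leaflet0,
            events=events,
            thinned_lipid_ids=self._geometry["thinned_ids"],
            imposed_thinning_nm=spec.local_thinning_nm,
            pore_lining_resids=self._geometry["lining_resids"],
            pathway_line_xy=self._geometry["line_xy"],
            n_lipids=n,
        )
        self.topology = self._geometry["topology"]
        self._angle_cache: Dict[int, np.ndarray] = {}

    # ---- angles -----------------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        spec = self.spec
        n_t = int(round(spec.duration_ns / spec.frame_interval_ns)) + 1
        return np.arange(n_t) * spec.frame_interval_ns

    def angles(self, replica: int) -> np.ndarray:
        """(n_lipids, n_frames) orientation angles in degrees."""
        if replica not in self._angle_cache:
            self._angle_cache[replica] = _build_angles(
                self.spec,
                np.random.default_rng(self._noise_children[replica]),
                self.ledger.initial_leaflets,
                self.sweeps[replica],
                self.times,
            )
        return self._angle_cache[replica]

    def traces(self) -> List[OrientationTrace]:
        out = []
        times = self.times
        for r in range(self.spec.n_replicas):
            ang = self.angles(r)
            for lid in range(self.ledger.n_lipids):
                out.append(
                    OrientationTrace(
                        lipid_id=lid, replica=r, times=times, angles=ang[lid]
                    )
                )
        return out

    # ---- coordinates ------------------------------------------------------

    def frames(self, replica: int | None = None) -> Iterator[Frame]:
        """Lazily generate coordinate frames (all replicas, or one)."""
        replicas = range(self.spec.n_replicas) if replica is None else [replica]
        for r in replicas:
            rng = np.random.default_rng(self._coord_children[r])
            ang = self.angles(r)
            yield from _frame_stream(self.spec, self._geometry, ang, self.times, self.sweeps[r], r, rng)


def simulate(spec: SyntheticBilayerSpec) -> SyntheticSystem:
    """Realize a synthetic bilayer system (deterministic in ``spec.seed``)."""
    return SyntheticSystem(spec)


def simulate_traces(spec: SyntheticBilayerSpec):
    """Fast path: orientation traces plus ground truth, no coordinates.

    Returns ``(traces, ledger)``.  The traces are exactly the angles the
    coordinate pipeline would reproduce, so detector-level studies can skip
    coordinate realization entirely.
    """
    system = SyntheticSystem(spec)
    return system.traces(), system.ledger


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------


def _build_geometry(spec: SyntheticBilayerSpec) -> dict:
    a = float(np.sqrt(spec.area_per_lipid_nm2))
    m = int(np.ceil(np.sqrt(spec.n_lipids_per_leaflet)))
    box_xy = m * a
    sites = []
    for i in range(m):
        for j in range(m):
            if len(sites) < spec.n_lipids_per_leaflet:
                sites.append(((i + 0.5) * a, (j + 0.5) * a))
    sites = np.asarray(sites)

    center = np.array([box_xy / 2, box_xy / 2])
    if spec.protein is not None:
        keep = np.linalg.norm(sites - center, axis=1) > spec.protein.radius_nm + 0.2
        sites = sites[keep]
    n_upper = len(sites)
    anchors = np.vstack([sites, sites])          # same lateral sites, two leaflets
    n_lipids = 2 * n_upper

    radial = np.linalg.norm(anchors - center, axis=1)
    if spec.local_thinning_nm > 0:
        thin_r = spec.protein.radius_nm + spec.thinning_radius_nm
        thinned = np.flatnonzero(radial <= thin_r)
    else:
        thinned = np.array([], dtype=int)
    s_tail = np.full(n_lipids, S_TAIL)
    if len(thinned):
        s_tail[thinned] = S_TAIL - spec.local_thinning_nm / (
            2.0 * np.cos(np.radians(spec.base_angle_deg))
        )

    # topology arrays: lipids (10 beads each) then protein (1 bead/residue)
    names = list(BEAD_NAMES) * n_lipids
    resnames = [spec.lipid_resname] * (10 * n_lipids)
    resids = np.repeat(np.arange(1, n_lipids + 1), 10).tolist()

    prot_pos = np.empty((0, 3))
    lining_resids = np.array([], dtype=int)
    line_xy = None
    if spec.protein is not None:
        p = spec.protein
        n_cols = min(p.n_columns, p.n_residues)
        n_rows = int(np.ceil(p.n_residues / n_cols))
        coords = []
        lining = []
        for i in range(p.n_residues):
            col, row = i % n_cols, i // n_cols
            phi = 2 * np.pi * col / n_cols
            z = (
                spec.box_z_nm / 2
                if n_rows == 1
                else spec.box_z_nm / 2 - p.height_nm / 2 + p.height_nm * row / (n_rows - 1)
            )
            coords.append(
                [center[0] + p.radius_nm * np.cos(phi), center[1] + p.radius_nm * np.sin(phi), z]
            )
            resid = n_lipids + 1 + i
            names.append("BB")
            resnames.append("ALA")
            resids.append(resid)
            if col == 0:
                lining.append(resid)
        prot_pos = np.asarray(coords)
        lining_resids = np.asarray(lining, dtype=int)
        if p.pore:
            line_xy = (float(center[0] + p.radius_nm + 0.4), float(center[1]))

    box = np.array([box_xy, box_xy, spec.box_z_nm])
    topology = SystemTopology(
        names=np.asarray(names),
        resnames=np.asarray(resnames),
        resids=np.asarray(resids, dtype=int),
        box=box,
        lipid_resnames=(spec.lipid_resname,),
    )
    return {
        "anchors": anchors,
        "n_lipids": n_lipids,
        "n_upper": n_upper,
        "s_tail": s_tail,
        "thinned_ids": thinned,
        "protein_positions": prot_pos,
        "lining_resids": lining_resids,
        "line_xy": line_xy,
        "box": box,
        "topology": topology,
    }


def _draw_flips(
    spec: SyntheticBilayerSpec,
    rng: np.random.Generator,
    leaflet0: np.ndarray,
    replica: int,
    n_lipids: int,
) -> Tuple[List[_Sweep], List[TrueFlip]]:
    """Poisson flip marks (the far-threshold crossing times) with exponential
    buffer dwell, assigned to lipids that are not already mid-transit."""
    base = spec.base_angle_deg
    span = 180.0 - 2 * base
    frac_entry = (BUFFER_LOW - base) / span
    frac_cross = (BUFFER_HIGH - base) / span
    n_ev = rng.poisson(spec.flip_rate_per_us * spec.duration_ns / 1000.0)
    marks = np.sort(rng.uniform(0.0, spec.duration_ns, n_ev))

    current = leaflet0.copy()
    busy_until = np.full(n_lipids, -np.inf)
    sweeps: List[_Sweep] = []
    events: List[TrueFlip] = []
    for t in marks:
        d_buf = max(rng.exponential(spec.transit_dwell_ns), spec.frame_interval_ns)
        full = d_buf * span / (BUFFER_HIGH - BUFFER_LOW)
        t0 = t - frac_cross * full
        t1 = t0 + full
        lid = None
        for _ in range(200):
            cand = int(rng.integers(n_lipids))
            if busy_until[cand] < t0:
                lid = cand
                break
        if lid is None:  # all lipids mid-transit; drop the mark
            logger.warning("replica %d: dropped a flip mark at %.1f ns (no free lipid)", replica, t)
            continue
        if current[lid] is Leaflet.UPPER:
            theta_from, theta_to = base, 180.0 - base
            direction = Direction.UPPER_TO_LOWER
        else:
            theta_from, theta_to = 180.0 - base, base
            direction = Direction.LOWER_TO_UPPER
        sweeps.append(_Sweep(lid, t0, t1, theta_from, theta_to))
        events.append(
            TrueFlip(
                replica=replica,
                lipid_id=lid,
                start_ns=max(t0 + frac_entry * full, 0.0),
                completion_ns=float(t),
                direction=direction,
            )
        )
        busy_until[lid] = t1
        current[lid] = current[lid].flipped()
    return sweeps, events


def _build_angles(
    spec: SyntheticBilayerSpec,
    rng: np.random.Generator,
    leaflet0: np.ndarray,
    sweeps: List[_Sweep],
    times: np.ndarray,
) -> np.ndarray:
    n = len(leaflet0)
    n_t = len(times)
    sigma = spec.angular_noise_deg
    if sigma > 0:
        # within-leaflet wobble, truncated at 3 sigma: noise alone must never
        # constitute a leaflet crossing, so the flip ledger stays exact
        ang = sigma * np.clip(rng.standard_normal((n, n_t)), -3.0, 3.0)
    else:
        ang = np.zeros((n, n_t))

    base_upper = spec.base_angle_deg
    by_lipid: Dict[int, List[_Sweep]] = {}
    for sw in sweeps:
        by_lipid.setdefault(sw.lipid_id, []).append(sw)

    for lid in range(n):
        b = base_upper if leaflet0[lid] is Leaflet.UPPER else 180.0 - base_upper
        row = np.full(n_t, b)
        for sw in sorted(by_lipid.get(lid, []), key=lambda s: s.t0):
            b = 180.0 - b
            row[times > sw.t1] = b
        ang[lid] += row

    # fold into [0, 180] (mirror at both poles)
    ang = np.abs(ang)
    ang = np.where(ang > 180.0, 360.0 - ang, ang)
    ang = np.clip(ang, 0.0, 180.0)

    # deterministic linear sweeps overwrite the noise during transit
    for sw in sweeps:
        idx = np.flatnonzero((times >= sw.t0) & (times <= sw.t1))
        if len(idx) == 0:
            continue
        frac = (times[idx] - sw.t0) / (sw.t1 - sw.t0)
        ang[sw.lipid_id, idx] = sw.theta_from + frac * (sw.theta_to - sw.theta_from)
    return ang


def _frame_stream(
    spec: SyntheticBilayerSpec,
    geo: dict,
    ang: np.ndarray,
    times: np.ndarray,
    sweeps: List[_Sweep],
    replica: int,
    rng: np.random.Generator,
) -> Iterator[Frame]:
    n = geo["n_lipids"]
    anchors = geo["anchors"]
    s_tail = geo["s_tail"]
    prot = geo["protein_positions"]
    box = geo["box"]
    z_mid = spec.box_z_nm / 2.0
    phi = rng.uniform(0.0, 2 * np.pi, n)  # fixed azimuth per lipid
    guided = spec.protein is not None and spec.protein.pore and geo["line_xy"] is not None
    line_xy = np.asarray(geo["line_xy"]) if guided else None

    # per-lipid sweep intervals for pathway guidance
    sweep_bounds = [(sw.lipid_id, sw.t0, sw.t1) for sw in sweeps] if guided else []

    s_cols = np.empty((n, 10))
    s_cols[:, 0] = S_HEAD
    s_cols[:, 1] = S_PO4

    for k, t in enumerate(times):
        theta = np.radians(ang[:, k])
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        u = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
        # lower-leaflet directors have cos(theta) < 0, pointing heads down

        axy = anchors.copy()
        if guided:
            for lid, t0, t1 in sweep_bounds:
                if t0 <= t <= t1:
                    # place the headgroup exactly on the pathway line
                    axy[lid] = line_xy - S_HEAD * sin_t[lid] * np.array(
                        [np.cos(phi[lid]), np.sin(phi[lid])]
                    )

        s = s_cols.copy()
        s[:, HYDRO_COLS] = rng.uniform(0.0, 1.0, (n, len(HYDRO_COLS))) * s_tail[:, None]
        pos = np.empty((n, 10, 3))
        pos[:, :, 0] = axy[:, 0, None] + s * u[:, None, 0]
        pos[:, :, 1] = axy[:, 1, None] + s * u[:, None, 1]
        pos[:, :, 2] = z_mid + s * u[:, None, 2]
        # split the two tail-terminal beads laterally (theta-direction unit vector)
        e_theta = np.stack([cos_t * np.cos(phi), cos_t * np.sin(phi), -sin_t], axis=1)
        pos[:, C4A_COL, :] += PERP_OFFSET * e_theta
        pos[:, C4B_COL, :] -= PERP_OFFSET * e_theta

        coords = pos.reshape(-1, 3)
        if len(prot):
            coords = np.vstack([coords, prot])
        if spec.positional_noise_nm > 0:
            coords = coords + rng.normal(0.0, spec.positional_noise_nm, coords.shape)
        yield Frame(time_ns=float(t), positions=coords, box=box.copy(), replica=replica)


# --------------------------------------------------------------------------
# standard-format output
# --------------------------------------------------------------------------


def write_system(system: SyntheticSystem, outdir) -> dict:
    """Write GRO topology, one XTC per replica, and the ground-truth ledger.

    Returns a dict with keys ``topology``, ``trajectories`` (list, replica
    order) and ``ledger``.  Files are readable by mainstream MD analysis
    software and by :func:`scramblescan.topology.load_system`.
    """
    import MDAnalysis as mda

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topo = system.topology
    n_atoms = topo.n_atoms
    resids = topo.resids
    # compress residue index map for MDAnalysis Universe construction
    uniq, res_index = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(uniq),
        atom_resindex=res_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", topo.names.tolist())
    first_names = [str(topo.resnames[resids == r][0]) for r in uniq]
    u.add_TopologyAttr("resnames", first_names)
    u.add_TopologyAttr("resids", uniq.tolist())
    dims = [topo.box[0] * 10, topo.box[1] * 10, topo.box[2] * 10, 90.0, 90.0, 90.0]

    gro_path = outdir / "system.gro"
    first = next(system.frames(0))
    u.atoms.positions = first.positions * 10.0
    u.dimensions = dims
    u.atoms.write(str(gro_path))

    traj_paths = []
    for r in range(system.spec.n_replicas):
        xtc_path = outdir / f"replica{r}.xtc"
        with mda.coordinates.XTC.XTCWriter(str(xtc_path), n_atoms=n_atoms) as writer:
            for frame in system.frames(r):
                u.atoms.positions = frame.positions * 10.0
                u.dimensions = dims
                u.trajectory.ts.time = frame.time_ns * 1000.0
                u.trajectory.ts.frame = int(round(frame.time_ns / system.spec.frame_interval_ns))
                writer.write(u.atoms)
        traj_paths.append(xtc_path)

    ledger_path = outdir / "ground_truth.json"
    ledger_path.write_text(system.ledger.to_json())
    return {"topology": gro_path, "trajectories": traj_paths, "ledger": ledger_path}
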