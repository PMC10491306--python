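"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import scramblescan as ss


# ---------------------------------------------------------------------------
# independent brute-force oracle for the two-threshold state machine
# ---------------------------------------------------------------------------


def brute_force_events(angles, initial_state: str, lo: float = 55.0, hi: float = 125.0):
    """Naive sample-by-sample hysteresis counter, independent of the
    implementation: returns a list of (sample_index, direction_str)."""
    state = initial_state
    angles = list(angles)
    if not angles:
        return []
    if state == "UPPER" and angles[0] > hi:
        state = "LOWER"  # initialization artifact: corrected, not counted
    elif state == "LOWER" and angles[0] < lo:
        state = "UPPER"
    events = []
    for i, a in enumerate(angles):
        if state == "UPPER" and a > hi:
            events.append((i, "UPPER->LOWER"))
            state = "LOWER"
        elif state == "LOWER" and a < lo:
            events.append((i, "LOWER->UPPER"))
            state = "UPPER"
    return events


def make_trace(angles, lipid_id=0, replica=0, stride=1.0):
    angles = np.asarray(angles, dtype=float)
    return ss.OrientationTrace(
        lipid_id=lipid_id,
        replica=replica,
        times=np.arange(len(angles)) * stride,
        angles=angles,
    )


# ---------------------------------------------------------------------------
# tiny hand-written GRO topologies
# ---------------------------------------------------------------------------


def write_gro(path, atoms, box=(10.0, 10.0, 10.0), title="test system"):
    """atoms: sequence of (resid, resname, atomname, x, y, z) in nm."""
    lines = [title, f"{len(atoms):5d}"]
    for i, (resid, resname, name, x, y, z) in enumerate(atoms, start=1):
        lines.append(f"{resid:5d}{resname:<5s}{name:>5s}{i:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def dopc_residue(resid, x, y, z_head, z_tail):
    """A minimal 4-bead DOPC pseudo-lipid (NC3/PO4/C4A/C4B)."""
    zm = z_tail + 0.8 * (z_head - z_tail)
    return [
        (resid, "DOPC", "NC3", x, y, z_head),
        (resid, "DOPC", "PO4", x, y, zm),
        (resid, "DOPC", "C4A", x - 0.05, y, z_tail),
        (resid, "DOPC", "C4B", x + 0.05, y, z_tail),
    ]


@pytest.fixture
def bilayer_gro(tmp_path):
    """8-lipid symmetric bilayer GRO (4 upper, 4 lower) around z = 5 nm."""
    atoms = []
    resid = 1
    for i in range(4):
        atoms += dopc_residue(resid, 1.0 + 2.0 * i, 2.0, z_head=7.0, z_tail=5.2)
        resid += 1
    for i in range(4):
        atoms += dopc_residue(resid, 1.0 + 2.0 * i, 2.0, z_head=3.0, z_tail=4.8)
        resid += 1
    return write_gro(tmp_path / "bilayer.gro", atoms)


# ---------------------------------------------------------------------------
# synthetic systems reused across modules
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_scrambler():
    """16+16 lipids, 2 replicas x 2.5 us, high flip rate: traces + ledger."""
    spec = ss.SyntheticBilayerSpec(
        n_lipids_per_leaflet=16,
        duration_ns=2500.0,
        n_replicas=2,
        flip_rate_per_us=20.0,
        seed=11,
    )
    traces, ledger = ss.simulate_traces(spec)
    return spec, traces, ledger


@pytest.fixture(scope="session")
def pore_system():
    """Pore-protein system with guided flips, coordinates materialized."""
    spec = ss.SyntheticBilayerSpec(
        n_lipids_per_leaflet=49,
        duration_ns=3000.0,
        n_replicas=1,
        flip_rate_per_us=10.0,
        protein=ss.ProteinSpec(pore=True),
        seed=12,
    )
    system = ss.simulate(spec)
    frames = list(system.frames(0))
    return system, frames
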