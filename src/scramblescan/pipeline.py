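"""Run configuration and end-to-end analysis pipelines.

The defaults reproduce the analysis protocol exactly: orientation angles
sampled every 1 ns, buffer band 55-125 deg, 2 us equilibration discard,
1 us rate bins, scrambler cut-off 1 event/us, 1.0 nm protein proximity for
thickness, density sampled every 5 ns.  Every run writes a manifest (config
echo, package version, input checksums) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .detector import build_traces, detect_all, events_to_table
from .errors import ScrambleScanError
from .pathway import map_pathway, write_point_cloud_pdb
from .rates import bin_events, bins_to_table, summarize
from .thickness import bulk_thickness, membrane_thinning
from .topology import assign_initial_leaflets, load_system, select_lipids

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, YAML-serializable configuration for all pipeline stages."""

    topology: str = ""
    trajectories: List[str] = field(default_factory=list)
    output_dir: str = "scramblescan_out"

    lipid_residue: str = "DOPC"
    lipid_head_bead: str = "NC3"
    lipid_tail_beads: Tuple[str, str] = ("C4A", "C4B")

    detector_stride_ns: float = 1.0
    detector_buffer_low_deg: float = 55.0
    detector_buffer_high_deg: float = 125.0
    angle_method: str = "vector-mean"

    equilibration_ns: float = 2000.0
    bin_width_ns: float = 1000.0
    cutoff_per_us: float = 1.0

    thickness_cutoff_nm: float = 1.0
    thickness_stride_ns: float = 5.0
    thickness_exclude_beads: Tuple[str, ...] = ("NC3", "PO4")
    thickness_bin_nm: float = 0.1

    pathway_contact_cutoff_nm: float = 0.6

    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ScrambleScanError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lipid_tail_beads", "thickness_exclude_beads"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lipid_tail_beads"] = list(self.lipid_tail_beads)
        d["thickness_exclude_beads"] = list(self.thickness_exclude_beads)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, stage: str) -> None:
    manifest = {
        "stage": stage,
        "scramblescan_version": __version__,
        "config": config.to_dict(),
        "input_checksums": {
            str(p): _sha256(p)
            for p in [config.topology, *config.trajectories]
            if p and Path(p).exists()
        },
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _load(config: RunConfig):
    topology, frames = load_system(
        config.topology, config.trajectories, lipid_resnames=(config.lipid_residue,)
    )
    selection = select_lipids(
        topology,
        residue_name=config.lipid_residue,
        head_bead_name=config.lipid_head_bead,
        tail_bead_names=config.lipid_tail_beads,
    )
    return topology, frames, selection


def run_scrambling(config: RunConfig) -> dict:
    """Event detection, rate binning and classification.

    Writes ``events.tsv``, ``bins.tsv``, ``summary.json`` and a manifest to
    the output directory; returns a dict with the summary and tables.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    topology, frames, selection = _load(config)
    logger.info("selected %d %s lipids", selection.n_lipids, config.lipid_residue)

    frames = iter(frames)
    first = next(frames)
    assignment = assign_initial_leaflets(first, selection)

    def _chain():
        yield first
        yield from frames

    traces = build_traces(
        _chain(), selection, stride_ns=config.detector_stride_ns, method=config.angle_method
    )
    replicas = sorted({tr.replica for tr in traces})
    t_end = {r: max(tr.times[-1] for tr in traces if tr.replica == r) for r in replicas}
    logger.info("built %d traces over replicas %s", len(traces), replicas)

    events = detect_all(
        traces,
        assignment,
        lower_threshold=config.detector_buffer_low_deg,
        upper_threshold=config.detector_buffer_high_deg,
    )
    logger.info("detected %d scrambling events", len(events))

    binned = bin_events(
        events,
        t_end,
        replicas=replicas,
        equilibration_ns=config.equilibration_ns,
        bin_width_ns=config.bin_width_ns,
    )
    summary = summarize(binned, cutoff=config.cutoff_per_us)
    logger.info(
        "%d data points, mean %.3f events/us -> %s",
        summary.n_points,
        summary.mean,
        summary.classification,
    )

    events_to_table(events).to_csv(outdir / "events.tsv", sep="\t", index=False)
    bins_to_table(binned).to_csv(outdir / "bins.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    _write_manifest(config, outdir, "scramble")
    return {
        "summary": summary,
        "events": events,
        "binned": binned,
        "assignment": assignment,
        "t_end": t_end,
    }


def run_thickness(config: RunConfig, bulk_only: bool = False) -> dict:
    """Protein-proximal vs bulk hydrophobic thickness (or bulk only)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    topology, frames, selection = _load(config)

    if bulk_only or len(topology.protein_indices) == 0:
        thickness, profile = bulk_thickness(
            frames,
            topology,
            selection,
            exclude_beads=config.thickness_exclude_beads,
            stride_ns=config.thickness_stride_ns,
            equilibration_ns=config.equilibration_ns,
            bin_width_nm=config.thickness_bin_nm,
        )
        report = {"bulk_nm": thickness, "method": "FWHM of hydrophobic z-density"}
        _write_profile(profile, outdir / "profile_bulk.tsv")
        result = None
    else:
        result, local_profile, bulk_profile = membrane_thinning(
            frames,
            topology,
            selection,
            cutoff=config.thickness_cutoff_nm,
            exclude_beads=config.thickness_exclude_beads,
            stride_ns=config.thickness_stride_ns,
            equilibration_ns=config.equilibration_ns,
            bin_width_nm=config.thickness_bin_nm,
        )
        report = dict(result.to_dict(), method="FWHM of hydrophobic z-density")
        _write_profile(local_profile, outdir / "profile_local.tsv")
        _write_profile(bulk_profile, outdir / "profile_bulk.tsv")
    (outdir / "thickness.json").write_text(json.dumps(report, indent=2))
    _write_manifest(config, outdir, "thickness")
    return {"report": report, "result": result}


def _write_profile(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("z_nm\tdensity\n")
        for z, d in zip(profile.z_centers, profile.density):
            fh.write(f"{z:.4f}\t{d:.6f}\n")


def run_pathway(config: RunConfig) -> dict:
    """Event detection followed by scrambling-pathway mapping."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    topology, frames, selection = _load(config)

    frames = iter(frames)
    first = next(frames)
    assignment = assign_initial_leaflets(first, selection)
    frame_list = [first, *frames]  # pathway needs two passes over coordinates

    traces = build_traces(
        iter(frame_list), selection, stride_ns=config.detector_stride_ns, method=config.angle_method
    )
    events = detect_all(
        traces,
        assignment,
        lower_threshold=config.detector_buffer_low_deg,
        upper_threshold=config.detector_buffer_high_deg,
    )
    pathway = map_pathway(
        events,
        iter(frame_list),
        topology,
        selection,
        contact_cutoff=config.pathway_contact_cutoff_nm,
        stride_ns=config.detector_stride_ns,
        equilibration_ns=config.equilibration_ns,
    )
    pathway.contacts.to_csv(outdir / "residue_contacts.tsv", sep="\t", index=False)
    write_point_cloud_pdb(pathway.positions, outdir / "pathway_points.pdb")
    _write_manifest(config, outdir, "pathway")
    return {"pathway": pathway, "events": events}
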