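# Methods

This note documents the models, conventions and numerical choices behind
`scramblescan`, including the points where the protocol leaves a design
decision open and what was chosen.

## Units and coordinate model

Everything internal is nanometres and nanoseconds (GROMACS-native). Readers
convert on ingestion (PDB Å → nm; MDAnalysis ps → ns). Distances in the
membrane plane use the xy minimum-image convention; the bilayer is assumed
whole (not wrapped) along z and this is validated at leaflet assignment —
a head bead further than half a box from the midplane raises a geometry
error instructing re-imaging rather than silently producing 90°-ish angles.
Replicate trajectories are identified by input file order; the replica
index is carried through every downstream record (traces, events, bins).

## Lipid orientation

Each lipid contributes one angle per sample: the angle between its
orientation vector and +z. Two tail→head vectors exist (one per chain);
the default combines them as the **mean of the two unit vectors** before
taking the angle. This is robust to chain splay and insensitive to the
chains' instantaneous lengths. The alternative — averaging the two angles —
is exposed as `method="angle-mean"`; the two conventions differ only at
large splay and never flip a leaflet-scale orientation. Coincident beads
(zero-length vector) and exactly anti-parallel chains are hard errors
naming the lipid, not NaNs.

## Leaflet assignment

The analysis needs an initial leaflet per lipid; afterwards leaflet state
is owned exclusively by the event detector (no static re-assignment is ever
performed, so a flip never "resets" silently). Initialization: the bilayer
midplane is the mean z of all tail-terminal beads at the reference frame,
and a lipid is UPPER iff its head bead lies above it. The assignment is
cross-checked against the orientation angle (UPPER ⇒ θ < 90° up to noise);
lipids mid-flip at the reference frame are flagged, and the detector's
initial-state correction (below) handles them.

## Event detection

A hysteresis state machine per lipid trace, sampled on a fixed 1 ns grid:

* state UPPER → LOWER (one event) at the first sample with θ strictly
  greater than 125°;
* state LOWER → UPPER at the first sample with θ strictly lower than 55°;
* samples inside the closed band [55°, 125°] never change state.

Numerical conventions: crossing detection is sample-based (no interpolation
of a continuous crossing time — the measurement grid is 1 ns, and so is the
event-time resolution); equality with a threshold counts as inside the
buffer, mirroring the strict inequalities of the counting rule; a first
sample already beyond the threshold opposite the declared initial state is
a state correction with a warning, not a counted event (counting it would
book the initialization artifact as scrambling).

The transit window attached to each event is the contiguous buffer-resident
run ending at the counted crossing (an instantaneous jump across the whole
band gets a zero-length window). The implementation is vectorized; the test
suite holds it against an independent naive sample-by-sample oracle on tens
of thousands of random traces, plus property tests for mirror symmetry
(θ → 180° − θ with swapped leaflet), concatenation consistency and the
guarantee that buffer-confined traces never fire.

## Rate statistics and classification

Events are counted per system (summed over lipids), since the reported
quantity is events/μs per simulated system. The first 2 μs (default) of
each replicate are discarded; the rest is tiled with half-open 1 μs bins
(boundary events belong to the later bin; a trailing partial bin is dropped
and logged). Two 10 μs replicates ⇒ 16 data points. Boxplot statistics use
linear interpolation between order statistics for the quartiles; both Tukey
(1.5 × IQR, clamped to the data) and min/max whiskers are emitted, since
either convention is common.

Classification: **mean** pooled rate ≥ cut-off (default 1 event/μs) ⇒
scrambler. The mean is used rather than the median because it is the
unbiased estimator of a Poisson rate and the median of 16 small counts is
coarse; the cut-off is configurable.

## Thickness and thinning

Hydrophobic thickness is read off the z-density of the membrane's
hydrophobic body — all lipid beads minus the configured headgroup/phosphate
names (defaults NC3, PO4) — sampled every 5 ns after the equilibration
discard, with z referenced to the per-frame midplane (mean tail-terminal z)
to remove bilayer drift. The extraction rule is **FWHM with linear
interpolation** at the half-maximum crossings: parameter-free and standard
for slab densities. A curve with more than two half-max crossings is
reported as ambiguous rather than guessed at. Profiles are normalized so
that ∑ density × bin width = mean selected beads per frame.

Protein proximity is lipid-level: if any bead of a lipid lies within the
1.0 nm cutoff of any protein bead, all of that lipid's hydrophobic beads
enter the local profile — lipids, not beads, are the physical unit being
selected. Thinning = bulk FWHM − local FWHM; both profiles are accumulated
in a single trajectory pass. A Pearson correlation helper
(`rate_thinning_correlation`) supports scrambling-vs-thinning comparisons
across systems.

## Pathway mapping

Only post-equilibration events contribute (consistency with the rate
window). For each event the headgroup positions over the transit window are
pooled into a point cloud (written as pseudo-atom PDB) and counted against
protein residues: one contact per (event, stride point) with any residue
bead within 0.6 nm — a typical CG bead-contact distance, configurable.
Both pooled and per-event position sets are retained, since a figure may
want one representative flip or the ensemble.

## The synthetic bilayer generator

The generator is a *kinematic fixture*, not an MD engine: no force field,
energetics or barostat. What it emulates, and why each piece exists:

* **Orientation statistics.** Upper/lower lipids hold base angles of
  10°/170° plus Gaussian within-leaflet noise (default σ = 12°). The noise
  is truncated at 3σ so that noise alone can never constitute a leaflet
  crossing — flips happen only through the explicit flip process, keeping
  the ground-truth ledger exact. With the defaults, 3σ excursions stay
  outside the buffer; at σ = 25° they enter it but cannot cross, which is
  precisely the regime the hysteresis rule must absorb.
* **Flip-flop.** Event completion times are a Poisson process at the
  requested system rate; each flip sweeps the angle linearly through the
  buffer over an exponential dwell (mean 10 ns, floored at one frame
  interval), assigned to a lipid not already mid-transit. The linear sweep
  crosses each threshold exactly once, making ledger↔detector matching
  unambiguous to within one frame.
* **Geometry.** Ten beads per lipid (NC3, PO4, C1A..C4A, C1B..C4B) on a
  0.8 nm lateral grid (0.64 nm² per lipid, a realistic CG area). The eight
  hydrophobic beads are placed uniformly along the director between the
  midplane anchor and a 1.8 nm tail extent, so the hydrophobic z-density is
  an analytically known slab (FWHM ≈ 2 × 1.8 × ⟨cos θ⟩ ≈ 3.5 nm, a
  realistic hydrophobic thickness); PO4 and NC3 sit at 2.1 and 2.5 nm. The
  two tail-terminal beads are split laterally by 0.05 nm so the two
  orientation vectors are distinct. Positions, not angles, are what the
  analysis pipeline consumes — the angles it measures reproduce the
  generator's internal angle matrix exactly.
* **Protein, thinning, pore.** The pseudo-protein is a cylinder of
  single-bead residues in vertical columns (default radius 1 nm, height
  5 nm, 40 residues in 8 columns). Imposed thinning shortens the tail
  extent of lipids within a 2 nm annulus of the protein by δ/(2 cos θ̄),
  the cos factor compensating mean tilt so the *measured* FWHM difference
  equals δ. With `pore=True`, flipping headgroups are guided along a
  vertical line 0.4 nm outside column 0, whose residues are recorded as the
  pore lining.
* **Determinism.** One root seed; events, per-replica noise and coordinate
  realization draw from named substreams, so trajectories are
  byte-identical across runs of the same spec.

What it does **not** emulate — and hence what passing tests do not show
about real membranes: no correlated lipid motion or undulations, no
area/volume fluctuations, no protein flexibility, no solvent, no
composition asymmetry, and flip kinematics are deterministic sweeps rather
than diffusive barrier crossings. The generator validates the *analysis*,
not the physics.

## Problem sizes in the shipped tests

The test and acceptance runs use 32–576 lipids per leaflet and 2.5–10 μs
synthetic trajectories: large enough that the 16-bin protocol, Poisson
recovery within 3 standard errors (50 seeds per rate), 0.3 ± 0.05 nm
thinning recovery and pore localization are all well-powered, while the
whole suite stays fast enough to run routinely. Rate studies use the
angle-trace fast path (no coordinate realization), which is exactly
equivalent for the detector by construction.

One statistical caveat: for ~20 systems with genuinely independent rates
and thinning, the sample Pearson |r| exceeds 0.3 in roughly a fifth of
realizations (SE ≈ 1/√n), so "no correlation" is asserted on pooled data
(240 pairs, |r| < 0.25 ≈ 4 SE) rather than per small batch.

## Known limitations

* Orthorhombic boxes only; xy minimum-image assumes a rectangular cell.
* No PBC re-imaging: inputs must have whole lipids (the loader validates z
  but cannot repair a wrapped bilayer).
* FWHM thickness is one defensible extraction rule; profiles with strong
  shoulders (e.g. cholesterol-rich mixtures) may need the emitted raw
  profiles instead of the scalar.
* The detector's event time is the completing sample (1 ns granularity);
  sub-nanosecond transit structure is invisible by design.
* No significance testing between systems and no time-resolved rate
  modeling; the ranked comparison table is descriptive.
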