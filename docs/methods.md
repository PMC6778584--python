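# Methods

`tractdissect` re-creates, at desk scale and on synthetic phantoms, a
complete analysis chain for dissecting deep-brain fiber bundles from
whole-brain tractograms: seed-based streamline selection, tract- and
terminal-density mapping, parcel-wise projection quantification, diffusion
signal normalization with angular reorientation, and a global
simulated-annealing fiber tracker with a reheat-accumulation strategy.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic phantoms do and do not establish.

## Coordinate and data conventions

All streamline coordinates are world millimetres, RAS; MNI conventions
apply when a tractogram carries the `MNI` space tag (x > 0 is the right
hemisphere). Volumes use 0-based voxel indices with a voxel-center affine.
TCK is the canonical streamline format because its coordinates are world mm
with no header-dependent affine ambiguity. Arc-length cut points
(resampling, distal segments) are linearly interpolated between samples, so
results do not depend on how densely a streamline was stored.

## Seed-based dissection

The seed catalog holds the standard MNI coordinates of the dissection:
latVTA (±6, −12, −8; r 3 mm), PLIC (±22, −20, 10; r 15), ALIC (±14, 13, −2;
r 8), mammillary body (±4, −7.5, −12.5; r 3), unpaired pontine seed
(0, −33, −25; r 10), and the DRT triple — dentate (±17, −58, −29; r 8),
superior cerebellar peduncle (±8.5, −40, −30; r 4), ventro-lateral thalamus
(±18.5, −16, 5; r 5). The motorMFB is the conjunction latVTA ∧ PLIC; the
PFC/MB/BC sub-bundles add the ALIC / MB / pontine seed respectively and
need not be disjoint. The DRT requires dentate and SCP on one side and the
VL seed on the *opposite* side, so its decussation is enforced purely by
laterality; no passage-order constraint is used anywhere.

"Attached" means the streamline's continuous piecewise-linear path
intersects the closed ball. This is computed by exact point-to-segment
distances, making selection independent of sampling density; an
endpoint-only alternative would discard fibers that traverse a seed, which
contradicts how the latVTA seed is used. Radii are inclusive; the boundary
has measure zero.

A deliberate open point: whether the original selection tested sampled
points or continuous segments is not determinable from the sources; the
continuous test was chosen and is verified against a 0.01 mm dense-sampling
oracle. A conflicting z-sign for latVTA appears in one figure caption
((−6, −12, +8)); the body-text value (−8) is used.

## Density and terminal maps

"Trilinear rendering" is implemented as trilinear *splatting* — the adjoint
of trilinear sampling: each streamline is subdivided into sub-segments of
at most 0.02 voxel edges and each sub-segment deposits its length at its
midpoint into the eight neighbouring voxels with trilinear weights. Units
are therefore mm of streamline per voxel, which is what the 1 mm/voxel
indicator threshold requires (inclusive comparison). Interior tractograms
conserve total length to 1e-6 relative; the 0.02-voxel subdivision keeps
the per-voxel difference from a 0.01 mm subdivision below 1e-3 mm.

Terminal maps deposit both distal 20 mm segments of every streamline (for
streamlines shorter than 40 mm, the whole streamline once), then smooth
with an isotropic Gaussian of FWHM 3 mm (σ = FWHM/(2√(2 ln 2))). Both ends
are used because no "cortical end" is designated; non-cortical terminal
mass is harmless downstream since quantification intersects cortical
parcels only. Group maps are 100 × the voxelwise mean of per-subject binary
indicators. Thresholding is applied after warping the density volume by
default; a `threshold_before_warp` switch provides the other order, which
the sources leave ambiguous.

Reference grids: 2.5 mm isotropic for density/terminal maps
(`MNI-2.5mm`), 1.5 mm isotropic for the template grid (`template-1.5mm`).

## Projection quantification

For each bundle, `cell(parcel) = 100 × |{s : parcel ∈ terminal_hits(s)}| /
|bundle|`, where `terminal_hits` resamples both distal 20 mm segments at
0.25 mm and tests nearest-voxel membership in the parcel mask. Multi-parcel
hits count in every parcel hit, and many streamlines end outside all
parcels, so columns do not sum to 100%. The denominator is always the
bundle's streamline count. Gyral parcels and motor-area (HMAT-style) masks
are quantified independently against their own atlases; the masks may
overlap the gyral parcels. An `endpoint` terminal rule is available as a
config switch.

## Spatial normalization with angular reorientation

With `w(x)` the template→subject displacement (pull-back convention) and
`J(x)` its Jacobian, the normalized signal is `S′(x, n) = S(w(x), J(x)n)`
with no angular modulation. Implementation: per-voxel least-squares fit of
the real, even (antipodally symmetric) spherical-harmonic basis in source
space (default lmax 8; ridge 1e-8 relative to the mean Gram diagonal — a
numerical safeguard chosen small enough not to bias band-limited signals
above 1e-6); trilinear interpolation of each coefficient map at `w(x)`;
evaluation along `J(x)n/‖J(x)n‖` for 90 output directions per shell on a
golden-angle hemisphere design. `J(x)n` is renormalized because spherical
harmonics are defined on the sphere; voxels with ‖J(x)n‖ < 1e-6 are
zero-filled and counted. b = 0 volumes are warped spatially only.
Jacobians of sampled displacement fields use central differences in the
interior and one-sided differences at the boundary, chained through the
grid affine (exact for affine fields, O(h²) otherwise).

## Global tracker

The tracker is a deliberately simple segment-particle re-creation of global
fiber tracking by simulated annealing; it preserves the algorithmic shape —
polymerization of short oriented segments under Metropolis–Hastings with
slow cooling, a white-matter mask at probability ≥ 0.5, and the five-round
reheat-accumulation strategy — without reproducing any published energy in
detail. The energy is

E = −w_data Σ score(xᵢ, dᵢ) + w_birth·N
  + w_link Σ_links [ c·θ/π + g·gap² − 1 ]
  + crowding · #{aligned same-voxel pairs}

* **Data term.** `score` is an even-SH fit (lmax 6) of the mean-normalized,
  sign-inverted multi-shell signal, tabulated on 64 hemisphere directions;
  it peaks along fiber directions. w_data = 4.
* **Link term.** θ is the turning angle between the outgoing directions of
  the linked endpoints. The penalty is *linear* in θ (c = 6), not
  quadratic: a quadratic bend cost makes a 60° turn distributed over many
  links almost free, which lets chains switch bundles at a crossing; a
  total-curvature penalty charges the same for a distributed turn as for a
  sharp one. `gap` is the endpoint distance (g = 0.15 mm⁻²) and the −1 is
  the connection bonus that makes polymerization favorable. w_link = 1.
* **Birth and crowding.** w_birth = 0.6 per segment. The crowding term adds
  a fixed repulsion (0.12) per pair of segments whose centers share a voxel
  and whose directions agree within 45°; it saturates the segment density,
  which the raw score-sum data term would otherwise grow without bound.
  Crossing populations in one voxel do not repel each other.
* **Proposals.** The kind mixture is fixed (birth 0.25, death 0.25, move
  0.30, link 0.10, unlink 0.10). Births are data-steered: half are chain
  extensions — a segment born pre-linked at a free chain end, directed at
  the best-scoring tabulated direction within a 30° forward cone — and half
  are nucleations at random mask voxels aligned with the locally
  best-scoring direction. Death is restricted to segments with at most one
  link (isolated segments and tip retraction); interior chain segments
  never die. Moves are either a positional/angular jitter or, for chain
  tips, a pivot about the linked endpoint toward a steered direction. Link
  proposals connect a free endpoint to the lowest-cost free partner within
  2.5 mm, rejecting links that would close a cycle; unlink removes an
  existing link. Segments (center and both endpoints) must lie inside the
  mask at all times, so extracted streamlines never leave it.
* **Schedule.** Geometric cooling T(k) = T_start·(T_end/T_start)^(k/n)
  (defaults 1.0 → 0.02; the cooling law and initial temperature are this
  package's defaults, not claims about any published implementation), then
  five accumulation rounds at the reheat temperature 0.1, each round
  iterating further on the same evolving state and appending a fresh
  extraction; the result is five times one extraction up to stochastic
  round-to-round variation. Desk-scale budgets are 5×10⁵ cooling and
  2.5×10⁵ per round (the full-scale value, 10⁷ per round, is impractical on
  a workstation and unnecessary on phantoms of a few hundred voxels).
  Segment half-length is 1.5 mm. A single integer seed drives the whole
  run; identical seeds give identical states.

Extraction walks maximal link chains (cycles are impossible by
construction and raise an integrity error if ever encountered), emitting
each chain's 2k endpoints as a streamline and dropping chains below
`min_points` (6).

## Synthetic phantoms

The generators define the study conditions and every ground truth the tests
use.

* **Scene.** The default grid is 40×48×40 voxels at 2.5 mm with an MNI-like
  origin, so the real seed catalog applies unchanged. Bundle trunks are
  natural cubic splines through waypoints that include the exact seed
  centers (PFC: frontal→ALIC→latVTA→PLIC; MB: MB→latVTA→PLIC; BC:
  brainstem→Pons→latVTA→PLIC; DRT: left dentate→left SCP→right VL,
  decussating; plus an slMFB-like distractor threading latVTA but not
  PLIC). Each streamline adds a constant lateral offset — Gaussian with
  sd 0.5 mm, truncated at 3 sd, projected onto the plane normal to the
  local tangent — so every streamline passes within 3·sd of every waypoint
  and seed-ball attachment is guaranteed by construction.
* **Terminations.** Cortical parcels are axis-aligned box slabs (four
  disjoint gyral slabs; three disjoint motor-area masks overlapping them
  medially/laterally). A configured fraction of each bundle terminates in
  each parcel — exactly `round(f·n)` streamlines, steered up a vertical
  approach into the slab at a medial or lateral x-track — and the
  generator emits the implied bundle × parcel percentage matrix as ground
  truth. The default fractions echo the relative distribution reported for
  the real tracts, so the recovered table is a desk-scale stand-in for the
  published one rather than a reproduction of it.
* **Diffusion signal.** Per voxel, tangents of traversing streamlines are
  clustered by bundle into axially symmetric tensors (λ∥ = 1.7e−3,
  λ⊥ = 0.3e−3 mm²/s), weighted by traversed length:
  S = S0 Σ fᵢ exp(−b nᵀDᵢn), with an isotropic tensor (0.8e−3 mm²/s)
  elsewhere, shells at b = 1000 and 2000 s/mm², 90 directions each, and
  optional Rician noise (two Gaussian channels; off by default). The WM
  probability is 1 on traversed voxels with a smoothed edge.
* **Crossing phantom.** Two straight bundles of 32 mm crossing at 60° in
  plane, 30 streamlines each with 1.2 mm jitter on a 2 mm grid — the tube
  is ~2.5 voxels across, because a bundle narrower than the grid
  resolution is not resolvable by any tracker operating on that grid.
  Endpoint balls of radius 6.5 mm sit at the bundle ends; balls of
  different bundles are ≥ 3 mm apart.
* **Warps.** identity / translation / rotation / sinusoid displacement
  fields are produced together with their analytic Jacobians, which serve
  as oracles for the finite-difference and reorientation code.

What the phantoms do not emulate: cortical folding, partial-volume and
CSF compartments, realistic noise levels and artefacts, inter-subject
anatomical variability beyond jitter and per-subject seeds, and the scale
of a whole-brain connectome. Passing tests therefore establish the
correctness and internal consistency of the pipeline's operations, not
anatomical claims about real data.

## Pipeline

The `tractdissect` CLI exposes simulate / normalize / track / select /
maps / quantify / all over one YAML config; every run writes its resolved
config, all intermediates in standard formats (TCK, NIfTI, CSV), and a
JSON log with per-stage counts (including streamlines not captured by any
seed, the analog of spurious attractions in real data — reported, never
silently removed). Deterministic stages are byte-reproducible; the tracker
stage is reproducible given its seed. Exit codes: 0 ok, 2 config error,
3 stage failure.

## Known limitations

* The tracker's energy is a simplification; its absolute temperatures and
  weights are meaningful only relative to each other, and the 0.1 reheat
  temperature refers to this package's energy scale.
* Greedy link selection and data-steered births are efficiency devices;
  the sampler is not a strict reversible-jump MCMC, which is acceptable
  here because the object of interest is the optimized configuration, not
  the posterior.
* On the crossing phantom a reconstructed streamline occasionally spans
  only part of a bundle or switches bundles inside the crossing region
  (of order 10–15% of long streamlines at the default budgets).
* Group-level machinery averages indicator volumes over phantom subjects;
  no template construction beyond voxelwise averaging is provided.
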