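# Methods

This note documents the models, numerical choices and limitations behind
`axonarray`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Fall-off model

The state is the multiset of contiguous-array OAD counts {N_i} together
with the apo reference total (the 100 % coverage mark).  One event removes
exactly one OAD, so coverage decreases by 1/reference per event and the
number of events needed to reach a target coverage is deterministic; the
stopping rule is "first step at which coverage ≤ target", which overshoots
by at most one OAD.

*End release.*  The next release happens on array *i* with probability
L_i/ΣL_j, L_i = 1 + α(N_i − 1).  Because the state is a length multiset the
two ends of an array are indistinguishable; events label the end as
`"end"`.  Sampling uses the mixture identity
L_i = (1 − α)·1 + α·N_i: with probability (1 − α)n/S a uniformly random
array is decremented, otherwise a uniformly random *bound OAD* is drawn and
its array decremented — the two branches reproduce L_i/ΣL_j exactly while
keeping the per-step cost linear.  The hot loop consumes pre-drawn
uniforms from a `numpy` Generator and is JIT-compiled with numba; the
public step functions are an independent, readable implementation, and the
test suite checks both against exact enumeration of the next-step
distribution on small populations.

*Random break.*  A bound OAD is drawn uniformly; end positions shorten the
array, interior positions split it into the two flanking pieces (array
count grows by at most one per event).

*Discrepancy and α estimation.*  The comparison metric between observed
and simulated length multisets is the first Wasserstein distance between
the empirical distributions (Kolmogorov–Smirnov is available via
`metric="ks"`); it is robust to binning and sensitive to the
sequential-vs-random contrast.  `estimate_alpha` simulates, for each α on
a grid (default 0 to 1, step 0.05) and each replicate (default 100), the
end-release process from the reference population down to every observed
condition's coverage, sums discrepancies over conditions, averages over
replicates and returns the grid argmin, breaking ties toward the smallest
α (conservative: the weakest length dependence consistent with the data).
Replicate simulations are averaged rather than pooled.  Observed
conditions carry their own coverage (in a real titration it is measured
from images; the synthetic generator records the true pool coverage) —
coverage is an input, not inferred from possibly subsampled tables.

*Length-to-count conversion.*  Measured array lengths divide by a 24-nm
OAD repeat (four OADs per 96-nm array repeat) and round to the nearest
whole OAD.

## Synthetic titration data

The generator draws an apo population of per-array OAD counts, runs the
configured true model to per-condition target coverages, and reports
`min(n_condition, survivors)` arrays sampled without replacement — the way
a negative-stain image samples a reaction.  Defaults are the conditions
the analysis is meant for:

* per-condition array counts 319/180/214/222/159 (labels 0/10/30/100/1000
  μM ATPγS) — the study's sample sizes;
* apo length sampler: geometric (p = 0.125) truncated to [1, 60], mean ≈ 8
  OADs — a stand-in resembling the observed spread of apo array lengths,
  fully configurable; the true apo distribution is only available in the
  source data of the original experiment and is not claimed here;
* target coverages 1.0/0.8/0.6/0.4/0.15 — a stand-in depletion series
  mirroring the qualitative titration trend (near-complete loss at 1 mM);
  the per-condition coverages are not printed numerically anywhere and are
  configurable.

Passing parameter-recovery tests on these data shows the estimator works
at the study's sample sizes under the model's own assumptions; it does not
validate the model against real micrograph counts, and the generator makes
no attempt to emulate measurement error in array-length reading.

RNG streams are spawned per purpose from the config seed with
`numpy.random.SeedSequence`, so every generator is byte-reproducible and
adding a stream does not perturb the others.

## Light-chain identification

The size-class table maps every standard residue to exactly one of
large {W, Y, R, F, H}, middle {L, Q, N, I, M, K},
small {P, V, S, T, C, E, D, A} or glycine; acidic residues are "small"
because negatively charged side chains image weakly.  (The large-group
member written "Try" in some descriptions is read as Tyr; no amino acid
"Try" exists.)  Patterns add an `X` wildcard for uninterpretable density;
`X` matches every residue and contributes no penalty.  Matching is
ungapped — candidates are fitted "into a position", insertions/deletions
are out of scope.  Window ties break toward the smallest offset and the
runner-up penalty is always reported, so ambiguous cases are visible.
The MS criterion is an input whitelist of record ids; no significance
model is imposed.  A candidate is `identified` only when it is the unique
strict penalty minimum *and* an MS hit; equal minima give
`ambiguous_tie`, a best non-hit gives `no_ms_hit`.

The synthetic proteome plants one exact-match target and decoys carrying
exactly k class-changing mutations; construction verifies (and reruns
flanks until) each record's best window is the planted one, uniquely, so
ground-truth penalties are guaranteed, not merely likely.

## Lattice geometry

Rigid fits are least-squares proper rotations (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`); degenerate (collinear)
inputs are rejected, reflections cannot be returned.  The inter-PF angle
of an adjacent pair is the *total* rotation angle
arccos((tr(R_b R_aᵀ) − 1)/2) of the relative rotation of the two dimer
fits — well-defined without a lattice axis and matching the behaviour of
the common "angle between domains" visualization commands; a signed
component about a supplied axis is available
(`rotation_angle_about_axis`) for strictly lateral readings.  Angles are
summarised over three axial regions (first, middle, last repeat by
default) as mean ± s.d. per pair.  Because relative rotations cancel the
reference frame, measurements are invariant to the reference-dimer
choice, which is why file round-trips (where the reference is not stored)
preserve them.

Domain rotations between states superpose state 2 onto state 1 by the
align selection before fitting the measure selection.  Axial offsets are
centroid differences projected on a unit axis (default: first principal
component of dimer centroids, oriented toward increasing repeat index),
reported in nm from Å coordinates.

Synthetic lattices place rigid copies of a reference point cloud (60
points, 18 Å spread — enough spatial extent that 0.3 Å coordinate noise
propagates to ≪ 0.5° of angle error) on a cylinder of radius 120 Å with
planted inter-PF rotations about the cylinder axis and a planted axial
rise (default 8 nm).  Closed tubes require the planted angles to sum to
360° within 1e-6.

## Filament-signal weakening

The mask is a rectangle along a center line with a hard edge at its ends
and a cosine soft edge across its width.  The soft edge is transverse-only
on purpose: the along-axis averaging weights are then constant per
transverse offset, which makes the subtraction exactly idempotent on the
full-weight core for axis-aligned filaments (with end ramps it would not
be).  The "weighted average" is a 1-D profile — the mask-weighted mean
intensity along the long axis, one value per 1-px transverse bin,
interpolated linearly at each pixel's exact transverse coordinate — since
the filament is continuous along its axis while particles are localized;
a scalar-mean variant is available via `profile=False` and recorded in
the call signature rather than hidden state.  Subtraction is
weight-scaled, so the result is continuous across the soft edge and
pixels with zero weight are bit-identical to the input.  Arithmetic runs
in float64 and is written back in the input dtype (float32 images keep
float32).  Within-mask energy (Σ intensity²) never increases because
Σw² ≤ Σw for weights in [0, 1].

## Gliding statistics

Velocity is path speed: the sum of distances between consecutive smoothed
samples over elapsed time ("positions along the gliding paths"); a
net-displacement variant can be formed from `Track.net_displacement_um`.
Smoothing is a centered moving average (default 3 frames = 0.22 s at
13.5 Hz) that shortens the track by window − 1 samples; filtering runs on
the *raw* tracks so the <1-s rule applies to the track as recorded
(strict: exactly 1 s is retained), then velocities are computed on the
smoothed retained tracks.  The immobile rule (net displacement < 0.2 μm,
configurable) stands in for the original manual inspection, and
collision/dirt exclusions are caller-supplied flags; every exclusion is
logged with its reason and the log plus retained set partition the input.
The histogram uses left-closed right-open 0.4 μm s⁻¹ bins from 0, so a
boundary value opens its bin.

The synthetic default planted velocity is 3.0 μm s⁻¹, a typical
OAD-driven gliding speed.  This matters quantitatively: path-speed
estimates carry a noise-inflation bias ≈ σ_eff²/(2·step²) per frame, so
with 0.05 μm position noise at 13.5 Hz the bias is < 1 % at 3 μm s⁻¹ but
would be ~8 % at 0.8 μm s⁻¹; recovery tolerances in the tests presume the
assay's realistic speed scale.

## Problem sizes

Simulation-heavy checks run the full study-scale conditions (319 apo
arrays, ≈ 2,500 OAD units, 21-point α grid): one grid estimate with 100
replicates costs a few seconds with the JIT-compiled kernel, the
model-contrast check uses 50 data seeds with 20 replicates each, and the
parameter-recovery check uses 3 seeds × 100 replicates per planted α —
sizes chosen so the whole suite remains comfortably interactive while the
Monte-Carlo error stays well inside the stated tolerances.

## Known limitations

* The fall-off model is the discrete release process only — no rate
  constants, nucleotide concentrations or time axis; "condition" order is
  encoded purely through target coverages.
* The discrepancy metric underlying α estimation is a design choice
  (Wasserstein-1); reported estimates should state it.
* Filament images are geometric phantoms: no contrast-transfer function,
  projection physics or detector model, so weakening results demonstrate
  the operator's contracts, not cryo-EM image fidelity.
* Identification treats the density pattern as given; reading size
  classes out of an actual map, and any homology search to produce the
  candidate list, are upstream of this package.
* Tracks are supplied, not detected; tracking errors beyond the modelled
  isotropic position noise (linking errors, drift) are not emulated.
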