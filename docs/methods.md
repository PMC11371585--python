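# Methods

`aslreg` simulates and analyzes the alignment of arterial-spin-labeling
(ASL) perfusion images to structural T1-weighted images, and the downstream
group analyses that depend on that alignment. Everything runs on synthetic
phantom cohorts with known ground truth, so every stage — quantification,
quality control, registration, surface sampling, consistency evaluation,
group statistics — can be validated against the generative truth.

## The phantom

Each participant is a nested-shell digital head on a structural grid
(default 64×64×54 voxels at 2 mm): a white-matter (WM) core, a
gray-matter (GM) ribbon (default thickness 4 mm), a CSF shell (3 mm), and
two ventricle-like CSF cavities placed asymmetrically inside the WM. The
shells are *radially-modulated ellipsoids*: an ellipsoid with distinct
semi-axes (fractions 0.70/0.60/0.55 of the half field of view) whose
radius is scaled by a fixed smooth angular undulation of amplitude 6% (a
mild pseudo-gyrification). Two properties motivated this geometry:

* **Provable surface correctness.** The WM–GM interface has a closed-form
  implicit function g(p) = ρ(p) − s(û(p)); mesh vertices are constructed
  exactly on g = 0 (icosphere directions mapped through the radial scale)
  and normals follow ∇g. Tests assert sub-0.1 mm agreement.
* **Pose identifiability.** On a perfectly smooth quadric, rotating the
  boundary slides sample points tangentially *along* the surface, so both
  an intensity cost and a boundary-contrast cost are nearly blind to
  rotation; with equal semi-axes one rotation is an exact symmetry. The
  angular undulation, distinct axes, and ventricles give every head pose a
  distinct image, the way folded cortex and ventricles do in real heads.

T1w-like contrast is WM > GM > CSF (1000/700/250 by default). Ground-truth
CBF is 60 mL/100g/min in GM and 20 in WM (physiological convention),
with the GM value modulated by a second fixed smooth angular pattern
(±15%) — a shared regional perfusion topography. Without it, phantom GM
CBF would be spatially constant and inter-subject vertex-wise correlations
would measure only noise; with it, well-registered maps correlate and
misregistered maps decorrelate, which is the behavior the consistency
framework exploits. Cortical atrophy is modeled as thinning of the GM
ribbon only; the WM–GM interface, and hence the boundary mesh and
parcellation, are shared across the whole cohort.

## Acquisition forward model

Each participant's pCASL session is 14 label–control pairs (28 volumes)
plus a separate noise-free M0 volume, on a 64×64×34 grid at 3.75 mm
isotropic by default. The session is acquired in "head space": the
structural-space truth is pulled onto the ASL grid through the inverse of
the participant's true rigid ASL→T1w transform (drawn uniformly within
±5 mm / ±5° per axis by default).

The perfusion-weighted difference signal is the exact inverse of the
quantification model: ΔM = CBF · M0 / k, with

    k = 6000 · λ · exp(PLD/T1b) / (2 · α · T1b · (1 − exp(−τ/T1b)))

(τ = 1.8 s labeling duration, PLD = 1.8 s post-labeling delay, α = 0.72
labeling efficiency; λ = 0.9 mL/g and T1b = 1.65 s are documented package
defaults, chosen from common single-compartment practice). Control volumes
carry the static M0 signal multiplied by a radial-sinusoid "ringing"
artifact (random phase per pair); label volumes subtract ΔM from the same
modulated static signal. Because both members of a pair share the
artifact, the control − label subtraction cancels it *exactly*, which is
the modeling target: spiral-readout ringing corrupts individual volumes
but not subtracted perfusion maps. Per-voxel Gaussian noise (default
sd 1.0 intensity units, i.e. ≈4 mL/100g/min in a single-pair CBF map
after division by M0) is added to every raw volume.

Consequences tested: with zero noise, quantification reproduces the
acquisition-grid truth to machine precision; with noise, the cohort-mean
GM CBF is unbiased.

## Quantification

Head-motion correction (rigid, 6 degrees of freedom, one trilinear
resampling per volume) is available via the same intensity engine used for
ASL→T1w registration; the cohort simulator injects no inter-volume motion,
so the pipeline skips it by default. Pairwise control − label subtraction
(interleaving order is a manifest field), the closed-form kinetic model
above, and voxelwise averaging produce the mean CBF map. Voxels with M0
below 10% of the M0 maximum are masked: dividing by near-zero
partial-volume M0 at the brain edge otherwise turns noise into unbounded
CBF values that corrupt every downstream intensity computation.

## Quality control

The quality index combines three scale-free components of a CBF map:
Pearson correlation r with a segmentation-derived pseudo-CBF (GM 60,
WM 20, CSF 0), the coefficient of variation (CV) of GM CBF, and the
fraction of negative GM voxels:

    QEI = clip(r, 0, 1)^a · exp(−b·CV) · (1 − negfrac)^c,  (a, b, c) = (1, 1, 2).

The functional form is this package's own (the published index's trained
coefficients are not reproduced); it is monotone in each component, lies
in [0, 1], and is invariant to global positive rescaling. Maps pass iff
QEI strictly exceeds 0.4. Structureless (pure-noise) and sign-flipped maps
score far below the gate; clean pipeline maps score ≈0.65–0.9, the spread
coming from partial-volume dilution at ASL resolution.

## Registration

Three strategies produce ASL→T1w transforms; the moving image is always
the mean CBF map, never a single raw volume.

* **Emulated manual** — the ground-truth transform perturbed by seeded
  Gaussian operator error (default 1 mm and 1° per axis; the accuracy of a
  careful human operator is not known precisely, so this is a documented
  placeholder). It plays the benchmark role of a human alignment.
* **Rigid intensity (FLIRT-like)** — 6-DOF minimization of
  1 − η²(moving | fixed bins), the correlation ratio with the *moving*
  intensities as response and fixed-image bins as predictor, over a
  3-level Gaussian pyramid with deterministic Powell line searches. Two
  numerical choices matter. First, the cost is evaluated only on
  fixed-image head voxels (above 5% of the fixed maximum): letting the
  evaluation set vary with pose rewards transforms that slide air into the
  overlap. Second, the response/predictor orientation matters at
  mismatched resolutions — predicting the sharp structural image from
  smooth CBF bins has its optimum displaced from the true pose by partial
  volume, while the direction used here keeps the optimum at truth (this
  was verified against an L2 alignment oracle on noiseless phantoms).
  Accepted steps never increase the full-resolution cost.
* **Boundary-based refinement (BBR)** — for each boundary vertex v with
  outward normal n, sample the moving image at the pullbacks of v ± 2 mm·n,
  form the percent contrast Q = 100·(I_out − I_in)/(½(I_out+I_in)+ε), and
  minimize the mean of 1 − tanh(slope · sign · Q) over 6-DOF (or optionally
  12-DOF affine) updates composed with the initialization. The expected
  contrast sign is positive (GM CBF > WM CBF). The slope default is 0.02
  per percent: with the phantom's ≈100% boundary contrast a steeper slope
  saturates the tanh and flattens the basin, letting the optimizer wander.
  Vertices whose samples leave the volume are excluded; if more than half
  do, the cost is invalid and the registration is flagged as failed —
  the operational counterpart of failed-registration accounting in real
  cohorts.

On noiseless phantoms at these grid sizes, the rigid engine recovers poses
to ≈0.1 mm/0.3° and BBR refinement converges to the same transform from
either initialization (manual or FLIRT) to within ≈0.5 mm/0.5°; BBR's own
residual (≈0.1 mm/0.2°) is a discretization floor set by the ASL voxel
size relative to the 4 mm GM ribbon.

## Surface sampling and ROIs

CBF is sampled at each vertex displaced +1 mm along its outward normal
(mid-GM; the projection fraction is configurable) through the inverse of
each method's transform, trilinearly. The cortical parcellation is a
deterministic farthest-point partition of the mesh vertices into 219
parcels (the cardinality of the Lausanne125 cortical labels, whose actual
atlas geometry is out of scope); because the mesh is shared, parcel ids
correspond across participants by construction, standing in for
template-space normalization. ROI mean CBF averages valid vertices per
parcel; ROI GM volume assigns each GM voxel to its nearest boundary vertex's
parcel (total GM volume is conserved exactly).

## Consistency evaluation

Within each group and method, every unordered pair of participants
contributes a Pearson correlation over vertices valid in both maps
(n(n−1)/2 pairs; the two patient groups may be concatenated *without*
cross-group pairs). A participant's score is the mean of its incident pair
correlations; the grand mean of participant scores equals the mean of all
pairwise correlations exactly. Methods are compared with paired t-tests on
per-pair differences (default) or a pooled two-sample mode whose degrees
of freedom are 2·n_pairs − 2; both are provided because the two
conventions coexist in practice, and neither is asserted as canonical.
Group differences in mean participant CC use a pooled two-sample t-test
(df = n₁ + n₂ − 2). With operator error (1 mm/1°) exceeding the BBR
residual floor, simulated cohorts rank manual < manual+BBR ≈ FLIRT+BBR in
mean participant CC — the qualitative ordering the consistency framework
is designed to detect.

## Group statistics

ROI-wise hypoperfusion and atrophy contrasts use two-tailed two-sample
t-tests (pooled variance by default, so df = n₁ + n₂ − 2, matching the
degrees of freedom printed in standard reports; Welch optional) with
Bonferroni correction over 219 tests at p_FWE < 0.05. Severity analysis
regresses each ROI's mean CBF on the participant severity score with OLS
(participants lacking scores are excluded; a negative slope is an inverse
association), reported at uncorrected p < 0.05. Demographic comparisons
use pooled t-tests for ordinal variables and chi-squared (no continuity
correction by default) for categorical ones.

The generator couples severity to CBF additively in affected ROIs as
slope · (severity − group mean severity), on top of the multiplicative
group reduction, plus ROI-level Gaussian noise; centering keeps the
group-mean ROI effect equal to the nominal reduction fraction while
producing exactly the linear association the regression estimates. The
ground truth records the *realized* per-parcel reduction
1 − mean_after/mean_before, so effect conservation is exact by
construction.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms at reduced grids —
typically 48×48×40 structural voxels at 2.5 mm and 40×40×24 ASL voxels at
3.75 mm, cohorts of ~13, 8–20 registration recoveries, and
stats-level calibration with 100–200 replicates — sizes chosen so the full
analysis remains exact in structure (28 volumes, 219 parcels, all three
methods) while each run finishes in minutes on one CPU. Error-control and
power checks are performed at the ROI-table level (Gaussian draws at the
generative means), which calibrates the statistics module itself without
re-imaging hundreds of cohorts.

Other numerical details: all resampling is single-pass trilinear;
transforms compose in world coordinates with point_fixed = T(point_moving);
rotation centers are the fixed-image FOV center (intensity registration)
or the boundary centroid (BBR); Powell optimization is derivative-free and
deterministic, with a descent guard that returns the initialization if no
improvement is found; parcellation ties break toward the lowest vertex
index; empty parcels are reported missing and excluded pairwise; t-tests
on zero-variance differences return t = 0, p = 1.

## What passing tests do and do not show

The phantoms share exact geometry across participants, have no scanner
drift, bias fields, distortion, slice-timing effects, background
suppression physics, partial-volume beyond grid resampling, or anatomical
variability, and their "manual" registration is a stochastic model rather
than a human. Passing tests therefore validate the *machinery* — the
kinetic algebra, the cost functions and their optima, the combinatorics,
the error control — under conditions where truth is known; they do not
certify accuracy on real ASL data, where registration difficulty is
dominated by exactly the artifacts the phantoms omit. Effect sizes for the
simulated hypoperfusion groups are package defaults for power
demonstrations, not estimates of any real population.
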