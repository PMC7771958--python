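# Methods

`massp` implements a Bayesian multi-object parcellation of subcortical brain
structures from co-registered multi-channel quantitative MRI (R1, R2*, QSM or
any channel set). The central idea is to model the *interfaces* between
structures explicitly: for every ordered pair (i, j) of delineated
structures, a signed-distance construction defines the thin band "inside i,
next to j", and priors for location, intensity and global volume are learned
for these bands from a small cohort of expert delineations. Inference for a
new subject combines the priors with the subject's intensities voxel by
voxel, regularizes the result spatially and topologically, and finally
commits to disjoint labels by volume-constrained region growing.

## The model

**Interface distances.** Let φ_i be the exact Euclidean signed distance
function of structure i (negative inside, voxel units). The interface band
is described by

    d_i|j(x) = max(φ_i(x), φ_j(x) − δ)   for i ≠ j,
    d_i|i(x) = φ_i(x),

whose non-positive set is exactly "inside i, within δ of j" (for i = j, the
whole interior of i). δ defaults to one voxel — the expected partial-voluming
scale. The alternative clamp `min(φ_i, φ_j − δ, 0)` is available as
`interface_form="printed"` for comparison; it is non-positive everywhere and
degenerates the location prior, so the band form is the default.

**Interface priors.** Across N training subjects, each voxel receives, per
ordered pair, μ = mean of d_i|j,n(x) and σ = population std + δ, and the
unnormalized Gaussian plausibility (2πσ²)^(−1/2) exp(−μ²/2σ²). Only the
K = 16 largest pair entries per voxel are stored (enough for any 3D
interface configuration), and one global factor rescales the map so the 95th
percentile of per-voxel maxima equals 0.95. That percentile is evaluated
over the sampling region (all voxels within 10 mm of any delineated
structure): over the full grid the far-field near-zeros dominate the
percentile and the anchoring rule degenerates.

**Skeleton priors.** The interface prior for i|i peaks on the *boundary* of
i (where φ_i = 0); interior coverage comes from the skeleton (medial axis)
prior. The discrete skeleton is S_i = {x : |∇φ_i| ≤ 1/2, φ_i ≤ −1}: where
opposing distance wavefronts meet, the central-difference gradient of the
SDF collapses. Two numerical choices matter here:

* |∇φ| is computed after a half-voxel Gaussian pre-smoothing of φ. On the
  raw exact EDT, the Voronoi boundaries of discrete surface voxels produce
  spurious gradient minima one to two voxels inside curved boundaries (a
  25³ digital ball grows two dozen false medial voxels without smoothing).
* Medial voxels must be at least one voxel deep (φ ≤ −1); a structure that
  is locally thinner than one voxel cannot carry a medial surface. A
  structure so thin that no voxel qualifies falls back to the single voxel
  of minimum φ, so every structure has a nonempty skeleton.

The skeleton distance field s_i is the unsigned Euclidean distance to the
skeleton set (0 on it); the Gaussian prior construction is the same as for
interfaces, the rescale uses the interface factor, and the stored field is
clipped to never exceed the interior interface prior (skeletons lie inside
their structures; `clip_skeleton=False` disables the clip — on the phantom
the two variants are indistinguishable, Dice differences below 0.02).

**Intensity priors.** Per ordered pair and channel, a 200-bin histogram over
the channel's global range within the sampling region. A voxel of training
subject n contributes to pair (i, j) when it lies in *that subject's own*
interface band (d_i|j,n(x) ≤ 0), weighted by a robust group-consistency
Gaussian N(R_n(x); μ_R(x), σ_R(x)) with μ_R the across-subject median and
σ_R = IQR/1.349 (floored at 1e−6). Two deliberate choices:

* *Per-subject band membership, not the group prior, as histogram weight.*
  The group location prior spills ~1σ outside each structure, so weighting
  by it contaminates every interior histogram with background intensities
  at near-peak weight; in a pilot run this destroyed the likelihood's
  ability to reject background (held-out Dice ≤ 0.17 vs ≥ 0.90 with crisp
  per-subject bands). The subject's own band is known exactly during
  training, so the crisp indicator is both cleaner and cheap.
* *σ_R = IQR/1.349*, the consistent robust estimator of a Gaussian standard
  deviation (the IQR of a standard normal is 1.349).

Histograms are normalized to unit maximum, not unit area, so that the
percentile renormalization at inference time is the only likelihood scaling.
The weighted standard deviation of each histogram is recorded; its median
across pairs gives the per-channel similarity scale of the MRF below.

**Volume priors.** Structure volumes are modeled log-normally: μ_V and
(population) σ_V of log V over the training subjects, in log mm³, with σ_V
floored at 1e−6.

## Inference

1. **Voxel-wise posteriors.** For each pair kept at a voxel, posterior ∝
   spatial term × fused likelihood. The spatial term is the interface prior,
   except for i|i where it is max(P(B_i|i), √P(S_i)) — the square root lifts
   the (sub-unit) skeleton prior and extends coverage deep into each
   structure. Likelihoods are sampled from the histograms (intensities
   outside the range are clamped to edge bins and logged), renormalized per
   channel so the 95th percentile of per-voxel maxima is 0.95, and fused
   across C channels by geometric mean (exponent 1/C).
2. **Markovian diffusion.** A sparse MRF couples each voxel to its four most
   intensity-similar in-region 26-neighbors, selected once from the
   intensities and frozen (similarity ∏_c exp(−ΔR_c²/2σ_c²)). Each
   iteration replaces every kept pair probability with the
   similarity-weighted average over the 5-voxel neighborhood, weights
   normalized to sum to one (the unnormalized update is not
   mass-preserving and decays under iteration). Iteration stops when the
   fraction of changed argmax labels over the region drops below
   `stop_ratio` (default 0.001; the coarser 0.1 is selectable) or at
   `max_iter` = 200 (flagged as non-converged). On the crisp phantom
   contrasts convergence takes under ~15 iterations; noisier, lower-contrast
   data takes proportionally longer.
3. **Topology correction.** Per structure, the posterior is the max over its
   kept pairs, then corrected by topology-preserving fast marching: voxels
   are accepted in decreasing posterior order from the global maximum, only
   when acceptance is a simple point for (26, 6) foreground/background
   connectivity; each accepted value is lowered to the running minimum, so
   every superlevel set of the output is a single 26-component with simply
   connected complement ("spherical object topology"). Voxels popped while
   non-simple are re-queued when a neighbor is accepted; never-acceptable
   voxels (e.g. a second blob, a cavity center) are capped just below the
   smallest accepted value. The pass is idempotent and never raises values.
4. **Volume targets.** The observed volume is the argmax parcellation of the
   corrected posteriors thresholded at 0.5 (on the 0.95-anchored
   probability scale; the threshold is exposed as
   `membership_threshold`). The target blends observation and prior,
   V̂ = P·V + (1−P)·exp(μ_V) with P = exp(−(ln V − μ_V)²/2σ_V²) — an
   unnormalized log-Gaussian plausibility, so implausible observations
   (including an empty one) fall back to the prior mean and every structure
   can grow to a plausible size.
5. **Region growing.** All structures grow concurrently from their corrected
   posterior maxima through a single global priority queue; the priority of
   growing from x into neighbor y for structure i is
   [P_i(y) − max_{j≠i} P_j(y)] − |P(y∈S_i) − P(x∈S_i)|,
   the second term steering growth along isocontours of the skeleton prior
   so regions keep their intrinsic shape. A popped voxel is assigned iff
   still unassigned and the structure is under its voxel budget
   round(V̂_i / voxel volume); ties break by higher candidate posterior,
   then lexicographic voxel index, then structure index, making the whole
   pipeline bit-deterministic. Voxels never reached remain background.

## Evaluation metrics

Dice 2|A∩B|/(|A|+|B|); dilated Dice (|A∩d(B)|+|B∩d(A)|)/(|A|+|B|) with d a
one-voxel 26-neighborhood dilation — overlap allowing one voxel of boundary
uncertainty, always ≥ Dice; average surface distance: symmetric mean over
each set's boundary voxels (inside voxels with an outside 6-neighbor) of the
Euclidean distance to the other boundary, reported in voxels and mm; volume
bias: mean signed relative volume error. Local structure thickness is
th(x) = 2(s(x) − φ(x)), the caliper width (2R on a ball of radius R, T on a
slab of thickness T, within one voxel on digital shapes).

## The synthetic cohort

The phantom generator emulates the training situation at desk scale: a 64³,
1 mm isotropic grid with seven structures spanning the difficult size/shape
regimes — a large ellipsoid (~1800 voxels, thalamus-like), a medium ball
sharing an interface with it (striatum-like), a two-shell pair
(internal/external pallidum analogue, the inner fully enclosed), a thin
curved sheet (~400 voxels, claustrum analogue), a tube (ventricle analogue)
and a small ball of ~130 voxels (subthalamic-nucleus analogue). Three
channels carry R1-, R2*- and susceptibility-like value ranges with distinct
per-structure means. Inter-subject anatomical variability is a smooth random
displacement field (Gaussian noise smoothed at 8 mm, scaled to 2 mm RMS;
per-structure volume CVs land at 7–15%, a realistic anatomical range);
intensity variability is a per-subject Gaussian shift of each structure's
channel means plus voxel noise. Labels are warped by nearest-neighbor
sampling so boundaries stay crisp; a deformation that empties any structure
rejects the spec. Cohorts default to ten subjects, the usual
atlas-building cohort size, with subject seeds derived as spec.seed + index.

What the phantom does *not* emulate: MRI bias fields, partial-volume mixing
beyond the boundary voxel, spatially correlated noise, registration error,
and the low inter-structure contrast of real subcortical tissue. Passing the
phantom suite therefore demonstrates the correctness and stability of the
machinery — not the accuracy level to expect on real data, where contrasts
are weaker and boundaries genuinely ambiguous.

## Problem sizes and defaults

Experiments run on the 64³ ten-subject cohort (leave-one-out: atlas from
nine, test on the tenth, all ten folds in a few minutes on one core); dense
all-pairs oracle checks use a 24³ three-structure cohort where the full S²
pair computation is cheap. Defaults throughout: δ = 1 voxel, K = 16, 200
bins, 10 mm sampling radius, stop ratio 0.001, (26, 6) connectivity.

## Known limitations

* Registration is out of scope: all inputs must share one grid; the package
  rejects grid mismatches rather than resampling.
* The dense all-pairs prior pass scales as S² volumes; fine for tens of
  structures, wasteful for hundreds.
* Anisotropic voxels are handled by the mm-aware region/volume computations,
  but the skeleton gradient threshold assumes near-isotropic voxels (the
  phantom grids are isotropic, so this choice is untested on strongly
  anisotropic data).
* Background is implicit: voxels no structure claims within its budget. An
  explicit background intensity model could sharpen boundaries further.
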