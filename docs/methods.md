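# Methods

This note documents the models, algorithms and numerical choices behind
`axonmatch`, and what the synthetic test substrate does and does not show
about real data.

## Problem setting

A tissue volume is imaged twice: first with 3D confocal fluorescence
microscopy (LM), in which a sparse subset of axons carries a label, then
with dense 3D electron microscopy (EM), in which *every* neurite can be
reconstructed but the label is invisible.  Intrinsic fiducials (blood-vessel
bifurcations) support a coarse LM→EM registration with a precision
λ_align of roughly 5–10 µm — far coarser than the ~1 µm spacing of axons in
neuropil, so a transformed LM axon initially overlaps dozens of EM
candidates.  The toolchain identifies labeled axons in the EM volume anyway,
by exploiting the fact that axonal *trajectories* become unique over tens of
micrometres.

All geometry is carried in physical nanometres.  Voxel-to-nm conversion
happens exactly once, at I/O time, using the voxel size declared in the data
(the NML `<scale>` element; SWC positions are interpreted as micrometres).
Membership predicates are closed: a node on a box face or exactly at
distance r counts as inside.  Skeletons are strict trees; cyclic inputs are
rejected rather than repaired (only duplicate edges have an explicit repair
utility), because a silent repair would change path lengths.

## Marching-sphere uniqueness (d_unique, d_unique90)

Given all axons traversing a cubic seed box of edge λ_align, each reference
axon is resampled to 500 nm node spacing (so results do not depend on
annotator node density) and a sphere of radius λ_align is placed on every
node.  For each other axon this yields a binary presence vector; nodes are
sorted by Euclidean distance from the *seed-box center* and pooled into 1 µm
bins.  A neighbor's dropout distance is the lower edge of the last bin in
which it appears — the **final** true→false transition, so an axon that
leaves and re-enters the λ-surround counts as present until it leaves for
good ("persistently within").  This convention makes the candidate-count
curve of the matching stage monotonically non-increasing.  d_unique of an
axon is the maximum dropout distance over its neighbors; a neighbor present
in the reference's last occupied bin means the axon never becomes unique
within the dataset.  d_unique90 is the smallest binned distance at which 90%
of axons are unique.

Choices worth making explicit:

* distances are measured from the box **center** (the box "origin" would
  shift every distance by up to half a box diagonal);
* bin width (1 µm) and resampling spacing (500 nm) are configuration knobs;
  dropout distances are reported at the bin's lower edge, so two
  implementations can only disagree by one bin;
* the λ sweep rescales the seed box edge together with the sphere radius.
  When the traversing set is held fixed (axons seeded inside the smallest
  box), presence vectors grow monotonically with λ, which makes
  "d_unique90 non-decreasing in λ" exact; with per-λ reselection it holds
  only statistically.

The layer-comparison bootstrap draws 30 subsamples of 128 axons (without
replacement) from one population's per-axon d_unique values, measures
d_unique90 on each, and runs a one-sample t-test against the other
population's d_unique90 — controlling for unequal axon counts between
datasets.  Constant draws make the t statistic undefined; this is flagged
rather than silently converted.

## Landmark registration

**Affine.**  The transform family is `y = R·diag(s)·x + t` with a unit
quaternion R, a per-axis positive scale s of the source frame, and a
translation t.  Anisotropic scale matters because EM processing shrinks
tissue differently along the cutting axis.  Horn's closed-form absolute
orientation solves the rigid part; the scale vector is optimized by block
coordinate descent in which *both* blocks are closed-form (Horn refit on the
scaled source; exact per-axis least-squares scale update
`s_a = Σ x_a·[Rᵀ(y−t)]_a / Σ x_a²`), iterated until the relative MSE
improvement falls below 1e-12 (at most 500 rounds).  The iteration starts
from Horn's isotropic-scale solution and is monotone in MSE, so the result
is never worse than any isotropic-scale Horn fit.  Degenerate geometry
(fewer than 3 pairs, collinear points) raises instead of returning an
ill-conditioned fit.  Note the family is anisotropic in the *source* axes:
it is closed under rigid re-expression of the target frame and translation
of the source frame, but not under source-frame rotations.

**Free-form.**  A multi-level cubic B-spline displacement field is added on
top of the affine: level 0 fits the residuals `em − affine(lm)` as a
function of the affine-frame position on a knot lattice with 32 µm spacing;
each of the (default four) refinement levels halves the knot spacing and
fits what remains.  Each level solves a damped least-squares problem (LSQR,
damp = √ridge with ridge = 1e-3) on the 64-entry-per-point tensor-product
design matrix; the damping keeps lattice cells with fewer than a handful of
control points stable and biases unconstrained coefficients to zero.  The
zero solution is always feasible, so training residual is non-increasing
across levels.  The lattice covers the control-point bounding box plus one
full knot margin; points outside a level's support receive zero displacement
from that level.  Per-level residual fitting (rather than one joint
multi-level solve) was chosen for its standard coarse-to-fine behavior and
because the increments are individually regularized.

**Residuals and the control-point curve.**  Registration error is the
Euclidean distance ‖cp_EM − T(cp_LM)‖ on held-out pairs, reported as
mean ± sd and median.  The bootstrap curve fits on n ∈ {5, 10, 25, 50, 75,
100, 150, 200, 250} randomly drawn constraint pairs, measures the mean
residual on 30 disjoint held-out pairs, and repeats 10 times per count, all
from one seeded generator recorded in the report.

A note on validating free-form recovery: a fixed smooth deformation is
partially linear over any bounded region, so the fitted affine absorbs part
of it and the spline field alone is *not* comparable to the generating
field.  Recovery is therefore measured as the RMS error of the total fitted
map against the total generating map on a probe grid, relative to the RMS
magnitude of the generating displacement field.

## Matching

The initial match ranks all EM axons traversing the seed box by how far
along the coarsely transformed LM template they remain persistently within
λ_align (same binning and final-dropout rule as the uniqueness analysis).
Never-dropping candidates rank first, then larger dropout distance; ties are
broken by the smaller mean distance from template nodes to the candidate —
trajectory similarity.  The tie-break is what keeps recovery high even when
two straight, near-parallel axons both persist to the dataset boundary: the
true partner hugs the template at the registration error (≈2 µm) while an
impostor sits a few µm away on average.  An empty candidate set raises an
error telling the user to widen the box (the tool does not decide when a
human must reconstruct more axons).

Later matches use varicosity-seeded reduced search: a (2×2×3) µm box around
a transformed LM varicosity, keeping only candidates with an annotated
varicosity inside; the box grows by ×1.5 per step (at most 5 steps) while
that subset is empty, and falls back to the full intersecting set with a
warning.  Each accepted match appends its varicosity/branchpoint control
points (validated to lie within 500 nm of a node on both matched axons),
refits the registration — affine below 20 accumulated pairs, free-form from
20 up — and logs effort.  Re-matching an LM axon is a conflict error.

## Varicosity statistics

* Equivalent sphere diameter: d = 2·(3V/4π)^(1/3).  EM volumes enter as
  voxel counts × voxel volume (voxel segmentation itself is out of scope);
  LM volumes come from Gaussian-plus-baseline fits to intensity profiles
  along the three principal axes, V = (π/6)·FWHM₁·FWHM₂·FWHM₃ with
  FWHM = 2√(2 ln 2)·σ above the local baseline.
* The pattern-match randomization test scores the mean distance from each
  (transformed) LM varicosity to its **nearest** EM varicosity (the pairing
  rule is a design choice; index pairing would require an ordering the data
  does not provide).  The null re-places the same number of EM varicosities
  uniformly on the nodes of the EM skeleton, resampled to 500 nm spacing so
  annotator node density does not bias the null, without replacement within
  a draw; 100,000 draws by default.  p uses the +1 correction,
  p = (1 + #{null ≤ observed})/(n_draws + 1), so p ≥ 1/(n_draws+1) and the
  test is exact under ties.
* Bouton likelihood: Gaussian KDE per diameter class with a fixed 100 nm
  bandwidth (the bandwidth is absolute, not a data-driven factor), weighted
  by class prevalence and normalized pointwise so the two likelihoods sum
  to 1; evaluation grid 0–2000 nm in 10 nm steps.  A fixed-bandwidth KDE
  estimates the class density convolved with its kernel, so the correct
  closed-form reference for Gaussian classes N(µ, σ²) is the posterior of
  N(µ, σ² + h²); tests compare against that.

## Matched-signal fraction and labeling density

LM planes are binarized per plane (Otsu by default — the exact recipe is a
package choice; a manual threshold can be supplied) and segmented into
8-connected 2D components.  Skeletons are resampled below the voxel pitch,
rasterized to the voxel grid, and dilated by one voxel (3D Chebyshev) to
absorb rasterization error; a component counts as matched when it intersects
that raster.  The matched fraction of a plane is matched suprathreshold
voxels over all suprathreshold voxels — monotone in the matched set by
construction.  Labeling density is the suprathreshold voxel fraction per
plane.

## Synthetic scenes

The generator emulates the study geometry: by default 220 axons seeded
inside a (5 µm)³ box at the center of a 130×110×85 µm³ volume (so all of
them traverse it), a labeled fraction of 15% visible in LM, a ground-truth
LM→EM map (mild rotation, anisotropic scale, plus a separable sinusoidal
displacement of 2 µm amplitude and 100 µm wavelength — smooth and
analytically invertible by fixed-point iteration), 100 nm LM annotation
jitter, fragmentation of LM axons at 0.1 breaks per 10 µm (mean fragment
≈ 95 µm, emulating finite reconstructable length), and varicosities with
exponential 8 µm path spacing in two diameter classes (boutons
N(1100, 250²) nm at 60% prevalence, non-synaptic N(600, 150²) nm).

Trajectories are persistent random walks: 1 µm steps with von Mises–Fisher
directional persistence κ = 40 (persistence length ≈ κ·step ≈ 40 µm, gentle
cortical-axon-like curvature).  κ→∞ gives straight lines, for which dropout
distances have closed-form counterparts used as test oracles.

**What the model does not capture.**  Independently seeded random
directions produce more near-parallel axon pairs than real neuropil: on the
default scene roughly half the axons retain some neighbor within λ = 5 µm
all the way to the dataset boundary, so the fraction-unique curve saturates
near 0.5 and d_unique90 is undefined at λ = 5 µm — unlike real cortical
data, where axon trajectories decorrelate faster and ~90% become unique
within a few tens of µm.  Passing tests on these scenes therefore
demonstrate the *machinery* (exactness of the marching-sphere measurement
against brute force, monotonicity in λ, ≥95% matching recovery under a
2 µm deformation), not the empirical uniqueness statistics of tissue.
Matching recovery is evaluated on LM fragments of at least 40 µm, the scale
at which these scenes' fraction-unique curves saturate.

Everything is reproducible bit-for-bit from (config, seed), and every CLI
report embeds the resolved configuration and seed.

## Problem sizes in the standard runs

The test suite and the acceptance script run the full default scene
(220 axons, 130×110×85 µm³) for matching, 30-axon scenes for
oracle-equivalence (20 seeds), 25-axon scenes for the λ sweep, 200
calibration repeats at 5,000 randomization draws (100,000 draws for the
single headline test), and 10⁴ samples per class for the KDE comparison.
These sizes keep a complete run in the low tens of seconds on one CPU while
leaving every statistical check well-powered.

## Known limitations

* No diffeomorphic guarantee for the free-form field; strong folds are not
  prevented (ridge damping only discourages them).
* The uniqueness measurement reports distances at bin resolution (1 µm);
  sub-bin comparisons between implementations are not meaningful.
* The LM-volume estimator assumes a single dominant peak per intensity
  profile; overlapping varicosities need manual axes.
* The synthetic trajectory model is minimal (see above); it is a test
  substrate, not a biophysical morphology model.
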