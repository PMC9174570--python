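# Methods

## Scope and model

dissectflow quantifies hemodynamics from gridded 4D phase-contrast
velocity data **v**(r, t) (3 spatial components × cardiac phase) with a
labeled lumen segmentation. All geometry lives in world millimetres
(NIfTI affine), velocities in m/s, flow rates in mL/s and per-cycle
volumes in mL — with these units a flux integral Σ s·dA (s in m/s, dA
in mm²) is numerically in mL/s, so no unit constants appear in the
quantification code. Cardiac phases are assumed uniformly spaced over
the RR interval (retrospective gating); time integrals use the
rectangle rule, cycle averages the uniform mean over phases.

Flow direction is defined against the vessel centerline: the signed
through-plane speed is s = v · t̂ with t̂ the local unit tangent,
oriented proximal → distal by the seed landmark. Forward flow is the
flux of max(s, 0), reverse flow of min(s, 0); net = forward + reverse
holds exactly per phase and per section because the decomposition is
performed sample-wise before summation.

Stasis is the percentage of phases with velocity *magnitude* below the
threshold (default 0.1 m/s). Magnitude — not the through-plane
component — is the only voxel-wise reading that yields a meaningful
parametric map; an alternative flow-rate reading of the same threshold
exists in the literature but cannot be evaluated per voxel.

Helicity density is H = v · (∇ × v) in m/s²; its sign encodes the
rotation handedness. Profiles along the centerline report the
*mean* H and mean |H| per cross-section over false-lumen samples rather
than area integrals, so values are comparable across grid resolutions.
|mean H| ≤ mean |H| per section, with equality iff H is single-signed
there.

## Pipeline stages and the parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| stasis threshold | 0.1 | m/s | speed below which a phase counts as static |
| centerline resampling | 1.0 | mm | cross-section spacing |
| smoothing window | 5 | mm | moving average before tangent estimation |
| prune length | 5 | mm | spur length removed from the skeleton |
| section radius | 30 | mm | in-plane cutoff so a plane cannot capture the FL limb twice where it wraps around the TL |
| stent threshold | auto | (m/s)/mm summed over phases | exclusion cut on the gradient image G |
| septum closing radius | 1 | voxel | morphological closing before thinning on dissections |

### Stent-artifact exclusion

Metallic stents corrupt the phase signal locally. The detector computes
G = Σ_t ‖∇ v_FH‖ on the foot-head component only and excludes voxels
with G above a threshold. Two deliberate choices:

* **Gradient operator.** Per axis, G uses the *minimum* of the forward
  and backward one-sided difference magnitudes rather than central
  differences. A centered stencil skips the voxel itself, so an
  isolated corrupted voxel scores low while its clean neighbors score
  high — exactly backwards. The min-of-one-sided form is large only
  where the voxel deviates from *both* neighbors, which localizes the
  exclusion to the corrupted voxels themselves. Plain central
  differences remain available (`robust=False`).
* **Auto threshold.** The default is median + 10·MAD of G over the
  lumen. A percentile rule would excise a fixed fraction of voxels
  regardless of whether any artifact exists; the robust outlier rule
  excludes essentially nothing on clean data and scales with the
  artifact burden. Numeric and percentile modes are exposed for users
  who calibrated a threshold on their own scanner. The raw-phase
  frequency units sometimes quoted for such thresholds presuppose data
  this package does not consume; the threshold here lives in velocity
  gradient units.

Excluded voxels become holes in the labeled mask — no interpolation or
infill at the map level. At the flux-integral level, however,
`section_flow` by default rescales a section's flux by the
sampled-area fraction (1 + n_excluded/n_valid): excluded samples are
lumen whose velocity was discarded, and for artifact exclusion
unrelated to the local velocity the rescaled integral is an unbiased
estimate of the full-lumen flux. The raw valid-sample integral is
available via `compensate_excluded=False`.

### Centerline

The centerline is computed on the *combined* TL+FL(+ascending) mask by
topology-preserving 3-D thinning (Lee's algorithm). On a dissection the
zero-velocity septum disconnects the two lumens, so a morphological
closing (default radius 1 voxel) precedes thinning — this is what
"the combined lumen" means operationally. The skeleton voxel nearest
the proximal seed anchors the curve; the geodesically farthest voxel
defines the distal end; the shortest skeleton path between them is the
centerline. Side spurs shorter than the prune length vanish silently,
longer branches (arch-vessel stubs) are also off the main path but
counted in the log; ties for the distal end break on the
lexicographically smallest voxel index so runs are deterministic.

The curve is smoothed by a 5 mm moving average (odd reflection at the
endpoints, so straight segments — ends included — are fixed points)
before arclength-uniform resampling at 1 mm; tangents come from central
differences of the smoothed curve. Without smoothing, voxel-level
jaggedness leaks into the tangents and corrupts the forward/reverse
split.

Cross-sections sample an in-plane lattice at the voxel resolution:
labels nearest-neighbor (categorical), velocities trilinear. Samples
beyond the section radius are dropped.

### Parametric maps

FF/RF maps assign each lumen voxel the tangent of its nearest
centerline point (ties to lower arclength) and accumulate through-plane
*volume*: FF = Σ_t max(s,0)·Δt·A_eff with A_eff = voxel volume /
centerline spacing. This makes map sums over a centerline band
reconcile with the per-section volumes (the `band_sums` helper does the
aggregation, widening to whole voxel slabs because the grid is coarser
than the 1 mm centerline sampling).

### Vorticity and helicity

The curl uses spacing-aware differences restricted to the mask: central
where both neighbors are inside, one-sided at mask boundaries, missing
(NaN) where a direction has no in-mask neighbor. Boundary voxels (any
6-neighbor outside) are flagged and excluded from profile means by
default — one-sided differences are the least accurate there. Fields
that are linear in the coordinates (rigid rotation + uniform axial
flow) are differentiated exactly by every branch of this scheme; the
discretization-convergence checks therefore use a parabolic axial
profile, whose quadratic velocity leaves a genuine, spacing-dependent
one-sided-difference error at the boundary while keeping the closed
form H ≡ 2Ωv₀ (the radial terms cancel).

### Statistics

The pre/post comparison uses the two-sided Wilcoxon signed-rank test:
zero differences dropped, mid-ranks for ties, exact p by the
generating-polynomial convolution of the (doubled) ranks for up to 20
effective pairs — the exact distribution is symmetric about half the
rank sum even under ties, and the two-sided p is the symmetric tail
probability — and a tie-corrected normal approximation with continuity
correction beyond. Stent agreement uses ICC(A,1), the two-way
mixed-effects absolute-agreement single-measure coefficient, computed
from the explicit ANOVA decomposition; absolute agreement (not
consistency) is the right model because a constant intra-stent bias is
a real disagreement. ICC(C,1) is exposed for comparison.

## The synthetic phantoms

The phantom module emulates the statistical and physical structure the
analysis assumes, with closed-form ground truth:

* **Straight tube / U-bend**: Poiseuille profile v(r,t) =
  v_peak(1 − r²/R²)w(t); Q(t) = w(t)·v_peak·πR²/2. The U-bend is a
  half-torus with straight inflow/outflow legs (2R) so thinning end
  erosion stays outside the bend whose arclength (πR_bend) is the
  geometric oracle.
* **Helical**: rigid in-plane rotation Ω×r plus axial flow; vorticity
  exactly 2Ω, helicity density 2Ω·v_z (uniform axial) or the constant
  2Ω·v₀ (parabolic axial).
* **Dissection**: a proximal single-lumen "ascending" segment feeding
  two half-lumens split by a 1-voxel septum. Smooth in-plane profiles
  (zero at walls and septum) are normalized by their *discrete* slice
  integral, so the prescribed flow split is exact for the rasterized
  field: TL carries tl_fraction of the inflow forward under the spec
  waveform; the FL waveform is piecewise constant, forward then
  retrograde, meeting the (1−tl)(1−r)V and (1−tl)rV volume targets
  exactly. Options: entry-tear jet through a septum gap, a distal FL
  stasis pocket (velocities × 0.05 over the distal quarter), a side
  branch with a prescribed flow fraction.
* **Noise**: additive i.i.d. Gaussian per component/phase/voxel, one
  seeded generator threaded through every stochastic call; identical
  spec + seed ⇒ byte-identical output.
* **Stent noise**: checkerboard sign-alternating (space and time)
  perturbations of the FH component in a chosen voxel set, with
  magnitude jitter bounded below so every region voxel provably
  differs from the input.

Ground-truth stasis is reported two ways: the noise-free indicator
fraction, and the *expected* stasis under the generator's own noise —
per sample P(‖v₀+ε‖ < thr) from the noncentral-χ² CDF with 3 dof. The
noise-aware value is what an unbiased analysis of the noisy field
recovers (a zero-velocity pocket under SD 0.05 m/s noise has expected
stasis ≈ 74%, not 100%).

Defaults mirror a typical aortic protocol: 2.5 mm isotropic voxels, 20
reconstructed phases, VENC 150 cm/s, RR 1000 ms. The systolic-pulse
waveform is sin²(πt/0.35) over the first 35% of the cycle with a 0.05
diastolic level — a generic shape chosen once for realism, not a fit to
any cohort. The dissection default of 70 mL/cycle inflow corresponds to
a normal cardiac output at 60 bpm.

**What the phantoms do not emulate** — and hence what passing tests do
not establish about patient data: MR acquisition physics (k-space,
eddy currents, Maxwell terms), velocity aliasing (only flagged),
background phase offsets, segmentation error, wall motion and
compliance, turbulence, and anatomically realistic curved/wrapped
false lumens. The phantoms validate the *quantification operators*
against known fields, not the acquisition chain.

## Numerical choices and degenerate inputs

* Voxel rasterization: a voxel is lumen iff its center is inside the
  analytic geometry; tolerance budgets (2% flux, 5% helicity) absorb
  the partial-volume error. Phantom grids use odd in-plane dimensions
  so tube axes pass through voxel centers — Lee thinning can erode a
  cylinder to nothing when the medial axis falls between voxels.
* Interpolation: trilinear for velocity (zero constant extension
  outside the grid, matching the zero background), nearest-neighbor
  for labels.
* Empty sections, absent labels, zero-length profiles are flagged
  results, not errors; all-zero difference vectors (Wilcoxon) and
  zero-variance pairs (ICC) return degenerate-flagged results (p = 1,
  NaN). Relative change from a zero baseline is missing (NaN) unless
  the value stayed zero, which is a zero change.
* Aliased phase values are flagged with a warning and never clamped.

## Problem sizes

The test suite and the acceptance script run phantoms of 15–25 voxel
in-plane extent and 40–160 mm length at 2.5 mm spacing (the
convergence series refines to 0.625 mm on a short 20 mm tube), 1–20
cardiac phases — sizes chosen so the full suite completes in seconds
on one CPU while every oracle retains a comfortable margin over its
tolerance.

## Known limitations

* The centerline is a single proximal→distal curve; per-lumen
  centerlines and branch centerlines are out of scope (branch flows use
  manually placed planes).
* Flux-area compensation for excluded samples assumes exclusion is
  uncorrelated with velocity; a stent artifact that systematically
  covers the high-velocity core would bias the rescaled flux.
* Helicity profile values at sections where the false lumen is thinner
  than ~3 voxels rest on few interior samples and are noisy; the
  n_samples column in the profile output is the quality indicator.
* The Wilcoxon implementation's affine invariance is tested; general
  strictly-monotone transforms can reorder absolute differences and
  change the signed-rank p — that is a property of the test itself.
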