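# Methods

`lvdose` asks a dosimetric question with a fully synthetic instrument: how
far can the x-ray tube current of a cardiac CT acquisition be reduced
before left-ventricular (LV) functional metrics derived from automatic
segmentations stop being trustworthy?  Because every stage — anatomy,
scanner, observer, measurement — is simulated, the answer can be checked
against exact ground truth at every step.

## The phantom and its closed-form ground truth

The LV is a truncated prolate-spheroid shell in a canonical pose (long
axis along +z, apex at −z).  At end-diastole (ED) the endocardial and
epicardial surfaces are concentric spheroids with semi-axes
(a_en, c_en) and (a_ep, c_ep); the blood pool is the endocardial interior
truncated by a basal plane at `base_truncation_frac · c_en` above the
centre (default 0.5), and the myocardial shell closes over the cavity with
a basal lid one apical-wall-thickness deep, so the pool is always enclosed
by myocardium.  Default HU values are 40 (background soft tissue), 100
(myocardium) and 350 (contrast-enhanced blood).

End-systole (ES) scales the endocardial semi-axes by
`es_radial_scale` (s_r) and `es_long_scale` (s_l) **about the apex**: the
apex stays fixed while the base descends, emulating mitral-annular
descent.  This choice matters: scaling about the centre would pull the
apical short-axis plane off the ES ventricle for physiological strains.
The epicardium follows one of two rules:

* `volume-preserving` (default): the epicardial long semi-axis follows the
  endocardium (c_ep′ = s_l·c_ep) and the short semi-axis is solved in
  closed form so the truncated-shell (myocardial) volume is conserved —
  myocardium is nearly incompressible, and this guarantees genuine wall
  thickening;
* `fixed-thickness`: the ED wall thickness along each canonical axis is
  kept.

Every surface being an ellipsoid gives closed forms for all four metrics
(ED is the reference phase, shortening negative):

* EF = 100·(1 − s_r²·s_l), from truncated-spheroid cavity volumes
  V = π a² c (2/3 + f − f³/3);
* GLS = 100·(s_l − 1), from the apex-to-basal-plane cavity length;
* CS per short-axis level = 100·(r_ES/r_ED − 1) with r the endocardial
  ellipse radius at the (fixed, ED-derived) plane height;
* WT per level = 100·(t_ES − t_ED)/t_ED with t the radial wall thickness
  at that plane.

The ground-truth evaluator uses the same plane convention as the
measurement chain (planes at fractions 0.8/0.5/0.2 of the epicardial-apex
→ basal-cut axis, fixed in space for both phases), so measured-vs-analytic
comparisons are apples-to-apples.

`build_phantom_spec(target_ef_pct=...)` solves s_r by 1-D root finding
(Brent) on the analytic EF with s_l held fixed.  Cohorts draw axes, wall
thicknesses, s_l, EF targets and uniformly random orientations
(quaternion method) from stated ranges; defaults span roughly 22–30 mm
endocardial short semi-axes, 40–50 mm long semi-axes, 6–10 mm walls, EF
targets 20–70% — normal through severely reduced function.

Voxelization is an analytic inside-test at voxel centres on the rotated
surfaces (default grid 96³ at 1.5 mm; tests also use 147³ at 1.0 mm). A
caveat learned the hard way: when a flat cut plane coincides exactly with
a layer of voxel centres, voxel counts acquire a half-layer bias; odd-sized
1 mm grids keep the default phantom generic.  Randomly oriented cohort
members do not suffer from this alignment.

## The simulated scanner

A deliberately simple parallel-beam, per-axial-slice scanner stands in for
the clinical wide-coverage system: the study's question concerns noise
level, not geometry.  HU volumes are converted to attenuation
μ = μ_water·(1 + HU/1000), clamped at zero, resampled per slice onto the
detector-pitch grid, masked to the inscribed field-of-view circle, and
Radon-transformed (scikit-image) into sinograms of dimensionless line
integrals.  Reconstruction is per-slice filtered back-projection with a
Hann-apodised ramp filter — the surrogate for a clinical "standard"
kernel.  Defaults: 192 detectors × 1.0 mm, 180 angles, μ_water
0.020/mm; the desk-scale experiments use 96 × 1.6 mm and 96 angles.

Noise enters in the projection (count) domain:
`N = Poisson(I0·e^(−p)) + Normal(0, σ_e²)`, with counts floored at 0.1
before the log (photon-starvation guard) and `p_noisy = ln(I0/N)`.  Flux
scales linearly with tube current, I0(mA) = I0_ref·mA/500, with
I0_ref = 10⁵ photons/ray and σ_e = 10 counts.  These are artifact
calibrations, not physical claims: they put the standard-dose
reconstruction at ≈16 HU noise (clinically plausible) and the 10 mA rung
at ≈90 HU — degraded to the point where automatic analysis begins to
fail, which is the regime the dose ladder is meant to probe, while
keeping adjacent rungs statistically distinguishable for the observers.  The delta-method log-domain variance
(N̄+σ_e²)/N̄² agrees with Monte-Carlo simulation to a few percent at the
fluxes used.

Low doses are emulated, not re-scanned: per ray, zero-mean Gaussian noise
with the *incremental* variance (low-dose minus standard-dose predicted
variance) is added to the measured standard-dose sinogram.  The ensemble
mean and variance of the emulated sinogram then match a direct low-dose
acquisition (validated by Monte Carlo in the tests); the Gaussian
approximation thins at 10 mA where counts are low, which is why a direct
simulation mode exists for cross-checks.  The paired design — every rung
of a case's ladder shares the same underlying anatomy and standard-dose
noise realisation — mirrors how clinical noise-insertion studies avoid
repeated patient scans.

## Observers

**Rule-based.**  Gaussian pre-smoothing (σ = 1 voxel), two ordered HU
thresholds (70, 225 — the midpoints of the phantom's class HU values),
largest-connected-component selection and hole filling per class.
Deterministic, training-free; it anchors the ladder experiments and the
tests that must not depend on training.

**Residual 3D U-Net.**  Four encoder–decoder levels, two residual blocks
per level (conv–ReLU–conv with identity shortcut), channel doubling on
descent, additive skips, deep supervision via 1×1×1 heads at the three
decoder resolutions (weights 1/0.5/0.25), generalized Dice loss on softmax
probabilities, Adam.  The engine is a compact NumPy implementation with
hand-written backprop (im2col convolutions; the input gradient is the
correlation with the flipped, channel-transposed kernel), verified against
finite differences.  Two stability choices substitute for normalisation
layers: the second convolution of every residual block and all heads are
zero-initialised (near-identity start), and inputs are affinely normalised
((HU−150)/200) and clipped to ±3 so the out-of-FOV corners (≈−1000 HU)
cannot push activations outside the training distribution.  Inference is
sliding-window with averaged probabilities, argmax (ties to the lower
class index), then largest-component cleanup per foreground class —
standard cardiac-segmentation post-processing that removes stray islands.

Two training recipes realise the study arms: the *Standard* observer
trains on standard-dose images only; the *Noise-Robust* observer trains on
the standard-dose plus emulated low-dose ladder of the same cases.  Both
arms use a fixed number of patch draws per epoch so their optimisation
budgets match.  A continuous-learning mode (warm-starting the Noise-Robust
observer from the trained Standard observer via
``train_observer(init_from=...)``) is available; in the scaled-down
experiments the extra-trained warm-started observer is sharper, which
raises its accuracy against ground truth at every dose but slightly
lowers its dose-to-dose self-consistency, so the matched-budget
from-scratch arms are the default comparison.  The desk-scale configuration (4 base
channels, 32×32×16 patches, 60 epochs × 16 draws, lr 10⁻³, batch 2,
foreground-biased sampling at 0.9) trains in a few CPU-minutes; the
validation battery asserts median held-out myocardium Dice of at least
0.70 against generator labels at the standard dose (observed around 0.8,
with blood pool around 0.95).  Paper-scale settings (32 channels,
128×128×64 patches, lr 5×10⁻⁴, batch 32, 200 epochs) remain available in
the configuration but are not CPU-practical.  No data augmentation is
used.

## Views and measurement

The long axis is the principal eigenvector of the blood pool's second
central moment tensor (an eigenvalue ratio below 1.2 is a degenerate-axis
error).  The basal end is identified from the cavity's cross-section area
profile along the axis — the cavity ends basally in a flat cut (large
terminal area) and tapers to a point apically — and the apex is the
myocardial extreme on the opposite side.  Five planes are resampled: two
long-axis views (2-CH and PLAX, azimuths 0° and 90° about the axis) and
three short-axis views at fractions 0.8/0.5/0.2 of the apex→base length.
ED-derived planes are reused for the ES phase so strains compare
corresponding planes; a per-phase mode exists.  Labels are resampled
nearest-neighbour; measurement additionally uses per-class float masks
resampled trilinearly and averaged over a thin 3 mm slab (three
sub-planes), which suppresses voxel-quantisation bias the way clinical
thick-slab reformats do.

Measurements on views use integral estimators rather than single
crossings: a star-shaped region's radius along a ray equals the integral
of its mask along that ray, and the wall thickness equals the integrated
myocardium occupancy — both average out partial-volume quantisation.
Endocardial contours for CS are traced by 360 rays from the pool centroid;
the radius function is smoothed by truncating its angular Fourier series
at harmonic 8 (cross-sections of any rotated ellipsoid live in the low
harmonics; the jitter that would otherwise inflate the polygon perimeter
does not).  WT uses 16 equally spaced spokes about each phase's own
centroid, matched by angular index; a spoke that misses the ring is
flagged missing, more than 4 missing is an error.  An obliterated cavity
at ES reports CS = −100 with a flag.  EF is computed in native
coordinates from blood-pool voxel volumes.  With generator labels at 1 mm,
recovery errors against the closed forms are ≤ ~0.4 pp (EF, GLS, CS) and
≤ ~1.6 pp (average WT) across a 10-phantom cohort — within the 1 pp / 2 pp
bands the tests assert.

## The dose-ladder study

For each case and phase the ideal sinogram is computed once, measured at
the standard dose, and each lower rung is emulated from that measurement;
all rungs are reconstructed on the same grid.  Every observer segments
every rung; functional metrics are computed per dose; and every low-dose
result is compared with *the same observer's standard-dose result of the
same case*: per-class Dice (averaged over ED and ES) and signed deltas
Δ = metric(dose) − metric(SD) in percentage points.  Segmentation overlap
and functional measurement are recorded independently, so a failed
functional analysis at 10 mA (an expected outcome — the lowest rung exists
precisely to show where analysis fails) still contributes its Dice row,
and failures are recorded per case/observer/dose rather than dropped.

Aggregates per dose and metric: mean ± SD of Δ, mean ± SD of |Δ|, and the
90th-percentile |Δ| (linear-interpolation quantile).  Individual metrics'
per-case responses are heavy-tailed (a few boundary-voxel flips can swing
one plane's strain by percentage points), so for dose-trend analyses the
package also provides paired (complete-case) and pooled-over-metric-set
mean |Δ| curves, which are stable at 10-case cohort sizes.  The acceptable-dose
rule makes the narrative judgement explicit: the detected threshold is the
lowest tube current at which P90(|Δ|) ≤ 2.5 pp for every metric in the
configured set at that rung and every higher one.  The default set is
{EF, GLS, CS basal/middle/apical}; WT is excluded by default because of
its intrinsically higher variability, and can be added via configuration.
Deltas are stored signed; absolute values are formed at aggregation.

## What the synthetic study does and does not show

The phantom has no papillary muscles, trabeculation, right ventricle,
atria, coronary vessels, motion blur or metal; its class HU values are
uniform, so segmentation is far easier than in patients, observers are
more robust to noise than clinical networks, and absolute Dice values or
detected thresholds must not be read as clinical claims.  What the
synthetic conditions do support: the noise model's variance structure and
the equivalence of incremental injection with direct low-dose simulation;
exact bookkeeping of the paired ladder design; the monotone degradation of
observer agreement with falling dose; the direction of the
noise-robust-training effect; and the correctness of every measurement
stage against closed-form ground truth.  The scaled-down U-Nets differ
mainly in smoothness, so their separation at moderate dose reduction is
small compared with the patient-scale effect.

## Reproducibility and numerical choices

Every stochastic stage takes an explicit seed; a single global seed
derives per-stage seeds by hashing the stage name, and per-case scan seeds
are spawned from a `SeedSequence`.  Training, inference and the study
driver are pure NumPy/SciPy and bit-reproducible for fixed seeds on a
fixed platform.  Tie-breaks: argmax ties go to the lower class index;
max-pool gradient ties share equally.  Degenerate inputs (empty pools,
isotropic cavities, inverted thresholds, undersampled geometries,
unattainable EF targets) raise typed, descriptive errors; the scanner
warns when the angle count falls below the n_det·π/2 rule of thumb.
Desk-scale problem sizes (64³ at 2.25 mm study grids, 96-detector
geometry, 10-case cohorts, 60-epoch trainings) are the package's default
experiment configuration; all are plain parameters.
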