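# Methods

This note documents the models, algorithms, parameter choices and
numerical decisions behind `hippomicro`, and states what the synthetic
benchmarks do and do not demonstrate.

## Units and conventions

All internal quantities are kept at magnitude O(1): b-values in ms/μm²
(1 ms/μm² = 1000 s/mm²; FSL-style `bval` files are divided by 1000 on
read), diffusivities in μm²/ms, radii in μm, pulse timings in ms.  Voxel
indices are 0-based; world coordinates come from the NIfTI affine; meshes
live in world mm.  Shells are grouped with a 50 s/mm² tolerance (vendor
rounding); a shell below 25 s/mm² counts as b = 0, so the lowest
diffusion-weighted shell (b = 50 s/mm²) is never absorbed into the b = 0
group.

## Forward model (SANDI compartments)

The spherical-mean signal is a convex mixture of sphere, stick and ball
compartments (README for the closed forms).  Assumptions: no exchange
between compartments (reasonable at the short diffusion time Δ = 19 ms),
no orientation-dispersion modelling (everything downstream of the
simulator consumes direction averages), and no T2 weighting of the signal
fractions.

The sphere kernel is the finite-pulse Murday–Cotts (Gaussian phase
distribution) form

    −ln S = 2(γg)² Σ_m [α_m²(α_m²R² − 2)]⁻¹ ·
            [2δ/τ_m − (2 + e^{−τ_m(Δ−δ)} − 2e^{−τ_mδ} − 2e^{−τ_mΔ}
                        + e^{−τ_m(Δ+δ)}) / τ_m²],

with τ_m = α_m²·D_is, α_m = x_m/R, and x_m the positive roots of
x·J′₃⁄₂(x) = ½·J₃⁄₂(x) (first root ≈ 2.0816).  (γg)² is recovered from
b = (γg)²δ²(Δ − δ/3), so no gyromagnetic constant appears.  The series is
truncated at 20 roots; 20 vs 50 roots differ by < 1e-8 over the tested
(R, b) range.  For τ_m(Δ+δ) < 1e-3 the bracket is evaluated by its Taylor
expansion τδ²(Δ−δ/3) − τ²Δ²δ²/2, because the direct expression suffers
catastrophic cancellation in the frozen-spin / vanishing-radius limit.

### Validity of the Gaussian-phase approximation

An independent Monte-Carlo simulator (`randwalk.py`) propagates walkers
inside a reflecting sphere (radial-mirror reflection, trapezoidal phase
integration, time step capped so the rms step is ≤ 15% of the radius) and
averages cos(phase).  At the protocol's b = 3.45 ms/μm² shell the GPD
kernel agrees with the walk to 0.01% (R = 2 μm) and 0.6% (R = 5 μm), but
overestimates the signal by tens of percent for R ≥ 8 μm, where
qR = γgδR reaches 3.7–5.1 and the signal enters the diffusion-diffraction
regime that a Gaussian phase distribution cannot represent.  This is a
property of the GPD model itself — the same closed form used by the
established toolboxes — not of this implementation: the discrepancy is
stable under time-step refinement and under an independently coded
uniform-step walker, and vanishes at low qR for every radius.  Parameter
estimates for large somata therefore inherit a model error from the
kernel, exactly as they do in the reference tools.

## Inversion

Training sets draw (f_soma, f_neurite) uniformly over the simplex triangle
(rejection sampling), R_soma ~ U[1, 12] μm, D_in, D_e ~ U[0.25, 3] μm²/ms,
with D_is fixed at 3 μm²/ms; signals optionally receive Rician noise
√((S+ε₁)² + ε₂²) with σ = 1/SNR (signals are b0-normalized, so the b = 0
level is 1).  One random-forest regressor per parameter (200 trees at full
scale; forest hyper-parameters beyond the tree count are library
defaults, recorded in the fitted estimators); predictions are clipped to
the training ranges; f_extra = 1 − f_soma − f_neurite with negative
remainders clipped and the pair renormalized.  Training noise uses a
single scalar SNR (the median in-mask SNR from `estimate_snr`, which
upsamples the σ² map — not σ — before re-rooting, preserving the variance
bookkeeping of i.i.d. noise under nearest-neighbour interpolation);
voxelwise-SNR training is out of scope.

### What recovery benchmarks show

The closed-loop benchmark (train on 10⁴ draws, 50 trees; test on fresh
draws) recovers R_soma at SNR 50 with a median absolute error ≈ 0.9 μm for
true radii in [3, 10] μm, but the fraction errors plateau around RMSE 0.15
noiseless and 0.18 at SNR 50.  This plateau is intrinsic to the
spherical-mean inverse problem over a uniform prior, not a regressor
limitation: multi-start nonlinear least squares finds exactly-degenerate
parameter sets (a large-soma sphere curve is reproducible by a stick+ball
mixture), and k-nearest-neighbour inversion on 2×10⁵ samples and a
two-layer perceptron on 10⁵ samples reach the same error floor as the
forest.  The error grows with true R_soma (≈ 0.09 for R < 3 μm vs ≈ 0.19
for R > 9 μm), consistent with that degeneracy.  Consequences for use:
contrasts and trends in f_soma across conditions remain informative
(predictions correlate strongly with truth), but absolute fraction values
carry a prior-dependent bias, as in any simulation-trained inversion of
this model.

## DKI

The kurtosis representation ln S = ln S₀ − b·D(n) + (b²/6)·V(n) with
V = MD̄²·W is linear in 22 coefficients (1 + 6 tensor + 15 fourth-order).
The fit is weighted least squares with weights S² on the b = 0, 0.8, 1.5,
2.4 and 3.45 ms/μm² shells (the two lowest weightings are excluded).
Physical constraints — D(n) ≥ 0, V(n) ≥ 0 and monotonic decay
D(n) − (b_max/3)·V(n) ≥ 0 — are linear in the coefficients; they are
checked on the acquired directions plus a 60-direction Fibonacci sphere,
and violating voxels are re-solved by SLSQP projection started from the
unconstrained solution.  Summaries: MD/AD/RD/FA from the tensor
eigensystem; MK as the mean directional kurtosis over 200 Fibonacci
directions; AK along the principal eigenvector; RK averaged over 30
directions in the perpendicular plane.  Identifiability of the 15
fourth-order coefficients needs well-spread directions; the design matrix
is rank-checked and the fit refuses rank-deficient schemes.

## Super-resolution

Each 3D volume is processed independently.  Initialization replicates each
low-resolution voxel into its factor³ children.  Per iteration, every
in-mask voxel is replaced by the weight-normalized average over a 5×5×5
kernel, with

    −ln w = h² · [ Σ_patch ΔDWI² / (N_patch·k_DWI) + ΔT1w²/k_T1w ],

3×3×3 patches, and no spatial-distance term.  Design choices where the
algorithm leaves freedom:

* **Downsample/upsample pair.** Block mean and nearest replication are
  exact adjoints, so the data-consistency step (add back the upsampled
  residual of the block-mean of the estimate) makes the downsampled output
  equal the acquired volume to machine precision after every iteration;
  the block mean also models scanner partial-volume averaging.
* **Normalization.** k_DWI is the mean squared in-mask intensity of the
  current volume (intensity scale varies strongly across shells), k_T1w of
  the reference, computed once.
* **Boundaries.** Patches truncated by the volume edge are normalized by
  their actual voxel count, replacing the nominal 27.
* **Ordering.** One weighting pass then one consistency pass per h, with
  the bandwidth series h = 1, 2, 4, 6, 8, 16 over six iterations; the
  center voxel participates with weight 1, so the weight normalizer never
  vanishes.
* **Reference term.** The anatomical dissimilarity uses the single-voxel
  intensity difference at the two kernel positions (not a patch SSD).

The two-tissue phantom benchmark (32³ ground truth, factor-2 degradation,
Rician SNR 50) gives a masked RMSE ≈ 0.57× that of nearest-neighbour
upsampling, with more boundary voxels within 10% of truth than either
nearest-neighbour or trilinear interpolation.

## Surface morphometrics

Meshes across representations (native/unfolded/inner/outer/mid-thickness)
share vertex indexing and connectivity, so all cross-representation
quantities are per-vertex with no resampling.  Mean curvature uses the
cotangent Laplace–Beltrami operator with Meyer mixed-Voronoi vertex areas;
the sign is taken against outward vertex normals (positive = locally
convex), and open-boundary vertices are returned as NaN rather than
silently computed.  Gyrification is the ratio of per-vertex barycentric
areas (one third of incident triangle areas — per-vertex rather than
per-face, a documented choice) between native and unfolded space.
Thickness is the Euclidean inner–outer vertex distance, undefined (NaN)
for the dentate gyrus, which has no two-layer structure.  Volumetric maps
are sampled at vertices by trilinear interpolation after mapping world
coordinates through the inverse affine.  On analytic meshes the curvature
estimator is accurate to ≪ 1% on icospheres and ≈ 3% on a coarse
cylinder lattice.

## Statistics

The primary model is `metric = β₀ + β₁·age + β₂·sex + ε` (M3); variants M1
(age), M2 (age + age²) and M4 (age + age² + sex) are available, compared
by the nested-OLS likelihood-ratio statistic n·ln(RSS₀/RSS₁) against
χ²(Δp).  The Pearson r is always reported from the age-only fit, linked to
its t-statistic by t = r√(n−2)/√(1−r²) (asserted to 1e-10).  Sex is coded
0/1; the coding does not affect the age t-statistic.  FDR families are the
six subfields within each metric for ROI tables and all vertices within a
map for vertexwise analysis.  ROI means over vertices are unweighted (the
area-weighted alternative differs on skewed-area fixtures by an amount the
tests document).  Constant responses return r = 0, t = 0, p = 1 by
convention.  Two-sample group comparisons are provided in both the
classical pooled-variance and the Welch unequal-variance forms; the
package's cohort sex/age-balance check uses the pooled form
(t = 0.3517, p = 0.7261 for the 32 male / 40 female summaries), which the
Welch statistic matches to three decimals.

## Synthetic data

The generators emulate the structure of a hippocampal aging study without
reproducing its anatomy: a 32³ (default) 1-mm ground-truth grid whose
ellipsoidal foreground is partitioned into six pseudo-subfield slabs with
distinct SANDI parameters; per-direction signals set to the shell's
spherical mean (no orientation dispersion — every downstream SANDI
computation consumes spherical means; DKI direction-dependence tests use
separately generated tensor signals); b = 0 volumes interleaved every 16
diffusion volumes; Rician noise referenced to the b = 0 level; block-mean
degradation to create super-resolution pairs; a piecewise-constant
anatomical reference exactly aligned to the ground truth (registration is
out of scope).  Cohorts draw n = 72 ages uniformly on [19, 85] with a
32/40 male/female split; per-parameter linear age slopes are calibrated
from a target cross-sectional correlation r* via
slope = r*/√(1−r*²)·σ_noise/σ_age, values are clamped to physiological
ranges, and clamping beyond 20% of subjects is recorded in the provenance.
Every generator is a pure function of (spec, seed).

What passing tests therefore show: the pipeline's operations are correct
on signals that obey the forward model exactly, noise enters only as
Rician magnitude noise, and geometry is idealized.  They do not show
robustness to orientation dispersion, exchange, susceptibility or motion
artifacts, imperfect registration, or realistic hippocampal folding.

## Problem sizes and seeds

The bundled benchmarks run at desk scale as the package's own choice of
default: 10⁵ Monte-Carlo walkers per radius; 32³ phantoms with factor-2
degradation; 10⁴ training draws and 50 trees for closed-loop recovery
(the full-scale defaults, 10⁵ draws and 200 trees, are exposed as
parameters); 200 replicates for null-calibration and effect-size coverage.
The demo pipeline uses a 12³ phantom, six subjects and six directions per
shell.  All randomness flows from explicit integer seeds (library default
20250101); reruns with the same configuration are bit-reproducible.

## Known limitations

* The GPD sphere kernel is biased in the diffusion-diffraction regime
  (large R at high b); see above.
* Fraction estimates carry the intrinsic spherical-mean degeneracy; only
  R_soma and relative contrasts are sharply recoverable at realistic SNR.
* In-sample R² of the forest on noiseless training fractions saturates
  near 0.94–0.95 for the same reason — conflicting targets for
  near-identical signals cannot be memorized.
* The SLSQP constraint projection in DKI is per-voxel and becomes the
  bottleneck when noise makes many voxels violate positivity.
* Surface metrics assume manifold meshes with consistent winding; meshes
  with inverted normals flip the curvature sign.
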