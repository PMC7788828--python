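# Methods

`brainshift` analyses paired two-condition quantitative MRI of the rodent
brain: tissue-compartment volumetry from proton-density-weighted (PDW)
images, T2\* relaxometry from multi-gradient-echo (MGE) series, multi-range
apparent-diffusion-coefficient (ADC) and kurtosis fitting from
diffusion-weighted imaging (DWI), and voxel-wise paired statistics with
false-discovery-rate control.  Because no scanner data ship with the package,
a digital phantom generates every input with known ground truth; each
estimator is validated by recovering what the phantom planted.

## The digital phantom

**Geometry.** A subject is a set of per-voxel GM/WM/CSF membership
probabilities on a regular grid (default 96 × 96 × 64 voxels at 0.23 mm
isotropic).  Voxels are ranked by a per-subject jittered ellipsoidal radius
and filled inside-out: a ventricle-like CSF core (40% of the CSF volume by
default), the WM interior, the GM rind, and the remaining CSF as a
basal-cistern-like pocket confined to a downward angular sector.  The sector
matters: spreading ~110 mm³ of outer CSF uniformly over the brain surface
yields a film ~0.17 mm thick — thinner than a voxel and unresolvable by any
segmentation — whereas real subarachnoid CSF pools in cisterns and
peri-vascular conduits several voxels across.  Boundary voxels receive
fractional membership, so each compartment's probability sum times the voxel
volume equals its requested volume to float precision; a 0.23 mm FWHM blur
then adds partial-volume mixing without changing any compartment total
(reflective-boundary Gaussian convolution conserves the sum exactly).

**Tissue properties** (defaults; a.u. = arbitrary units):

| compartment | proton density (a.u.) | T2\* (ms) | f_IVIM | D\* (mm²/s) | ADC₀ (mm²/s) | K |
|---|---|---|---|---|---|---|
| GM  | 0.85 | 28.8 | 0.10 | 1e-2 | 7.0e-4 | 0.70 |
| WM  | 0.72 | 28.8 | 0.05 | 1e-2 | 6.0e-4 | 0.90 |
| CSF | 1.00 | 60   | 0    | —    | 3.0e-3 | 0 |

Compartment volumes default to the deeply-sedated study-group means: CSF
190 mm³, parenchyma 1841 mm³ (GM fraction 0.62).  Parenchymal T2\* defaults
to the corresponding 28.8 ms group mean; kurtosis values sit in the 0.6–0.9
range reported for rodent cortex and white matter at high field.

**Forward models.** PDW: mixture of proton densities times an optional
mean-one second-order-polynomial bias field (B1-type inhomogeneity),
plus noise.  MGE: per-compartment mono-exponential decay
S(TE) = PD·exp(−TE/T2\*) summed by membership, sampled at 16 evenly spaced
echoes from 2 to 32 ms.  DWI: the biexponential IVIM + kurtosis model

    S(b)/S0 = f_IVIM·exp(−b·D*) + (1 − f_IVIM)·exp(−b·ADC0 + (b·ADC0)²·K/6)

summed over compartments, identical along three orthogonal gradient
directions (isotropic truth) with independent noise per direction, at 57
b-values spanning 20–2518 s/mm² (15/21/21 uniformly placed inside the low
20–205, mid 235–1016, and high 1117–2518 s/mm² windows; the acquisition the
protocol emulates does not list its individual b-values, so uniform placement
preserving the window boundaries and count is used).  A mono-exponential
DMSO-like control signal (default ADC 680 μm²/s) exercises the fitting
chain on a liquid with no perfusion or kurtosis.

**Noise.** No signal-to-noise figures are available for the emulated
acquisitions, so the default is additive Gaussian noise at σ/S0 = 2% on
magnitude-scale signals — comfortable for log-linear estimators while leaving
visible estimator variance; Rician noise is available
(`noise_model="rician"`) for magnitude-bias studies.  Every simulator takes
an explicit seed; identical configuration and seed give bit-identical
volumes.

**Paired cohorts.** Each of n subjects (default 12) draws anatomy jitter
once — CSF volume CV 10.5%, parenchyma CV 4.9%, a global T2\* offset with SD
1.1 ms, matching the reference between-animal spreads — shared across both
conditions.  Condition B then applies an `EffectSpec`: the CSF volume is
rescaled (default 180/190) with the exchanged probability mass drawn from, or
returned to, the parenchyma at the CSF boundary, which conserves total
intracranial volume exactly (a Monro–Kellie-style constraint); focal GM
"swelling" sites add capped Gaussian probability bumps recruiting mass from
CSF, then WM, then background; and a global T2\* shift (default +1.8 ms,
the isoflurane-like condition) moves every compartment.

## T2\* relaxometry

Per-voxel ordinary least squares on ln S versus TE: slope = −1/T2\*,
intercept = ln S0.  The log-linear form is deterministic and closed-form; at
16 echoes and 2% noise its bias on a 30 ms T2\* is below 0.5%, so no
nonlinear refinement is fitted by default.  Voxels with any non-positive echo
or a non-decaying slope are flagged invalid, never zeroed.  Compartment
summaries are means over voxels with summed membership probability > 0.5,
after discarding values outside the 0.1–99 percentile interval, a simple
guard against stray non-physical fits skewing the mean.  The fit is scale-equivariant:
scaling all signals by c leaves T2\* unchanged and scales S0 by c.

## Diffusion analysis

**Direction combination.** The three orthogonal direction volumes are
combined per b-value by the geometric mean (zero if any direction is zero) —
the trace-weighted combination appropriate when only the mean diffusivity is
sought.

**Windowed ADC.** Unweighted OLS of ln S on b restricted to the named
window (low/mid/high).  Brain signal is super-mono-exponential at low b
(perfusion/IVIM) and sub-mono-exponential at high b (kurtosis), so on
realistic inputs ADC_low > ADC_mid > ADC_high, while a liquid phantom
returns one ADC from every window.

**Kurtosis fit.** For b ≥ 235 s/mm² the IVIM term is negligible
(f_IVIM ≪ 1, D\* ≫ ADC₀) and the signal follows
S(b) = S0·exp(−b·ADC₀ + (b·ADC₀)²·K/6).  The three parameters are fitted per
voxel by bounded trust-region nonlinear least squares on signal amplitudes
(the box-constrained equivalent of Levenberg–Marquardt; a log-domain residual
option exists).  Initialization: S0 and ADC₀ from the mid-window
mono-exponential fit, K = 0.623.  Box constraints per voxel:
0.5·S0_mid < S0 < 2.0·S0_mid, 0.5·ADC_mid < ADC₀ < 2.0·ADC_mid, 0 ≤ K ≤ 2.
Solver tolerances 1e-10 with at most 200 objective evaluations; voxels
whose mid-window fit failed are invalid (no initialization); non-converged or
bound-pinned voxels keep their parameters and are flagged.  On noiseless
model signals recovery is exact to better than 1e-6 relative; truth outside
the box (e.g. K = 2.5) pins at the bound and is flagged.

**Kurtosis-sensitivity simulation.** To quantify how a drop in kurtosis
inflates the high-b ADC, noiseless simplified-model signals are generated
over 21 b-values in 1200–2500 s/mm² and refitted with a plain
mono-exponential (nonlinear LSQ on amplitudes, recorded in the output
metadata).  The reference parameter set is calibrated by a one-dimensional
root search on ADC₀ (K_ref = 1.0, S0 = 1000) such that a 20% kurtosis
reduction raises the fitted ADC by exactly 9%; the 40% reduction then lands
at ≈18%, and the percent increase is strictly monotone in the reduction.

## Morphometry

**Bias correction.** The multiplicative field is the heavily smoothed
(default 8 mm FWHM) log-intensity trend, estimated by mask-normalized
convolution and refined over three passes (one pass attenuates the trend it
estimates; re-estimating the residual recovers the attenuated part
geometrically).  Two variants exist.  `correct_bias` works from intensity
alone and suits structure-free objects.  `correct_bias_with_priors` — the
pipeline default — first divides out the expected clean image (tissue priors
mixed with prior-confident class means) and estimates the trend over
deep-tissue voxels only; without this, genuine compartment contrast (a bright
CSF pocket, the dark WM core) masquerades as field and its removal
systematically dims thin CSF structures.  On phantoms the prior-based
variant recovers the true polynomial field at r ≈ 0.93–0.99.

**Segmentation.** A four-class (GM/WM/CSF/background) Gaussian-mixture EM
with the spatial priors as per-voxel mixing weights.  Class statistics are
initialized from prior-confident voxels (prior > 0.8); variances stay fixed
at that initialization by default because CSF borders two very different
intensities (parenchyma and background) and a free variance turns it into a
catch-all class.  Updating only the means is still coordinate ascent, so the
log-likelihood trace is non-decreasing; non-convergence within `max_iter`
is flagged, not raised.  Near-flat priors (no spatial information) trigger a
percentile-based symmetry-breaking initialization using the PDW intensity
ordering air < WM < GM < CSF.

**Partial-volume refinement.** After EM, boundary voxels (second prior
≥ 0.02, top prior ≤ 0.95) are re-expressed as two-class mixtures: the mixing
fraction is read off the intensity axis, α = (y − μ₂)/(μ₁ − μ₂) clipped to
[0, 1], which is unbiased under additive noise where a hard classification
flips whole voxels.  The class references μ are local (normalized convolution
of prior-deep voxels over a 3 mm FWHM neighbourhood, prior-weighted with a
0.75 admission threshold so thin cisterns contribute, falling back to global
means where a class has no nearby deep voxels): residual intensity
inhomogeneity of even 2–3% between distant CSF pockets, against the ~15%
CSF–GM contrast, would otherwise misread mixing fractions by ~20%.

**Volumetry.** Probabilistic counting: volume = posterior mass × voxel
volume, no thresholding, so partial-volume voxels contribute their actual
tissue content.  GM + WM + CSF + background mass equals the grid volume
exactly.  End-to-end on 12-subject cohorts at the default grid, mean signed
volume errors are ≲1% for CSF and ≲0.2% for GM and WM.

**Smoothing.** Gaussian kernels specified as FWHM in mm
(σ = FWHM/2.3548 per axis, converted to voxels), reflective boundaries
(mass-conserving), default 0.6 mm for maps entering voxel-wise statistics.

## Voxel-wise and total statistics

Paired t-tests on within-subject condition differences (n − 1 degrees of
freedom, two-tailed p).  Zero-variance voxels get p = 1 and a flag rather
than being dropped, keeping map geometry intact.  Multiplicity over the
analysis mask is controlled by the Benjamini–Hochberg step-up procedure
(significance = the step-up rejection set, equivalently adjusted q ≤ α;
Benjamini–Yekutieli available for arbitrary dependence).  Scalar compartment
totals (TIV, CSF, parenchyma, compartment-mean T2\*) use the classical
paired t-test; ROI means exclude and count invalid voxels.  Note that under
a complete null BH attains its bound exactly (FDR = α·m₀/m = α), so
Monte-Carlo checks of "FDR ≤ α" need a sampling margin.

## The end-to-end pipeline

`run_pipeline` simulates a cohort and executes, per subject and condition:
PDW → prior-based bias correction → EM segmentation → volumes; MGE → T2\*
fit → trimmed compartment means; DWI → geometric-mean combination → three
windowed ADC fits → ROI-restricted kurtosis fit; then group-level paired
tests on totals and voxel-wise paired tests with BH-FDR on smoothed CSF
posterior and T2\* maps.  The DWI stage runs on a central 16-slice axial
slab — the diffusion acquisition it emulates was a thin 2-D multislice
protocol, unlike the whole-head 3-D PDW/MGE scans — and the kurtosis fit is
restricted to the GM ROIs by default (per-voxel nonlinear fits over the full
volume are available with `kurtosis_fit_scope: all`).  ROIs are spheres
(default radius 0.7 mm) placed at well-separated maxima of the
distance-to-non-GM transform of a template anatomy.  ADC is stored in mm²/s
internally (so b·ADC is dimensionless with b in s/mm²) and converted to
μm²/s only at table boundaries.  All stage seeds derive from the single
configuration seed; rerunning with the same configuration yields
bit-identical CSVs, and every output embeds the configuration hash.

## Problem sizes and determinism

Cohort-level validations run 12 paired subjects: volumetry on the default
96 × 96 × 64 grid at 0.23 mm, relaxometry on 64 × 64 × 48 — sizes chosen so
the full suite completes in about a minute while leaving thousands of voxels
per compartment.  The `scripts/acceptance.py` summary recomputes the
kurtosis-sensitivity value (deterministic, no randomness) and the T2\*
cohort recovery (12 subjects, seeded) from scratch at those sizes.

## What the phantom does and does not show

The phantom is schematic: nested ellipsoids plus a cisternal sector, not an
atlas of rat neuroanatomy; the analysis operates on compartment
probabilities, so anatomical fidelity is irrelevant to the estimators being
validated.  Passing tests demonstrate estimator correctness — forward-model
inversion, volume bookkeeping, FDR control, effect recovery at planted
sizes — under the stated noise model.  They do not demonstrate robustness to
motion, susceptibility distortion, registration error, coil-profile
extremes, or partial-volume geometries more adversarial than the phantom's
(the package assumes all volumes share one space; motion correction and
nonlinear registration are out of scope).  Perfusion parameters (f_IVIM,
D\*) are simulated but never estimated from data — at b ≥ 235 s/mm² they are
unidentifiable by design, which is exactly why the simplified kurtosis model
is used there.
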