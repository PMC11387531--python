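# Methods

`prmivim` implements a voxel-wise multi-modal tumor-imaging analysis:
intravoxel incoherent motion (IVIM) parameter estimation from multi-b-value
diffusion MRI, rigid registration of a PET SUV volume into the IVIM frame,
parametric response mapping (PRM) of the co-registered maps, and cohort
statistics relating pre-treatment imaging to tumor-volume change under
chemoradiation.  Because no patient imaging is distributed, every stage is
exercised on digital phantoms with known ground truth; this note records the
models, the defaults and why, and what the synthetic validation does and does
not establish.

## IVIM signal model

The diffusion-weighted signal follows the two-compartment bi-exponential

    S(b) = S0 [ f exp(-b D*) + (1 - f) exp(-b D) ],

with tissue diffusivity `D` (mm²/s, bounded [1e-5, 3e-3]), perfusion fraction
`f` (bounded [0, 0.5]), and pseudo-diffusion coefficient `D*` (mm²/s, bounded
[3e-3, 0.3]).  The `D` upper bound coincides with the `D*` lower bound so the
compartments cannot swap.  The default acquisition is 11 b-values
{0, 10, 20, 30, 50, 80, 100, 150, 200, 500, 800} s/mm²; the dense low-b
sampling is what separates `f` from `D*`, and a scheme with no b-value in
(0, 200) flags `f` and `D*` unidentifiable rather than returning them
silently.

## Estimators

**Segmented least squares** (the reference fitter and the Bayesian
initializer): log-linear regression on b ≥ 200 s/mm² gives `D` and the
extrapolated intercept; `f` is the intercept deficit at b = 0; a coarse
bounded search plus a projected, damped Gauss–Newton polish refines all four
parameters inside the bounds.  Estimates landing on a bound carry a `clipped`
flag; non-finite or non-positive-b0 voxels carry `failed` and never raise, so
volume fitting always completes.

**Bayesian fitter**: Gaussian likelihood on magnitudes (standard at b=0 SNR
≳ 20; the data are Rician but the approximation error is small compared with
the posterior width).  The amplitude S0 enters linearly and is marginalized
in closed form (flat prior); the noise scale is marginalized with a Jeffreys
prior; this leaves a 3-D integral over (D, f, D*) evaluated by dense
marginalization on a per-voxel grid (default 33 points per axis, geometric
in D and D* and linear in f, trapezoid quadrature) centered on the
least-squares initializer.  The point estimate is the posterior mean; the
posterior SD is reported per parameter.  The scheme is fully deterministic:
identical inputs give identical estimates, and per-voxel results do not
depend on the order voxels are visited.

A flat box prior on `D*` makes its posterior mean unusable at realistic
noise: the likelihood is nearly flat over much of [3e-3, 0.3], so the wide
upper tail drags the mean up by a factor of 2–3 at SNR 50 (confirmed
against an independent affine-invariant-ensemble MCMC run with the same
likelihood and priors; the posterior *median* is still ~70% high).  Batch
and volume fits therefore use empirical-Bayes shrinkage: stage-1 LSQ fits
across the voxels give robust (median / scaled-MAD) hyperpriors — lognormal
for `D*`, normal for `f` — whose widths are floored (0.3 in log-D*, 0.04 in
f) so a homogeneous region cannot collapse them, and capped so the weak
upper tail is always shrunk.  Hierarchical shrinkage of exactly this kind
is why Bayesian IVIM fitting beats per-voxel least squares on repeatability.
Measured on 500 Rician replicate voxels at SNR 50 (tumor-mean parameters),
the median relative biases are about −1% (D), +6% (f), +10% (D*); noiseless
inputs are recovered to machine precision because the initializer sits on
the grid.  Single-voxel `fit_voxel_bayesian` calls keep the pure box prior
(there is no ensemble to learn from) and inherit the D* bias; volume means
of `D*` run ~10–35% high depending on tissue heterogeneity — consistent
with `D*` being the least stable IVIM parameter — and `D*`-based conclusions
should be treated accordingly.

## Registration and resampling

PET is brought into the IVIM frame (never the reverse) by a 6-DOF rigid
transform estimated with histogram-based Mattes mutual information (32
bins, full deterministic sampling, two-level pyramid 2×/1× with 1 mm/0 mm
smoothing, regular-step gradient descent).  Padding voxels created by
resampling are excluded from the metric through an eroded validity mask;
without it the artificial frame-aligned edge biases rotation by ~1–2°.
Transforms are stored as 4×4 row-major text matrices mapping moving-world →
fixed-world in mm; an externally produced transform file is accepted in
place of estimation.  Resampling pulls each target-voxel center back through
the inverse transform (trilinear for intensity maps, nearest for masks);
out-of-domain voxels are NaN and excluded downstream.  On phantom SUV
volumes, perturbations up to 10 mm / 5° are recovered within 0.2° and
0.1 mm; cross-modality (SUV → b0) registration is accurate to roughly one
degree and a third of a voxel, which is adequate for PRM but is the main
error source in voxel-wise comparisons, as it is with patient data.

## Parametric response mapping

Population thresholds are the unweighted across-patient means of the
spatially averaged pre-treatment GTV values (μ_SUV, μ_D, μ_f).  Each GTV
voxel of a co-registered pair (A, B) is classified into one joint-histogram
quadrant: 1 = A^hi B^hi (cyan), 2 = A^hi B^lo (magenta), 3 = A^lo B^lo (red),
4 = A^lo B^hi (green); "hi" is strictly greater than the threshold, so a
voxel exactly at a threshold counts as "lo" — a measure-zero convention fixed
for reproducibility.  Class counts are normalized to the total tumor volume
to give four relative-volume percentages that sum to 100 (integer counts,
one division each).  Thresholds are frozen to disk with the contributing
patient ids, so adding a patient cannot silently shift earlier
classifications; PRM is computed inside the pre-treatment GTV, with the
D×f variant also evaluated on-treatment against the same frozen thresholds.

## Cohort statistics

ΔGTV = 100·(GTV_on − GTV_pre)/GTV_pre (signed; shrinkage negative — with
this convention a negative ΔGTV-vs-GTV_pre correlation reads "bigger tumors
shrink proportionally more").  Pre/on differences use two-sided Wilcoxon
signed-rank tests: zero differences dropped, mid-ranks for ties, exact
null below n = 26 (scipy's count recursion without ties; a direct 2^n
sign-flip enumeration over mid-ranks for tied magnitudes up to n = 16;
the tie-corrected normal approximation otherwise).  Associations use
Spearman correlations with mid-ranks, exact permutation p for n ≤ 9 and the
t-approximation above; voxel-wise SUV-vs-IVIM correlations are computed per
patient inside the GTV and summarized as mean ± SD.  Shapiro–Wilk screens
normality and motivates the fixed non-parametric choice.  Significance is
two-sided α = 0.05 on raw p-values; a Benjamini–Hochberg column is appended
to the association table as a clearly labelled extension, not used for the
significance flags.

## Synthetic phantoms

A phantom is an ellipsoidal GTV inside a pelvic "body" ellipsoid, with an
equal-volume core/rim split (radii scaled by 2^(-1/3)): the core is denser
(−17% D), less perfused (−17% f) and hotter (higher SUV) than the rim.
Within-tissue heterogeneity is low-pass-filtered Gaussian noise
(6 mm correlation length; relative SDs 8% D, 12% f, 12% D*, 3% S0, 15% SUV).
DWI magnitudes are Rician, sqrt((s+n₁)² + n₂²), with σ = S0/SNR and default
SNR 50 at b = 0, so background voxels carry Rayleigh noise.

Cohort defaults reproduce a 20-patient chemoradiation cohort's demographics:
per-patient tumor means drawn from Normal distributions — D 1.07e-3 (SD
0.2e-3) mm²/s, f 12.7% (3.3), D* 13.7e-3 (3.5e-3) mm²/s, SUV_mean 3.7 (1.6),
GTV 65 (48) cc clipped to [15, 180] cc (the floor keeps the smallest tumors
large enough for the SUV-coupling calibration below).  Cohort phantoms use
40³ grids at 3 mm voxels with 36³/4 mm PET grids — sizes chosen so the full
20-patient pipeline runs in minutes on one CPU.

**SUV coupling.**  The SUV map is a monotone exponential of
−w·z(D) + sqrt(1−w²)·ε with smooth unit noise ε, scaled to the patient's
drawn SUV_mean inside the GTV over a cooler background (half the tumor mean,
floored at 0.8), then blurred by a 5 mm FWHM PET point-spread function.  The
mixing weight w is solved per patient by 1-D root finding so that the
*measured* within-GTV Spearman correlation — after the PSF and the full
PET-grid resampling round trip — equals the target (default −0.15 for SUV
vs D); calibrating on anything earlier in the chain misses the edge-darkening
the PSF induces at the GTV boundary and overshoots the correlation by ~0.06.
The SUV-vs-f correlation is not independently controlled: it emerges from
the phantom's spatial D–f correlation and lands near −0.10 against a −0.08
reference.  If a tumor's geometry makes the target unreachable (very small
GTVs under the PSF), the nearest achievable coupling is used rather than
aborting the cohort; an explicitly requested infeasible target raises.

**Treatment response.**  The on-treatment GTV keeps the k voxels deepest
inside the tumor by signed Euclidean distance (deterministic index
tie-break) — the discrete analogue of scaling the ellipsoid — with k set by
the per-patient volume-change fraction.  Because shrinkage preferentially
keeps the low-D core, D and f shifts are applied so the *surviving region's
mean* moves by delta relative to the pre-treatment tumor mean (D* delta 0,
i.e. unchanged on average); without this re-centering the composition shift
cancels the intended increase.  Per-patient shrinkage magnitude is
0.5 − 0.20·z(D) + 0.06·z(SUV) + 0.05·z(GTV) + N(0, 0.05), clipped to
[0.05, 0.92]: dense, metabolically active and larger tumors shrink more,
which is what couples the PRM SUV^hi D^lo sub-volume to stronger shrinkage
and SUV^lo D^hi to resistance.  Mean D and f shifts are +0.12e-3 mm²/s and
+0.03.

**What the phantoms do not emulate**: irregular tumor shapes, partial-volume
and EPI distortion, motion, scanner/vendor variability, DICOM ingestion, an
on-treatment PET (the study design acquires PET pre-treatment only), and any
biological mechanism behind the SUV–IVIM coupling — the generator matches
the reported correlation structure, not a physiology.  Passing tests
therefore establish that the pipeline's computations are correct and
well-calibrated on data with this structure, not that the clinical effect
sizes would replicate.

## Numerical choices and degenerate inputs

Seeding: one master seed per generator call, per-patient sub-seeds via
`numpy.random.SeedSequence.spawn`, so results are independent of patient
order.  The grid sampler consumes no randomness.  Residual sums of squares
are floored at 1e-30·‖s‖² so noiseless data cannot produce log(0).  Voxels
with non-positive b = 0 signal are excluded from the fit mask; all-zero or
non-finite signals yield flagged estimates, not exceptions.  PRM ties break
"lo"; fraction percentages are integer counts times 100 over the total.
Pipeline tables are written with fixed float formatting and volumes as
uncompressed NIfTI, so a rerun with the same config and cohort is
byte-identical apart from the wall-clock log.

## Known limitations

- `D*` point estimates are only order-of-magnitude reliable at SNR 50; the
  on-treatment decrease in *fitted* mean D* seen on phantom cohorts is a
  fitting/composition artifact (the truth is constructed unchanged) and
  mirrors the parameter's known instability.
- The fitted cohort mean of `f` runs ~1–2 percentage points above the
  generator target (Rician floor plus posterior skew).
- Mutual-information registration assumes overlapping fields of view and a
  rigid relation; soft-tissue deformation is out of scope.
- The exact Wilcoxon path with tied magnitudes is limited to n ≤ 16 by
  enumeration cost; larger tied samples use the normal approximation.
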