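# Methods

This note documents the models, numerical choices and known limitations of
`pbifkit`. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is quoted from external data.

## Input-function model

The arterial input function (AIF) is Feng's sum of a gamma variate and two
exponentials with an arrival delay τ (minutes), seven parameters in all
(τ, A1, A2, A3, λ1 > λ2 > λ3 > 0). The curve is identically zero up to τ
and continuous there by construction (the amplitudes cancel at t′ = 0).
Although the bare model equation carries no delay term, the delay is
treated as the seventh fitted parameter: whole-body protocols start the
scanner before injection, so the arrival time is genuinely unknown per
subject. All definite and running integrals of the model are evaluated in
closed form from the antiderivatives of t′·e^(−λt′) and e^(−λt′); the
closed forms are cross-checked in the tests against fine-grid trapezoidal
quadrature (< 0.1% over 0–65 min).

Frame values are treated as instantaneous samples at frame mid-times
throughout. This is an approximation — a scanner reports frame averages —
but the schedule uses 2-s frames exactly where the curve is fast, so the
mid-time error is negligible relative to the fitted residuals.

### Fitting

`feng_fit` runs bounded trust-region least squares
(`scipy.optimize.least_squares`) from multiple starts: a data-driven
initial guess (onset from the 2% rise point, λ1 from the peak time,
amplitude from the peak height, tail amplitude from the last frame), plus
n−1 perturbed starts with log-normal jitter and λ1 walked across a
log-spaced grid. Bounds: τ ∈ [0, 2] min, λ1 ∈ [1, 100], λ2 ∈ [0.01, 2],
λ3 ∈ [10⁻⁴, 0.1] min⁻¹, amplitudes nonnegative. The lowest-cost solution
satisfying the eigenvalue ordering wins; ties break toward lower λ1.
Residuals are unweighted by default (optional per-frame weights, e.g.
frame durations, are accepted). The fit is deterministic given its seed.
On noiseless 62-frame data the fitter recovers all seven generating
parameters to ≪ 1% across the population variability box (tested).

## PBIF construction and scaling

Averaging is performed on delay-aligned fitted model curves, not on raw
samples and not on parameter vectors: parameter-space averages of
multi-exponentials are not shape-preserving, and raw-sample averages would
smear the peak across subjects with different delays. The dense common
grid uses 0.01-min steps over [0, 65] min, fine enough to resolve the
sub-minute peak (λ1 ≈ 18 min⁻¹). The averaged shape is renormalized to
unit AUC and also refit with Feng's model; both representations (tabulated
curve and analytic fit) are stored, because the scaling step wants the
tabulated curve while Patlak wants the analytic integral.

The sPBIF scale factor is a ratio of like quantities — both tail AUCs are
trapezoidal integrals of sampled curves — so the matched-window tail AUC
equality is exact by construction (asserted at 10⁻⁹ relative). Window
edges falling between or beyond frame mid-times are handled by linear
interpolation/extrapolation from the two nearest mid-times; constant
extension would bias the 55–65 min tail AUC by ~0.3% because the last
frame mid-time is 62.5 min. The scaled PBIF keeps the population delay;
no per-subject delay re-estimation is performed in the validation step.

## Patlak analysis

The transform uses x(t) = ∫₀ᵗCp/Cp(t), y(t) = Ct/Cp, with frames
qualifying for the fit iff their mid-time ≥ t*. The line is unweighted
ordinary least squares (frame-duration weighting is available behind a
flag but off by default). Frames with nonpositive Cp are excluded and
logged, never silently dropped.

When the input function is analytic (Feng parameters, PBIF, sPBIF), ∫₀ᵗCp
uses the closed form — this is the abbreviated-protocol premise: the early
curve is known from the population shape, not from early images. When the
input function is a sampled IDIF, the running integral uses a cumulative
Simpson rule over the mid-time grid (first value extended back to t = 0).
A cumulative trapezoid was rejected deliberately: its O(h²) error on the
2-s peak frames leaves a persistent +0.12–0.16% excess in the late
integral, which propagates into every IDIF-referenced Patlak slope;
Simpson reduces the residual to ~0.03%, below the pipeline's error budget.

Scale equivariance (Cp → c·Cp implies Ki, V → Ki/c, V/c) is exact and
tested at 10⁻¹⁰.

## Synthetic cohort: study conditions

The generator emulates a 65-min oncological protocol on the 62-frame
schedule (2×10, 30×2, 4×10, 8×30, 4×60, 5×120, 9×300 s). Defaults, chosen
once as realistic field values:

- Mean AIF shape: the published population parameter set (unit-AUC units),
  with amplitudes multiplied by 550 kBq·min/ml so the mean full-curve AUC
  matches a typical validation-cohort value.
- Inter-subject variability: unit-mean log-normal factors with 10% CV on
  the three amplitudes and three eigenvalues; arrival delay uniform on
  [0.4, 1.0] min. At this CV the population-shape mismatch bounds the
  tail-scaled sPBIF to within ~10% of a subject's true AIF everywhere
  after the scaling window (measured worst cases: 5–7%).
- Kinetic priors: tumors K1 ~ U(0.05, 0.3) ml/g/min, k2 ~ U(0.1, 0.5),
  k3 ~ U(0.02, 0.15) min⁻¹, vB ~ U(0.02, 0.1); gray matter in ±10% boxes
  around K1 = 0.1, k2 = 0.15, k3 = 0.07, vB = 0.04. Four tumor ROIs and
  one gray-matter ROI per subject, giving 32 lesions across a default
  8-subject validation group.
- Noise: zero-mean Gaussian with SD = level·√(value/frame-duration), the
  standard decay-corrected dynamic-PET heuristic, level 0.2 by default
  (≈3% on a 5-min late tissue frame); values clipped at zero. The IDIF is
  the true AIF sampled on the schedule plus the same noise — the eroded
  aorta VOI is treated as partial-volume-free ground truth, as the
  analysis it feeds assumes.
- Determinism: subject i uses seed + i; one global seed fans out to stage
  seeds (+1000 validation, +2000 fitting, +3000 phantoms).

The tissue forward model is the closed-form convolution of the Feng terms
with the 2TCM impulse response K1·(k3/β + (k2/β)e^(−βt)), β = k2 + k3,
with near-degenerate λ ≈ β handled by series limits; it agrees with stiff
ODE integration (Radau, rtol 10⁻¹⁰) to ~10⁻¹² relative. The measured
signal mixes fractional blood volume, (1−vB)·Ct + vB·Cp, so the expected
Patlak slope of a simulated voxel or ROI is (1−vB)·Ki, and ground truth is
recorded as (Ki, vB) pairs.

What the generator does **not** model: partial-volume and motion effects on
the IDIF, scanner resolution/PSF, scatter and randoms, attenuation,
count-rate-dependent noise correlations between voxels, and reconstruction
smoothing. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated statistical model, not clinical
image quality; in particular voxel-level noise in the phantoms is harsher
than in smoothed clinical parametric images, so phantom SSIM/PSNR values
at the default noise level are substantially lower than those reported for
reconstructed patient data.

## Evaluation conventions

Percent bias is 100·(test−ref)/ref per lesion; precision is the sample SD
(n−1) of per-lesion biases pooled flat across subjects within a tissue
class (no subject-level hierarchy); R² comes from OLS of test on ref. The
AUC comparison uses the two-sided Wilcoxon signed-rank test with zeros
dropped and the exact null distribution for n ≤ 25; an all-zero difference
vector is reported as p = 1. No multiple-testing correction is applied
across windows.

The factorial reference is the subject's own IDIF with t* = 35 min. Note
that cells with t* > 35 min are then *not* pure pipeline error even under
perfect conditions: for slow kinetics (β ≈ 0.2 min⁻¹) the fitted Patlak
slope at t* = 55 min sits ~0.1% closer to its asymptote than at t* = 35
min, an equilibration transient of the tracer model itself. Under null
conditions (zero population variability, zero noise) the measured
machinery-only error is < 0.03%, while late-t* gray-matter cells show
~0.1% total — the transient, not an implementation artifact.

## Parametric maps and image metrics

Voxel-wise Patlak shares one abscissa across voxels (the input function is
common), so the whole map is a single vectorized least-squares sweep; it
is bit-consistent with the ROI-level fit per voxel (tested on 100 voxels
at 10⁻¹⁰). Failed voxels become NaN and are counted in a QC field.

RC statistics exclude voxels whose |reference| is below 1% of the masked
maximum (division guard, recorded in the output). SSIM uses a 7³ window,
K1 = 0.01, K2 = 0.03, and data range = masked (max − min) of the reference
map, with voxels outside the mask zeroed in both images and the SSIM map
averaged within the mask. PSNR uses range = masked maximum of the
reference and reports +∞ (serialized `"inf"`) for identical images. With
the reference-based data range, SSIM symmetry holds exactly only for image
pairs sharing min/max; the symmetry test uses such pairs.

## Known limitations

- Indirect (image-space) voxel-wise Patlak stands in for
  reconstruction-domain direct Patlak; sinogram/list-mode simulation is
  out of scope.
- No dispersion or metabolite correction, no whole-blood-to-plasma
  conversion; concentrations are assumed decay-corrected.
- The kinetic priors are generic FDG literature ranges, config-exposed,
  not calibrated to any specific cohort; population-level conclusions from
  the synthetic factorial are qualitative (orderings, not absolute
  percentages).
- Default problem sizes (16+8 subjects, 32³ phantoms, 0.01-min PBIF grid)
  are desk-scale choices that keep a full run in seconds to minutes while
  resolving every feature the estimators depend on.
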