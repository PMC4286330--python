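# Methods

This note records the scientific model implemented by `pettcp`, the
design of the synthetic cohort generator, and the numerical and
statistical choices, with their rationale and limitations.

## 1. Imaging surrogates

Each patient contributes a pre-treatment and a post-treatment SUV volume
on a common grid. The tumor is delineated on the **pre-treatment** image
as the set of voxels with SUV strictly greater than 2.5. Over that fixed
mask, the package computes:

- `mean_ratio` ⟨SUV_R⟩ = mean over voxels of SUV_post / SUV_pre — the
  primary survival-fraction surrogate;
- `ratio_of_means` = ⟨SUV_post⟩ / ⟨SUV_pre⟩;
- `mean_pre`, `mean_post`, and `mean_diff` = ⟨SUV_pre⟩ − ⟨SUV_post⟩
  (baseline minus follow-up, i.e. the uptake *decrease*).

The binary outcome R is 1 for gross residual disease (nonresponder) and
0 for pathologic complete response or microscopic residual disease
(responder). An empty mask, mismatched grids, or non-positive
pre-treatment voxels inside the mask are hard errors naming the patient.

## 2. Tumor-control and recurrence model

Under Poisson statistics with N₀ initial clonogens distributed over
compartments with fractions f_k and survival S_k,

TCP = ∏_k exp(−N₀ f_k S_k) = exp(−N₀ ⟨S⟩),

so the mean survival is sufficient. With ⟨SUV_R⟩ standing in for ⟨S⟩,
the tumor-recurrence probability is modeled as

TRP(x) = ½ [1 + erf(√π γ₅₀ (x − SUVR₅₀))],  TCP(x) = 1 − TRP(x).

The √π factor makes dTRP/dx at x = SUVR₅₀ equal γ₅₀ *exactly*; this is
the defining property of the slope parameter and the form implemented
here (verified analytically and by finite differences in the tests).
`tcp_compartments` deliberately evaluates the literal per-compartment
product so the Eq.-equivalence test is not a tautology.

## 3. Maximum likelihood and confidence regions

Outcomes are Bernoulli: LL(θ) = Σ_i [R_i log p_i + (1−R_i) log(1−p_i)]
with p_i = TRP(x_i; θ). Probabilities are clamped to
[10⁻¹², 1−10⁻¹²] to keep the LL finite under separation; the upper tail
is evaluated as ½ erfc(−z) for accuracy. The fit maximizes LL on a
rectangular grid (default SUVR₅₀ ∈ [0.05, 1.2], γ₅₀ ∈ [0, 6], 241×241
nodes), with ties broken toward smaller γ₅₀ then smaller SUVR₅₀, and an
optional Nelder–Mead polish constrained near the grid maximum
(`refine=True`).

Grid search was chosen over generic optimizers because (a) the
likelihood is cheap and two-dimensional, (b) the confidence construction
needs the full surface anyway, and (c) it is immune to the flat ridges
produced by separation. The surface is evaluated vectorized in chunks of
roughly 4·10⁶ likelihood terms.

Uncertainty uses the **joint 2-dof likelihood-ratio region**:
{θ : LL(θ) ≥ LL_max − ½ χ²₂(level)} (ΔLL ≈ 2.3026 at 90%). Marginal CIs
are the projections of this region onto each axis. Projections are wider
than profile-likelihood intervals, but they honestly reflect the joint
uncertainty of a 2-parameter fit on ~20 patients, naturally produce a
γ₅₀ interval reaching 0 when the slope is weakly identified, and need no
extra machinery. Results flag when the region touches the grid boundary
and when the maximum is non-interior or a class is absent
(`identifiable=False`). A simulation check (500 cohorts of 20, truth
SUVR₅₀=0.5, γ₅₀=2) measured joint 90% coverage of 0.886.

## 4. Synthetic cohort generator

Real serial PET volumes cannot be shipped, so `pettcp.simulate` renders
a cohort whose *patient-level surrogate statistics* are controllable:

1. **Class mixture.** Each patient is a responder or nonresponder.
   Defaults: 20 patients, 9 responders (see §5).
2. **Patient targets.** Per class, the target ⟨SUV_R⟩ and target
   ⟨SUV_pre⟩ are truncated Gaussians (defaults: responders 0.45 ± 0.11,
   pre 4.1 ± 0.94; nonresponders 0.60 ± 0.24, pre 3.50 ± 0.87). Ratios
   are truncated below at 0.05 (post-treatment uptake cannot be
   non-positive); pre-means are truncated below at 2.75 because the mean
   over a mask delineated at SUV > 2.5 necessarily exceeds 2.5 — the raw
   Gaussian puts ~15% of nonresponder mass below the threshold, which
   would be internally inconsistent. The truncation biases the realized
   nonresponder pre-mean up by ≈0.2 SUV; the package's contract (and its
   tests) is the analytic truncated-normal moment, not the raw Gaussian.
3. **Correlation.** The target mean uptake decrease is defined exactly as
   diff = pre · (1 − ratio). The observed cohort correlation between pre
   and diff (default Pearson r = 0.77) is induced by a **Gaussian
   copula** between the pre and ratio targets. Because truncation and
   the class mixture distort the mapping from latent to realized
   correlation, the single latent correlation is calibrated numerically:
   a fixed deterministic quasi-sample (40 000 draws, fixed internal
   seed) is pushed through the exact generator transform and `brentq`
   solves realized r(latent) = target. Unattainable targets (outside
   roughly [−0.31, 0.98] at defaults) raise a configuration error.
4. **Volume rendering.** Each tumor is an ellipsoid of an exact voxel
   count (uniform in a configurable range) on a background below the
   delineation threshold. Voxel-wise pre-SUVs and voxel response ratios
   get log-normal heterogeneity (default CV 0.3), then an exact rescale
   pins the realized masked mean pre-SUV and mean voxel ratio to the
   patient targets to within 10⁻⁶, and an affine shrink keeps every
   tumor voxel above 2.55 so delineation recovers the exact mask.
   Volumes round-trip through NIfTI (nibabel) with 4 mm isotropic
   spacing by default.

All randomness flows from a single `numpy` Generator; identical
configurations are bit-identical. What the generator does **not**
emulate: spatial texture/gradients within the tumor, partial-volume and
reconstruction blur, registration error between time points, necrotic
cores, or multiple lesions. It is a statistical stand-in at the
surrogate level, not an image-physics simulator.

## 5. Inferring the responder:nonresponder split

The source cohort's class split is not published directly, but its
group-comparison P values are. Scanning all splits of 20, the printed
P values for the five surrogate comparisons (0.04 / 0.03 / 0.02 / 0.08
/ 0.13) are reproduced at printed precision on four of five rows by
**one-sided Welch t tests at a 9:11 split** (0.0424 / 0.0298 / 0.0196 /
0.0804 / 0.1202); no other split comes close under either pooled or
Welch, one- or two-sided variants. The generator therefore defaults to
9 responders / 11 nonresponders. This is the package's own inference
from the published summary statistics; `compare_groups` itself defaults
to the conventional two-sided Welch test, with sidedness as a flag.

## 6. Cohort statistics

- Group comparisons: Welch (default) or pooled t via
  `scipy.stats.ttest_ind`, any alternative.
- Correlations: `scipy.stats.pearsonr`, with guards for < 3 patients or
  zero variance; subsets (e.g. responders only) supported.
- Calibration: patients binned on the surrogate (default edges 0.2, 0.4,
  0.6 with an open top bin and a flagged underflow bin), observed
  recurrence fraction per bin with Wilson score intervals
  (`statsmodels`), against the fitted TRP at the bin midpoint.

## 7. Build vs. buy

Standard numerics are delegated: NIfTI I/O (nibabel), t tests and
Pearson r and χ² quantiles (scipy), Wilson intervals (statsmodels),
truncated-normal quantiles (scipy), root finding (brentq), optimization
polish (Nelder–Mead). The scientific content — the erf sigmoid, the
Poisson TCP forms, the grid ML fit with LR regions, and the calibrated
copula generator — is authored in this package.

## 8. Numerical parameters and problem sizes

Defaults were chosen as package decisions: 241×241 grid (resolution
~0.005 in SUVR₅₀, 0.025 in γ₅₀ — below any scientifically meaningful
difference at n≈20); probability clamp 10⁻¹²; calibration sample 40 000
(latent-correlation MC error ≪ 0.01); replicate studies use 500 cohorts
(SE of a mean SUVR₅₀ ≈ 0.005) and rendered-cohort checks use 2000
patients. A full 500-fit replicate study runs in ~30 s.

## 9. Limitations

- Marginal CIs are joint-region projections (conservative vs. profile
  likelihood).
- The generator reproduces surrogate-level statistics, not image
  physics (§4); `ratio_of_means` and voxel-level analyses beyond the
  mean are rendered plausibly but are not calibrated targets.
- With ~20 patients the γ₅₀ slope is weakly identified; boundary flags
  should be heeded before interpreting the estimate.
- The 9:11 split and the 2.75 SUV pre-mean truncation are inferences/
  consistency fixes, not published facts.
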