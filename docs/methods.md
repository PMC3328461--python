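# Methods

This note documents the models, parameter choices and numerical
decisions behind `nigrastar`, and what the synthetic generators do and
do not emulate.

## Signal model and relaxometry

Voxel-wise magnitude signal follows the mono-exponential spoiled
gradient-echo decay

    S(TE) = S0 · exp(−R2* · TE)        (optionally + C),

with R2\* stored in s⁻¹ and TE in ms (converted internally, so regional
values land in the physiologically familiar 20–40 s⁻¹ range). The default
echo train is six echoes, TE = 7, 15, …, 47 ms, TR = 54 ms, flip 20°.
T1 weighting of the spoiled-GRE signal, susceptibility-induced
macroscopic field gradients, multi-compartment T2\* decay, motion and
bias fields are all outside the model.

Two fits are provided because "linear least-squares fit to a
mono-exponential with free baseline" admits two readings:

- **Log-linear (default):** OLS/WLS of ln S on TE with free intercept;
  slope = −R2\*. A truly additive baseline cannot be estimated by
  linear least squares on the log signal, so "free baseline" is read
  here as the free multiplicative S0. Weights wᵢ = Sᵢ² (default on)
  are the first-order variance stabilisation for log-transformed
  magnitude data, since Var[ln S] ≈ σ²/S²; unweighted OLS is available
  for comparison.
- **Nonlinear offset (alternative and cross-check):** three-parameter
  least squares over (S0, R2\*, C), Levenberg-Marquardt with
  xtol/ftol/gtol = 1e−15, initialised from the log-linear fit. On
  noise-free baseline-free data the two agree to <1e−6 s⁻¹ (tested,
  also against an independent profile-likelihood scan oracle).

Voxels with any non-positive echo are excluded from the fitted mask and
counted in the QC report rather than clamped; masked-out voxels carry
NaN. The object mask keeps voxels whose first-echo intensity exceeds
0.1 × the 99th percentile of the first echo (robust to isolated bright
noise). The map-level fit shares one vectorised kernel with the
per-voxel fit, so the two are bit-identical.

## Phantoms and noise

Phantoms are axis-aligned boxes/ellipsoids on a common grid — one label
per structure, background label 0 with zero signal (air) — because the
quantities under test are fitting and summary statistics, not
segmentation; anatomical realism is a non-goal. Per-voxel truth R2\* is
drawn from Normal(mean, sd) truncated at 0; S0 defaults to 1000
arbitrary units with SNR 40 (σ = S0/SNR per channel), both simulator
conventions since real tissue S0/SNR figures are acquisition-dependent.
Rician noise (independent Gaussian on real and imaginary channels
before magnitude) is the default; additive Gaussian is provided for
analytic work and clipped at zero. Each ROI and each echo draws from
its own seeded substream, so adding an ROI or echo never reshuffles the
rest.

Known systematic: fitting Rician magnitudes in the log domain biases
recovered rates low — at SNR 40 the 5–95% trimmed-mean error over a
5000-voxel ROI grows from ≈−0.13 s⁻¹ at 22 s⁻¹ to ≈−0.50 s⁻¹ at
37 s⁻¹ (last-echo SNR falls to ~7 there). The recovery experiments in
`analysis/01_phantom_recovery.py` quantify this; no Rician floor
correction is applied because the estimand of interest downstream is a
rank correlation, which a smooth monotone bias does not disturb.

## ROI summaries

The per-subject regional statistic is the 5–95% trimmed mean: compute
P5 and P95 by linear-interpolation percentiles and average all fitted
voxels within the closed interval [P5, P95]. This guards the regional
mean against segmentation/registration edge voxels. An alternative
convention — trimming 5% of voxels from each tail by count — nearly
coincides for large ROIs; the percentile-value rule is implemented and
the trim bounds are configurable. The SN is treated as a single ROI
(no pars compacta/reticulata split) and hemispheres are pooled.

## Cohort generator

The generator emulates a two-arm observational cohort (default 40 PD /
29 controls): age, gender (17/23 vs 17/12 F/M), statin use (9/40 vs
6/29), fasting total and LDL cholesterol, PD-only clinical scores
(UPDRS-III, disease duration, LEDD — structurally missing in controls),
and per-ROI R2\*. Group marginal means/SDs default to the study-group
values (e.g. PD total cholesterol 195 ± 36 mg/dL, SN R2\*
34.9 ± 5.7 s⁻¹).

Mechanism: exogenous covariates first (age Gaussian; gender, statin
Bernoulli), then for each outcome a standardised latent

    Z_j = a_j·age* + g_j·gender* + s_j·statin* + √(1−a²−g²−s²)·e_j,

with e ~ MVN(0, R_e). Marginals are matched by monotone quantile
transforms — Gaussian for age, lipids, R2\*; moment-matched gamma for
UPDRS-III and LEDD and lognormal for duration (non-negative,
right-skewed) — which leave all Spearman correlations untouched and
reproduce population moments exactly.

**Correlation calibration.** A Spearman target ρₛ between two jointly
Gaussian latents corresponds to a Pearson correlation 2·sin(πρₛ/6).
One further refinement is needed: the rank-based partial-correlation
estimator (ranks residualised on covariate ranks) converges to the
partial correlation of the *uniform scores* — equivalently, the partial
computed from the pairwise Spearman correlation matrix — not to the
Spearman of the Gaussian conditional law. With covariates that
correlate appreciably with the outcome pair (most visibly under the
six-covariate adjustment) the two differ by up to a few hundredths, so
each targeted entry of R_e is root-solved (Brent, xtol 1e−10) so that
the estimator's population value, computed analytically on the Spearman
scale, equals the target; 2·sin(πρ/6) remains the conversion inside the
solve, and binary covariates are treated as Gaussian there (a
second-order approximation at the default loadings). Measured at
n = 20,000 the estimator then sits within ±0.004 of every target; at
the study size (n = 39) small-sample attenuation of order 0.01–0.02
remains, quantified in `analysis/02_cohort_calibration.py`.

Targets stated under the extended covariate set are solved conditioning
on the clinical scores as well, so restating a cell (e.g. GP/total
cholesterol at −0.552 given six covariates) changes only that entry.
The implied R_e must be positive definite; it is checked and the
generator refuses otherwise (no silent projection). Control arms use
zero targets (their printed correlations are non-significant) while
keeping the structural conventions.

**Conventions with no reported counterpart** (config-exposed, chosen
once): covariate loadings — age→R2\* 0.30 (iron accumulates with age),
age→lipids 0.10, gender→lipids 0.15, statin→lipids −0.35, small
age loadings on clinical scores, none binary on clinical so their
latents stay exactly Gaussian; structural correlations — total/LDL
cholesterol 0.85, clinical inter-correlations 0.35–0.45, ROI–ROI 0.25.
The cholesterol-outlier injector sets a chosen subject to group mean +
k·SD (LDL rescaled proportionally) and flags the row; at k = 2.64 a
PD-arm subject lands at ≈290 mg/dL, beyond the 2-SD exclusion rule.

What the generator does *not* emulate: longitudinal progression,
medication pharmacology, genetic covariates, measurement error in the
lipid assay, or any causal structure — correlations are calibrated, not
mechanistic. Passing recovery tests therefore demonstrates that the
estimation chain is unbiased under the stated copula model, not that
the clinical associations would replicate.

## Statistics

- **Spearman partial correlation:** rank x, y and every covariate
  column (average ranks for ties), residualise the ranked x and y on an
  intercept plus the ranked covariates by least squares, and correlate
  the residuals. Two-sided p from t = ρ√((n−2−k)/(1−ρ²)) with
  df = n−2−k. With k = 0 this is exactly classical Spearman (tested to
  1e−12), and with one covariate it matches the 3×3
  correlation-matrix-inversion formula exactly. Binary covariates enter
  as 0/1 indicators (ranks of a binary are affine in the indicator, so
  coding cannot change ρ). Constant x/y or collinear covariates raise;
  a covariate that is constant *within one analysis cell* of the table
  builders is dropped for that cell and logged, since adjusting for a
  constant is vacuous. Note: at n = 39, k = 3, ρ = −0.429 this df
  convention gives p ≈ 0.009; other software conventions can print
  ≈0.011 for the same ρ.
- **ANCOVA:** OLS of outcome on group indicator + covariates; the group
  coefficient (case − control) and its two-sided t-test p are reported.
  Without covariates this reduces exactly to the pooled-variance
  two-sample t-test.
- **Fisher's exact test:** two-sided by summing hypergeometric
  probabilities ≤ the observed table's (scipy), verified against full
  enumeration over fixed margins in the tests.
- **Outlier rule:** a subject is excluded when total cholesterol
  exceeds its *own group's* mean + 2 SD (mean/SD computed including the
  candidate). Per-group rather than pooled SD because both reference
  extreme values (290 and 285 mg/dL) satisfy the rule under per-group
  moments. Exclusion is applied before the correlation tables and
  logged with subject ids.
- No multiple-comparison correction anywhere, by design; analyses are
  complete-case per table cell with logged n.

## Pipeline, seeding and problem sizes

`run_pipeline` executes simulate → fit → summarise → analyse from one
config, writing CSV tables plus a manifest (seed, per-stage wall clock,
SHA-256 of every output). One master seed is split into named
substreams (CRC-32 of "cohort", "phantom/<subject>", …), so stages
re-run independently and adding a subject never reshuffles another's
draws; equal config + seed gives byte-identical outputs (tested).

Default problem sizes were chosen so every experiment runs in seconds
while keeping Monte-Carlo error well inside the decision margins:
5000-voxel ROIs for noisy recovery (trimmed-mean SE ≈ 0.02 s⁻¹),
500 replicate cohorts of n = 39 for correlation recovery (SE of the
mean ≈ 0.006), 10,000–20,000 subjects for marginal calibration, and a
24³-scale grid per subject in the end-to-end pipeline (≈500 voxels per
ROI). Larger sizes only shrink error bars; they do not change any
conclusion.

## Known limitations

- The Rician/log-fit bias is uncorrected (see above); absolute R2\*
  accuracy at low late-echo SNR is bounded by it.
- The estimator-inverting calibration treats binary covariates as
  Gaussian; residual asymptotic miscalibration is ≲0.005 at the default
  loadings and grows with binary loading size.
- The copula model is single-timepoint and linear-in-latents; it cannot
  represent interaction or threshold effects between covariates and
  outcomes.
- The offset-model fit needs ≥4 echoes and can sit in a shallow
  objective at high rates where the late echoes carry little signal;
  non-convergence falls back to the log-linear fit and is flagged.
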