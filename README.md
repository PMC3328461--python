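# nigrastar

Quantitative pipeline from multi-echo gradient-echo MRI to nigrostriatal
R2\* (a brain-iron proxy) to covariate-adjusted cholesterol–iron
correlations, with digital phantoms and synthetic case-control cohorts
so that every stage is verifiable by parameter recovery.

## The problem

Iron accumulates in the substantia nigra (SN) of people with Parkinson's
disease, and serum cholesterol appears inversely related to disease risk
and progression. Ferritin-bound iron shortens the effective transverse
relaxation time T2\* of gradient-echo MRI, so the relaxation rate
R2\* = 1/T2\* (s⁻¹) serves as an in-vivo iron proxy. The analysis chain
this package implements asks: *after adjusting for age, gender and
statin use, do regional R2\* values co-vary with fasting serum
cholesterol in a case-control cohort?*

Clinical image data of this kind are rarely shareable, so the package
pairs each analysis stage with a generator that emulates its inputs:

1. **`nigrastar.phantom`** — digital phantoms: ROI label maps (SN,
   caudate, putamen, globus pallidus + background) with ground-truth
   R2\*/S0 maps, and simulation of six-echo magnitude volumes
   (TE 7–47 ms, ΔTE 8 ms, TR 54 ms, flip 20°) under Rician noise.
2. **`nigrastar.relaxometry`** — voxel-wise mono-exponential fitting:
   weighted log-linear fit of ln S on TE (slope = −R2\*), and a
   three-parameter fit S(TE) = S0·e^(−R2\*·TE) + C with additive
   baseline; object masking and QC counts.
3. **`nigrastar.roi`** — per-ROI summaries via the 5–95% trimmed mean
   (mean of voxels between the 5th and 95th ROI percentiles).
4. **`nigrastar.cohort`** — a Gaussian-copula cohort generator whose
   group marginals (R2\*, lipids, clinical scores, demographics) and
   covariate-adjusted Spearman correlation structure are calibrated
   targets; a target ρₛ maps to a latent Pearson correlation through
   2·sin(πρₛ/6), refined so the rank-based partial-correlation
   estimator converges exactly to the target.
5. **`nigrastar.stats`** — Spearman partial correlation with covariate
   adjustment (rank → residualize → correlate; t-test with df = n−2−k),
   ANCOVA group comparisons, pooled-variance t-tests, Fisher's exact
   test, the 2-SD cholesterol outlier rule, and tidy table builders.
6. **`nigrastar.pipeline` / `nigrastar.cli`** — one-config end-to-end
   orchestration with named seed substreams and a run manifest.

Numbered drivers under `analysis/` run the full study-scale experiments
and write their tables to `results/`.

## Worked example

```python
import nigrastar as ns

# 1. phantom -> six-echo volume -> R2* map -> ROI summary
spec = ns.default_nigrostriatal_spec("control")
labels, truth, s0 = ns.build_phantom(spec, seed=1)
vol = ns.simulate_multi_echo(truth, s0, ns.EchoTrain.default(),
                             ns.NoiseSpec("rician", snr=40, seed=1))
r2map = ns.fit_map(vol, ns.make_mask(vol))
print(round(ns.trimmed_mean(ns.extract_roi_values(r2map, labels, 1)), 2))
# 30.12  <- SN trimmed-mean R2* (s^-1); ground-truth ROI mean was 30.4

# 2. synthetic cohort -> adjusted correlation
df = ns.simulate_cohort(ns.default_cohort_spec(seed=42))
table, log = ns.build_correlation_table(df)
row = table.query("group=='PD' and roi=='SN' and variable=='total_chol'"
                  " and covariate_set=='basic'").iloc[0]
print(f"rho={row.rho:.3f} p={row.p:.4f} n={row.n}")
# rho=-0.216 p=0.2057 n=39
```

The first number is the regional iron estimate a real study would carry
forward per subject (the 0.28 s⁻¹ shortfall is the expected Rician /
log-fit bias at SNR 40). The second is the covariate-adjusted rank
correlation between SN iron and total cholesterol in one simulated PD
arm: n is 39 because one subject was excluded by the 2-SD cholesterol
rule, and a single draw at this sample size scatters around the
generating target of −0.429 with SD ≈ 0.13 — averaging over replicate
cohorts (see `analysis/02_cohort_calibration.py`) recovers the target
to within ~0.02.

The same stages are available from the shell:

```bash
nigrastar phantom --out-dir run/ph --seed 1
nigrastar fit-r2star --input run/ph/multiecho.nii.gz --out run/ph/r2star.nii.gz
nigrastar roi-summarize --r2star run/ph/r2star.nii.gz --labels run/ph/labels.nii.gz --out run/roi.csv
nigrastar simulate-cohort --out run/cohort.csv --seed 7
nigrastar analyze --cohort run/cohort.csv --out run/tables
nigrastar run-all pipeline.yaml
```

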