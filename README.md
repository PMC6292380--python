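# covfdr

Covariate-conditional estimation of the proportion of true null hypotheses,
π₀(x), and the resulting plug-in false discovery rates, for large-scale
multiple testing problems where per-feature meta-data is available — e.g. a
GWAS meta-analysis in which every SNP has its own sample size N and minor
allele frequency (MAF), and loci with larger N or MAF are a priori more
likely to show true associations.

## The method

Given m p-values P₁,…,P_m and an m×p covariate design **Z** (intercept plus
linear, natural-cubic-spline, or quantile-category terms):

1. For each threshold λ in a grid (default 0.05, 0.10, …, 0.95), form the
   exceedance indicators Yᵢ = 1(Pᵢ > λ). Null p-values are uniform, so
   E(Yᵢ | xᵢ) ≈ π₀(xᵢ)·(1 − λ).
2. Estimate E(Yᵢ | xᵢ) by logistic regression on **Z** (a linear-regression
   variant is also provided) and set π̂₀^λ(xᵢ) = Ê(Yᵢ | xᵢ)/(1 − λ),
   thresholded into [0, 1].
3. Smooth each feature's profile λ ↦ π̂₀^λ(xᵢ) with a cubic smoothing spline
   at 3 effective degrees of freedom; the final estimate π̂₀(xᵢ) is the
   smoothed value at the largest threshold, clipped into [0, 1].
4. Bootstrap (resampling features, p-value and covariate row together) gives
   percentile confidence bands for π̂₀(xᵢ).
5. The covariate-adjusted plug-in FDR is F̂DR(xᵢ) = π̂₀(xᵢ) · BHᵢ, the
   product with the Benjamini–Hochberg adjusted p-value, capped at 1.

With an intercept-only design and the linear method, step 2 reduces exactly
to the classical threshold estimator π̂₀ = (m − R)/((1 − λ)m), so the scalar
"Storey-style" smoothed estimator is the no-covariate special case. Because
π̂₀(xᵢ) ≤ 1, every BH discovery is also a discovery of the plug-in at the
same nominal level; when the covariates are informative the method gains
power by locally discounting the null fraction.

The package also contains the full Monte-Carlo study used to validate the
method: scenario families for π₀(x) (flat, smooth, category-offset, linear,
x^k), alternative statistic families (Beta(1,20) p-values; normal, t(10),
and χ²(1 or 4 df) statistics), optional block-equicorrelated statistics, and
the realized-FDR / true-positive-rate scoring of the covariate plug-in
against the scalar-π₀ and BH baselines.

## Worked example

Estimate π₀(N, MAF) for a 5,000-feature table with a spline in sample size
and MAF terciles:

```bash
covfdr estimate --input example.tsv --p-col p \
    --covariates N:spline --covariates MAF:terciles \
    --id-col snp --seed 7 --out example_results.tsv
# wrote example_results.tsv: 5000 features, 468 discoveries at nominal FDR 0.05
```

The output table has one row per feature — `id, p, pi0, ci_lower, ci_upper,
bh_adjusted, fdr_covariate` — plus a `.provenance.json` sidecar with the
full configuration and seed. `pi0` is the estimated prior probability that
the feature is null given its covariates; `fdr_covariate = pi0 ×
bh_adjusted` is the quantity to threshold at the nominal FDR level.

Simulation study, one cell (π₀(x₁) = x₁, normal statistics, 50 runs):

```bash
covfdr simulate --scenario V --m 1000 --dist normal --runs 50 --seed 3 --out sim_v.tsv
```

```
scenario   dist reg_model    method metric  value   se  n_runs
       V normal    linear BL-linear    FDR   4.18 0.17      50
       V normal    linear BL-linear    TPR  78.70 0.49      50
       V normal    linear    Storey    FDR   4.57 0.18      50
       V normal    linear    Storey    TPR  74.07 0.45      50
       V normal    linear        BH    FDR   2.51 0.13      50
       V normal    linear        BH    TPR  66.83 0.37      50
```

All three procedures hold the realized FDR at or below the nominal 5%; with
this highly informative covariate the covariate-regression plug-in
(`BL-linear`) detects ~79% of true alternatives versus ~74% for the
scalar-π₀ baseline and ~67% for BH.

## Library use

```python
import numpy as np
from covfdr import estimate_pi0, bh_adjust, plugin_fdr

fit = estimate_pi0(p, Z)                 # Z: m×p design, intercept first
fdr = plugin_fdr(fit.pi0, bh_adjust(p))  # covariate-adjusted FDR per feature
discoveries = fdr <= 0.05
```

`covfdr.design.build_design` assembles **Z** from a covariate table
(splines, terciles, interactions); `covfdr.pi0.bootstrap_pi0` adds
confidence bands; `covfdr.simulate.run_study` runs a full simulation cell.

## Acceptance script

`scripts/acceptance.py` re-runs the validation studies from scratch — the
full 200-replicate simulation cells at m = 1,000 and 10,000 for the flat,
linear-π₀, and global-null scenarios across the alternative families — and
writes the summary quantities (mean realized FDR and TPR in percent, mean
π̂₀ under the global null) as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes about half a minute on one CPU.
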