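# combatstab

**When can you trust ComBat?** Multi-site neuroimaging studies routinely pool
ROI-level scalar features (mean fractional anisotropy or mean diffusivity per
white-matter region) across scanners, and routinely remove the resulting site
effects with ComBat. ComBat's empirical-Bayes machinery, however, is estimated
from the data at hand — and its stability depends on how many participants
each site contributes, how unevenly, and how demographically mismatched the
sites are. `combatstab` is a toolkit for quantifying that stability: it pairs
a synthetic two-site cohort generator with known ground-truth site effects, a
parametric empirical-Bayes ComBat implementation, a bootstrap experiment over
sample size × site imbalance × covariate (age) shift, RMSE-based stability
metrics referenced to a full-cohort "silver standard", and diagnostics for
ComBat's distributional assumptions.

It is aimed at researchers planning or auditing multi-site harmonization:
before trusting ComBat on a 40-per-site study with a 6-year age gap between
sites, simulate that design and measure what happens.

## The model

ComBat assumes each feature *f* measured on participant *i* at site *s*
decomposes as

    Y_isf = α_f + X_i β_f + γ_sf + δ_sf ε_isf ,   ε_isf ~ N(0, σ_f²)

with additive site shift γ_sf and multiplicative site scale δ_sf. Fitting
standardizes the data,

    Z_isf = (Y_isf − α̂_f − X_i β̂_f) / σ̂_f ,

under the identifiability constraint Σ_s n_s γ̂_sf = 0 (σ̂_f² uses the 1/N
divisor), shrinks the per-site location/scale estimates across features via
empirical Bayes — a normal prior on γ, an inverse-gamma prior on δ² with
method-of-moments hyperparameters, iterated conditional-posterior updates —
and adjusts:

    Ŷ_isf = σ̂_f (Z_isf − γ̂*_sf) / δ̂*_sf + α̂_f + X_i β̂_f .

Downstream, each feature's association with age is fit per feature as
`Ŷ ~ 1 + age + sex + site + diagnosis`, and every bootstrap subsample is
scored against the silver-standard fit by the mean-over-features RMSE of the
standardized age effect (β_age divided by the silver-standard SE), of γ̂*, of
log δ̂*, and of their between-site differences. The implementation matches
Bioconductor's `sva::ComBat` to ~1e-8 on shared inputs (this is one of the
tests).

## Worked example

```python
import combatstab as cs

# a matched two-site cohort: 159/site, ~74y, 112 FA-like features,
# known site shifts (~±0.01) and scales (ratio ≈ 1 ± 10%)
table, truth = cs.generate_matched_cohort(cs.CohortConfig(seed=1))

harmonized, fit = cs.harmonize(table)           # parametric EB ComBat
print(fit.n_iter)                               # {'site1': 3, 'site2': 3}

# site-mean gap before/after, averaged over features
import numpy as np
m1, m2 = table.site_mask("site1"), table.site_mask("site2")
raw = np.abs(table.values[m1].mean(0) - table.values[m2].mean(0)).mean()
adj = np.abs(harmonized.values[m1].mean(0) - harmonized.values[m2].mean(0)).mean()
print(f"{raw:.5f} -> {adj:.5f}")                # 0.01984 -> 0.00113

# bootstrap stability at three sample sizes, balanced, no age shift
reg = cs.fit_feature_regressions(harmonized, "combat_ols")
grid = cs.build_grid(table, [36, 144, 306], [10], [0])
runs = cs.run_experiment(table, grid, B=10, master_seed=1)
report = cs.compute_stability(runs, (fit, reg))
print(report.long[report.long.metric == "rmse_std_beta_age"]
      [["point_id", "value"]].to_string(index=False))
#          point_id    value
#    N36_X10_S0_none 2.791613
#   N144_X10_S0_none 1.117634
#   N306_X10_S0_none 0.198199
```

The last column is the mean (over 112 features) RMSE of the standardized age
effect across 10 bootstrap subsamples: at N=36 total the age effect is off by
~2.7 silver-standard standard errors on average — harmonization plus
regression is unstable — while at N=306 it is reproducible to a fraction of
an SE. A 1.0 is the natural instability threshold (errors the size of the
reference SE).

The same machinery is exposed as a CLI:
`combatstab simulate|harmonize|grid-run|regress|report|diagnose --help`.

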