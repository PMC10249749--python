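# combatsim

Simulation toolkit for studying how outliers affect **ComBat harmonization**
of multisite imaging-derived phenotypes (IDPs).

Multisite neuroimaging studies pool measures such as regional grey-matter
volumes across acquisition sites whose scanners and protocols shift both the
mean and the spread of the data ("site effects").  ComBat removes these
effects with an empirical-Bayes location-scale model — but its site-effect
estimates are themselves sample statistics, so extreme values in one site
bias the fit, squeeze the non-outlier ("normal") samples of the contaminated
site, inflate the others, and corrupt pooled brain–behavior correlation
analyses.  `combatsim` generates realistic multisite data, injects outliers
under six controlled placement scenarios, harmonizes with ComBat (naive or
robust fit-on-normals), and quantifies the damage.

## The model

Per site *i*, subject *j* and feature *v*:

```
Y_ijv = α_v + X_ij β_v + γ_iv + δ_iv ε_ijv ,   ε_ijv ~ N(0, σ_v²)
```

with additive (γ) and multiplicative (δ) site effects.  Data are
standardized feature-wise, `Z = (Y − α̂ − Xβ̂)/σ̂`, the per-(site, feature)
effects are shrunk across features by empirical Bayes under the parametric
priors `γ_iv ~ N(γ̄_i, τ_i²)` and `δ_iv² ~ InverseGamma(λ_i, θ_i)`
(method-of-moments hyperpriors, coupled conditional-posterior-mean updates),
and the adjusted data are

```
Y*_ijv = σ̂_v (Z_ijv − γ*_iv) / δ*_iv + α̂_v + X_ij β̂_v .
```

Outliers are defined by Tukey's k = 3 fences: a value is an outlier when its
**outlier score** `min(|x − Q1|, |x − Q3|)/IQR` is at least 3.  Injected
outlier clouds are multivariate-normal with per-feature mean
`Q3 + score·IQR` (or `Q1 − score·IQR`) and covariance `0.003² × R`, R being
the site's normal-data correlation matrix.  Six scenarios place the clouds
on one side or both sides of one or two sites; every non-target site gains
an equal number of fresh normal rows so sample sizes stay balanced, and the
behavioral variable never receives outliers.

The implementation is validated against Bioconductor `sva::ComBat`
(agreement to ~1e-13) and an independent brute-force location-scale oracle.

## Worked example

```python
from combatsim import (make_default_dataset, OutlierSpec, Scenario,
                       inject_outliers, detect_outliers, harmonize,
                       correlations_by_site, normal_sample_moments)

ds = make_default_dataset(n_per_site=300, n_features=30, target_idp=15, seed=0)
spec = OutlierSpec(scenario=Scenario.ONE_SITE_UNILATERAL,
                   quantity_fraction=0.05, score=20.0, seed=1)
inj = inject_outliers(ds, spec, target_idp=15)

naive, _ = harmonize(inj.values, inj.site_labels)
flags = detect_outliers(inj).subject_flags          # Tukey-fence detection
robust, _ = harmonize(inj.values, inj.site_labels, exclude_mask=flags)
```

This injects 15 score-20 outlier rows above Site 1's upper fence and prints
(see `normal_sample_moments` / `correlations_by_site`):

```
normal-sample variance of the target IDP:
          before  naive  robust
Site 1     0.332  0.120   0.473
Site 2     0.520  4.404   0.510
Site 3     0.616  4.296   0.485
combined   1.120  3.018   0.489

IDP-behavior Pearson r (all rows | normal rows):
  before: +0.299 | +0.645
   naive: +0.718 | +0.862
  robust: +0.283 | +0.980
```

Reading: the naive fit equalizes each site's **total** variance, so the
outlier-inflated Site 1 gets squeezed (0.33 → 0.12) while the clean sites
are stretched (≈0.5 → ≈4.4), and the pooled normal-sample correlation stays
attenuated (0.86 vs the outlier-free ≈0.98).  The robust variant — fit on
Tukey-unflagged rows, apply to all rows — restores both the normal-sample
variances (≈0.5 everywhere) and the pooled correlation (0.980).

## Command line

```
combatsim generate --n-per-site 300 --n-features 30 --target-idp 15 --seed 0 --out data.csv
combatsim inject --dataset data.csv --scenario one_site_unilateral \
          --quantity 0.05 --score 20 --target-idp 15 --out injected.csv
combatsim harmonize --dataset injected.csv --robust --out harmonized.csv
combatsim run-all --seed 11 --out sweep_out     # full 6x5x7 sweep + reports
combatsim report --run-dir sweep_out
```

`run-all` writes a tidy `report.csv` (one row per grid cell × site × phase ×
mode), `scenario_icc.csv` (ICC agreement of the 35-cell correlation vectors
across outlier-placement scenarios), `normal_summary.json`, `manifest.json`
(config + per-cell seeds) and `run.log`.

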