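# thermoparam

Plasma differential scanning calorimetry (DSC) thermogram parameterization
and statistical modelling of melanoma patient status and survival.

A plasma thermogram is the excess specific heat capacity of a plasma sample,
c_p^ex(T) in cal/°C·g, recorded over 45–90 °C at 0.1 °C steps as the plasma
proteome thermally denatures.  Disease-related changes in the proteome
reshape this curve, so thermograms are candidates for inexpensive blood-based
screening, surveillance, and prognosis.  `thermoparam` implements, as a
tested and reusable library, the full analysis pathway used to evaluate that
idea in a three-group melanoma cohort (healthy controls, patients with no
evidence of disease (NED), patients with active disease):

1. **Preprocessing** (`thermoparam.io`) — reference subtraction, protein-mass
   normalization, linear baseline correction anchored at 45–50 / 85–90 °C,
   replicate averaging, and interpolation onto the canonical 451-point mesh.
2. **Parameterization** (`thermoparam.metrics`, `thermoparam.pca`) — 20
   summary metrics per curve (Width at half height, Area, Max, Median, TMax,
   first-moment temperature TFM, the three window-defined peaks at 60–66.9 /
   67–72.9 / 73–78 °C with positions, the Peak 1–2 valley V1.2, and six
   height ratios), with two cross-checked peak finders (windowed maximum vs
   monotone run-length), plus mean-centered PCA of the full curves.  The
   statistical parameter set is the 19 metrics (TPeak3 excluded) + PC1–PC4.
3. **Status models** (`thermoparam.status`) — per-parameter linear models of
   group × sex with partial-F model reduction, Shapiro/Breusch–Pagan
   diagnostics with a median-regression fallback, Benjamini–Hochberg FDR
   across the 23-parameter family, and Tukey-adjusted marginal-mean pairwise
   contrasts.
4. **NED-vs-active classification** (`thermoparam.classify`) — logistic
   regression with VIF ≤ 5 multicollinearity screening, forward/backward
   stepwise AIC/BIC selection, and 25×5 repeated stratified cross-validated
   ROC-AUC.  Model effects are reported as percent change in odds,
   100·(e^β − 1).
5. **Survival** (`thermoparam.survival`) — univariate Cox screening with FDR,
   backward-BIC multivariable Cox, Kaplan–Meier curves split at the median
   parameter value with the Mantel–Cox test, and restricted mean survival
   time at τ = 8 years with Greenwood plug-in variances (verified against R's
   `survival` package).
6. **Synthetic cohorts** (`thermoparam.simulate`) — a generator producing
   49/74/33 three-group cohorts of three-transition curves with realistic
   demographics, a +0.4 °C active-group T_Peak2 shift, and a latent
   PC3-like factor driving the overall-survival log-hazard at β = 0.553, so
   every stage is testable end to end without patient data.

## Worked example

```python
import numpy as np
from thermoparam import (GeneratorConfig, generate_cohort, build_cohort_table,
                         NedActiveLogit, km_median_split, rmst_compare)
from thermoparam.classify import LogisticModel, calibrate_intercept, predict_probability

cohort = generate_cohort(GeneratorConfig(), seed=0)          # 156 samples
table = build_cohort_table(cohort.curves, cohort.clinical)   # metrics + PCs + clinical

model = NedActiveLogit(table, ["age", "TPeak2"])
print(model.fit().summary().round(4).to_string(index=False))
print(f"mean cross-validated AUC: {model.cross_validate(seed=0).mean_auc:.3f}")
```

```
     term  estimate     se  odds_change_pct
Intercept  -49.5748    NaN              NaN
      age    0.0451 0.0153              4.6
   TPeak2    0.6797 0.2894             97.3
mean cross-validated AUC: 0.707
```

Each additional year of age raises the odds of active disease by ~4.6%, and
each 1 °C upward shift of the second denaturation peak roughly doubles them —
the synthetic cohort's generating effects, recovered by the fitted model.
With the published slopes (0.0427 per year, 0.5010 per °C) and the intercept
calibrated to a 74.1% active-disease probability at the cohort medians
(age 57, T_Peak2 = 70 °C):

```python
slopes = {"age": 0.0427, "TPeak2": 0.5010}
b0 = calibrate_intercept(slopes, {"age": 57, "TPeak2": 70}, 0.741)
m2 = LogisticModel(["age", "TPeak2"], [0.0427, 0.5010], b0)
```

a one-SD drop in age (57 → 43) gives 61.1% and a one-SD drop in T_Peak2
(70 → 69 °C) gives 63.4% — nearly equivalent impacts per standard deviation.

Survival, on the same synthetic cohort:

```python
active = table[table.status == "active"]
split = km_median_split(active["PC3"], active["os_time"], active["os_event"])
arm = np.where(active["PC3"] > split.median_value, "above", "at-or-below")
rmst = rmst_compare(arm, active["os_time"], active["os_event"], tau=8.0,
                    level_order=("above", "at-or-below"))
```

prints `log-rank p = 0.023` and restricted means of 4.06 years (above the
PC3 median) versus 5.35 years (at or below): patients whose curves load
high on the valley-deepening / peak-3-tail mode die sooner.

## Command line

```bash
thermoparam simulate --out data/ --seed 1
thermoparam all --thermograms data/thermograms.csv --clinical data/clinical.csv \
                --out report/ --seed 1
```

`report/` then holds the cohort table, PCA loadings/scores with scree plot,
per-parameter status-model and contrast tables, classification CV results
with ROC bands, Cox/KM/RMST outputs, diagnostic figures and a manifest.
Subcommands `metrics`, `pca`, `status`, `classify` and `survive` run single
stages.  Real thermogram matrices in the same wide-CSV layout (column 1
`Temperature`, one column per sample) are accepted anywhere the synthetic
files are.

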