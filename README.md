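# secrdsm

Spatially explicit capture-recapture (SECR) with density-surface modelling
for DNA hair-snag surveys of wide-ranging carnivores, plus the classical
closed-population + telemetry-residency estimator for comparison and a
source-sink ("safe harbor" / "attractive sink") classification of the
sampled landscape.

The package targets the design used in large grizzly bear inventories: a
systematic grid of hair-snag detectors (one site per 7 × 7 km cell, moved
between each of 4 sampling occasions), individual identification from hair
DNA, habitat-value (RSF) and mortality-risk surfaces as spatial covariates,
and radio-telemetry from a subset of animals. Because such data are
typically access-restricted, a synthetic-study generator reproduces every
structural feature of the design with known truth, and all statistical
claims in the test suite are checked against that truth.

## The model

Animal activity centres are a realisation of an inhomogeneous Poisson point
process with intensity `D(x)` on a habitat mask (a regular lattice of points
with cell area `a`, default spacing 3.5 km). Detection of an animal centred
at `x` by detector `k` in occasion `s` is an independent Bernoulli trial
with half-normal kernel

```
p_sk(x) = g0_sk · exp( −d(x, x_sk)² / (2 σ_sk²) )
```

where `g0` (logit link) is detectability at the home-range centre and `σ`
(log link) the spatial scale of movement. Both may depend on site
covariates (terrain ruggedness, canopy closure), a linear session trend,
behavioural responses (`b`, `bk`), or a 2-class finite mixture. The full
log-likelihood of the `n` observed capture histories ω is

```
log L = Σᵢ log[ a Σₘ D(xₘ) Pr(ωᵢ | xₘ) ] − Λ − log n!,
Λ = a Σₘ D(xₘ) p·(xₘ)
```

with `p·(x)` the probability of at least one detection. Density surfaces are
log-linear in the mask covariates — `constant`, `RSF`, `Risk`, `RSF+Risk`,
`RSF×Risk` — fit jointly with detection by maximum likelihood and compared
by AICc and Akaike weights. Home-range centres have posterior
`∝ D(xₘ)·Pr(ωᵢ|xₘ)` over the mask. The comparison estimator is a Huggins
closed-population model (conditional likelihood; M0/Mt/Mb/Mh2) with
Horvitz–Thompson abundance `N̂ = Σᵢ 1/p*ᵢ`, corrected for partial use of the
grid by per-animal residency predicted from a binomial regression of
telemetry residency on distance from the grid edge.

## Worked example

```python
import numpy as np
from secrdsm import (StudyDesign, LandscapeConfig, simulate_study,
                     DetectionModelSpec, fit_density_models, categorize_mask,
                     category_summary, predict_density)

design = StudyDesign(n_cells_x=8, n_cells_y=8)   # 8×8 cells of 7 km, 4 occasions
study = simulate_study(
    design,
    detection_params={"F": (0.2, 3.5)},          # true g0, sigma (km)
    density_betas={"F": {"intercept": np.log(45.0) - 0.25*5.5 + 0.15*5.5,
                         "RSF": 0.25, "Risk": -0.15}},
    landscape=LandscapeConfig(extent=(-14, -14, 70, 70), autocorr_range=10.0, seed=1),
    seed=1,
)
fits, table = fit_density_models(study.capture, study.layouts, study.mask,
                                 DetectionModelSpec())
print(table)
best = fits[table["model"].iloc[0]]
print(best.summary())
```

prints the AICc ranking of the five density surfaces

```
   model    loglik  k     AICc  dAICc  weight  tied_with_constant
RSF*Risk -1082.672  6 2177.953  0.000   0.561               False
RSF+Risk -1084.008  5 2178.448  0.495   0.438               False
     RSF -1091.784  4 2191.853 13.900   0.001               False
    Risk -1111.703  4 2231.692 53.738   0.000               False
constant -1123.715  3 2253.601 75.647   0.000               False
```

— the RSF-containing surfaces dominate (the data were generated with a
positive RSF and negative Risk effect), and the selected fit recovers the
generating detection parameters:

```
  g0    = 0.1375  (95% CI 0.0999-0.1862)
  sigma = 3.875 km  (95% CI 3.435-4.371)
  D     = 45.203 /1000 km^2  (95% CI 34.571-59.106)
```

The σ interval covers the generating 3.5 km; on this particular realisation
`ĝ0` lands somewhat below the generating 0.2 (single-dataset sampling error —
the replicated recovery study in `scripts/acceptance.py` shows the estimator
is centred). Classifying the mask at the covariate medians and summarising
the predicted surface:

```python
labels, thresholds = categorize_mask(study.mask)
cats = category_summary(predict_density(best), labels, study.mask)
ra = best.region_abundance()
```

```
         category  area_km2  mean_density_per_1000km2  relative_abundance
      safe_harbor     857.5                     142.4               122.1
  attractive_sink     710.5                      57.7                41.0
 low_rsf_low_risk     735.0                      25.6                18.8
low_rsf_high_risk     833.0                      26.3                21.9
grid abundance: N = 203.8 (95% CI 164.9-251.9), density 65.0 per 1000 km^2
```

Mean density in safe-harbor habitat (high RSF, low Risk) is ~2.5× that in
attractive-sink habitat (high RSF, high Risk), exactly the contrast the
negative generating Risk effect implies; `relative_abundance` is mean
density × category area, so the four rows add up to the grid abundance.

A thin CLI drives the same pipeline from YAML configs:

```sh
secrdsm simulate config.yaml   # write synthetic layouts/capture/mask/telemetry
secrdsm select   config.yaml   # AICc table of the five density surfaces
secrdsm report   config.yaml   # full pipeline -> report.json
```

(also `fit`, `predict`, `centers`, `closedtel`, `classify`, `esa`).

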