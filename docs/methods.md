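# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the standing simulation studies. Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
compute.

## SECR likelihood

Detectors are binary proximity devices: each animal × detector × occasion
cell is an independent Bernoulli trial, and repeated hair deposits at one
site within one occasion collapse to a single record (a DNA hair snag
identifies presence per session, not counts). Activity centres follow an
inhomogeneous Poisson process with log-linear intensity on the habitat
mask, so the number of *detected* animals is Poisson with mean
Λ = a Σₘ D(xₘ) p·(xₘ) and the full likelihood of the observed histories is

    log L = Σᵢ log[ a Σₘ D(xₘ) Pr(ωᵢ|xₘ) ] − Λ − log n!

The −log n! constant is included so values are comparable across models fit
to the same data. All spatial integrals are mask sums; mask-refinement
tests confirm the approximation error is far below inferential relevance at
the default 3.5 km spacing when σ ≳ the spacing.

**Links and standardisation.** logit(g0), log(σ), log(D). Detection
covariates are z-scored over detector-occasions before fitting, density
covariates over in-grid mask points; reported covariate effects are on the
standardised scale. Intercepts therefore describe a site/point at mean
covariates. Density is parameterised per 1000 km² throughout.

**Detection-model menu.** Per parameter (g0 and σ): any layout covariate
column; `trend` (linear in occasion index, z-scored); `b` (permanent
response after an animal's first detection); `bk` (site-specific response);
`h2` (2-class finite mixture with shared logit mixing weight — the standard
finite-mixture treatment of unobserved heterogeneity). Behavioural terms
modify only occasions after the triggering detection; Λ and p· always use
naive (pre-response) parameters, since an undetected animal never triggers
a response. `bk` is of limited use when sites move between occasions and is
excluded from default candidate sets in that case. The kernel is
half-normal only.

**Fitting.** Quasi-Newton (L-BFGS-B) on the packed link-scale vector with
finite-difference gradients; starting values are data-driven (σ from the
within-animal spread of detection sites, g0 from detections per animal per
effective site, D from n over mask area). Convergence is flagged on the
result and never silent; g0 → 1 triggers a boundary warning. The
variance matrix is the inverse finite-difference Hessian at the optimum;
positive parameters get delta-method SEs and log-scale (σ, D) or
logit-scale (g0) 95% intervals. Five-fold perturbed restarts agree to
< 1e−4 in log-likelihood on the test fixtures. With no spatial recaptures σ
is structurally unidentifiable: the fit proceeds but σ is flagged and its
estimate suppressed from summaries.

**Model selection.** AICc with n = number of detected individuals (the
standard convention for capture-recapture); Akaike weights over the
candidate set; models within 2 AICc units of the constant model are flagged
"tied with constant". The density candidate set is exactly five surfaces:
constant, RSF, Risk, RSF+Risk, RSF×Risk (interaction = product of the
standardised mains, mains always included). RSF/Risk enter as continuous
values; ordinal score inputs are accepted as-is.

**Buffer choice.** `esa_curve` reports the implied density n/esa(buffer),
esa = a Σ p·, over a ladder of buffer widths; `choose_buffer` takes the
smallest width at which the estimate moves < 1% per step. Simulation
studies here use a 4σ buffer, which sits on the flat part of the curve in
all test configurations.

## Density surfaces, centres, classification

Covariate rasters are summarised to the mask as the mean within a 1.75 km
radius of each point (half the 3.5 km spacing); points without raster
coverage fall back to the containing cell, then to nearest-neighbour fill
from covered mask points, and fills are flagged `<name>_filled`. Predicted
surfaces carry delta-method SEs on the response scale; predictions at
covariate values outside the fitted range are flagged `extrapolated` with a
warning and excluded from region summaries by default. Region abundance is
N̂ = a Σ D̂ over flagged points with a delta-method log-normal CI.

Home-range-centre posteriors are D̂(xₘ)·Pr(ωᵢ|xₘ) normalised over the mask,
computed in log space; region tabulations use the posterior *mode* (a mask
point with a well-defined region flag; ties break to the lowest point
index), with the posterior mean reported alongside as a diagnostic.

Classification splits both covariates at their median over in-grid points;
"high" is strictly above the median, so ties go low for both RSF and Risk
(documented tie rule). High RSF + low Risk = safe harbor; high RSF + high
Risk = attractive sink. Category summaries report mean density, area,
relative abundance (mean density × area), the overall mean density
(the reference line), and the equal-density abundance expectation
(proportional to area); an optional per-category count of estimated centres
supports the observed-vs-modelled comparison. Under a constant-density fit
the selection signal is zero by construction.

## Closed-population + telemetry estimator

Occasion-pooled histories (detector identity discarded) are fit by Huggins
conditional likelihood: M0, Mt, Mb (first capture vs recapture), Mh2
(2-class mixture). Abundance is Horvitz–Thompson, N̂ = Σ 1/p*ᵢ, with
variance = HT component Σ(1−p*)/p*² plus delta-method parameter
uncertainty, and a log-normal interval on f0 = N̂ − n.

Residency is, per collared animal, the fraction of telemetry locations
inside the grid polygon, regressed (binomial, logit) on the mean distance
from the grid edge of the *inside-grid* locations only — the restriction
that makes the covariate comparable with mean DNA-detection locations of
uncollared animals. Distance from edge is signed Euclidean distance to the
polygon boundary (positive inside). The combined density estimator weights
each detected animal by its predicted residency at its mean-detection
distance:

    D̂ = Σᵢ r̂(distᵢ) / p*ᵢ / A        (per 1000 km²)

This per-animal weighting is this package's formulation of the
closed/telemetry estimator; it reduces exactly to N̂/A when residency ≡ 1,
and a `per_animal=False` flag provides the mean-residency variant (the two
coincide whenever p* is equal across animals, e.g. under M0/Mt/Mh2).
Variance combines the residency-weighted HT component with delta-method
propagation through both (independent) parameter vectors. Distances outside
the fitted telemetry range produce clamped predictions with a warning.
Animals with no inside-grid locations are excluded from the residency fit
with a warning.

## Synthetic-data generator

Coordinates are projected planar km and all distances Euclidean (SECR's
planar assumption). The generator emulates:

- **Landscape**: two Gaussian white-noise fields smoothed at a configurable
  autocorrelation range (default 14 km), optionally correlated, then
  quantile-binned into ordinal scores 1..levels of ~equal area (default 10
  levels) — RSF and Risk score maps. Continuous fields for TRI/CC-like site
  covariates come from the same machinery.
- **Design**: one detector per 7 × 7 km cell per occasion, 4 occasions,
  position re-drawn uniformly within the cell each occasion when
  `move_sites` (the field protocol), fixed otherwise. A `biased_placement`
  option (default off) draws positions preferentially toward high values of
  a supplied raster, emulating expert micro-habitat site selection.
- **Population**: activity centres from per-mask-cell Poisson counts with
  intensity exp(β0 + βᵀz(x)) per 1000 km² on *raw* covariates, jittered
  uniformly within cells. |linear predictor| > 50 is rejected as overflow.
  Sexes are independent populations with sex-specific (g0, σ, β) —
  matching a sexes-fit-separately analysis.
- **Detections**: independent Bernoulli per animal × detector × occasion
  with the half-normal kernel. Undetected animals stay only in the truth
  record, as in real DNA sampling.
- **Telemetry**: circular bivariate-normal locations around each centre.

Everything is reproducible bit-for-bit from a seed. What the generator does
*not* emulate: genotyping error, open-population dynamics between
occasions, non-circular home ranges, sex-biased site attraction, and
telemetry location error — so passing tests demonstrate correctness of the
estimators under the model's assumptions, not robustness to their
violation.

## Standing simulation studies (`secrdsm.studies`)

Problem sizes were chosen so the full suite runs in minutes on one core;
they are the package's own calibration designs.

- **Parameter recovery**: truth D = 30/1000 km², g0 = 0.15, σ = 4 km on a
  10 × 10-cell grid (7 km cells), 4 occasions, 3.5 km mask spacing, 4σ
  buffer; 100 replicates. Checks: medians of the MLEs within 10% of truth,
  95% interval coverage within [90%, 98%] per parameter.
- **Model-set recovery**: 7 × 7-cell grid, g0 = 0.2, σ = 3.5 km,
  autocorrelated landscape (10 km range). RSF scenario: β_RSF = 0.25 per
  score unit (~9.5-fold density range over scores 1..10), baseline tuned to
  ~100 detected animals; constant scenario: homogeneous 45/1000 km². 30
  replicates per scenario. Checks: RSF ranked first ≥ 80%; constant within
  2 AICc of best ≥ 90%. At 30 replicates these rates carry ±6% Monte-Carlo
  error; the observed rates sit near 90% and 95%.
- **Cross-method agreement**: 8 × 8-cell grid with σ = 3 km (well-covered:
  modest edge effect), M0 closed model, 40 telemetry locations per animal;
  50 replicates. Checks: SECR and closed/telemetry 95% CIs overlap ≥ 90%,
  median relative difference ≤ 15%.
- **Sex contrast**: females (g0 = 0.25, σ = 3 km) vs males (g0 = 0.10,
  σ = 6 km), fit separately; 100 replicates. Check: σ̂_F < σ̂_M ≥ 95%.
- **Residency pattern**: 30 interior animals, σ = 3 km, 56 km grid. Check:
  predicted residency > 0.95 beyond 15 km from the edge, positive slope.

## Numerical details and degenerate inputs

- Detection probabilities are clipped to ≤ 1 − 1e−12 before logs; animal
  marginals use log-sum-exp over the mask. A likelihood evaluation that
  produces a non-finite intermediate raises naming the offending mask point
  or animal rather than returning garbage.
- The likelihood has a vectorised fast path (single class, no behavioural
  response) restricted to the union of detected columns; the general path
  covers mixtures and b/bk. The two agree to machine precision and both are
  tested against an independent brute-force summation at 1e−10 relative.
- Empty capture data is allowed in the likelihood (log L → −Λ) but not in
  `SecrModel.fit`.
- AICc requires n > k + 1 and errors otherwise ("model too rich for data").
- Mask construction errors on polygons too small for the requested spacing;
  `esa_curve` rejects buffers below the mask spacing (other than 0).
- Median splits error on constant covariates; empty categories are reported
  with zero area and flagged, not dropped.

## Open design choices made here

- Sexes are fit separately throughout (separate data, separate fits) rather
  than jointly with sex covariates.
- The detection kernel is half-normal only — the default of the maximum-
  likelihood SECR framework this package follows.
- Region membership of a home-range centre uses the posterior mode; the
  mean is emitted alongside.
- The closed/telemetry estimator uses per-animal residency weighting, with
  the mean-residency variant behind a flag.
- Within-cell detector placement is uniform by default; biased placement is
  available but off, since moved sites and >cell-scale movement make the
  micro-placement largely immaterial to the estimators.

## Known limitations

- No open-population models, no multi-session trend in density, no
  least-cost (non-Euclidean) distances, no hazard-rate/exponential kernels,
  no spline/GAM density surfaces, no demographic source-sink projection.
- The Hessian-based variance can be optimistic near parameter boundaries
  (g0 → 1, mixture weights → 0/1); such fits are flagged by warnings.
- Finite-mixture (h2) likelihoods are multimodal in principle; the default
  single start is adequate on the test fixtures but a restart ladder is
  advisable for sparse real data.
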