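# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `aerospora`, in enough detail
to judge what the package's passing tests do and do not establish.

## The analysis pipeline

The package assumes the data of a global air-sampling study: sites with
40-year climate normals (MAT, MAP, MAI, mean wind) sampled repeatedly over
one or more years, each sample an OTU read vector with a synthetic DNA
spike-in, plus daily weather, a seven-rank taxonomy, trait tables and
negative controls.

### Spike-in quantification

The spike-in is a fixed amount of synthetic DNA added before sequencing,
so the non-spike/spike read ratio is proportional to the sample's fungal
DNA amount. Zero-spike samples are flagged missing (kept for richness);
zero-fungal samples get DNA amount 0 whose log is treated as missing
rather than mapped to a pseudo-count — a log ratio of −∞ carries no usable
signal, and an arbitrary pseudo-count would manufacture one. Samples with
fewer than 10,000 total reads are discarded; depth is otherwise handled
statistically via a log-depth covariate, never by rarefying (rarefying
discards reads and with them rare OTUs of the deepest samples).

### Community structure

Multivariate analyses run at the site level on prevalence (the share of a
site's samples containing the OTU). Distances are Bray–Curtis on
prevalence, or unweighted UniFrac on the taxonomy tree. The taxonomy tree
is rooted at the kingdom with one unit branch at each of the six levels
below (phylum … species); UniFrac is the unshared branch length over the
union's branch length, so two sites sharing no ranks below the kingdom
are maximally distant.

NMDS uses non-metric stress-1 minimisation with isotonic regression (ties
averaged) over random restarts; the implementation is scikit-learn's
nonmetric MDS, best of `n_restarts` inits, deterministic under a seed,
coordinates centred.

The ordination surface of a covariate is a thin-plate radial-basis
expansion (kernel r² log r plus linear terms) with a ridge penalty chosen
by generalised cross-validation over a 10-decade grid; deviance explained
is 1 − RSS/TSS clipped to [0, 1]. This approximates the GAM-type
smoothers usual in ordination software; exact equality with any
particular smoother's defaults is not claimed, and the smoothed deviance
should be read as a descriptive, not inferential, quantity.

Variance partitioning regresses the unfolded upper triangle of the
community distance matrix on great-circle distance (haversine, km) and on
climate distance (|ΔMAT| or analogous), in the three nested OLS models,
and applies Whittaker's identity: space = R²_full − R²_env, environment =
R²_full − R²_geo, shared = R²_geo + R²_env − R²_full. Pairwise distances
are not independent; like the original partitioning approach this ignores
that non-independence (no Mantel permutation), so the fractions are
descriptive decompositions, not tests.

### Seasonality index

Within each site, sample pairs ≤ 30 days apart are "same season" and
75–105 days apart "different season" ("1 month" and "3 ± 0.5 months"
operationalised in days for determinism; calendar-month alternatives are
ambiguous across month lengths). Only pairs where both samples hold ≥ 5
species enter. The index = mean same-season Jaccard − mean
different-season Jaccard; subtracting the same-season mean removes
site-specific baseline turnover. Date gaps are plain calendar differences
by default, so cross-year anniversary pairs (≈ 365 d) are "neither"; a
`circular` flag folds gaps into day-of-year distance instead. The index
is regressed on site MAT by OLS with a two-sided slope test.

### Weather anomalies

Wind speed is √(u² + v²) from the eastward/northward components. Each
weather variable is reduced to anomalies: observed daily value minus the
prediction of a site-seasonality model with the CS4 structure (fixed: MAT,
MAT², latitude × sin/cos of 2πd/365; random per site: intercept and both
seasonal slopes, diagonal covariance, maximum likelihood via statsmodels
MixedLM; singular fits fall back to a random-intercept-only CS3
structure). Precipitation is modelled on the raw scale, so negative
predictions — hence anomalies more negative than −(observed) — can occur
and are left as-is. Anomalies are averaged over 1-, 7- or 30-day windows
*ending on the sampling date inclusive*: a 24-h sampling period means the
sampling day's weather is part of the exposure, and inclusivity makes the
1-day window equal the sampling-day value exactly.

Note the shift contract: adding a constant to one site's series shifts its
anomalies by exactly that constant only *without* refitting; refitting
absorbs the shift into the site random intercept.

### Mixed-model families and AIC selection

Responses: log(DNA amount), log(richness + 1), CWM log spore volume
(asexual/sexual), log(guild richness + 1); natural logs throughout; the
depth covariate is the log of total reads including spike. CS1 holds the
site random intercept (plus log depth where relevant); CS2 adds MAT and
MAT²; CS3 adds latitude × (sin, cos); CS4 adds per-site random seasonal
slopes. W1–W4 add anomaly covariates (main effects; + MAT interactions
and site × weather random slopes; + seasonality interactions; + site ×
weather-seasonality random slopes), each over the 4³ = 64 grid of
per-covariate window choices including exclusion.

All fits are maximum likelihood, not REML, because candidates differ in
fixed effects and their AICs must be comparable. Random-effect covariance
is diagonal (independent intercept and slopes) for tractability — a
deliberate divergence from unstructured covariances some mixed-model
software defaults to. The parameter count k = fixed effects + variance
components (site intercept + each slope component + residual); AIC =
−2ℓ + 2k exactly. Non-converged or non-finite fits are dropped from
selection with a warning rather than patched; AIC ties break toward fewer
parameters, then stable candidate order. Weather selection holds the
AIC-best CS structure fixed and evaluates the full 64-grid per W level.

Seasonal prediction curves are fixed-effects-only, evaluated over the
year at representative zone (MAT, latitude) under the Northern-Hemisphere
convention.

### Per-species occurrence models

Presence/absence of each species occurring ≥ 50 times is modelled by
probit regression on intercept, MAT, MAT², latitude × sin, latitude ×
cos, and centred log depth, with a site random intercept. Sampling is the
Albert–Chib latent-variable Gibbs scheme: truncated-normal latent scores
(inverse-CDF draws), conjugate normal updates for coefficients (prior
N(0, 2²) on standardised covariates, results transformed back) and site
effects, and an inverse-gamma(2, 0.1) update for the site variance — a
weakly-informative conjugate prior (mean 0.1) chosen so that a
zero-variance truth yields a posterior concentrating near zero. The
default schedule is 2 chains × 1,500 iterations (500 burn-in, thin 5);
the full published-scale schedule (4 × 37,500, burn-in 12,500, thin 100 →
1,000 draws) is available via `published_schedule()` but is unnecessary
for the synthetic studies shipped here. Convergence is monitored by the
Gelman–Rubin PSRF across chains.

This per-species formulation deliberately replaces a joint
latent-factor occurrence model: every derived quantity used downstream
(fixed effects, their variance partition, Tjur R², AUC) is a per-species
functional, so the joint residual-covariance structure adds cost without
changing those quantities' definitions. Species-to-species residual
associations are therefore out of scope.

Derived metrics: variance shares of the linear predictor by group (MAT
polynomial, seasonal pair, log depth, site variance; cross-group
covariances excluded, shares normalised to 1); climatic/seasonal
sensitivity = share × Tjur R² (floored at 0 for negative Tjur R², since a
worse-than-chance fit cannot ground a sensitivity); optimal MAT = vertex
of the quadratic truncated to the observed MAT range (better boundary for
convex fits); optimal day = atan2(β_sin, β_cos) · 365/2π under the
Northern convention (+182.5 d for Southern interpretation — the phase is
invariant to positive latitude scaling, so no reference latitude is
needed). Optima are reported only at ≥ 5% of the matching sensitivity —
the threshold applies to the final share × Tjur product, the quantity
actually called "sensitivity". Order-level summaries cover orders with
≥ 10 analysed species.

### Phylogenetic signal

The taxonomy correlation is C_ij = (depth of the most recent common rank
below the kingdom root)/6: congeners 5/6, confamilials 4/6, different
phyla 0. Pseudotaxon placeholders count as real taxa — they encode
genuine cluster structure even when unnamed. Pagel's λ scales the
off-diagonal: V(λ) = I + λ(C − I). The mean-only GLS profile likelihood
is computed from a single eigendecomposition of C (each λ costs O(n)) and
maximised by bounded scalar search with 10 interval restarts (tolerance
1e−8); λ may go negative down to the positive-definiteness bound of V.
Significance is a χ²₁ LRT against λ = 0.

The default criterion is the *restricted* likelihood. With plain ML the
profiled mean induces a finite-sample negative bias in λ̂ whose LRT is
badly anticalibrated under the null (type-I error far above nominal at
n = 200 species in our simulations); REML — also the default of the
standard GLS tooling in this area — restores approximate uniformity of
the null p-values. Both criteria are implemented (`method="ml"`).

Optimal day is analysed as a linear variable despite being circular,
mirroring standard GLS practice in the field; for species whose peaks
straddle the year boundary this misstates distances, a caveat rather
than a bug to be fixed silently.

### Trait backfilling and CWM

Spore volumes are backfilled hierarchically: species entry; else
geometric mean over congeners with data; else geometric mean of the
genus means within the family (mean of genus means, so large genera do
not dominate); else missing — never borrowing above family. Averages are
taken on the log scale for consistency with the CWM being defined on log
volume (the raw-scale alternative is exposed but not default). Guilds
borrow by set union (species → congeners → family), so an OTU may carry
several potential guilds and counts once in each guild's richness.

The CWM of a sample is the unweighted mean of log volumes over present
species with data; species with missing volume are dropped from numerator
and denominator (treating the whole sample as missing would be needlessly
destructive); samples with < 10 present species (counting all present
species, with or without volume data) are missing.

### Contamination robustness

Cross-contamination is emulated by adding, to each field sample, the full
read vector of a uniformly chosen negative control, ten independent
replicates. The concordance report gives per-replicate Pearson and
Spearman correlations and max absolute difference of any per-sample or
per-species metric against the uncontaminated run.

## The synthetic-data generator

The generator is first-class, tested code that defines the study
conditions under which everything else is validated.

* **Sites** (default 40): latitude magnitudes stratified over 2–70° with
  alternating hemispheres (guaranteeing all three climatic zones at
  n ≥ 4); MAT = 27 − 0.47·|lat| + N(0, 1.5); MAP log-normal (median
  ≈ 800 mm/yr), MAI derived from MAP with noise, wind log-normal. Zone
  thresholds on MAT: ≥ 18 °C tropical-subtropical, 3–18 °C temperate,
  < 3 °C polar-continental (configurable; the thresholds are this
  package's operationalisation, chosen near conventional climate-zone
  isotherms).
* **Weather**: daily temperature = MAT + 0.33·|lat| · cos-seasonal (peak
  day 196 in the NH, shifted 182.5 d in the SH) + stationary AR(1)
  anomalies (ρ = 0.7, sd 2.2 °C); gamma precipitation with mild seasonal
  modulation; wind components with a weak seasonal cycle.
* **Taxonomy**: fully nested, default fanout (2, 3, 5, 1, 2, 5) → 300
  species in 30 orders of 10 species — enough structure for congeneric/
  confamilial contrasts and order summaries.
* **Species parameters**: each coefficient field across species is an
  affine transform of √λ·(tree-structured unit-variance draw) +
  √(1−λ)·(independent draw), giving Pagel's λ = `lambda_target` exactly
  by construction (affine maps preserve correlation). Locations/scales:
  intercept −1.0 ± 0.6; β_MAT 0.24 ± 0.08 and β_MAT² −0.010 ± 0.003
  (placing most thermal optima at realistic interior MATs ≈ 12 ± 4 °C);
  seasonal coefficients scaled so a |lat| = 60 site has probit amplitude
  ≈ `beta_season` (default 1.2); β_logdepth 0.25 ± 0.10.
* **Samples**: weekly over two years per site. Presence ~
  Bernoulli(Φ(η)) with η from the truth record plus a per-species-site
  effect N(0, 0.5²). Total depth log-normal (log-mean 10.8, log-sd 0.6 —
  median ≈ 49k reads). Reads of present species are multinomial with
  log-normal intensities; the read-generation mechanism is a stand-in
  (the analysis layer never models reads beyond presence and totals), the
  simplest one preserving presence/absence truth. The spike-in emulates
  fixed spike DNA: a sample's spike share is S/(S + latent intensity)
  with S calibrated by bisection so the mean share equals
  `spike_fraction_mean` (0.1) — making log DNA amount a monotone function
  of the latent fungal intensity, as on a real sequencer.
* **Negative controls**: 99 controls (the published study's count), a
  contamination_rate = 0.11 share carrying Poisson(3) counts of 1–3 of
  the 20 most prevalent OTUs, emulating the observed 89%-clean rate with
  "a few reads of common OTUs".
* **Traits**: 55% species coverage, 25% stage-level missingness,
  family-level log-normal volume means — exercising every backfill path.

What the generator does **not** emulate: read-level error or chimeras,
spatial autocorrelation beyond the site intercept, species interactions,
multi-kingdom communities, trait–environment correlations, and
non-stationary climate. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated generative assumptions,
not robustness to the full messiness of field data.

## Problem sizes used in tests

The suite validates on deliberately scaled studies: the default fixture
(40 sites × ~105 weekly dates × 300 species) for probit recovery (60
seeded species, 2 chains × 1,000 iterations), a 48-species × 8-site
fixture for module tests and contamination robustness (25 species, 2 ×
600 iterations), 200-species taxonomies for λ recovery and 100-replicate
null calibration, and 25 replicates of n ≈ 1,700 for AIC model-class
recovery. These sizes were chosen as the smallest at which the targeted
statistical properties are comfortably identifiable; all are
configuration, not code, and scale up freely.

## Known limitations

* The ordination-surface smoother approximates, not replicates, GAM-based
  `ordisurf`-style deviance; treat percentages as indicative.
* Distance-matrix regressions ignore pairwise dependence (as in the
  partitioning approach they reproduce).
* The per-species probit replaces a joint species distribution model;
  co-occurrence structure is not estimated.
* λ on optimal day ignores circularity.
* The Gibbs sampler's PSRF can exceed 1.2 for weakly identified species
  at the default short schedule; the `converged` flag reports this
  honestly and longer schedules resolve it.
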