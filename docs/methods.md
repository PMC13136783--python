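# Methods

`droughtlegacy` quantifies how long-term drought changes ecosystem gross
primary production (GPP), separating the **direct effect** — the GPP change
while the drought is underway — from the **legacy effect** — the residual
change in the recovery years after it ends. This note documents the models,
the defaults and why they were chosen, the synthetic study population used
for validation, and the numerical decisions a user replicating results
should know about.

## Event model

Drought is defined meteorologically on annual index values, per site:

* **PDSI**: a year is drought when annual-mean Palmer Drought Severity
  Index is strictly below −3 (severe long-term drought).
* **CWD**: a year is drought when annual total climatic water deficit
  (potential minus actual evapotranspiration) strictly exceeds the site's
  95th-percentile CWD. The percentile is meant to come from a long
  climatological record (several decades); when the input table carries a
  `cwd_q95` column that threshold is used, otherwise the within-record
  empirical 95th percentile (linear interpolation between order statistics)
  is the stand-in. Note that a within-record threshold can, by rank
  arithmetic, never classify more than ~5% of that record's years as
  drought, so supplying a climatological threshold is preferred whenever
  drought frequency may exceed that.

Consecutive drought years form one **event**; a missing calendar year
terminates a run, because an unobserved year cannot be certified either
drought or drought-free. The two metrics run as parallel analyses:
drought-free status for windows is always judged by the metric that
detected the event.

Monthly indices can be aggregated to calendar years (PDSI: mean, CWD: sum)
or to growing seasons (Apr–Oct above 23.5° N, Oct–Apr below 23.5° S, all
months in the tropics); a site-year missing any required month is flagged
and excluded rather than partially aggregated.

## Effect model

For each event,

```
dGPP_dir = GPP_drought    − GPP_predrought
dGPP_lag = GPP_postdrought − GPP_expected
```

`GPP_predrought` is the mean over up to **3** drought-free years
immediately preceding the event (after the previous event);
`GPP_postdrought` the mean over up to **4** drought-free years following
it (before the next event). Fewer available years are used as-is; an empty
window yields a missing value, never a substitute. Within the nearest
drought-free years, years with missing GPP are dropped without pulling in
further years. `GPP_expected` is either

* **baseline**: the predrought mean itself, or
* **counterfactual**: the mean of per-year random-forest predictions of
  no-drought GPP over the same postdrought years.

Effects are reported on three scales: absolute (gC m⁻² yr⁻¹), anomaly
(per-site mean-centred GPP; for the counterfactual method the forest is
retrained on the centred response so predictions live on the same scale),
and relative (deltas divided by the site's mean annual GPP over all
available years — a documented choice of denominator).

Stratum summaries (global, five aridity classes, six land-cover groups)
use the **median** across events with a percentile bootstrap (1000
resamples of the event-level effects, 95% interval); an effect is
significant when the interval excludes zero. Aridity classes are half-open:
hyper-arid AI < 0.05, arid < 0.2, semi-arid < 0.5, dry sub-humid < 0.65,
humid ≥ 0.65. The resampling unit is the drought event; site-level
clustering is not resampled (events at one site are treated as exchangeable
observations), a simplification worth remembering for records with many
events per site.

## Counterfactual model

A random forest (500 trees) regresses GPP on PDSI, shortwave radiation,
VPD, temperature, precipitation, soil moisture, LAI, land cover (explicit
integer encoding), SOC, soil N and soil CEC, trained only on site-years
strictly before each site's first drought event; never-drought sites
contribute all years. `mtry` (candidate predictors per split) is selected
by held-out R² on a seeded 70/30 split over all possible values, ties
toward the smaller value, then the model is refit on all predrought
samples. Training rows are always scored out-of-bag. Reported accuracy:
R², the slope of observed-on-predicted regression, and bias = mean
(observed − predicted).

A caveat on fidelity: forests approximate smooth multivariate response
surfaces with local averages, so even noiseless smooth functions of five
covariates plateau near held-out R² ≈ 0.95–0.96 at a few thousand training
rows. The fidelity tests therefore use a piecewise-constant
(tree-representable) response, which isolates the correctness of the
training/tuning/OOB machinery from that approximation ceiling.

## Driver model

Driver attribution fits an additive model of the standardized effect on
standardized predictors: period means of PDSI and climate covariates over
the same year sets as the GPP windows (drought period for the direct
effect, postdrought period for the legacy effect), their differences from
the predrought means, soil properties, aridity index, site traits, land
cover, and — for the legacy model only — the direct effect itself.
Standardization is the z-score with sample (ddof = 1) standard deviation.
Following the averaging idea for a single response per event, the response
is the per-event mean across expected-GPP methods (the direct effect is
method-invariant by construction), and events from both drought metrics
are pooled as rows.

Each continuous predictor enters through a small centred cubic B-spline
basis (five basis functions; limited wiggliness is deliberate at
event-level sample sizes), land cover through centred treatment dummies;
the model is fit by least squares. Backward elimination removes, while any
term is non-significant, the least-important non-significant term, where

* **significance** is the partial-F p-value of the term compared against a
  family-wise level: alpha (default 0.05) divided by the number of initial
  candidate terms (Bonferroni). The correction is what keeps a pure-noise
  response from retaining spurious drivers — with 20+ candidates an
  unadjusted 0.05 rule would end with at least one false driver in well
  over half of null datasets;
* **importance** is the drop in explained variance when the term is
  removed with all others held, floored at zero and normalized to
  percentages summing to 100 for the final model.

The final model must satisfy a **concurvity** guard: for every ordered
pair of terms, the R² of regressing one term's fitted component on another
term's basis must stay below 0.8; violating pairs lose the member with the
higher concurvity (ties: lower importance), and significance is re-checked
after each removal. Partial-effect curves are evaluated on a 100-point
grid over each retained smooth's observed range. A model that retains no
terms is a valid diagnostic outcome, not an error, and the fit requires at
least 10 rows per candidate term.

## Synthetic study population

The generator emulates a multi-site network of annual flux records:

* **Covariates** follow stationary AR(1) processes around site-level means
  (temperature 10 ± 3 °C between sites, ±1.2 °C interannually, lag-1 0.4;
  precipitation 800 ± 200/120 mm; radiation 180 ± 25/12 W m⁻²; VPD
  8 ± 2.5/1.2 hPa; soil moisture 0.25 ± 0.05/0.03; LAI 3 ± 1/0.35).
* **Baseline GPP** is log-linear in standardized T, P, Srad, SM and LAI
  (coefficients fixed in code, LAI dominant) plus a land-cover offset and
  a lognormal site intercept (σ = 0.10) — smooth, monotone, positive, and
  learnable by both the forest and the additive model.
* **Drought years** are i.i.d. Bernoulli (default probability 0.10);
  their PDSI is forced below −3 and their CWD above the site's
  climatological q95, computed from an internal 40-year non-drought
  reference series and exported as `cwd_q95`, so detector and generator
  agree exactly by construction.
* **Effects**: GPP is multiplied by (1 + direct_effect) in drought years
  (default −0.10) and by 1 + legacy_effect·(1 − (k−1)/d) in recovery year
  k = 1..d after the last drought year (default legacy −0.05, d = 3
  years); observation noise is multiplicative lognormal with unit mean
  (default CV 0.05).
* **Site attributes** span all five aridity classes and six land-cover
  groups with at least 10 sites each at the default 200 sites (floors
  shrink proportionally for smaller populations); traits and soils are
  drawn from plausible clipped normals.

What the generator does **not** emulate: real site geography and
climatology, drought–covariate coupling (droughts do not depress P/SM in
the generated covariates), disturbance screening, sub-annual dynamics, or
observation gaps (tests construct those explicitly). Passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed data-generating process, not the field accuracy of any specific
published estimate.

## Problem sizes and numerical choices

Validation runs use desk-scale populations chosen as the package's own
study conditions: effect recovery uses 200 sites × 30 years (noise CV
0.05); null-legacy coverage uses 200 replicates of 60 sites × 25 years;
driver recovery uses 50 signal and 50 null datasets of 400 events with 21
candidate terms. Determinism is end-to-end: a single pipeline seed derives
independent per-stage streams (simulation, forest split, bootstrap) via
hashed stage labels, and rerunning a configuration reproduces every output
file byte-for-byte. Quantiles use linear interpolation between order
statistics throughout. Degenerate inputs are defined, not errors: empty
windows give missing effects, a constant bootstrap sample gives a
zero-width interval, and an all-noise driver model retains nothing.

A property of the window design worth noting: predrought years are
required to be drought-free, not legacy-free, so when events follow each
other within a site the predrought baseline can itself be depressed by the
previous event's legacy. This attenuates both recovered effects toward
zero (at the default 10% annual drought probability, by roughly one
percentage point on the injected −10%/−5% effects); it is inherent to
defining baselines from inter-drought years rather than a defect of the
implementation.

## Known limitations

* The CWD metric with a within-record threshold cannot flag more than
  ~5% of a record's years; supply climatological thresholds for
  drought-prone records.
* The additive-model F-tests are conditional on the selected basis and do
  not account for the stepwise selection itself; the Bonferroni family-wise
  rule is a pragmatic guard, not a full selective-inference correction.
* Counterfactual predictions carry no site random effect, so per-site
  prediction bias is possible when site heterogeneity is large; it cancels
  in the event-median summaries.
* Bootstrap intervals ignore within-site correlation of events.
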