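# droughtlegacy

Direct and legacy effects of long-term drought on ecosystem gross primary
production (GPP), as a tested, reusable analysis pipeline.

Severe droughts reduce carbon uptake while they last, but ecosystems can
also remain altered for years afterwards. Given multi-site annual records
of flux-derived GPP with drought indices and climate covariates, this
package separates the two responses per drought event:

```
ΔGPP_dir = GPP_drought    − GPP_predrought
ΔGPP_lag = GPP_postdrought − GPP_expected
```

* **Events** are maximal runs of consecutive drought years, with drought
  defined by annual PDSI < −3 or annual climatic water deficit (CWD) above
  the site's 95th-percentile threshold.
* **Windows** supply the comparisons: up to 3 drought-free predrought
  years and up to 4 drought-free postdrought years, bounded by
  neighbouring events.
* **GPP_expected** — the GPP had the drought not occurred — is either the
  predrought mean (baseline) or the prediction of a random forest trained
  only on pre-first-drought site-years (counterfactual).
* **Inference**: stratum medians (global, aridity classes, land-cover
  groups) with percentile-bootstrap 95% confidence intervals (1000
  resamples); effects on absolute, anomaly and relative scales and at
  postdrought horizons of 1–4 years.
* **Drivers**: a stepwise additive model (spline GAM with backward
  elimination, family-wise significance, concurvity < 0.8 guard)
  attributes the variability of ΔGPP_dir and ΔGPP_lag to climatic and
  ecophysiological predictors with importance shares summing to 100%.

A fully ground-truthed synthetic flux-network generator (known injected
direct and legacy effects, indices forced past the detection thresholds)
makes every stage testable at desk scale. Audience: carbon-cycle and
ecosystem-ecology researchers analysing flux-tower style site-year tables.

## Worked example

```python
import droughtlegacy as dl
from droughtlegacy.events import build_windows_all, detect_events_all

# 200 sites x 30 years; 10% GPP loss in drought years and a 5% first-year
# legacy deficit decaying to zero over three recovery years
cfg = dl.SimConfig(n_sites=200, years_per_site=30, seed=101,
                   direct_effect=-0.10, legacy_effect=-0.05,
                   legacy_decay_years=3, noise_cv=0.05)
table, truth = dl.generate_sites(cfg)

events = detect_events_all(table, "PDSI")
windows = build_windows_all(events, table)
eff = dl.compute_effects(table, windows, method="baseline", horizon=4,
                         scale="relative")
attrs = table[["site_id", "ai", "igbp"]].drop_duplicates("site_id")
est = dl.stratified_estimates(eff, attrs, strata="global", effect="dir",
                              n_boot=1000, seed=0)
print(est.round(4).to_string(index=False))
```

```
stratum effect  median  ci_low  ci_high  significant   n
 global    dir -0.0854 -0.0982  -0.0665         True 527
```

The global median relative direct effect is −8.5% (95% CI −9.8% to
−6.7%) over 527 drought events and the interval excludes zero, so the
during-drought GPP loss is significant. Repeating with `horizon=1` on
`delta_lag` gives a median of −3.7% against the injected −5% first-year
legacy deficit. Both recoveries are mildly attenuated toward zero because
predrought windows are only required to be drought-free and can still
carry legacy deficits from an earlier event — an inherent property of the
pre/post window design discussed in `docs/methods.md`.

The same analysis runs from the shell:

```bash
droughtlegacy simulate --sites 200 --years 30 --seed 101 --out table.csv
droughtlegacy run --table table.csv --outdir results/
```

`run` writes events, windows, per-event effects, stratified estimates,
random-forest accuracy metrics, driver fits and a manifest; reruns with
the same configuration are byte-identical.

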