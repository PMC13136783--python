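"""Synthetic multi-site flux-record generator with known drought effects.

Produces annual site-year tables with the statistical structure the
attribution pipeline assumes: AR(1) climate covariates, a smooth log-linear
baseline GPP response with a site random intercept, drought years whose
indices are forced past the detection thresholds (PDSI < -3, CWD above the
site's climatological 95th percentile), a multiplicative direct GPP effect
in drought years, and a linearly decaying legacy effect in the recovery
years that follow.  The paired ground-truth table records, for every
site-year, the no-drought expected GPP and the multipliers actually applied,
so that recovery tests can compare estimates against truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

# Baseline GPP model: log GPP is linear in standardized covariates plus a
# land-cover offset and a site random intercept.  Coefficients are fixed
# here (not configurable) so the response surface is a published, recoverable
# function of the predictors.
LOG_GPP_INTERCEPT = 7.09  # exp() ~ 1200 gC m-2 yr-1
BASELINE_COEFS = {"t": 0.10, "p": 0.12, "srad": 0.06, "sm": 0.08, "lai": 0.25}
LANDCOVER_LOG_OFFSET = {
    "needleleaf_forests": 0.05,
    "broadleaf_forests": 0.15,
    "mixed_forests": 0.10,
    "shrublands": -0.25,
    "savannas": -0.05,
    "grasslands": -0.15,
}

# IGBP member codes per land-cover group (croplands/non-vegetated excluded
# upstream of this analysis, so they are never generated).
GROUP_IGBP = {
    "needleleaf_forests": ("ENF", "DNF"),
    "broadleaf_forests": ("EBF", "DBF"),
    "mixed_forests": ("MF",),
    "shrublands": ("CSH", "OSH"),
    "savannas": ("WSA", "SAV"),
    "grasslands": ("GRA",),
}

# Aridity classes: [lower, upper) on the aridity index, humid open above.
ARIDITY_BOUNDS = {
    "hyper_arid": (0.005, 0.05),
    "arid": (0.05, 0.2),
    "semi_arid": (0.2, 0.5),
    "dry_sub_humid": (0.5, 0.65),
    "humid": (0.65, 2.0),
}

TABLE_COLUMNS = [
    "site_id", "year", "gpp", "pdsi", "cwd", "srad", "vpd", "t", "p", "sm",
    "lai", "soc", "soil_n", "soil_cec", "ai", "igbp", "diversity", "sla",
    "root_depth", "root_shoot", "wood_density", "canopy_height", "latitude",
    "cwd_q95",
]


def _allocate_classes(rng: np.random.Generator, n: int, labels: list[str],
                      min_per_class: int = 10) -> np.ndarray:
    """Assign ``n`` sites to classes, guaranteeing a floor per class.

    The floor shrinks proportionally when ``n`` is too small for 10 per
    class, so tiny test populations still span every class.
    """
    k = len(labels)
    floor = min(min_per_class, max(1, n // k))
    counts = np.full(k, floor)
    rest = n - counts.sum()
    if rest > 0:
        extra = rng.multinomial(rest, np.full(k, 1.0 / k))
        counts = counts + extra
    elif rest < 0:  # n < k: drop classes from the end
        counts = np.zeros(k, dtype=int)
        counts[:n] = 1
    out = np.repeat(np.array(labels, dtype=object), counts)
    rng.shuffle(out)
    return out


def _ar1_series(rng: np.random.Generator, site_mean: float, sd: float,
                phi: float, n: int) -> np.ndarray:
    x = np.empty(n)
    x[0] = site_mean + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(n) * innov_sd
    for i in range(1, n):
        x[i] = site_mean + phi * (x[i - 1] - site_mean) + eps[i]
    return x


def _legacy_multiplier(drought: np.ndarray, legacy_effect: float,
                       decay_years: int) -> np.ndarray:
    """Per-year legacy multiplier: 1 + effect * (1 - (k-1)/d) for recovery
    year k = 1..d after the most recent drought year, exactly 1 otherwise."""
    n = len(drought)
    mult = np.ones(n)
    if decay_years <= 0 or legacy_effect == 0.0:
        return mult
    k = None  # recovery-year counter; None until first drought passes
    for i in range(n):
        if drought[i]:
            k = 0
            continue
        if k is None:
            continue
        k += 1
        if k <= decay_years:
            mult[i] = 1.0 + legacy_effect * (1.0 - (k - 1) / decay_years)
    return mult


def generate_sites(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the annual site-year table and its ground truth.

    Returns ``(table, truth)``.  ``table`` has one row per site-year with
    GPP, drought indices, covariates and site attributes (columns
    ``TABLE_COLUMNS``); ``truth`` records the true drought indicator, the
    no-drought expected GPP and the applied direct/legacy multipliers.
    Identical config (including seed) yields byte-identical tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, ny = config.n_sites, config.years_per_site
    years = config.start_year + np.arange(ny)

    aridity_class = _allocate_classes(rng, n, list(ARIDITY_BOUNDS))
    lc_group = _allocate_classes(rng, n, list(GROUP_IGBP))

    ai = np.array([rng.uniform(*ARIDITY_BOUNDS[c]) for c in aridity_class])
    igbp = np.array([rng.choice(GROUP_IGBP[g]) for g in lc_group], dtype=object)
    latitude = rng.uniform(-35.0, 60.0, n)
    soc = np.clip(rng.normal(60.0, 20.0, n), 5.0, None)
    soil_n = np.clip(rng.normal(4.0, 1.5, n), 0.3, None)
    soil_cec = np.clip(rng.normal(20.0, 6.0, n), 2.0, None)
    diversity = np.clip(rng.normal(25.0, 10.0, n), 1.0, None)
    sla = np.clip(rng.normal(15.0, 4.0, n), 3.0, None)
    root_depth = np.clip(rng.normal(2.0, 1.0, n), 0.2, None)
    root_shoot = np.clip(rng.normal(0.30, 0.10, n), 0.05, None)
    wood_density = np.clip(rng.normal(0.55, 0.10, n), 0.2, None)
    is_forest = np.array(["forest" in g for g in lc_group])
    canopy_height = np.where(
        is_forest,
        np.clip(rng.normal(20.0, 6.0, n), 2.0, None),
        np.clip(rng.normal(1.5, 1.0, n), 0.2, None),
    )
    site_intercept = rng.normal(0.0, config.site_log_sd, n) \
        if config.site_log_sd > 0 else np.zeros(n)

    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    else:
        sigma = 0.0

    table_rows, truth_rows = [], []
    for s in range(n):
        site_id = f"SITE{s:04d}"
        cov = {}
        for name, spec in config.covariates.items():
            site_mean = spec.mean + spec.site_sd * rng.standard_normal()
            cov[name] = _ar1_series(rng, site_mean, spec.sd, spec.ar1, ny)
        cov["p"] = np.clip(cov["p"], 0.0, None)
        cov["sm"] = np.clip(cov["sm"], 0.01, 0.60)
        cov["lai"] = np.clip(cov["lai"], 0.1, None)
        cov["vpd"] = np.clip(cov["vpd"], 0.1, None)
        cov["srad"] = np.clip(cov["srad"], 50.0, None)

        drought = rng.random(ny) < config.drought_prob

        pdsi = np.clip(rng.normal(0.5, 1.2, ny), -2.9, None)
        pdsi[drought] = -3.0 - np.abs(rng.normal(0.8, 0.5, drought.sum())) - 1e-6

        # CWD: climatological q95 from a long non-drought reference series
        # (the stand-in for "the past four decades"); drought years forced
        # strictly above it, non-drought years capped strictly below.
        cwd_mean = 250.0 + 450.0 * max(0.0, 1.0 - ai[s])
        ref = np.clip(rng.normal(cwd_mean, 60.0, config.cwd_reference_years), 0.0, None)
        q95 = float(np.quantile(ref, 0.95))
        cwd = np.clip(rng.normal(cwd_mean, 60.0, ny), 0.0, q95 * (1.0 - 1e-9))
        cwd[drought] = q95 + 20.0 + np.abs(rng.normal(40.0, 20.0, drought.sum()))

        log_gpp = LOG_GPP_INTERCEPT + LANDCOVER_LOG_OFFSET[lc_group[s]] \
            + site_intercept[s]
        for name, coef in BASELINE_COEFS.items():
            spec = config.covariates[name]
            log_gpp = log_gpp + coef * (cov[name] - spec.mean) / spec.marginal_sd
        gpp_expected = np.exp(log_gpp)

        dir_mult = np.where(drought, 1.0 + config.direct_effect, 1.0)
        lag_mult = _legacy_multiplier(drought, config.legacy_effect,
                                      config.legacy_decay_years)
        if sigma > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, ny))
        else:
            noise = np.ones(ny)
        gpp = gpp_expected * dir_mult * lag_mult * noise

        table_rows.append(pd.DataFrame({
            "site_id": site_id, "year": years, "gpp": gpp, "pdsi": pdsi,
            "cwd": cwd, "srad": cov["srad"], "vpd": cov["vpd"], "t": cov["t"],
            "p": cov["p"], "sm": cov["sm"], "lai": cov["lai"], "soc": soc[s],
            "soil_n": soil_n[s], "soil_cec": soil_cec[s], "ai": ai[s],
            "igbp": igbp[s], "diversity": diversity[s], "sla": sla[s],
            "root_depth": root_depth[s], "root_shoot": root_shoot[s],
            "wood_density": wood_density[s], "canopy_height": canopy_height[s],
            "latitude": latitude[s], "cwd_q95": q95,
        }))
        truth_rows.append(pd.DataFrame({
            "site_id": site_id, "year": years, "drought": drought,
            "gpp_expected": gpp_expected, "direct_multiplier": dir_mult,
            "legacy_multiplier": lag_mult,
        }))

    table = pd.concat(table_rows, ignore_index=True)[TABLE_COLUMNS]
    truth = pd.concat(truth_rows, ignore_index=True)
    return table, truth


def generate_monthly(config: SimConfig) -> pd.DataFrame:
    """Monthly PDSI/CWD table consistent with the annual table.

    For every site-year the 12 monthly PDSI values average exactly to the
    annual PDSI and the 12 monthly CWD values sum exactly to the annual CWD.
    """
    table, _ = generate_sites(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(table)
    wiggle = rng.normal(0.0, 0.8, (n, 12))
    wiggle -= wiggle.mean(axis=1, keepdims=True)
    pdsi_m = table["pdsi"].to_numpy()[:, None] + wiggle
    w = rng.gamma(2.0, 1.0, (n, 12))
    w /= w.sum(axis=1, keepdims=True)
    cwd_m = table["cwd"].to_numpy()[:, None] * w

    out = pd.DataFrame({
        "site_id": np.repeat(table["site_id"].to_numpy(), 12),
        "year": np.repeat(table["year"].to_numpy(), 12),
        "month": np.tile(np.arange(1, 13), n),
        "pdsi": pdsi_m.ravel(),
        "cwd": cwd_m.ravel(),
        "latitude": np.repeat(table["latitude"].to_numpy(), 12),
    })
    return out


def write_outputs(table: pd.DataFrame, truth: pd.DataFrame, config: SimConfig,
                  table_path, truth_path=None, config_path=None) -> None:
    """Write table/truth as CSV (UTF-8, NA token) and the config as YAML."""
    table.to_csv(table_path, index=False, na_rep="NA")
    if truth_path is not None:
        truth.to_csv(truth_path, index=False, na_rep="NA")
    if config_path is not None:
        config.to_yaml(config_path)
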