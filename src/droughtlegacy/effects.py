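"""Direct and legacy drought-effect estimation.

Per event, the direct effect is

    dGPP_dir = GPP_drought - GPP_predrought

and the legacy effect is

    dGPP_lag = GPP_postdrought - GPP_expected

where GPP_drought / GPP_predrought / GPP_postdrought are mean annual GPP
over the event, predrought and postdrought windows, and GPP_expected is
either the predrought mean itself (baseline method) or the mean of
per-year model predictions of no-drought GPP over the same postdrought
years (counterfactual method).  Effects can be expressed on the absolute
scale (gC m-2 yr-1), as site-centred anomalies, or relative to the site's
mean annual GPP.  Stratum summaries are medians with percentile-bootstrap
95% confidence intervals; an effect is significant when the interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventWindows

ARIDITY_CLASSES = ("hyper_arid", "arid", "semi_arid", "dry_sub_humid", "humid")
# half-open classes [lo, hi): hyper arid AI < 0.05 ... humid AI >= 0.65
_ARIDITY_EDGES = (0.05, 0.2, 0.5, 0.65)

IGBP_TO_GROUP = {
    "ENF": "needleleaf_forests", "DNF": "needleleaf_forests",
    "EBF": "broadleaf_forests", "DBF": "broadleaf_forests",
    "MF": "mixed_forests",
    "CSH": "shrublands", "OSH": "shrublands",
    "WSA": "savannas", "SAV": "savannas",
    "GRA": "grasslands",
}
LAND_COVER_GROUPS = ("needleleaf_forests", "broadleaf_forests",
                     "mixed_forests", "shrublands", "savannas", "grasslands")


def aridity_class(ai: float) -> str:
    """Map an aridity-index value to its class label."""
    if not np.isfinite(ai) or ai < 0:
        raise ValueError("aridity index must be finite and >= 0")
    return ARIDITY_CLASSES[int(np.searchsorted(_ARIDITY_EDGES, ai, side="right"))]


def land_cover_group(igbp: str) -> str:
    """Map an IGBP code to its land-cover group (vegetated, non-cropland)."""
    try:
        return IGBP_TO_GROUP[str(igbp)]
    except KeyError:
        raise ValueError(f"IGBP code {igbp!r} outside the analysed classes")


def mean_window_gpp(window_years, site_record: pd.DataFrame,
                    gpp_col: str = "gpp") -> float:
    """Arithmetic mean GPP over the given years; NaN for an empty set."""
    years = list(window_years)
    if not years:
        return float("nan")
    rec = site_record.set_index("year")[gpp_col]
    return float(np.mean([rec.loc[y] for y in years]))


def to_anomaly(table: pd.DataFrame, gpp_col: str = "gpp") -> pd.DataFrame:
    """Centre each site's GPP on its own mean annual GPP.

    The identical transform must be applied to counterfactual predictions
    before differencing, which the pipeline achieves by training the
    prediction model on the centred response.
    """
    out = table.copy()
    site_mean = out.groupby("site_id")[gpp_col].transform("mean")
    out[gpp_col] = out[gpp_col] - site_mean
    return out


def site_mean_gpp(table: pd.DataFrame, gpp_col: str = "gpp") -> pd.Series:
    """Per-site mean annual GPP over all available years."""
    return table.groupby("site_id")[gpp_col].mean()


@dataclass(frozen=True)
class EventEffect:
    """Per-event effect record on one method/scale at one horizon."""

    site_id: str
    metric: str
    start_year: int
    end_year: int
    method: str
    scale: str
    horizon: int
    gpp_predrought: float
    gpp_drought: float
    gpp_postdrought: float
    gpp_expected: float
    delta_dir: float
    delta_lag: float


def effect_for_event(windows: EventWindows, site_record: pd.DataFrame,
                     method: str = "baseline", horizon: int = 4,
                     expected_supplier=None, scale: str = "absolute",
                     site_mean: float | None = None) -> EventEffect:
    """Compute dGPP_dir and dGPP_lag for one event.

    ``expected_supplier`` maps (site_id, year) to the predicted no-drought
    GPP and is required for the counterfactual method; years without a
    prediction are excluded from both sides of the legacy difference.
    ``horizon`` restricts the legacy effect to the first k postdrought
    years.  With ``scale='relative'``, deltas are divided by ``site_mean``
    (the site's mean annual GPP), which must be positive.
    """
    if method not in ("baseline", "counterfactual"):
        raise ValueError("method must be 'baseline' or 'counterfactual'")
    if method == "counterfactual" and expected_supplier is None:
        raise ValueError("counterfactual method needs an expected_supplier")
    ev = windows.event
    rec = site_record
    gpp_pre = mean_window_gpp(windows.pre_years, rec)
    gpp_drt = mean_window_gpp(ev.years, rec)
    post_k = list(windows.post_years[:horizon])

    if method == "counterfactual" and post_k:
        preds = {y: expected_supplier(ev.site_id, y) for y in post_k}
        post_k = [y for y in post_k if np.isfinite(preds.get(y, np.nan))]
        gpp_exp = float(np.mean([preds[y] for y in post_k])) if post_k else np.nan
    else:
        gpp_exp = gpp_pre

    gpp_post = mean_window_gpp(post_k, rec)
    delta_dir = gpp_drt - gpp_pre
    delta_lag = gpp_post - gpp_exp

    if scale == "relative":
        if site_mean is None or not np.isfinite(site_mean) or site_mean <= 0:
            delta_dir = np.nan
            delta_lag = np.nan
        else:
            delta_dir = delta_dir / site_mean
            delta_lag = delta_lag / site_mean
    elif scale not in ("absolute", "anomaly"):
        raise ValueError("scale must be 'absolute', 'anomaly' or 'relative'")

    return EventEffect(
        site_id=ev.site_id, metric=ev.metric, start_year=ev.start_year,
        end_year=ev.end_year, method=method, scale=scale, horizon=horizon,
        gpp_predrought=float(gpp_pre), gpp_drought=float(gpp_drt),
        gpp_postdrought=float(gpp_post), gpp_expected=float(gpp_exp),
        delta_dir=float(delta_dir), delta_lag=float(delta_lag),
    )


def compute_effects(table: pd.DataFrame, windows: list[EventWindows],
                    method: str = "baseline", horizon: int = 4,
                    expected_supplier=None,
                    scale: str = "absolute") -> pd.DataFrame:
    """Per-event effect table for one method/scale/horizon combination.

    For the anomaly scale the table (and, via the supplier, predictions)
    are assumed already centred with :func:`to_anomaly`.  For the relative
    scale the denominator is each site's mean annual GPP from ``table``.
    """
    means = site_mean_gpp(table) if scale == "relative" else None
    rows = []
    for sid, grp in table.groupby("site_id", sort=True):
        wins = [w for w in windows if w.event.site_id == str(sid)]
        for w in wins:
            eff = effect_for_event(
                w, grp, method=method, horizon=horizon,
                expected_supplier=expected_supplier, scale=scale,
                site_mean=float(means.loc[sid]) if means is not None else None)
            rows.append(eff.__dict__)
    cols = ["site_id", "metric", "start_year", "end_year", "method", "scale",
            "horizon", "gpp_predrought", "gpp_drought", "gpp_postdrought",
            "gpp_expected", "delta_dir", "delta_lag"]
    return pd.DataFrame(rows, columns=cols)


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0):
    """Percentile bootstrap of the median.

    Resamples the values with replacement ``n_boot`` times, takes the
    median of each resample, and returns ``(median, ci_low, ci_high,
    significant)`` where the point estimate is the median of the original
    values and significance means the interval excludes zero.
    Deterministic given the seed.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("bootstrap_ci requires at least one finite value")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    stats = np.median(vals[idx], axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    med = float(np.median(vals))
    significant = not (lo <= 0.0 <= hi)
    return med, float(lo), float(hi), bool(significant)


def stratified_estimates(effects: pd.DataFrame, site_attrs: pd.DataFrame,
                         strata: str = "global", effect: str = "dir",
                         n_boot: int = 1000, level: float = 0.95,
                         seed: int = 0) -> pd.DataFrame:
    """Median effect with bootstrap CI per stratum.

    ``strata`` is ``global``, ``aridity`` or ``land_cover``; events are
    mapped to their site's aridity class or land-cover group via
    ``site_attrs`` (one row per site with ``ai`` and ``igbp``).  Empty
    strata are omitted.  Returns a tidy table with one row per stratum.
    """
    if effect not in ("dir", "lag"):
        raise ValueError("effect must be 'dir' or 'lag'")
    col = f"delta_{effect}"
    df = effects.copy()
    attrs = site_attrs.drop_duplicates("site_id").set_index("site_id")
    if strata == "global":
        df["stratum"] = "global"
        order = ["global"]
    elif strata == "aridity":
        df["stratum"] = [aridity_class(float(attrs.loc[s, "ai"]))
                         for s in df["site_id"]]
        order = list(ARIDITY_CLASSES)
    elif strata == "land_cover":
        df["stratum"] = [land_cover_group(attrs.loc[s, "igbp"])
                         for s in df["site_id"]]
        order = list(LAND_COVER_GROUPS)
    else:
        raise ValueError("strata must be 'global', 'aridity' or 'land_cover'")

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17])
    child = {lab: np.random.default_rng(s)
             for lab, s in zip(order, ss.spawn(len(order)))}
    rows = []
    for lab in order:
        vals = df.loc[df["stratum"] == lab, col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        med, lo, hi, sig = bootstrap_ci(vals, n_boot=n_boot, level=level,
                                        seed=child[lab])
        rows.append({"stratum": lab, "effect": effect, "median": med,
                     "ci_low": lo, "ci_high": hi, "significant": sig,
                     "n": int(len(vals))})
    return pd.DataFrame(rows, columns=["stratum", "effect", "median",
                                       "ci_low", "ci_high", "significant", "n"])


def horizon_sweep(table: pd.DataFrame, windows: list[EventWindows],
                  horizons=(1, 2, 3, 4), method: str = "baseline",
                  expected_supplier=None, scale: str = "absolute",
                  site_attrs: pd.DataFrame | None = None,
                  strata: str = "global", n_boot: int = 1000,
                  level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Legacy-effect estimates across postdrought horizons.

    dGPP_lag is recomputed per horizon using the first k postdrought years;
    dGPP_dir is horizon-independent by construction.  Returns stacked
    stratum estimates with a ``horizon`` column.
    """
    if site_attrs is None:
        site_attrs = table[["site_id", "ai", "igbp"]].drop_duplicates("site_id")
    out = []
    for h in horizons:
        eff = compute_effects(table, windows, method=method, horizon=h,
                              expected_supplier=expected_supplier, scale=scale)
        est = stratified_estimates(eff, site_attrs, strata=strata,
                                   effect="lag", n_boot=n_boot, level=level,
                                   seed=int(seed) + h)
        est.insert(0, "horizon", h)
        out.append(est)
    return pd.concat(out, ignore_index=True)
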