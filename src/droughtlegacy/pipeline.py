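"""End-to-end orchestration: simulate/load -> detect -> windows -> effects
-> stratified estimates -> drivers, with validation, deterministic seeding
and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, SimConfig
from .counterfactual import make_supplier, predrought_samples, tune_and_fit
from .drivers import (assemble_driver_dataset, average_effects_across_methods,
                      fit_stepwise_gam)
from .effects import (compute_effects, site_mean_gpp, stratified_estimates,
                      to_anomaly)
from .events import build_windows_all, detect_events_all, events_to_frame, \
    windows_to_frame
from .simulate import generate_sites

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = {
    "site_id": "object", "year": "int", "gpp": "float", "pdsi": "float",
    "cwd": "float", "ai": "float", "igbp": "object",
}
NA_TOKEN = "NA"


def read_table(path) -> pd.DataFrame:
    """Read a site-year CSV (UTF-8, 'NA' missing token)."""
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=NA_TOKEN)


def validate_table(table_or_path) -> dict:
    """Structural validation of a site-year table.

    Checks required columns, (site_id, year) uniqueness and value ranges;
    returns ``{"ok": bool, "issues": [...]}`` with human-readable issue
    strings naming the offending rows.
    """
    if isinstance(table_or_path, (str, Path)):
        table = read_table(table_or_path)
    else:
        table = table_or_path
    issues: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        issues.append(f"missing required columns: {missing}")
        return {"ok": False, "issues": issues}
    dup = table.duplicated(subset=["site_id", "year"], keep=False)
    if dup.any():
        rows = table.loc[dup, ["site_id", "year"]].drop_duplicates()
        issues.append("duplicated (site_id, year) pairs: "
                      + "; ".join(f"{r.site_id}/{r.year}"
                                  for r in rows.itertuples()))
    neg = table["gpp"].notna() & (table["gpp"] < 0)
    if neg.any():
        issues.append(f"negative GPP in rows {list(table.index[neg])}")
    bad_ai = table["ai"].notna() & (table["ai"] < 0)
    if bad_ai.any():
        issues.append(f"negative aridity index in rows {list(table.index[bad_ai])}")
    if not np.issubdtype(table["year"].dtype, np.integer):
        if not (table["year"].dropna() == table["year"].dropna().astype(int)).all():
            issues.append("year column contains non-integer values")
    return {"ok": not issues, "issues": issues}


def _stage_seed(base_seed: int, stage: str) -> int:
    """Independent, stable per-stage seed stream (< 2**31)."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, table: pd.DataFrame | None = None,
                 outdir=None) -> dict:
    """Execute the full attribution analysis.

    If ``table`` is None, ``config.sim`` must describe a synthetic
    population to generate.  Returns a bundle dict with the table, events,
    windows, per-event effects, stratified estimates, driver fits and the
    manifest; writes everything as CSV/JSON under ``outdir`` if given.
    """
    bundle: dict = {}
    if table is None:
        if config.sim is None:
            raise ValueError("run_pipeline needs either a table or config.sim")
        table, truth = generate_sites(config.sim)
        bundle["truth"] = truth
    report = validate_table(table)
    if not report["ok"]:
        raise ValueError(f"stage=validate: invalid input table: "
                         f"{report['issues']}")
    bundle["table"] = table

    all_events, all_windows = [], []
    windows_by_metric: dict[str, list] = {}
    events_by_metric: dict[str, dict] = {}
    for metric in config.metrics:
        ev = detect_events_all(table, metric, pdsi_cut=config.pdsi_cut)
        wins = build_windows_all(ev, table, pre_len=config.pre_len,
                                 post_len=config.post_len)
        events_by_metric[metric] = ev
        windows_by_metric[metric] = wins
        all_events.append(events_to_frame(
            [e for evs in ev.values() for e in evs]))
        all_windows.append(windows_to_frame(wins))
    bundle["events"] = pd.concat(all_events, ignore_index=True)
    bundle["windows"] = pd.concat(all_windows, ignore_index=True)

    # counterfactual models (per metric, and per response scale)
    suppliers: dict[tuple[str, str], object] = {}
    rf_metrics_rows = []
    if "counterfactual" in config.methods:
        rf_seed = config.rf.seed if config.rf.seed is not None \
            else _stage_seed(config.seed, "rf")
        anom_table = to_anomaly(table)
        for metric in config.metrics:
            for scale_table, scale_name in ((table, "absolute"),
                                            (anom_table, "anomaly")):
                if scale_name == "anomaly" and "anomaly" not in config.scales:
                    continue
                try:
                    train = predrought_samples(scale_table,
                                               events_by_metric[metric])
                    model = tune_and_fit(train,
                                         split_frac=config.rf.split_frac,
                                         n_trees=config.rf.n_trees,
                                         seed=rf_seed)
                except ValueError as exc:
                    raise ValueError(
                        f"stage=counterfactual[{metric}/{scale_name}]: {exc}"
                    ) from exc
                suppliers[(metric, scale_name)] = make_supplier(model,
                                                                scale_table)
                rf_metrics_rows.append({"metric": metric, "scale": scale_name,
                                        "mtry": model.mtry,
                                        **model.metrics})
        bundle["rf_metrics"] = pd.DataFrame(rf_metrics_rows)

    # per-event effects for every metric x method x scale x horizon
    anom_table = to_anomaly(table)
    effect_frames = []
    for metric in config.metrics:
        wins = windows_by_metric[metric]
        for method in config.methods:
            for scale in config.scales:
                src = anom_table if scale == "anomaly" else table
                supplier = None
                if method == "counterfactual":
                    supplier = suppliers[(metric,
                                          "anomaly" if scale == "anomaly"
                                          else "absolute")]
                for h in config.horizons:
                    eff = compute_effects(src, wins, method=method,
                                          horizon=h,
                                          expected_supplier=supplier,
                                          scale=scale)
                    effect_frames.append(eff)
    effects = pd.concat(effect_frames, ignore_index=True)
    bundle["effects"] = effects

    # stratified estimates
    site_attrs = table[["site_id", "ai", "igbp"]].drop_duplicates("site_id")
    est_rows = []
    boot_seed = _stage_seed(config.seed, "bootstrap")
    hmax = max(config.horizons)
    for (metric, method, scale, h), grp in effects.groupby(
            ["metric", "method", "scale", "horizon"], sort=True):
        for strata in ("global", "aridity", "land_cover"):
            for eff_kind in ("dir", "lag"):
                if eff_kind == "dir" and h != hmax:
                    continue  # direct effect is horizon-invariant
                est = stratified_estimates(
                    grp, site_attrs, strata=strata, effect=eff_kind,
                    n_boot=config.n_boot, level=config.level,
                    seed=boot_seed + 7 * h)
                est.insert(0, "strata", strata)
                est.insert(0, "horizon", h)
                est.insert(0, "scale", scale)
                est.insert(0, "method", method)
                est.insert(0, "metric", metric)
                est_rows.append(est)
    bundle["estimates"] = pd.concat(est_rows, ignore_index=True)

    # driver attribution on method-averaged anomaly-scale effects
    if config.run_drivers:
        driver_fits = {}
        hm = max(config.horizons)
        per_method = [effects[(effects["method"] == m)
                              & (effects["scale"] == "anomaly")
                              & (effects["horizon"] == hm)]
                      for m in config.methods]
        per_method = [t for t in per_method if len(t)]
        if per_method:
            avg = average_effects_across_methods(per_method)
            pooled_windows = [w for m in config.metrics
                              for w in windows_by_metric[m]]
            for target in ("dir", "lag"):
                ds = assemble_driver_dataset(avg, pooled_windows, table,
                                             target=target)
                try:
                    driver_fits[target] = fit_stepwise_gam(
                        ds, alpha=config.gam.alpha,
                        spline_df=config.gam.spline_df,
                        min_rows_per_term=config.gam.min_rows_per_term)
                except ValueError as exc:
                    log.warning("stage=drivers[%s]: skipped (%s)", target, exc)
        bundle["drivers"] = driver_fits

    bundle["manifest"] = {
        "package": "droughtlegacy", "version": __version__,
        "config": config.to_dict(), "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("rf", "bootstrap")},
        "n_sites": int(table["site_id"].nunique()),
        "n_site_years": int(len(table)),
    }

    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("table", "truth", "events", "windows", "effects",
                 "estimates", "rf_metrics"):
        if name in bundle:
            write_table(bundle[name], outdir / f"{name}.csv")
    if "drivers" in bundle:
        for target, fit in bundle["drivers"].items():
            (outdir / f"drivers_{target}.json").write_text(
                json.dumps(fit.to_json_dict(), indent=2, sort_keys=True))
            for term, grid in fit.partial_effects.items():
                write_table(grid.assign(term=term),
                            outdir / f"partial_{target}_{term}.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, sort_keys=True, default=str))
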