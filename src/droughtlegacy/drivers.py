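"""Driver attribution for direct and legacy drought effects.

Assembles one row per drought event with the standardized effect size as
response and standardized climatic/ecophysiological predictors: period
means of the drought-index and climate covariates over the same year sets
used for the GPP windows, their drought-minus-pre (direct) or post-minus-
pre (legacy) differences, soil properties, site traits, aridity and land
cover; for the legacy model the direct effect itself is an additional
predictor.  A backward stepwise routine then removes non-significant
predictors one at a time (dropping the least important first), verifies
that the concurvity of the final model stays below 0.8, and reports each
retained driver's importance as its percentage share of the explained
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gam
from .events import EventWindows

log = logging.getLogger(__name__)

PERIOD_COVARIATES = ["pdsi", "srad", "vpd", "t", "p", "sm", "lai"]
SITE_PREDICTORS = ["soc", "soil_n", "soil_cec", "ai", "diversity", "sla",
                   "root_depth", "root_shoot", "wood_density", "canopy_height"]


@dataclass
class DriverDataset:
    """Standardized per-event rows ready for additive-model fitting."""

    data: pd.DataFrame
    response: str
    continuous: list[str]
    categorical: list[str]
    target: str  # "dir" or "lag"
    n_dropped: int
    standardization: pd.DataFrame  # mean/sd per standardized column


@dataclass
class DriverFit:
    """Retained drivers with importance shares and partial effects."""

    target: str
    retained: list[str]
    importance: dict[str, float]
    partial_effects: dict[str, pd.DataFrame]
    r2: float
    max_concurvity: float
    n: int
    history: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return len(self.retained) == 0

    def to_json_dict(self) -> dict:
        return {"target": self.target, "retained": self.retained,
                "importance": self.importance, "r2": self.r2,
                "max_concurvity": self.max_concurvity, "n": self.n,
                "history": self.history}


def _period_mean(rec: pd.Series, years) -> float:
    years = list(years)
    if not years:
        return float("nan")
    return float(np.mean([rec.loc[y] for y in years]))


def _standardize(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """z-score with sample sd (ddof=1); constant columns left unscaled."""
    stats = []
    for c in cols:
        m = float(df[c].mean())
        s = float(df[c].std(ddof=1))
        if np.isfinite(s) and s > 0:
            df[c] = (df[c] - m) / s
        else:
            df[c] = df[c] - m
            s = 1.0
        stats.append({"column": c, "mean": m, "sd": s})
    return pd.DataFrame(stats)


def assemble_driver_dataset(effects: pd.DataFrame,
                            windows: list[EventWindows],
                            table: pd.DataFrame,
                            target: str = "lag") -> DriverDataset:
    """Build the standardized per-event driver table.

    ``effects`` must carry one row per event (site_id/metric/start_year
    keyed) with ``delta_dir`` and ``delta_lag``.  Period predictor means
    use exactly the window year sets used for GPP: event years for the
    drought period, pre/post windows otherwise.  Events missing the
    required response or windows are dropped with a logged count.
    """
    if target not in ("dir", "lag"):
        raise ValueError("target must be 'dir' or 'lag'")
    eff = effects.set_index(["site_id", "metric", "start_year"])
    site_groups = {str(s): g.set_index("year") for s, g in
                   table.groupby("site_id", sort=True)}

    rows, dropped = [], 0
    for w in windows:
        ev = w.event
        key = (ev.site_id, ev.metric, ev.start_year)
        if key not in eff.index:
            dropped += 1
            continue
        erow = eff.loc[key]
        if isinstance(erow, pd.DataFrame):
            erow = erow.iloc[0]
        resp = erow["delta_lag"] if target == "lag" else erow["delta_dir"]
        if not np.isfinite(resp) or w.pre_missing or \
                (target == "lag" and w.post_missing):
            dropped += 1
            continue
        rec = site_groups[ev.site_id]
        focal_years = w.post_years if target == "lag" else ev.years
        row = {"response": float(resp), "site_id": ev.site_id,
               "metric": ev.metric, "start_year": ev.start_year}
        ok = True
        for c in PERIOD_COVARIATES:
            focal = _period_mean(rec[c], focal_years)
            pre = _period_mean(rec[c], w.pre_years)
            row[f"{c}_focal"] = focal
            row[f"d_{c}"] = focal - pre
            if not (np.isfinite(focal) and np.isfinite(pre)):
                ok = False
        for c in SITE_PREDICTORS:
            row[c] = float(rec[c].iloc[0])
        row["land_cover"] = str(rec["igbp"].iloc[0])
        if target == "lag":
            row["delta_gpp_dir"] = float(erow["delta_dir"])
            if not np.isfinite(row["delta_gpp_dir"]):
                ok = False
        if not ok:
            dropped += 1
            continue
        rows.append(row)

    if dropped:
        log.info("assemble_driver_dataset(%s): dropped %d events with "
                 "missing windows or responses", target, dropped)
    continuous = [f"{c}_focal" for c in PERIOD_COVARIATES] + \
        [f"d_{c}" for c in PERIOD_COVARIATES] + list(SITE_PREDICTORS)
    if target == "lag":
        continuous.append("delta_gpp_dir")
    df = pd.DataFrame(rows)
    if len(df):
        stats = _standardize(df, ["response"] + continuous)
    else:
        stats = pd.DataFrame(columns=["column", "mean", "sd"])
    return DriverDataset(data=df, response="response", continuous=continuous,
                         categorical=["land_cover"], target=target,
                         n_dropped=dropped, standardization=stats)


def _make_terms(continuous: list[str], categorical: list[str],
                spline_df: int) -> list:
    terms: list = [gam.SmoothTerm(c, df=spline_df) for c in continuous]
    terms += [gam.FactorTerm(c) for c in categorical]
    return terms


def fit_stepwise_gam(dataset: DriverDataset, alpha: float = 0.05,
                     spline_df: int = 5, min_rows_per_term: int = 10,
                     concurvity_max: float = 0.8) -> DriverFit:
    """Backward stepwise additive-model fit with a concurvity guard.

    ``alpha`` is a family-wise significance level: a term is significant
    when its partial-F p-value is below ``alpha`` divided by the number of
    initial candidate terms (Bonferroni), which keeps pure-noise responses
    from retaining spurious drivers.  While any term is non-significant the
    least important non-significant term is removed and the model refit.
    The surviving model must have every pairwise concurvity below
    ``concurvity_max``; violating pairs lose their higher-concurvity
    member.  An empty final model is a valid diagnostic outcome.
    """
    df = dataset.data
    cat = [c for c in dataset.categorical
           if c in df.columns and df[c].nunique() > 1]
    terms = _make_terms(dataset.continuous, cat, spline_df)
    n0 = len(terms)
    if n0 == 0:
        raise ValueError("no candidate terms")
    if len(df) < min_rows_per_term * n0:
        raise ValueError(
            f"{len(df)} rows is too few for {n0} candidate terms "
            f"(need >= {min_rows_per_term} rows per term)")
    thresh = alpha / n0
    history: list[str] = []

    def _fit(ts):
        return gam.fit_additive(df, dataset.response, ts)

    fit = None
    while terms:
        fit = _fit(terms)
        nonsig = [t for t in terms if fit.pvalues[t.name] > thresh]
        if not nonsig:
            break
        victim = min(nonsig, key=lambda t: fit.importance_raw[t.name])
        history.append(f"drop {victim.name} "
                       f"(p={fit.pvalues[victim.name]:.3g})")
        terms = [t for t in terms if t.name != victim.name]

    # concurvity guard on the surviving model
    while len(terms) >= 2:
        fit = _fit(terms)
        pairs = list(fit.pairwise_concurvity())
        worst = max(pairs, key=lambda p: p[2])
        if worst[2] < concurvity_max:
            break
        a, b = worst[0], worst[1]
        amax = max(c for i, _, c in pairs if i == a)
        bmax = max(c for i, _, c in pairs if i == b)
        if amax > bmax:
            victim_name = a
        elif bmax > amax:
            victim_name = b
        else:
            victim_name = min((a, b), key=lambda nm: fit.importance_raw[nm])
        history.append(f"drop {victim_name} (concurvity={worst[2]:.3f})")
        terms = [t for t in terms if t.name != victim_name]
        # removal can change significance; re-run the significance loop
        while terms:
            fit = _fit(terms)
            nonsig = [t for t in terms if fit.pvalues[t.name] > thresh]
            if not nonsig:
                break
            victim = min(nonsig, key=lambda t: fit.importance_raw[t.name])
            history.append(f"drop {victim.name} "
                           f"(p={fit.pvalues[victim.name]:.3g})")
            terms = [t for t in terms if t.name != victim.name]

    if not terms:
        return DriverFit(target=dataset.target, retained=[], importance={},
                         partial_effects={}, r2=0.0, max_concurvity=0.0,
                         n=len(df), history=history)

    fit = _fit(terms)
    shares = gam.importance_shares(fit)
    partials = {t.name: fit.partial_effect(t.name)
                for t in terms if t.kind == "smooth"}
    return DriverFit(target=dataset.target,
                     retained=[t.name for t in terms], importance=shares,
                     partial_effects=partials, r2=fit.r2,
                     max_concurvity=fit.max_pairwise_concurvity(),
                     n=len(df), history=history)


def average_effects_across_methods(effect_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-event average of delta columns across expected-GPP methods.

    Tables must share the (site_id, metric, start_year, end_year) event
    keys; the direct effect is method-invariant by construction, so this
    only changes the legacy column.
    """
    keys = ["site_id", "metric", "start_year", "end_year"]
    stacked = pd.concat(effect_tables, ignore_index=True)
    agg = stacked.groupby(keys, as_index=False).agg(
        delta_dir=("delta_dir", "mean"), delta_lag=("delta_lag", "mean"))
    return agg
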