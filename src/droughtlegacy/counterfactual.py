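"""Counterfactual no-drought GPP prediction with a random forest.

The model is trained only on site-years strictly before each site's first
drought event (sites that never experienced a drought contribute all their
years), so the learned GPP response surface is free of drought influence.
Predictions for postdrought years then estimate the GPP that would have
been observed had the drought not occurred.  For rows that were part of
the training data, out-of-bag predictions are returned so a training row
is never scored by trees that saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .events import DroughtEvent

PREDICTORS = ["pdsi", "srad", "vpd", "t", "p", "sm", "lai",
              "land_cover_code", "soc", "soil_n", "soil_cec"]

# Explicit IGBP category-to-integer encoding for the tree ensemble.
IGBP_CODES = {"ENF": 0, "DNF": 1, "EBF": 2, "DBF": 3, "MF": 4,
              "CSH": 5, "OSH": 6, "WSA": 7, "SAV": 8, "GRA": 9}


def encode_land_cover(igbp: pd.Series) -> pd.Series:
    """Integer-encode IGBP land cover; unknown codes become NaN."""
    return igbp.map(IGBP_CODES).astype(float)


def _accuracy(observed: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """R2, slope of the observed-on-predicted regression, and mean bias
    (observed minus predicted)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    sst = float(np.sum((obs - obs.mean()) ** 2))
    ssr = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    if np.std(pred) > 0:
        slope = float(LinearRegression().fit(pred[:, None], obs).coef_[0])
    else:
        slope = float("nan")
    return {"r2": r2, "slope": slope, "bias": float(np.mean(obs - pred))}


@dataclass
class CounterfactualModel:
    """Fitted ensemble plus the bookkeeping needed for honest prediction."""

    forest: RandomForestRegressor
    mtry: int
    n_trees: int
    seed: int
    predictors: list[str]
    metrics: dict[str, float]
    oob: pd.Series  # OOB predictions indexed by (site_id, year)
    response: str = "gpp"

    def save(self, path) -> None:
        """Persist the forest (joblib) with a JSON sidecar of settings."""
        path = Path(path)
        joblib.dump(self.forest, path)
        sidecar = {"mtry": self.mtry, "n_trees": self.n_trees,
                   "seed": self.seed, "predictors": self.predictors,
                   "metrics": self.metrics, "response": self.response}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))


def predrought_samples(table: pd.DataFrame,
                       events_by_site: dict[str, list[DroughtEvent]],
                       response: str = "gpp") -> pd.DataFrame:
    """Training rows: site-years strictly before each site's first event.

    Sites with no detected events contribute all their years (they are
    drought-free by definition).  Rows with a missing response or missing
    predictors are dropped.  Raises if nothing remains.
    """
    df = table.copy()
    df["land_cover_code"] = encode_land_cover(df["igbp"])
    first_start = {sid: min(e.start_year for e in evs)
                   for sid, evs in events_by_site.items() if evs}
    cut = df["site_id"].map(first_start)
    keep = cut.isna() | (df["year"] < cut)
    df = df[keep]
    df = df.dropna(subset=[response] + PREDICTORS)
    if len(df) == 0:
        raise ValueError("no predrought samples available for training")
    return df.reset_index(drop=True)


def tune_and_fit(training: pd.DataFrame, split_frac: float = 0.7,
                 n_trees: int = 500, seed: int = 0,
                 response: str = "gpp") -> CounterfactualModel:
    """Select mtry on a seeded 70/30 split, then refit on all samples.

    Every candidate mtry in 1..n_predictors is fit on the training split
    and scored by held-out R2; ties break toward the smaller mtry.  The
    final model is refit on all predrought samples with OOB scoring, and
    train metrics are computed from out-of-bag predictions.
    """
    if len(training) < 30:
        raise ValueError("need >= 30 predrought samples to train")
    X = training[PREDICTORS].to_numpy(dtype=float)
    y = training[response].to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    n = len(training)
    perm = rng.permutation(n)
    n_train = int(round(split_frac * n))
    tr, te = perm[:n_train], perm[n_train:]

    best_mtry, best_score = None, -np.inf
    for mtry in range(1, len(PREDICTORS) + 1):
        rf = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                                   random_state=int(seed) % (2**32),
                                   n_jobs=1)
        rf.fit(X[tr], y[tr])
        m = _accuracy(y[te], rf.predict(X[te]))
        score = m["r2"] if np.isfinite(m["r2"]) else -np.inf
        if best_mtry is None or score > best_score:  # ties keep smaller mtry
            best_mtry, best_score, test_metrics = mtry, score, m

    final = RandomForestRegressor(n_estimators=n_trees, max_features=best_mtry,
                                  random_state=int(seed) % (2**32),
                                  oob_score=True, bootstrap=True, n_jobs=1)
    final.fit(X, y)
    oob_pred = final.oob_prediction_
    train_metrics = _accuracy(y, oob_pred)
    metrics = {
        "r2_train": train_metrics["r2"], "slope_train": train_metrics["slope"],
        "bias_train": train_metrics["bias"], "r2_test": test_metrics["r2"],
        "slope_test": test_metrics["slope"], "bias_test": test_metrics["bias"],
    }
    oob = pd.Series(oob_pred, index=pd.MultiIndex.from_frame(
        training[["site_id", "year"]]))
    return CounterfactualModel(forest=final, mtry=int(best_mtry),
                               n_trees=n_trees, seed=int(seed),
                               predictors=list(PREDICTORS), metrics=metrics,
                               oob=oob, response=response)


def predict_expected(model: CounterfactualModel, rows: pd.DataFrame) -> pd.Series:
    """Expected no-drought GPP per row, indexed like ``rows``.

    Rows that were in the training data receive their out-of-bag
    prediction; new rows receive the ordinary ensemble prediction.  Rows
    with any missing predictor get NaN.  Predictions are invariant to row
    order and to predictor column order (columns are realigned by name).
    """
    df = rows.copy()
    if "land_cover_code" not in df.columns:
        df["land_cover_code"] = encode_land_cover(df["igbp"])
    out = pd.Series(np.nan, index=df.index, name="gpp_expected")

    key = pd.MultiIndex.from_frame(df[["site_id", "year"]])
    in_train = key.isin(model.oob.index)
    if in_train.any():
        out.iloc[np.flatnonzero(in_train)] = \
            model.oob.loc[key[in_train]].to_numpy()

    new = ~in_train
    if new.any():
        X = df.loc[new, model.predictors].to_numpy(dtype=float)
        ok = np.all(np.isfinite(X), axis=1)
        pos = np.flatnonzero(new)[ok]
        if len(pos):
            out.iloc[pos] = model.forest.predict(X[ok])
    return out


def make_supplier(model: CounterfactualModel, table: pd.DataFrame):
    """Build a ``(site_id, year) -> expected GPP`` lookup over a table."""
    preds = predict_expected(model, table)
    lut = dict(zip(zip(table["site_id"], table["year"]), preds))
    return lambda sid, yr: lut.get((sid, yr), float("nan"))
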