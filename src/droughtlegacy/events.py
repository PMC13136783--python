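"""Drought event detection and pre/postdrought window construction.

A long-term drought event is a maximal run of consecutive calendar years in
a site's record whose annual index crosses the severity threshold: annual
PDSI strictly below -3, or annual climatic water deficit strictly above the
site's 95th-percentile threshold.  Missing calendar years break run
contiguity (an unobserved year cannot be certified drought or drought-free).
Windows supply the drought-free comparison years: up to three predrought
years (the most recent eligible ones before the event, after the previous
event) and up to four postdrought years (the earliest eligible ones after
the event, before the next event), all with non-missing GPP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NORTH_MONTHS = (4, 5, 6, 7, 8, 9, 10)   # Apr-Oct growing season
SOUTH_MONTHS = (10, 11, 12, 1, 2, 3, 4)  # Oct (prev yr) - Apr


@dataclass(frozen=True)
class DroughtEvent:
    """One maximal run of consecutive drought years at a site."""

    site_id: str
    metric: str  # "PDSI" or "CWD"
    start_year: int
    end_year: int
    severity: float  # mean index value over the event years

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("start_year must be <= end_year")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.end_year + 1))


@dataclass(frozen=True)
class EventWindows:
    """An event plus its resolved drought-free pre/post year sets."""

    event: DroughtEvent
    pre_years: tuple[int, ...]
    post_years: tuple[int, ...]

    @property
    def pre_missing(self) -> bool:
        return len(self.pre_years) == 0

    @property
    def post_missing(self) -> bool:
        return len(self.post_years) == 0


def aggregate_annual(monthly: pd.DataFrame, mode: str = "calendar") -> pd.DataFrame:
    """Aggregate monthly PDSI/CWD to annual (or growing-season) values.

    Annual PDSI is the mean, annual CWD the sum, of the included months.
    Growing-season months are Apr-Oct for latitude > 23.5, Oct of the
    previous year through Apr for latitude < -23.5, and all 12 months in
    the tropics.  A site-year missing any included month gets NA aggregates
    and ``complete=False`` rather than a silently partial value.
    """
    if mode not in ("calendar", "growing_season"):
        raise ValueError("mode must be 'calendar' or 'growing_season'")
    need_lat = mode == "growing_season"
    if need_lat and "latitude" not in monthly.columns:
        raise ValueError("growing_season aggregation requires a latitude column")

    df = monthly.copy()
    if mode == "calendar":
        df["agg_year"] = df["year"]
        df["included"] = True
    else:
        lat = df["latitude"].to_numpy()
        month = df["month"].to_numpy()
        year = df["year"].to_numpy()
        agg_year = year.copy()
        included = np.ones(len(df), dtype=bool)
        north = lat > 23.5
        south = lat < -23.5
        included[north] = np.isin(month[north], NORTH_MONTHS)
        included[south] = np.isin(month[south], SOUTH_MONTHS)
        # southern-hemisphere Oct-Dec months belong to the NEXT year's season
        shift = south & (month >= 10)
        agg_year[shift] = year[shift] + 1
        df["agg_year"] = agg_year
        df["included"] = included

    df = df[df["included"]]
    out = []
    for (sid, yr), grp in df.groupby(["site_id", "agg_year"], sort=True):
        lat = float(grp["latitude"].iloc[0]) if "latitude" in grp.columns else 0.0
        if mode == "calendar":
            n_req = 12
        else:
            n_req = 7 if (lat > 23.5 or lat < -23.5) else 12
        months = set(grp["month"].tolist())
        complete = len(months) == n_req and not (
            grp["pdsi"].isna().any() or grp["cwd"].isna().any())
        out.append({
            "site_id": sid, "year": int(yr),
            "pdsi": float(grp["pdsi"].mean()) if complete else np.nan,
            "cwd": float(grp["cwd"].sum()) if complete else np.nan,
            "complete": complete,
        })
    return pd.DataFrame(out, columns=["site_id", "year", "pdsi", "cwd", "complete"])


def cwd_threshold(site_record: pd.DataFrame | pd.Series | np.ndarray) -> float:
    """Site CWD drought threshold: the empirical 95th percentile of the
    site's annual CWD series (linear interpolation between order statistics).

    Raises ``ValueError`` with fewer than two finite values (the site is
    then excluded from CWD detection).
    """
    if isinstance(site_record, pd.DataFrame):
        vals = site_record["cwd"].to_numpy(dtype=float)
    else:
        vals = np.asarray(site_record, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("cwd_threshold requires >= 2 annual CWD values")
    return float(np.quantile(vals, 0.95))


def _drought_mask(site_record: pd.DataFrame, metric: str, pdsi_cut: float,
                  cwd_q95: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Return (years, mask) sorted by year; NaN index values are never drought."""
    rec = site_record.sort_values("year")
    years = rec["year"].to_numpy(dtype=int)
    if metric == "PDSI":
        idx = rec["pdsi"].to_numpy(dtype=float)
        mask = np.isfinite(idx) & (idx < pdsi_cut)
    elif metric == "CWD":
        idx = rec["cwd"].to_numpy(dtype=float)
        if cwd_q95 is None:
            if "cwd_q95" in rec.columns and np.isfinite(rec["cwd_q95"].iloc[0]):
                cwd_q95 = float(rec["cwd_q95"].iloc[0])
            else:
                try:
                    cwd_q95 = cwd_threshold(rec)
                except ValueError:
                    return years, np.zeros(len(years), dtype=bool)
        mask = np.isfinite(idx) & (idx > cwd_q95)
    else:
        raise ValueError("metric must be 'PDSI' or 'CWD'")
    return years, mask


def detect_events(site_record: pd.DataFrame, metric: str,
                  pdsi_cut: float = -3.0,
                  cwd_q95: float | None = None) -> list[DroughtEvent]:
    """Identify maximal runs of consecutive drought years for one site.

    A gap in the observed year sequence terminates a run.  For CWD the
    threshold is, in order of preference: the explicit ``cwd_q95`` argument,
    a finite ``cwd_q95`` column in the record (a climatological threshold
    supplied with the data), or the within-record empirical 95th percentile.
    """
    if len(site_record) == 0:
        return []
    site_id = str(site_record["site_id"].iloc[0])
    years, mask = _drought_mask(site_record, metric, pdsi_cut, cwd_q95)
    rec = site_record.sort_values("year")
    idx = rec["pdsi" if metric == "PDSI" else "cwd"].to_numpy(dtype=float)

    events: list[DroughtEvent] = []
    i = 0
    n = len(years)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1] and years[j + 1] == years[j] + 1:
            j += 1
        events.append(DroughtEvent(
            site_id=site_id, metric=metric,
            start_year=int(years[i]), end_year=int(years[j]),
            severity=float(np.mean(idx[i:j + 1])),
        ))
        i = j + 1
    return events


def build_windows(events: list[DroughtEvent], site_record: pd.DataFrame,
                  pre_len: int = 3, post_len: int = 4,
                  gpp_col: str = "gpp") -> list[EventWindows]:
    """Resolve drought-free pre/postdrought windows for each event.

    Predrought years: the up-to-``pre_len`` most recent drought-free years
    strictly between the previous event (or record start) and the event
    start.  Postdrought years: the up-to-``post_len`` earliest drought-free
    years strictly between the event end and the next event (or record end).
    Within those nearest drought-free years, years with missing GPP are
    dropped without pulling in further years.  Empty sets are reported as
    missing, not errors.
    """
    rec = site_record.sort_values("year")
    years = rec["year"].to_numpy(dtype=int)
    gpp = rec[gpp_col].to_numpy(dtype=float)
    has_gpp = dict(zip(years.tolist(), np.isfinite(gpp).tolist()))
    drought_years = set()
    for ev in events:
        drought_years.update(ev.years)

    events = sorted(events, key=lambda e: e.start_year)
    out = []
    for k, ev in enumerate(events):
        lo = events[k - 1].end_year if k > 0 else -np.inf
        hi = events[k + 1].start_year if k + 1 < len(events) else np.inf
        pre_cand = [int(y) for y in years
                    if lo < y < ev.start_year and y not in drought_years]
        post_cand = [int(y) for y in years
                     if ev.end_year < y < hi and y not in drought_years]
        pre = [y for y in pre_cand[-pre_len:] if has_gpp.get(y, False)]
        post = [y for y in post_cand[:post_len] if has_gpp.get(y, False)]
        out.append(EventWindows(event=ev, pre_years=tuple(pre),
                                post_years=tuple(post)))
    return out


def events_to_frame(events: list[DroughtEvent]) -> pd.DataFrame:
    """Serialize events to a tidy table."""
    return pd.DataFrame(
        [{"site_id": e.site_id, "metric": e.metric, "start_year": e.start_year,
          "end_year": e.end_year, "severity": e.severity,
          "n_years": e.end_year - e.start_year + 1} for e in events],
        columns=["site_id", "metric", "start_year", "end_year", "severity",
                 "n_years"],
    )


def windows_to_frame(windows: list[EventWindows]) -> pd.DataFrame:
    """Serialize windows with explicit year lists (pipe-separated)."""
    rows = []
    for w in windows:
        e = w.event
        rows.append({
            "site_id": e.site_id, "metric": e.metric,
            "start_year": e.start_year, "end_year": e.end_year,
            "pre_years": "|".join(map(str, w.pre_years)),
            "post_years": "|".join(map(str, w.post_years)),
            "pre_missing": w.pre_missing, "post_missing": w.post_missing,
        })
    return pd.DataFrame(rows, columns=["site_id", "metric", "start_year",
                                       "end_year", "pre_years", "post_years",
                                       "pre_missing", "post_missing"])


def detect_events_all(table: pd.DataFrame, metric: str,
                      pdsi_cut: float = -3.0) -> dict[str, list[DroughtEvent]]:
    """Run detection per site over a full site-year table."""
    return {str(sid): detect_events(grp, metric, pdsi_cut=pdsi_cut)
            for sid, grp in table.groupby("site_id", sort=True)}


def build_windows_all(events_by_site: dict[str, list[DroughtEvent]],
                      table: pd.DataFrame, pre_len: int = 3,
                      post_len: int = 4) -> list[EventWindows]:
    """Build windows for every site's events over a full table."""
    out: list[EventWindows] = []
    for sid, grp in table.groupby("site_id", sort=True):
        evs = events_by_site.get(str(sid), [])
        if evs:
            out.extend(build_windows(evs, grp, pre_len=pre_len, post_len=post_len))
    return out
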