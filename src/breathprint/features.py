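"""Leakage-free per-record feature engineering and the high/low BrAC label.

Every feature for a record at time t is a function only of the same user's
records strictly before t, plus record-t metadata that exists before the
breath sample is taken (the subjective estimate, the timestamp, the
location, and static context tables).  Missing values are filled with an
out-of-range sentinel (-999 by default) after all features are computed, so
tree models can split on missingness itself.

The module exposes both small per-record operations (the primitive
definitions, convenient for inspection and testing) and a vectorized
assembler, wrapped in the sklearn-style :class:`PhenotypeFeaturizer`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import notes as _notes
from .calendars import SPORTS_EVENTS, us_holidays
from .config import SENTINEL, ConfigurationError
from .context import load_state_context, make_zip_context
from .geo import haversine_km
from .ingest import localize_timestamps

HIGH_BRAC_THRESHOLD = 0.08

PRIOR_STATS = ["prior_mean", "prior_min", "prior_max", "prior_range",
               "prior_median", "prior_q1", "prior_q3", "prior_iqr"]
DIST_STATS = ["dist_mean", "dist_min", "dist_max", "dist_median",
              "dist_q1", "dist_q3", "dist_iqr", "dist_dispersion"]

#: Default feature roster with family tags.  The exact roster of a deployed
#: model is configuration; families drive the ablation arms.
DEFAULT_FAMILIES: dict[str, str] = {
    **{f: "prior_brac" for f in PRIOR_STATS},
    "brac_lag1": "lag", "brac_lag2": "lag", "brac_lag3": "lag",
    "disc_lag1": "discrimination", "disc_prior_mean": "discrimination",
    "duration_days": "engagement", "n_prior_recordings": "engagement",
    "n_prior_active_days": "engagement", "n_prior_episodes": "engagement",
    "n_prior_photos": "engagement", "n_prior_drink_counts": "engagement",
    "n_prior_notes": "engagement",
    "minutes_since_last": "temporal", "hour_of_day": "temporal",
    "day_of_week": "temporal", "is_weekend": "temporal",
    "is_holiday": "temporal", "is_superbowl": "temporal",
    "is_world_series": "temporal", "is_nba_final": "temporal",
    "sports_winner_state": "temporal", "sports_loser_state": "temporal",
    "brac_estimate": "estimate",
    "verified": "flags",
    "dist_prev_km": "geospatial",
    **{f: "geospatial" for f in DIST_STATS},
    "elevation_m": "geospatial", "n_prior_zips": "geospatial",
    "n_prior_states": "geospatial", "n_prior_countries": "geospatial",
    "has_note": "nlp", "note_numeric_count": "nlp",
    "note_container_count": "nlp", "note_beverage_count": "nlp",
    "note_nlp_total": "nlp",
    "alcohol_tax": "context", "sales_tax": "context", "gas_tax": "context",
    "cigarette_tax": "context", "poverty_thousands": "context",
    "heavy_drinking_pct": "context", "urban_pct": "context",
    "population_thousands": "context",
    "zip_population": "context", "zip_urban_pct": "context",
}


@dataclass
class FeatureSpec:
    """Ordered feature roster with family tags and the missingness sentinel."""

    features: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    families: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    sentinel: float = SENTINEL

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ConfigurationError("feature names must be unique")
        missing = [f for f in self.features if f not in self.families]
        if missing:
            raise ConfigurationError(f"features without family tags: {missing}")

    def family(self, name: str) -> str:
        return self.families[name]

    def without_families(self, families) -> "FeatureSpec":
        drop = set(families)
        keep = [f for f in self.features if self.families[f] not in drop]
        return replace(self, features=keep,
                       families={f: self.families[f] for f in keep})

    def only(self, names) -> "FeatureSpec":
        names = list(names)
        unknown = [n for n in names if n not in self.families]
        if unknown:
            raise ConfigurationError(f"unknown feature name(s): {unknown}")
        return replace(self, features=names,
                       families={f: self.families[f] for f in names})


# ---------------------------------------------------------------------------
# primitive per-record operations

def label_high_brac(measured):
    """1 iff measured BrAC >= 0.08 g/dL (boundary inclusive)."""
    arr = np.asarray(measured, float)
    if np.any((arr < 0) | (arr > 0.50)):
        raise ValueError("measured BrAC outside [0, 0.50]")
    out = (arr >= HIGH_BRAC_THRESHOLD).astype(int)
    return out if arr.ndim else int(out)


def compute_discrimination(estimate, measured):
    """estimate - measured (negative = underestimate); NaN when estimate missing."""
    est = np.asarray(estimate, float)
    meas = np.asarray(measured, float)
    return est - meas


def prior_brac_stats(history, sentinel: float = SENTINEL) -> dict:
    """Order statistics of all strictly-prior BrAC values; sentinel when empty.

    Quantiles use linear interpolation between order statistics; range is
    max - min and IQR is Q3 - Q1.
    """
    h = np.asarray(history, float)
    if h.size == 0:
        return dict.fromkeys(PRIOR_STATS, sentinel)
    q1, med, q3 = np.percentile(h, [25, 50, 75])
    return {"prior_mean": h.mean(), "prior_min": h.min(), "prior_max": h.max(),
            "prior_range": h.max() - h.min(), "prior_median": med,
            "prior_q1": q1, "prior_q3": q3, "prior_iqr": q3 - q1}


def lag_features(history, sentinel: float = SENTINEL) -> dict:
    """The last three strictly-prior BrAC values (lag1 = most recent)."""
    h = np.asarray(history, float)
    out = {}
    for k in (1, 2, 3):
        out[f"brac_lag{k}"] = float(h[-k]) if h.size >= k else sentinel
    return out


def segment_episodes(table: pd.DataFrame, gap_hours: float = 12.0) -> pd.DataFrame:
    """Self-monitoring episode index per record under the >=``gap_hours`` rule.

    A user's first record opens episode 1; a record at least ``gap_hours``
    after the same user's previous record opens a new episode (a gap of
    exactly 12 h starts a new episode).  Requires (user_id, time) sorting.
    """
    ts = table["ts_parsed"] if "ts_parsed" in table.columns else table["ts_utc"]
    ts = pd.to_datetime(ts)
    grp_ts = ts.groupby(table["user_id"])
    if not grp_ts.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("table must be sorted by (user_id, time)")
    gaps = grp_ts.diff().dt.total_seconds() / 3600.0
    is_start = gaps.isna() | (gaps >= gap_hours)
    episode = is_start.groupby(table["user_id"]).cumsum().astype(int)
    return pd.DataFrame({"episode": episode, "is_episode_start": is_start,
                         "gap_hours": gaps}, index=table.index)


def merge_context_tables(records: pd.DataFrame,
                         state_context: pd.DataFrame | None = None,
                         zip_context: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join state- and zip-level context features onto records.

    Keys that miss (missing state, non-US country, unknown zip) yield NaN,
    which the sentinel fill later encodes as missingness.  Zip codes are
    join keys only — never emitted as raw features.
    """
    if state_context is None:
        state_context = load_state_context()
    required = {"state", "alcohol_tax"}
    if not required <= set(state_context.columns):
        raise ConfigurationError(
            "state context table missing required columns "
            f"{sorted(required - set(state_context.columns))}")
    sc = state_context.drop(columns=["impaired_driving_death_rate"],
                            errors="ignore")
    out = records.merge(sc, how="left", on="state")
    if zip_context is None:
        zip_context = make_zip_context(records["zip"].dropna().unique())
    out = out.merge(zip_context, how="left", on="zip")
    out.index = records.index
    return out


# ---------------------------------------------------------------------------
# vectorized assembly

def _shifted_expanding(df, col, uid, agg, **kw):
    """Expanding statistic over records 1..t-1 of the same user."""
    exp = df.groupby(uid, sort=False)[col].expanding()
    s = getattr(exp, agg)(**kw).reset_index(level=0, drop=True)
    return s.groupby(df[uid.name] if hasattr(uid, "name") else uid).shift(1)


def _prior_count_of_firsts(df, uid, flag):
    """Count of first-occurrence flags among strictly prior records."""
    csum = flag.astype(float).groupby(uid).cumsum()
    return csum.groupby(uid).shift(1)


def assemble_feature_matrix(table: pd.DataFrame,
                            spec: FeatureSpec | None = None,
                            state_context: pd.DataFrame | None = None,
                            zip_context: pd.DataFrame | None = None,
                            holidays=None,
                            sports_events: pd.DataFrame | None = None
                            ) -> pd.DataFrame:
    """Build the per-record feature matrix and binary high-BrAC label.

    ``table`` is a cleaned, (user_id, time)-sorted event table as produced
    by :func:`breathprint.ingest.clean_events`.  Returns one row per record
    with user_id, ts_utc, all features in ``spec`` order (sentinel-filled),
    and ``label_high``.
    """
    spec = spec or FeatureSpec()
    df = table.copy()
    if "ts_parsed" not in df.columns:
        df["ts_parsed"] = pd.to_datetime(df["ts_utc"], utc=True).dt.tz_localize(None)
    if "ts_local" not in df.columns:
        df = localize_timestamps(df)
    uid = df["user_id"]
    n = len(df)
    feats = pd.DataFrame(index=df.index)

    if n == 0:
        out = pd.DataFrame(columns=["user_id", "ts_utc", *spec.features,
                                    "label_high"])
        return out

    # --- prior-BrAC distribution statistics ---
    feats["prior_mean"] = _shifted_expanding(df, "brac", uid, "mean")
    feats["prior_min"] = _shifted_expanding(df, "brac", uid, "min")
    feats["prior_max"] = _shifted_expanding(df, "brac", uid, "max")
    feats["prior_median"] = _shifted_expanding(df, "brac", uid, "quantile",
                                               q=0.5)
    feats["prior_q1"] = _shifted_expanding(df, "brac", uid, "quantile", q=0.25)
    feats["prior_q3"] = _shifted_expanding(df, "brac", uid, "quantile", q=0.75)
    feats["prior_range"] = feats["prior_max"] - feats["prior_min"]
    feats["prior_iqr"] = feats["prior_q3"] - feats["prior_q1"]

    # --- lags ---
    g = df.groupby("user_id", sort=False)
    for k in (1, 2, 3):
        feats[f"brac_lag{k}"] = g["brac"].shift(k)

    # --- discrimination history ---
    disc = compute_discrimination(df["brac_estimate"], df["brac"])
    df["_disc"] = disc
    feats["disc_lag1"] = g["_disc"].shift(1)
    feats["disc_prior_mean"] = _shifted_expanding(df, "_disc", uid, "mean")

    # --- engagement ---
    first_ts = g["ts_parsed"].transform("first")
    dur = (df["ts_parsed"] - first_ts).dt.total_seconds() / 86400.0
    nprior = g.cumcount()
    feats["duration_days"] = dur.where(nprior > 0)
    feats["n_prior_recordings"] = nprior.astype(float).where(nprior > 0, np.nan)
    local_date = df["ts_local"].dt.date.where(
        df["ts_local"].notna(), df["ts_parsed"].dt.date)
    df["_date"] = local_date
    new_day = ~df.duplicated(["user_id", "_date"])
    feats["n_prior_active_days"] = _prior_count_of_firsts(df, uid, new_day)
    ep = segment_episodes(df)
    feats["n_prior_episodes"] = ep["episode"].groupby(uid).shift(1).astype(float)
    for name, col in (("n_prior_photos", "has_photo"),
                      ("n_prior_drink_counts", "drink_count"),
                      ("n_prior_notes", "note")):
        if col == "note":
            present = df[col].fillna("").astype(str) != ""
        elif col == "drink_count":
            present = df[col].notna()
        else:
            present = df[col].fillna(0).astype(float) > 0
        feats[name] = _prior_count_of_firsts(df, uid, present)

    # --- temporal ---
    feats["minutes_since_last"] = (g["ts_parsed"].diff()
                                   .dt.total_seconds() / 60.0)
    has_local = df["ts_local"].notna()
    feats["hour_of_day"] = df["ts_local"].dt.hour.where(has_local)
    feats["day_of_week"] = df["ts_local"].dt.dayofweek.where(has_local)
    feats["is_weekend"] = feats["day_of_week"].isin([5, 6]).astype(float).where(has_local)
    years = range(df["ts_parsed"].dt.year.min(), df["ts_parsed"].dt.year.max() + 1)
    hol = holidays if holidays is not None else us_holidays(years)
    feats["is_holiday"] = pd.Series(local_date, index=df.index).isin(hol).astype(
        float).where(has_local)
    sp = sports_events if sports_events is not None else SPORTS_EVENTS
    for ev in ("superbowl", "world_series", "nba_final"):
        dates = set(sp.loc[sp["event"] == ev, "date"])
        feats[f"is_{ev}"] = pd.Series(local_date, index=df.index).isin(
            dates).astype(float).where(has_local)
    win = dict(zip(sp["date"], sp["winner_state"]))
    lose = dict(zip(sp["date"], sp["loser_state"]))
    state = df["state"].fillna("").astype(str)
    ld = pd.Series(local_date, index=df.index)
    feats["sports_winner_state"] = (
        (ld.map(win).fillna("##") == state) & (state != "")).astype(float)
    feats["sports_loser_state"] = (
        (ld.map(lose).fillna("##") == state) & (state != "")).astype(float)

    # --- estimate & flags ---
    feats["brac_estimate"] = df["brac_estimate"]
    feats["verified"] = df["verified"].astype(float)

    # --- geospatial ---
    has_geo = df["lat"].notna() & df["lon"].notna()
    lat_g = df["lat"].where(has_geo)
    lon_g = df["lon"].where(has_geo)
    prev_lat = lat_g.groupby(uid).shift(1).groupby(uid).ffill()
    prev_lon = lon_g.groupby(uid).shift(1).groupby(uid).ffill()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = haversine_km(prev_lat, prev_lon, lat_g, lon_g)
    df["_pairdist"] = np.where(has_geo & prev_lat.notna(), d, np.nan)
    feats["dist_prev_km"] = df["_pairdist"]
    feats["dist_mean"] = _shifted_expanding(df, "_pairdist", uid, "mean")
    feats["dist_min"] = _shifted_expanding(df, "_pairdist", uid, "min")
    feats["dist_max"] = _shifted_expanding(df, "_pairdist", uid, "max")
    feats["dist_median"] = _shifted_expanding(df, "_pairdist", uid, "quantile",
                                              q=0.5)
    feats["dist_q1"] = _shifted_expanding(df, "_pairdist", uid, "quantile",
                                          q=0.25)
    feats["dist_q3"] = _shifted_expanding(df, "_pairdist", uid, "quantile",
                                          q=0.75)
    feats["dist_iqr"] = feats["dist_q3"] - feats["dist_q1"]
    qsum = feats["dist_q3"] + feats["dist_q1"]
    feats["dist_dispersion"] = (feats["dist_iqr"] / qsum).where(qsum > 0)
    feats["elevation_m"] = df["elevation_m"].where(has_geo)
    for name, col in (("n_prior_zips", "zip"), ("n_prior_states", "state"),
                      ("n_prior_countries", "country")):
        valid = df[col].fillna("").astype(str) != ""
        new = (~df.duplicated(["user_id", col])) & valid
        feats[name] = _prior_count_of_firsts(df, uid, new)

    # --- free-text notes ---
    nf = _notes.note_feature_frame(df["note"])
    for c in nf.columns:
        feats[c] = nf[c].astype(float)

    # --- context joins ---
    ctx_cols = [f for f in spec.features if spec.families.get(f) == "context"]
    if ctx_cols:
        ctx = merge_context_tables(df[["state", "zip"]], state_context,
                                   zip_context)
        for c in ctx_cols:
            if c in ctx.columns:
                feats[c] = pd.to_numeric(ctx[c], errors="coerce")
            else:
                raise ConfigurationError(f"context table provides no column {c!r}")

    unknown = [f for f in spec.features if f not in feats.columns]
    if unknown:
        raise ConfigurationError(f"unknown feature name(s) in spec: {unknown}")

    out = pd.DataFrame({
        "user_id": df["user_id"],
        "ts_utc": df["ts_parsed"],
    }, index=df.index)
    for f in spec.features:
        out[f] = feats[f].astype(float).fillna(spec.sentinel)
    out["label_high"] = label_high_brac(df["brac"].values)
    return out.reset_index(drop=True)


def select_features_by_correlation(matrix: pd.DataFrame, spec: FeatureSpec,
                                   threshold: float = 0.9,
                                   target_size: int | None = None
                                   ) -> FeatureSpec:
    """Greedy correlation pruning of the candidate roster.

    Repeatedly finds the most correlated remaining pair with |Pearson r|
    above ``threshold`` and drops the later (lower a-priori priority)
    member; optionally continues down the correlation ranking until
    ``target_size`` features remain.  Constant columns are dropped with a
    warning (their correlation is undefined).
    """
    cols = [f for f in spec.features if f in matrix.columns]
    X = matrix[cols].replace(spec.sentinel, np.nan)
    const = [c for c in cols if X[c].nunique(dropna=True) <= 1]
    if const:
        warnings.warn(f"dropping constant column(s): {const}")
        cols = [c for c in cols if c not in const]
        X = X[cols]
    corr = X.corr().abs()
    keep = list(cols)
    order = {c: i for i, c in enumerate(spec.features)}

    def worst_pair(names):
        best = (0.0, None, None)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = corr.loc[a, b]
                if pd.notna(r) and r > best[0]:
                    best = (float(r), a, b)
        return best

    while len(keep) > 1:
        r, a, b = worst_pair(keep)
        if a is None:
            break
        over = r > threshold
        need_more = target_size is not None and len(keep) > target_size
        if not over and not need_more:
            break
        drop = b if order[a] <= order[b] else a
        keep.remove(drop)
        if target_size is not None and len(keep) <= target_size and not over:
            break
    return spec.only(keep)


class PhenotypeFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer building the digital-phenotype matrix.

    Stateless in the statistical sense (all features are within-row or
    within-user-history functions), so ``fit`` only validates inputs and
    records the output schema.  ``transform`` accepts a cleaned event table
    and returns the feature matrix with label column.
    """

    def __init__(self, spec: FeatureSpec | None = None,
                 state_context: pd.DataFrame | None = None,
                 zip_context: pd.DataFrame | None = None,
                 holidays=None, sports_events: pd.DataFrame | None = None):
        self.spec = spec
        self.state_context = state_context
        self.zip_context = zip_context
        self.holidays = holidays
        self.sports_events = sports_events

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cleaned event-table DataFrame")
        if "user_id" not in X.columns or "brac" not in X.columns:
            raise ValueError("event table must contain user_id and brac")
        spec = self.spec or FeatureSpec()
        self.spec_ = spec
        self.feature_names_out_ = list(spec.features)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "spec_"):
            self.fit(X)
        return assemble_feature_matrix(
            X, self.spec_, state_context=self.state_context,
            zip_context=self.zip_context, holidays=self.holidays,
            sports_events=self.sports_events)
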