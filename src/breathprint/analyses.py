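"""Secondary statistical analyses of cleaned event tables.

Covers the discrimination learning curve over early self-monitoring
episodes (linear mixed model with a random intercept per user), the
user-level regression of BrAC discrimination on mean BrAC, per-state BrAC
aggregation with a sqrt-user adjustment, the robust ecological regression
of impaired-driving death rates on state mean BrAC, and the hour-by-day
intoxication grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .features import compute_discrimination, segment_episodes

__all__ = ["DiscriminationTrend", "discrimination_by_episode",
           "discrimination_vs_mean_brac", "state_brac_aggregate",
           "ecological_regression", "hour_day_heatmap"]


class InsufficientDataError(ValueError):
    pass


def _discrimination_rows(table: pd.DataFrame, require_local: bool = True
                         ) -> pd.DataFrame:
    """Rows eligible for discrimination analyses.

    Keeps rows with an estimate present and verified; drops rows where both
    the measured and estimated BrAC are zero (likely device demos); when
    ``require_local``, also requires a known local timestamp.
    """
    df = table.copy()
    keep = df["brac_estimate"].notna()
    keep &= df["verified"].fillna(0).astype(float) == 1
    keep &= ~((df["brac"] == 0) & (df["brac_estimate"] == 0))
    if require_local and "ts_local" in df.columns:
        keep &= df["ts_local"].notna()
    df = df[keep].copy()
    df["disc"] = compute_discrimination(df["brac_estimate"], df["brac"])
    return df


def _trim_central(df: pd.DataFrame, col: str, lower: float = 2.5,
                  upper: float = 97.5, bounds: tuple | None = None
                  ) -> pd.DataFrame:
    """Keep the closed central band of the pooled distribution of ``col``.

    The band is a property of the distribution it was computed on; pass
    ``bounds`` to re-apply an existing band (a no-op on already-trimmed
    data).
    """
    lo, hi = (np.percentile(df[col], [lower, upper]) if bounds is None
              else bounds)
    return df[(df[col] >= lo) & (df[col] <= hi)]


@dataclass
class DiscriminationTrend:
    slope: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    per_episode: pd.DataFrame     # episode, mean |disc|, ci_low, ci_high, n
    n_users: int
    n_records: int


def discrimination_by_episode(table: pd.DataFrame,
                              episodes: pd.DataFrame | None = None,
                              max_episode: int = 5) -> DiscriminationTrend:
    """Does estimation accuracy improve over early self-monitoring episodes?

    Trims discrimination to its central 95%, restricts to episodes
    1..``max_episode``, averages |discrimination| within user-episode, and
    fits mean|disc| ~ episode with a random intercept per user (REML).
    A negative slope means estimates approach the measured values.
    """
    ep = episodes if episodes is not None else segment_episodes(table)
    df = table.copy()
    df["episode"] = ep["episode"]
    df = _discrimination_rows(df)
    if df.empty or df["episode"].max() < 2:
        raise InsufficientDataError("need at least 2 self-monitoring episodes")
    df = _trim_central(df, "disc")
    df = df[df["episode"] <= max_episode]
    agg = (df.assign(abs_disc=df["disc"].abs())
             .groupby(["user_id", "episode"], as_index=False)["abs_disc"].mean())
    if agg["episode"].nunique() < 2:
        raise InsufficientDataError("need at least 2 episodes after trimming")
    if np.ptp(agg["abs_disc"].values) == 0:
        # perfectly constant discrimination: the trend is exactly flat and
        # the mixed model is degenerate
        per_ep = (agg.groupby("episode")["abs_disc"]
                  .agg(["mean", "count"]).reset_index())
        per_ep["ci_low"] = per_ep["mean"]
        per_ep["ci_high"] = per_ep["mean"]
        per_ep = per_ep.rename(columns={"mean": "mean_abs_disc", "count": "n"})
        return DiscriminationTrend(
            slope=0.0, ci_low=0.0, ci_high=0.0, z=np.nan, p_value=1.0,
            per_episode=per_ep[["episode", "mean_abs_disc", "ci_low",
                                "ci_high", "n"]],
            n_users=agg["user_id"].nunique(), n_records=len(df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("abs_disc ~ episode", agg, groups=agg["user_id"])
        fit = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = md.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:  # pragma: no cover - pathological design
            raise InsufficientDataError(
                "mixed model failed to converge on this table")
    slope = float(fit.params["episode"])
    se = float(fit.bse["episode"])
    per_ep = (agg.groupby("episode")["abs_disc"]
              .agg(["mean", "sem", "count"]).reset_index())
    per_ep["ci_low"] = per_ep["mean"] - 1.96 * per_ep["sem"]
    per_ep["ci_high"] = per_ep["mean"] + 1.96 * per_ep["sem"]
    per_ep = per_ep.rename(columns={"mean": "mean_abs_disc", "count": "n"})
    return DiscriminationTrend(
        slope=slope, ci_low=slope - 1.96 * se, ci_high=slope + 1.96 * se,
        z=slope / se if se > 0 else np.nan,
        p_value=float(fit.pvalues["episode"]),
        per_episode=per_ep[["episode", "mean_abs_disc", "ci_low", "ci_high", "n"]],
        n_users=agg["user_id"].nunique(), n_records=len(df))


def discrimination_vs_mean_brac(table: pd.DataFrame,
                                episodes: pd.DataFrame | None = None) -> dict:
    """User-level regression of mean discrimination on mean BrAC.

    Heavier-drinking users underestimate more: the coefficient is the
    change in mean discrimination (g/dL) per g/dL of within-user mean BrAC.
    Returns coefficient, SE, 95% CI, and adjusted R^2.
    """
    df = _discrimination_rows(table)
    g = df.groupby("user_id").agg(mean_disc=("disc", "mean"),
                                  mean_brac=("brac", "mean"),
                                  n=("disc", "size"))
    if len(g) < 3:
        raise InsufficientDataError("need at least 3 users with estimates")
    X = sm.add_constant(g["mean_brac"])
    fit = sm.OLS(g["mean_disc"], X).fit()
    coef = float(fit.params["mean_brac"])
    se = float(fit.bse["mean_brac"])
    return {"coef": coef, "se": se,
            "ci_low": coef - 1.96 * se, "ci_high": coef + 1.96 * se,
            "t": float(fit.tvalues["mean_brac"]),
            "p_value": float(fit.pvalues["mean_brac"]),
            "adj_r2": float(fit.rsquared_adj), "n_users": int(len(g))}


def state_brac_aggregate(table: pd.DataFrame,
                         death_rates: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Per-state mean BrAC with user/record counts and sqrt-user adjustment.

    States with no state-tagged rows are absent from the output.  If
    ``death_rates`` (columns state, impaired_driving_death_rate) is given it
    is joined for the ecological regression.
    """
    df = table.copy()
    df["state"] = df["state"].fillna("").astype(str)
    df = df[df["state"] != ""]
    if df.empty:
        raise InsufficientDataError("no state-tagged rows")
    agg = (df.groupby("state")
             .agg(mean_brac=("brac", "mean"), n_records=("brac", "size"),
                  n_users=("user_id", "nunique"))
             .reset_index())
    agg["sqrt_users"] = np.sqrt(agg["n_users"])
    if death_rates is not None:
        agg = agg.merge(
            death_rates[["state", "impaired_driving_death_rate"]],
            on="state", how="left")
    return agg


def ecological_regression(agg: pd.DataFrame,
                          rate_col: str = "impaired_driving_death_rate") -> dict:
    """Robust (Huber) regression of state death rates on state mean BrAC.

    Adjusts for the square root of the state's user count as a covariate.
    Returns the BrAC coefficient with normal-approximation CI, z and p.
    """
    df = agg.dropna(subset=["mean_brac", rate_col])
    if len(df) < 10:
        raise InsufficientDataError(
            f"need >= 10 states with mean BrAC and {rate_col}")
    X = sm.add_constant(df[["mean_brac", "sqrt_users"]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design in ecological regression")
    fit = sm.RLM(df[rate_col], X, M=sm.robust.norms.HuberT()).fit()
    coef = float(fit.params["mean_brac"])
    se = float(fit.bse["mean_brac"])
    return {"coef": coef, "se": se,
            "ci_low": coef - 1.96 * se, "ci_high": coef + 1.96 * se,
            "z": coef / se if se > 0 else np.nan,
            "p_value": float(fit.pvalues["mean_brac"]),
            "n_states": int(len(df))}


def hour_day_heatmap(table: pd.DataFrame) -> dict:
    """7x24 grids of mean BrAC (verified rows only) and reading counts.

    Hours/days use local time; rows with unknown time zone are excluded.
    Cells with no observations hold NaN in the mean grid and 0 in the count
    grid.
    """
    df = table[table["ts_local"].notna()].copy()
    df["dow"] = pd.DatetimeIndex(df["ts_local"]).dayofweek
    df["hour"] = pd.DatetimeIndex(df["ts_local"]).hour
    counts = np.zeros((7, 24))
    for (d, h), n in df.groupby(["dow", "hour"]).size().items():
        counts[d, h] = n
    ver = df[df["verified"].fillna(0).astype(float) == 1]
    mean_grid = np.full((7, 24), np.nan)
    n_grid = np.zeros((7, 24))
    for (d, h), grp in ver.groupby(["dow", "hour"]):
        mean_grid[d, h] = grp["brac"].mean()
        n_grid[d, h] = len(grp)
    return {"mean_brac": mean_grid, "n_verified": n_grid, "n_all": counts}
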