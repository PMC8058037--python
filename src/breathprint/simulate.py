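"""Synthetic smart-breathalyzer cohort generator.

Emulates the statistical structure the downstream analysis assumes: heavy-
tailed per-user engagement, a right-skewed BrAC marginal censored at
0 g/dL, habit structure (user-level means, weekend-midnight hour effects,
habitual locations, short-range autocorrelation), biased subjective BrAC
estimates whose accuracy improves over early self-monitoring episodes,
field-level missingness, and raw-log dirt (duplicates, missing ids,
physically impossible readings, unparseable timestamps) for the cleaning
stage to remove.

A single ``high_signal_strength`` knob in [0, 1] scales *every* channel
through which a reading's level is predictable — the user-habit spread, the
hour-of-week and location effects, the reading-to-reading autocorrelation,
and the estimate's within-user tracking — so that at 0 the labels are
exchangeable noise and a classifier can do no better than chance, while the
marginal BrAC distribution is held fixed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .config import EVENT_COLUMNS, SENTINEL, SimulationConfig  # noqa: F401
from .context import (FOREIGN_REGIONS, STATE_CENTROIDS, STATE_TIMEZONES,
                      US_STATES)

__all__ = ["UserProfile", "generate_cohort", "apply_estimate_bias",
           "apply_missingness", "write_cohort_csv"]

# Censoring-compensation constants, frozen from one-off calibration runs of
# this generator (see docs/methods.md, "Calibration").  Estimates are clipped
# at 0 g/dL, which would otherwise attenuate/shift the realized
# discrimination statistics away from their configured targets.
_SLOPE_CENSOR_ADJ = 0.13        # added to estimate_bias_slope pre-clip
_INTERCEPT_CENSOR_ADJ = -0.0237    # added to the bias intercept pre-clip
_EPISODE_SHIFT_PER_UNIT = -2.43  # pre-clip additive shift per unit of episode_improvement
_M0_ADJ = 0.0014                  # latent-mean correction for clip/skew mismatch
_RATE_MU_CAL = 0.15             # log-shift on the per-day-rate distribution
_RATE_SIGMA_CAL = 1.22          # log-scale inflation on the per-day-rate distribution

_NOTE_BANK = [
    "2 glasses of wine", "a bottle of beer", "feeling fine", "whiskey tumbler",
    "3 shots of vodka", "wine with dinner", "one beer", "testing the device",
    "tall glass of cider", "2 beers and a burger",
]


@dataclass
class UserProfile:
    """Latent per-user generative state."""

    user_id: str
    habit_mean_brac: float              # latent user mean BrAC deviation + base, g/dL
    habit_locations: list               # [(lat, lon), ...]
    location_weights: np.ndarray        # sums to 1
    location_effects: np.ndarray        # g/dL offsets per habit location
    home_state: str                     # "" for non-US users
    country: str
    tz_name: str
    diurnal_profile: np.ndarray         # 7x24 nonnegative propensity grid
    estimate_bias_intercept: float      # g/dL

    def __post_init__(self):
        assert self.habit_mean_brac >= 0
        w = np.asarray(self.location_weights, float)
        assert np.isclose(w.sum(), 1.0)
        assert (np.asarray(self.diurnal_profile) >= 0).all()


# ---------------------------------------------------------------------------
# propensity / effect grids

def diurnal_propensity() -> np.ndarray:
    """7x24 propensity for *when* readings are taken (Mon=0 .. Sun=6).

    Evenings dominate, with an extra late-night boost on weekend nights.
    """
    g = np.full((7, 24), 0.2)
    g[:, 17:24] = 1.0                       # evenings
    g[:, 12:17] = 0.45                      # afternoons
    for d in (4, 5):                        # Fri, Sat late evening
        g[d, 21:24] = 2.2
    for d in (5, 6):                        # small hours of Sat, Sun
        g[d, 0:3] = 1.8
    return g


def hour_effect_grid(amplitude: float) -> np.ndarray:
    """7x24 additive BrAC effect (g/dL), peaking midnight-2am on weekends."""
    g = np.zeros((7, 24))
    g[:, 19:24] = 0.45
    g[:, 12:19] = 0.15
    for d in (4, 5):                        # Fri, Sat 22-23
        g[d, 22:24] = 0.80
    for d in (5, 6):                        # Sat, Sun 00-02
        g[d, 0:2] = 1.0
        g[d, 2] = 0.80
    return amplitude * g


def _effect_moments(prop: np.ndarray, eff: np.ndarray) -> tuple[float, float]:
    """Mean and variance of the hour effect under the visit propensity."""
    w = prop / prop.sum()
    m = float((w * eff).sum())
    v = float((w * (eff - m) ** 2).sum())
    return m, v


def _solve_clipped_normal(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) of a normal whose max(0, .) has the target moments."""

    def eqs(p):
        m, s = p
        s = abs(s)
        a = m / s
        mean = m * stats.norm.cdf(a) + s * stats.norm.pdf(a)
        e2 = (m * m + s * s) * stats.norm.cdf(a) + m * s * stats.norm.pdf(a)
        var = e2 - mean * mean
        return [mean - target_mean, np.sqrt(max(var, 1e-12)) - target_sd]

    (m, s), info, ok, _ = optimize.fsolve(eqs, [target_mean * 0.6, target_sd * 1.4],
                                          full_output=True)
    if ok != 1:
        raise RuntimeError("clipped-normal calibration failed to converge")
    return float(m), float(abs(s))


# ---------------------------------------------------------------------------
# profiles

def make_profiles(config: SimulationConfig, rng: np.random.Generator
                  ) -> list[UserProfile]:
    s = config.high_signal_strength
    n = config.n_users
    prop = diurnal_propensity()
    # Right-skewed, zero-mean user habit deviations; scaled by signal strength.
    k = config.habit_shape
    dev = (rng.gamma(k, 1.0, n) - k) / np.sqrt(k) * config.habit_sd
    us = rng.random(n) < config.us_user_fraction
    state_idx = rng.integers(0, len(US_STATES), n)
    foreign_idx = rng.integers(0, len(FOREIGN_REGIONS), n)
    b_u = rng.normal(0.0, config.estimate_bias_intercept_sd, n)
    profiles = []
    for i in range(n):
        if us[i]:
            st = US_STATES[state_idx[i]]
            base = STATE_CENTROIDS[st]
            tz, country = STATE_TIMEZONES[st], "US"
        else:
            _, lat, lon, tz = FOREIGN_REGIONS[foreign_idx[i]]
            country = FOREIGN_REGIONS[foreign_idx[i]][0]
            st, base = "", (lat, lon)
        home = (base[0] + rng.normal(0, 0.5), base[1] + rng.normal(0, 0.5))
        locs = [home]
        for _ in range(config.n_habit_locations - 1):
            locs.append((home[0] + rng.normal(0, 0.3), home[1] + rng.normal(0, 0.3)))
        raw_w = np.array([0.55] + [0.45 / max(1, config.n_habit_locations - 1)]
                         * (config.n_habit_locations - 1))
        eff = np.zeros(config.n_habit_locations)
        if config.n_habit_locations > 1:
            eff[1] = config.location_effect * s   # the "venue" location
        profiles.append(UserProfile(
            user_id=f"u{i:05d}",
            habit_mean_brac=max(0.0, config.brac_mean + s * dev[i]),
            habit_locations=locs,
            location_weights=raw_w / raw_w.sum(),
            location_effects=eff,
            home_state=st,
            country=country,
            tz_name=tz,
            diurnal_profile=prop,
            estimate_bias_intercept=b_u[i],
        ))
    return profiles


# ---------------------------------------------------------------------------
# core simulation

def _episode_index_from_ts(ts: np.ndarray) -> np.ndarray:
    """1-based episode index within one user's sorted UTC timestamps (>=12 h gap)."""
    if len(ts) == 0:
        return np.zeros(0, int)
    gaps = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    return 1 + np.concatenate([[0], np.cumsum(gaps >= 12.0)]).astype(int)


def _simulate_user_times(config, rng, tz_name: str, n_rec: int):
    """Sample local reading datetimes honouring the engagement targets."""
    # Per-day-rate distribution: 1 + lognormal matching the configured
    # mean/sd, with frozen calibration offsets compensating the compression
    # introduced by integer rounding and the n_days <= n_rec constraint.
    m_ln = config.active_day_rate_mean - 1.0
    s_ln = config.active_day_rate_sd
    sig2 = np.log1p((s_ln / m_ln) ** 2)
    mu_r = np.log(m_ln) - sig2 / 2.0 + _RATE_MU_CAL
    rate = 1.0 + rng.lognormal(mu_r, np.sqrt(sig2) * _RATE_SIGMA_CAL)
    n_days = int(np.clip(round(n_rec / rate), 1, n_rec))
    duration = rng.lognormal(np.log(config.duration_median_days),
                             config.duration_log_sigma)
    cal_start = np.datetime64(config.calendar_start)
    cal_end = np.datetime64(config.calendar_end)
    span = int((cal_end - cal_start) / np.timedelta64(1, "D"))
    duration = int(np.clip(round(duration), n_days, span))
    start = cal_start + np.timedelta64(int(rng.integers(0, span - duration + 1)), "D")
    # weekday-weighted choice of active dates
    offs = np.arange(duration)
    dows = ((start - np.datetime64("1970-01-05")) / np.timedelta64(1, "D")
            + offs).astype(int) % 7          # Mon=0
    w = np.array([0.8, 0.8, 0.9, 1.0, 1.4, 1.6, 1.2])[dows]
    days = np.sort(rng.choice(offs, size=n_days, replace=False, p=w / w.sum()))
    # per-day counts: at least one, remainder multinomial
    extra = rng.multinomial(n_rec - n_days, np.full(n_days, 1.0 / n_days))
    counts = 1 + extra
    prop = diurnal_propensity()
    dates, naive = [], []
    for d, c in zip(days, counts):
        date = start + np.timedelta64(int(d), "D")
        dow = int(((date - np.datetime64("1970-01-05")) / np.timedelta64(1, "D"))) % 7
        p = prop[dow] / prop[dow].sum()
        h0 = rng.choice(24, p=p)
        t0 = float(h0) * 60 + rng.uniform(0, 60)
        tt = t0 + np.concatenate([[0.0], np.cumsum(rng.uniform(10, 120, c - 1))])
        naive.append(date.astype("datetime64[m]") + tt.astype("timedelta64[m]"))
        dates.append(np.full(c, d))
    naive = np.concatenate(naive)
    day_idx = np.concatenate(dates)
    local = pd.Series(naive.astype("datetime64[s]"))
    loc_aware = (pd.DatetimeIndex(local)
                 .tz_localize(tz_name, nonexistent="shift_forward", ambiguous=True))
    utc = loc_aware.tz_convert("UTC").tz_localize(None)
    order = np.argsort(utc.values, kind="stable")
    return utc.values[order], local.values[order], day_idx[order]


def _simulate_core(config: SimulationConfig, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, list[UserProfile]]:
    """Clean-cohort readings (numeric frame) before missingness and dirt."""
    config.validate()
    s = config.high_signal_strength
    profiles = make_profiles(config, rng)

    prop = diurnal_propensity()
    heff = hour_effect_grid(config.hour_effect_amplitude)
    eh, vh = _effect_moments(prop, heff)
    # location effect moments under the default weights
    w0 = np.array([0.55] + [0.45 / max(1, config.n_habit_locations - 1)]
                  * (config.n_habit_locations - 1))
    w0 = w0 / w0.sum()
    le = np.zeros(config.n_habit_locations)
    if config.n_habit_locations > 1:
        le[1] = config.location_effect
    el = float((w0 * le).sum())
    vl = float((w0 * (le - el) ** 2).sum())

    m_z, s_z = _solve_clipped_normal(config.brac_mean, config.brac_sd)
    struct_var = (s * config.habit_sd) ** 2 + s * s * (vh + vl)
    if struct_var >= s_z ** 2:
        raise ValueError("structural variance exceeds target marginal variance; "
                         "reduce effect amplitudes or habit_sd")
    sigma_w = float(np.sqrt(s_z ** 2 - struct_var))
    m0 = m_z - s * (eh + el) + _M0_ADJ
    rho = config.ar_coefficient * s

    n_rec_all = np.clip(np.round(rng.lognormal(np.log(config.recordings_median),
                                               config.recordings_log_sigma,
                                               config.n_users)),
                        1, config.recordings_cap).astype(int)
    if config.engagement_brac_correlation != 0.0:
        # Gaussian-copula reorder: pair engagement ranks with habit ranks.
        r = config.engagement_brac_correlation
        z1 = stats.norm.ppf((np.argsort(np.argsort(n_rec_all)) + 0.5) / config.n_users)
        z2 = r * z1 + np.sqrt(1 - r * r) * rng.normal(size=config.n_users)
        habit = np.array([p.habit_mean_brac for p in profiles])
        reassign = np.argsort(np.argsort(z2))
        sorted_habit = np.sort(habit)
        for i, p in enumerate(profiles):
            p.habit_mean_brac = float(sorted_habit[reassign[i]])

    frames = []
    for i, p in enumerate(profiles):
        n_rec = int(n_rec_all[i])
        ts_utc, ts_local, day_idx = _simulate_user_times(config, rng, p.tz_name, n_rec)
        loc_dow = pd.DatetimeIndex(ts_local).dayofweek.values
        loc_hour = pd.DatetimeIndex(ts_local).hour.values
        # per-active-day habitual location
        uniq_days, inv = np.unique(day_idx, return_inverse=True)
        day_loc = rng.choice(len(p.habit_locations), size=len(uniq_days),
                             p=p.location_weights)
        loc_idx = day_loc[inv]
        lats = np.array([p.habit_locations[j][0] for j in loc_idx])
        lons = np.array([p.habit_locations[j][1] for j in loc_idx])
        lats = lats + rng.normal(0, 5e-4, n_rec)
        lons = lons + rng.normal(0, 5e-4, n_rec)
        loc_eff = p.location_effects[loc_idx]

        eta = rng.normal(0, sigma_w * np.sqrt(max(1e-12, 1 - rho * rho)), n_rec)
        e = signal.lfilter([1.0], [1.0, -rho], eta) if rho > 0 else eta
        z = (m0 + (p.habit_mean_brac - config.brac_mean)
             + heff[loc_dow, loc_hour] * s + loc_eff + e)
        brac = np.clip(np.round(z, 3), 0.0, 0.50)

        frames.append(pd.DataFrame({
            "user_id": p.user_id,
            "ts_utc": ts_utc,
            "ts_local": ts_local,
            "tz_name": p.tz_name,
            "brac": brac,
            "lat": lats,
            "lon": lons,
            "state": p.home_state,
            "country": p.country,
            "zip": [_zip_for(p, j) for j in loc_idx],
            "elevation_m": _elevation_for_state(p) + rng.normal(0, 20, n_rec),
        }))
    if not frames:
        core = pd.DataFrame(columns=["user_id", "ts_utc", "ts_local", "tz_name",
                                     "brac", "lat", "lon", "state", "country",
                                     "zip", "elevation_m"])
        return core, profiles
    core = pd.concat(frames, ignore_index=True)
    core.sort_values(["user_id", "ts_utc"], inplace=True, kind="stable")
    core.reset_index(drop=True, inplace=True)

    # subjective estimates with planted bias and early-episode improvement
    est = np.full(len(core), np.nan)
    for uid, grp in core.groupby("user_id", sort=False):
        p = profiles[int(uid[1:])]
        ep = _episode_index_from_ts(grp["ts_utc"].values)
        est[grp.index.values] = apply_estimate_bias(
            grp["brac"].values, p, config, rng=rng, episode_index=ep)
    core["brac_estimate"] = est
    return core, profiles


def _zip_for(p: UserProfile, loc_idx: int) -> str:
    if p.country != "US":
        return ""
    h = int.from_bytes(f"zip:{p.user_id}:{loc_idx}".encode(), "little")
    return f"{US_STATES.index(p.home_state):02d}{h % 1000:03d}"


def _elevation_for_state(p: UserProfile) -> float:
    h = int.from_bytes(f"elev:{p.home_state or p.country}".encode(), "little")
    return float(h % 1600)


# ---------------------------------------------------------------------------
# public operations

def apply_estimate_bias(measured: np.ndarray, profile: UserProfile,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        episode_index: np.ndarray | None = None) -> np.ndarray:
    """Subjective BrAC estimates for one user's measured series.

    estimate = measured + intercept + slope * (user mean BrAC) + noise,
    with the deviation of measured from the user mean tracked only partially
    (``estimate_tracking``, scaled by signal strength), an additive
    early-episode improvement, censoring at 0 g/dL, and rounding to the app
    slider granularity.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    measured = np.asarray(measured, float)
    if len(measured) == 0:
        return measured.copy()
    if not ((measured >= 0) & (measured <= 0.50)).all():
        raise ValueError("measured BrAC outside [0, 0.50]")
    m_bar = float(measured.mean())
    lam = config.estimate_tracking * config.high_signal_strength
    slope = config.estimate_bias_slope
    b0 = config.mean_discrimination - slope * config.brac_mean
    ep_shift_scale = -1.0
    if config.censor_compensation:
        slope = slope + _SLOPE_CENSOR_ADJ * (slope / -0.772)
        b0 = b0 + _INTERCEPT_CENSOR_ADJ
        ep_shift_scale = _EPISODE_SHIFT_PER_UNIT
    dev = (b0 + profile.estimate_bias_intercept + slope * m_bar
           - (1.0 - lam) * (measured - m_bar)
           + rng.normal(0, config.estimate_noise_sd, len(measured)))
    if episode_index is not None and config.episode_improvement != 0.0:
        shift = (ep_shift_scale * config.episode_improvement
                 * np.minimum(np.asarray(episode_index) - 1, 4))
        dev = dev + shift
    est = np.clip(measured + dev, 0.0, None)
    if config.estimate_rounding > 0:
        est = np.round(est / config.estimate_rounding) * config.estimate_rounding
    return est


def apply_missingness(table: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Blank fields / set flags independently per row at the configured rates.

    Operates on the string-typed event table (empty string = missing); row
    count is unchanged.
    """
    config.missingness_rates.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    r = config.missingness_rates
    out = table.copy()
    n = len(out)
    if n == 0:
        return out
    geo_gone = rng.random(n) < r.geolocation_absent
    for col in ("lat", "lon", "elevation_m", "zip", "state", "country"):
        out.loc[geo_gone, col] = ""
    out.loc[rng.random(n) < r.unverified, "verified"] = "0"
    out.loc[rng.random(n) < r.estimate_absent, "brac_estimate"] = ""
    notes = rng.random(n) < r.note_present
    out.loc[notes, "note"] = rng.choice(_NOTE_BANK, int(notes.sum()))
    out.loc[~notes, "note"] = ""
    drinks = rng.random(n) < r.drink_count_present
    out.loc[drinks, "drink_count"] = rng.choice(
        ["1", "1", "1", "2", "2", "3"], int(drinks.sum()))
    out.loc[~drinks, "drink_count"] = ""
    out["has_photo"] = np.where(rng.random(n) < r.photo_present, "1", "0")
    return out


def _format_core(core: pd.DataFrame) -> pd.DataFrame:
    """Numeric core -> string-typed raw event table (empty string = missing)."""
    n = len(core)
    tbl = pd.DataFrame(index=range(n))
    tbl["user_id"] = core["user_id"].astype(str).values if n else []
    ts = pd.DatetimeIndex(core["ts_utc"]) if n else pd.DatetimeIndex([])
    tbl["ts_utc"] = ts.strftime("%Y-%m-%dT%H:%M:%SZ") if n else []
    tbl["tz_name"] = core["tz_name"].values if n else []
    tbl["brac"] = core["brac"].map("{:.3f}".format).values if n else []
    est = core["brac_estimate"] if n else pd.Series(dtype=float)
    tbl["brac_estimate"] = est.map(
        lambda v: "" if pd.isna(v) else f"{v:.6f}").values if n else []
    tbl["verified"] = "1"
    tbl["user_provided"] = "1"
    tbl["lat"] = core["lat"].map("{:.5f}".format).values if n else []
    tbl["lon"] = core["lon"].map("{:.5f}".format).values if n else []
    tbl["elevation_m"] = core["elevation_m"].map("{:.1f}".format).values if n else []
    tbl["zip"] = core["zip"].values if n else []
    tbl["state"] = core["state"].values if n else []
    tbl["country"] = core["country"].values if n else []
    tbl["note"] = ""
    tbl["drink_count"] = ""
    tbl["has_photo"] = "0"
    return tbl[EVENT_COLUMNS]


def _inject_dirt(tbl: pd.DataFrame, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Append defective rows at the configured rates (extras, not mutations),
    so the cleaned table keeps the engagement targets of the core cohort."""
    d = config.dirt_rates
    n = len(tbl)
    if n == 0:
        return tbl
    extras = []

    def sample(rate):
        k = int(np.round(rate * n))
        return tbl.iloc[rng.integers(0, n, k)].copy() if k else None

    dup = sample(d.duplicate)                      # exact duplicates
    if dup is not None:
        extras.append(dup)
    anon = sample(d.missing_user_id)
    if anon is not None:
        anon["user_id"] = ""
        extras.append(anon)
    nup = sample(d.not_user_provided)
    if nup is not None:
        nup["user_provided"] = "0"
        # shift timestamps a minute so they are not counted as duplicates
        ts = pd.to_datetime(nup["ts_utc"], format="%Y-%m-%dT%H:%M:%SZ")
        nup["ts_utc"] = (ts + pd.Timedelta(minutes=1)).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ")
        extras.append(nup)
    hot = sample(d.brac_over_limit)
    if hot is not None:
        hot["brac"] = [f"{v:.3f}" for v in rng.uniform(0.501, 0.95, len(hot))]
        extras.append(hot)
    bad_ts = sample(d.bad_timestamp)
    if bad_ts is not None:
        bad_ts["ts_utc"] = [f"not-a-timestamp-{i}" for i in range(len(bad_ts))]
        extras.append(bad_ts)
    if not extras:
        return tbl
    out = pd.concat([tbl] + extras, ignore_index=True)
    out.sort_values(["user_id", "ts_utc"], inplace=True, kind="stable")
    return out.reset_index(drop=True)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a raw event-log table (string-typed, CSV-faithful).

    Deterministic under (config, seed); includes injected dirt rows so that
    every cleaning rule is exercised.  Rows are sorted by user id then UTC
    timestamp.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    core, _ = _simulate_core(config, rng)
    tbl = _format_core(core)
    tbl = apply_missingness(tbl, config, rng=rng)
    tbl = _inject_dirt(tbl, config, rng)
    return tbl


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
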