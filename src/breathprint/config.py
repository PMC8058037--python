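"""Configuration objects for the simulator, model, and pipeline.

All stochastic components draw from a single integer seed; identical
configuration + seed reproduces outputs bit-for-bit.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Sentinel used for missing feature values.  Out of the natural range of every
#: engineered feature (BrAC is bounded by 0.50 g/dL, distances and counts are
#: nonnegative), so boosted trees can split on "missingness" itself.
SENTINEL = -999.0

#: Canonical event-log column order (CSV header).
EVENT_COLUMNS = [
    "user_id", "ts_utc", "tz_name", "brac", "brac_estimate", "verified",
    "user_provided", "lat", "lon", "elevation_m", "zip", "state", "country",
    "note", "drink_count", "has_photo",
]


class ConfigurationError(ValueError):
    """Raised when a configuration field is out of its valid range."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"invalid configuration field {name!r}: {msg}")


@dataclass
class MissingnessRates:
    """Per-field missingness / presence probabilities, each in [0, 1].

    ``geolocation_absent`` blanks lat/lon/elevation/zip/state/country together
    (a reading that cannot be geolocated cannot be assigned to a region);
    ``unverified`` clears the verified flag; the remaining rates govern the
    sparse optional fields (estimate, free-text note, drink count, photo).
    """

    geolocation_absent: float = 0.34
    unverified: float = 0.12
    estimate_absent: float = 0.25
    note_present: float = 0.001
    drink_count_present: float = 0.0087
    photo_present: float = 0.0114

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _require(0.0 <= v <= 1.0, f"missingness_rates.{f.name}",
                     f"{v} not in [0, 1]")


@dataclass
class DirtRates:
    """Rates of deliberately injected raw-log defects exercising each cleaning rule."""

    duplicate: float = 0.02
    missing_user_id: float = 0.08
    not_user_provided: float = 0.149
    brac_over_limit: float = 1e-5
    bad_timestamp: float = 0.001

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _require(0.0 <= v <= 1.0, f"dirt_rates.{f.name}", f"{v} not in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic smart-breathalyzer cohort.

    Defaults target the engagement, BrAC-marginal, estimation-bias, diurnal
    and missingness structure of a large naturalistic breathalyzer cohort:
    per-user recording counts log-normal (median 80, IQR 31-207), about 2.69
    recordings per active day, marginal BrAC 0.057 +/- 0.065 g/dL with a
    low:high label ratio near 2.37 at the 0.08 g/dL threshold, mean
    estimate-minus-measured discrimination -0.037 g/dL with a within-user
    slope of discrimination on mean BrAC of -0.772, and weekend late-night
    intoxication peaks.
    """

    n_users: int = 500
    seed: int = 0

    # Engagement: log-normal recording counts and a per-active-day rate.
    recordings_median: float = 80.0
    recordings_log_sigma: float = 1.408     # matches IQR 31-207
    recordings_cap: int = 1500
    active_day_rate_mean: float = 2.69      # recordings per active day
    active_day_rate_sd: float = 2.21
    duration_median_days: float = 106.0
    duration_log_sigma: float = 1.597       # matches IQR 45-388

    # BrAC generative process (see docs/methods.md for the calibration).
    brac_mean: float = 0.057
    brac_sd: float = 0.065
    high_signal_strength: float = 1.0
    habit_shape: float = 2.0                # gamma shape of the user habit spread
    habit_sd: float = 0.042                 # sd of user habit means at signal 1
    hour_effect_amplitude: float = 0.022    # g/dL at the weekend-midnight peak
    location_effect: float = 0.025          # g/dL offset of the "venue" habit location
    ar_coefficient: float = 0.5             # within-episode AR(1) at signal 1
    engagement_brac_correlation: float = 0.0

    # Subjective-estimate model.
    estimate_bias_slope: float = -0.772
    estimate_bias_intercept_sd: float = 0.015
    estimate_tracking: float = 0.15         # within-user tracking of momentary BrAC
    estimate_noise_sd: float = 0.015
    estimate_rounding: float = 0.005        # app slider granularity, g/dL
    episode_improvement: float = -0.002     # change in mean |discrimination| per episode, eps 1-5
    mean_discrimination: float = -0.037     # realized population target, g/dL
    censor_compensation: bool = True        # pre-clip correction for censoring at 0 g/dL

    # Geography.
    n_habit_locations: int = 3
    us_user_fraction: float = 0.8

    missingness_rates: MissingnessRates = field(default_factory=MissingnessRates)
    dirt_rates: DirtRates = field(default_factory=DirtRates)

    calendar_start: str = "2013-05-01"
    calendar_end: str = "2017-06-30"

    def validate(self) -> None:
        _require(self.n_users >= 0, "n_users", "must be >= 0")
        _require(self.recordings_median > 0, "recordings_median", "must be > 0")
        _require(self.recordings_log_sigma >= 0, "recordings_log_sigma", "must be >= 0")
        _require(self.active_day_rate_mean >= 1.0, "active_day_rate_mean", "must be >= 1")
        _require(0.0 <= self.high_signal_strength <= 1.0,
                 "high_signal_strength", "must be in [0, 1]")
        _require(self.brac_mean > 0, "brac_mean", "must be > 0")
        _require(self.brac_sd > 0, "brac_sd", "must be > 0")
        _require(0.0 <= self.estimate_tracking <= 1.0, "estimate_tracking",
                 "must be in [0, 1]")
        _require(self.estimate_noise_sd >= 0, "estimate_noise_sd", "must be >= 0")
        _require(self.n_habit_locations >= 1, "n_habit_locations", "must be >= 1")
        _require(0.0 <= self.us_user_fraction <= 1.0, "us_user_fraction",
                 "must be in [0, 1]")
        _require(-1.0 <= self.engagement_brac_correlation <= 1.0,
                 "engagement_brac_correlation", "must be in [-1, 1]")
        self.missingness_rates.validate()
        self.dirt_rates.validate()
        _require(self.calendar_start < self.calendar_end, "calendar_start",
                 "calendar_start must precede calendar_end")


@dataclass
class ModelConfig:
    """Gradient-boosted classification-tree hyperparameters.

    Defaults are the tuned settings of the study model: learning rate 0.1,
    89 trees with early stopping (patience 5) on validation log-loss, L1/L2
    regularization 0.5, inverse-frequency class balancing, and a 0.5
    decision threshold on the predicted probability.
    """

    learning_rate: float = 0.1
    n_estimators: int = 89
    l1: float = 0.5
    l2: float = 0.5
    early_stopping_rounds: int = 5
    class_balancing: bool = True
    decision_threshold: float = 0.5
    bagging_fraction: float = 1.0
    num_leaves: int = 31
    seed: int = 0

    def validate(self) -> None:
        _require(self.learning_rate > 0, "learning_rate", "must be > 0")
        _require(self.n_estimators > 0, "n_estimators", "must be > 0")
        _require(self.l1 >= 0, "l1", "must be >= 0")
        _require(self.l2 >= 0, "l2", "must be >= 0")
        _require(self.early_stopping_rounds > 0, "early_stopping_rounds", "must be > 0")
        _require(0.0 < self.decision_threshold < 1.0, "decision_threshold",
                 "must be in (0, 1)")
        _require(0.0 < self.bagging_fraction <= 1.0, "bagging_fraction",
                 "must be in (0, 1]")


def _from_mapping(cls, data: Mapping[str, Any]):
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "missingness_rates" and isinstance(v, Mapping):
            v = MissingnessRates(**v)
        elif f.name == "dirt_rates" and isinstance(v, Mapping):
            v = DirtRates(**v)
        kwargs[f.name] = v
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ConfigurationError(
            f"unknown configuration field(s) for {cls.__name__}: {sorted(unknown)}")
    obj = cls(**kwargs)
    obj.validate()
    return obj


def simulation_config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(SimulationConfig, data)


def model_config_from_yaml(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(ModelConfig, data)
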