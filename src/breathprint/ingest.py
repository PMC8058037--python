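"""Raw event-log parsing, cleaning, and timestamp localization.

Cleaning applies, in order: drop not-user-provided rows, drop duplicate
(user_id, ts_utc, brac) triples, drop rows missing a user id, drop rows
whose UTC timestamp cannot be parsed, drop readings above 0.50 g/dL
(physically implausible / device error).  Unverified readings are *kept*
— verification status is downstream model information, not an exclusion.
Every removal is tallied in a :class:`CleaningReport` whose accounting
balances exactly.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .config import EVENT_COLUMNS

__all__ = ["CleaningReport", "SchemaError", "parse_events", "clean_events",
           "localize_timestamps"]

BRAC_MAX = 0.50


class SchemaError(ValueError):
    """Raised when an input table does not match the event-log schema."""


@dataclass
class CleaningReport:
    rows_in: int = 0
    removed_not_user_provided: int = 0
    removed_duplicates: int = 0
    removed_missing_user_id: int = 0
    removed_timestamp_error: int = 0
    removed_brac_over_limit: int = 0
    retained_unverified: int = 0
    rows_out: int = 0

    @property
    def removed_total(self) -> int:
        return (self.removed_not_user_provided + self.removed_duplicates
                + self.removed_missing_user_id + self.removed_timestamp_error
                + self.removed_brac_over_limit)

    def balances(self) -> bool:
        return self.rows_in - self.removed_total == self.rows_out

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def parse_events(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a raw event-log CSV into a typed table.

    Unparseable timestamps are *flagged* (``ts_error`` column), not dropped;
    row order is preserved.  A header that does not match the declared
    schema raises :class:`SchemaError` naming the offending columns.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                          **(dialect or {}))
    except FileNotFoundError:
        raise
    got, want = list(raw.columns), list(EVENT_COLUMNS)
    if got != want:
        missing = sorted(set(want) - set(got))
        extra = sorted(set(got) - set(want))
        raise SchemaError(
            f"event-log header mismatch: missing columns {missing}, "
            f"unexpected columns {extra}")
    return _type_raw(raw)


def _type_raw(raw: pd.DataFrame) -> pd.DataFrame:
    """String table -> typed RawEventTable (adds ts_parsed / ts_error)."""
    df = raw.copy()
    ts = pd.to_datetime(df["ts_utc"], format="%Y-%m-%dT%H:%M:%SZ",
                        errors="coerce", utc=True)
    # second chance for other ISO spellings
    retry = ts.isna() & (df["ts_utc"] != "")
    if retry.any():
        ts2 = pd.to_datetime(df.loc[retry, "ts_utc"], errors="coerce",
                             utc=True, format="ISO8601")
        ts[retry] = ts2
    df["ts_parsed"] = ts.dt.tz_localize(None)
    df["ts_error"] = ts.isna()
    for col in ("brac", "brac_estimate", "lat", "lon", "elevation_m"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == ""), errors="coerce")
    for col in ("verified", "user_provided", "has_photo"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == ""),
                                errors="coerce").astype("Int64")
    df["drink_count"] = pd.to_numeric(df["drink_count"].mask(df["drink_count"] == ""),
                                      errors="coerce").astype("Int64")
    return df


def clean_events(raw: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the exclusion rules in order and tally a conservation report.

    Cleaning never raises on content; defective rows are removed and counted.
    Output is sorted by (user_id, ts_utc); the first occurrence of a
    duplicate key in input order survives.
    """
    if "ts_parsed" not in raw.columns:
        raw = _type_raw(raw)
    report = CleaningReport(rows_in=len(raw))
    df = raw

    keep = df["user_provided"].fillna(0).astype(int) == 1
    report.removed_not_user_provided = int((~keep).sum())
    df = df[keep]

    dup = df.duplicated(subset=["user_id", "ts_utc", "brac"], keep="first")
    report.removed_duplicates = int(dup.sum())
    df = df[~dup]

    keep = df["user_id"].astype(str).str.len() > 0
    report.removed_missing_user_id = int((~keep).sum())
    df = df[keep]

    keep = ~df["ts_error"]
    report.removed_timestamp_error = int((~keep).sum())
    df = df[keep]

    keep = df["brac"].notna() & (df["brac"] >= 0) & (df["brac"] <= BRAC_MAX)
    report.removed_brac_over_limit = int((~keep).sum())
    df = df[keep]

    report.retained_unverified = int((df["verified"].fillna(0) == 0).sum())
    df = df.sort_values(["user_id", "ts_parsed"], kind="stable").reset_index(drop=True)
    report.rows_out = len(df)
    assert report.balances(), "cleaning accounting out of balance"
    return df, report


def localize_timestamps(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``ts_local`` from ``ts_parsed`` and the row's IANA time zone.

    Unknown or missing zone names yield a null ts_local (downstream hour/day
    features fall back to the missingness sentinel); never fatal.
    """
    import warnings
    out = table.copy()
    out["ts_local"] = pd.NaT
    for tz, idx in out.groupby("tz_name").groups.items():
        if not tz:
            continue
        try:
            loc = (pd.DatetimeIndex(out.loc[idx, "ts_parsed"])
                   .tz_localize("UTC").tz_convert(tz).tz_localize(None))
        except Exception:
            warnings.warn(f"unknown time zone {tz!r}; ts_local left null")
            continue
        out.loc[idx, "ts_local"] = loc
    return out
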