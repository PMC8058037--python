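"""State- and zip-level contextual covariates.

The real study merged public tax, poverty, heavy-drinking-prevalence,
urban/rural and impaired-driving-mortality tables into the feature matrix.
Those exact tables are not redistributable here, so this module ships a
*synthetic* state context table with the same schema (and exposes the seeded
generator that produced it), plus a deterministic zip-level context
derivation.  Approximate state centroids and time zones are factual
constants used by the cohort simulator.
"""
from __future__ import annotations

import importlib.resources
from io import StringIO

import numpy as np
import pandas as pd

STATE_CONTEXT_COLUMNS = [
    "state", "alcohol_tax", "sales_tax", "gas_tax", "cigarette_tax",
    "poverty_thousands", "heavy_drinking_pct", "urban_pct",
    "population_thousands", "impaired_driving_death_rate",
]

# (abbrev, approx centroid lat, lon, IANA tz) for the 50 states + DC.
_STATES = [
    ("AL", 32.8, -86.8, "America/Chicago"), ("AK", 64.0, -152.0, "America/Anchorage"),
    ("AZ", 34.3, -111.7, "America/Phoenix"), ("AR", 34.9, -92.4, "America/Chicago"),
    ("CA", 37.2, -119.3, "America/Los_Angeles"), ("CO", 39.0, -105.5, "America/Denver"),
    ("CT", 41.6, -72.7, "America/New_York"), ("DE", 39.0, -75.5, "America/New_York"),
    ("DC", 38.9, -77.0, "America/New_York"), ("FL", 28.6, -82.4, "America/New_York"),
    ("GA", 32.6, -83.4, "America/New_York"), ("HI", 20.3, -156.4, "Pacific/Honolulu"),
    ("ID", 44.4, -114.6, "America/Boise"), ("IL", 40.0, -89.2, "America/Chicago"),
    ("IN", 39.9, -86.3, "America/Indiana/Indianapolis"), ("IA", 42.1, -93.5, "America/Chicago"),
    ("KS", 38.5, -98.4, "America/Chicago"), ("KY", 37.5, -85.3, "America/New_York"),
    ("LA", 31.1, -92.0, "America/Chicago"), ("ME", 45.4, -69.2, "America/New_York"),
    ("MD", 39.0, -76.8, "America/New_York"), ("MA", 42.3, -71.8, "America/New_York"),
    ("MI", 44.3, -85.4, "America/Detroit"), ("MN", 46.3, -94.3, "America/Chicago"),
    ("MS", 32.7, -89.7, "America/Chicago"), ("MO", 38.4, -92.5, "America/Chicago"),
    ("MT", 47.0, -109.6, "America/Denver"), ("NE", 41.5, -99.8, "America/Chicago"),
    ("NV", 39.3, -116.6, "America/Los_Angeles"), ("NH", 43.7, -71.6, "America/New_York"),
    ("NJ", 40.2, -74.7, "America/New_York"), ("NM", 34.4, -106.1, "America/Denver"),
    ("NY", 42.9, -75.5, "America/New_York"), ("NC", 35.5, -79.4, "America/New_York"),
    ("ND", 47.4, -100.5, "America/Chicago"), ("OH", 40.3, -82.8, "America/New_York"),
    ("OK", 35.6, -97.5, "America/Chicago"), ("OR", 43.9, -120.6, "America/Los_Angeles"),
    ("PA", 40.9, -77.8, "America/New_York"), ("RI", 41.7, -71.6, "America/New_York"),
    ("SC", 33.9, -80.9, "America/New_York"), ("SD", 44.4, -100.2, "America/Chicago"),
    ("TN", 35.8, -86.4, "America/Chicago"), ("TX", 31.5, -99.3, "America/Chicago"),
    ("UT", 39.3, -111.7, "America/Denver"), ("VT", 44.1, -72.7, "America/New_York"),
    ("VA", 37.5, -78.9, "America/New_York"), ("WA", 47.4, -120.4, "America/Los_Angeles"),
    ("WV", 38.6, -80.6, "America/New_York"), ("WI", 44.6, -89.7, "America/Chicago"),
    ("WY", 43.0, -107.6, "America/Denver"),
]

US_STATES = [s[0] for s in _STATES]
STATE_CENTROIDS = {s[0]: (s[1], s[2]) for s in _STATES}
STATE_TIMEZONES = {s[0]: s[3] for s in _STATES}

# Non-US countries used by the simulator: (code, city lat, lon, tz).
FOREIGN_REGIONS = [
    ("GB", 51.5, -0.13, "Europe/London"),
    ("CA", 43.7, -79.4, "America/Toronto"),
    ("AU", -33.9, 151.2, "Australia/Sydney"),
    ("DE", 52.5, 13.4, "Europe/Berlin"),
    ("SE", 59.3, 18.1, "Europe/Stockholm"),
]


def make_state_context(seed: int = 12345) -> pd.DataFrame:
    """Generate a synthetic state context table (schema of the public sources).

    Values are drawn from plausible ranges for 2014-era US state statistics;
    they are stand-ins, not the real figures.  The death-rate column is
    generated with a positive dependence on a latent state drinking level so
    that the ecological regression has structure to find.
    """
    rng = np.random.default_rng(seed)
    n = len(US_STATES)
    latent = rng.beta(2, 3, n)  # latent state-level drinking propensity in [0,1]
    df = pd.DataFrame({
        "state": US_STATES,
        "alcohol_tax": np.round(0.2 + 2.3 * rng.random(n), 2),     # $/gallon
        "sales_tax": np.round(8.0 * rng.random(n), 2),              # percent
        "gas_tax": np.round(10 + 40 * rng.random(n), 1),            # cents/gallon
        "cigarette_tax": np.round(0.2 + 4.0 * rng.random(n), 2),    # $/pack
        "poverty_thousands": np.round(50 + 5000 * rng.random(n), 0),
        "heavy_drinking_pct": np.round(4 + 8 * latent + rng.normal(0, 0.5, n), 2),
        "urban_pct": np.round(100 * rng.beta(4, 2, n), 1),
        "population_thousands": np.round(600 + 38000 * rng.beta(1.2, 4, n), 0),
        "impaired_driving_death_rate":
            np.round(1.0 + 8.0 * latent + rng.normal(0, 0.6, n).clip(-0.9, 9), 2),
    })
    return df


def load_state_context() -> pd.DataFrame:
    """Load the shipped synthetic state context fixture."""
    text = (importlib.resources.files("breathprint") / "data" /
            "state_context_synthetic.csv").read_text()
    return pd.read_csv(StringIO(text), dtype={"state": str})


def make_zip_context(zips) -> pd.DataFrame:
    """Deterministic synthetic zip-level context (population, urban/rural %).

    Each 5-digit zip string maps to a fixed population size and urban
    percentage via a hash of its digits, so repeated calls agree without any
    external table.
    """
    uniq = pd.unique(pd.Series(list(zips), dtype=str).dropna())
    uniq = [z for z in uniq if z and z != "nan"]
    rows = []
    for z in uniq:
        h = int.from_bytes(f"zipctx:{z}".encode(), "little") % (2**32)
        rng = np.random.default_rng(h)
        rows.append({
            "zip": z,
            "zip_population": int(1000 + 90000 * rng.beta(1.5, 3)),
            "zip_urban_pct": round(100 * rng.beta(3, 2), 1),
        })
    return pd.DataFrame(rows, columns=["zip", "zip_population", "zip_urban_pct"])
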