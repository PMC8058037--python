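"""Shared fixtures: synthetic cohorts at several scales, cleaned and featurized.

All fixtures are generated programmatically at test time from fixed seeds;
session scope keeps the expensive cohorts to one build each.
"""
import io

import pandas as pd
import pytest

from breathprint.config import SimulationConfig
from breathprint.features import FeatureSpec, assemble_feature_matrix
from breathprint.ingest import clean_events, localize_timestamps, parse_events
from breathprint.simulate import generate_cohort


def cohort_to_clean(cfg: SimulationConfig):
    """simulate -> CSV round-trip -> parse -> clean -> localize."""
    raw = generate_cohort(cfg)
    buf = io.StringIO()
    raw.to_csv(buf, index=False)
    buf.seek(0)
    table, report = clean_events(parse_events(buf))
    return localize_timestamps(table), report


@pytest.fixture(scope="session")
def small_clean():
    """~60-user cohort: fast unit-level checks."""
    table, _ = cohort_to_clean(SimulationConfig(n_users=60, seed=11))
    return table


@pytest.fixture(scope="session")
def small_matrix(small_clean):
    return assemble_feature_matrix(small_clean)


@pytest.fixture(scope="session")
def cohort500_clean():
    """500-user cohort at default study conditions (distributional checks)."""
    table, _ = cohort_to_clean(SimulationConfig(n_users=500, seed=123))
    return table


@pytest.fixture(scope="session")
def cohort500_matrix(cohort500_clean):
    return assemble_feature_matrix(cohort500_clean)


@pytest.fixture(scope="session")
def default_spec():
    return FeatureSpec()
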