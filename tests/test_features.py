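"""Feature engineering: episode rule, prior stats, lags, distances, notes,
context joins, correlation pruning, leakage, and sentinel hygiene."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from breathprint.config import SENTINEL, ConfigurationError
from breathprint.context import make_state_context
from breathprint.features import (FeatureSpec, assemble_feature_matrix,
                                  compute_discrimination, label_high_brac,
                                  lag_features, merge_context_tables,
                                  prior_brac_stats, segment_episodes,
                                  select_features_by_correlation)
from breathprint.geo import assign_geo_clusters, haversine_km


def _user_table(gaps_hours, user="u1", brac=0.05):
    t0 = pd.Timestamp("2015-03-01 12:00:00")
    ts = [t0]
    for g in gaps_hours:
        ts.append(ts[-1] + pd.Timedelta(hours=g))
    return pd.DataFrame({"user_id": user, "ts_parsed": ts,
                         "brac": brac})


class TestEpisodes:
    def test_gap_sequence(self):
        tbl = _user_table([3, 20, 1])
        ep = segment_episodes(tbl)
        assert list(ep["episode"]) == [1, 1, 2, 2]

    def test_singleton(self):
        ep = segment_episodes(_user_table([]))
        assert list(ep["episode"]) == [1]
        assert ep["gap_hours"].isna().all()

    def test_exactly_12h_opens_new_episode(self):
        ep = segment_episodes(_user_table([12.0]))
        assert list(ep["episode"]) == [1, 2]
        ep = segment_episodes(_user_table([11.999]))
        assert list(ep["episode"]) == [1, 1]

    def test_unsorted_input_raises(self):
        tbl = _user_table([3, 20]).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            segment_episodes(tbl)

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(8)
        rows = []
        for u in range(30):
            t = pd.Timestamp("2014-01-01") + pd.Timedelta(
                hours=float(rng.uniform(0, 24)))
            for _ in range(int(rng.integers(1, 40))):
                rows.append({"user_id": f"u{u:02d}", "ts_parsed": t,
                             "brac": 0.05})
                t += pd.Timedelta(hours=float(rng.exponential(9)))
        tbl = pd.DataFrame(rows).sort_values(["user_id", "ts_parsed"],
                                             ignore_index=True)
        got = segment_episodes(tbl)["episode"].to_numpy()
        # brute force: O(n) scan
        expected = []
        prev_user, prev_ts, ep = None, None, 0
        for _, r in tbl.iterrows():
            if r["user_id"] != prev_user:
                ep = 1
            elif (r["ts_parsed"] - prev_ts).total_seconds() >= 12 * 3600:
                ep += 1
            expected.append(ep)
            prev_user, prev_ts = r["user_id"], r["ts_parsed"]
        np.testing.assert_array_equal(got, expected)


class TestPriorStats:
    def test_empty_history_is_sentinel(self):
        assert set(prior_brac_stats([]).values()) == {SENTINEL}

    def test_hand_computed_example(self):
        s = prior_brac_stats([0.02, 0.09, 0.05])
        assert s["prior_mean"] == pytest.approx(0.05333333)
        assert s["prior_min"] == 0.02
        assert s["prior_max"] == 0.09
        assert s["prior_range"] == pytest.approx(0.07)
        assert s["prior_median"] == 0.05
        assert s["prior_q1"] == pytest.approx(0.035)
        assert s["prior_q3"] == pytest.approx(0.07)
        assert s["prior_iqr"] == pytest.approx(0.035)

    def test_constant_history(self):
        s = prior_brac_stats([0.04, 0.04, 0.04])
        assert s["prior_mean"] == s["prior_median"] == 0.04
        assert s["prior_range"] == s["prior_iqr"] == 0.0

    def test_lags(self):
        assert lag_features([0.03]) == {"brac_lag1": 0.03,
                                        "brac_lag2": SENTINEL,
                                        "brac_lag3": SENTINEL}
        got = lag_features([0.01, 0.02, 0.03, 0.04])
        assert (got["brac_lag1"], got["brac_lag2"], got["brac_lag3"]) == \
            (0.04, 0.03, 0.02)
        assert set(lag_features([]).values()) == {SENTINEL}


class TestLabelsAndDiscrimination:
    def test_label_boundary(self):
        assert label_high_brac(0.08) == 1
        assert label_high_brac(0.079) == 0
        assert label_high_brac(0.0) == 0

    def test_label_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            label_high_brac(0.6)

    def test_discrimination_sign_convention(self):
        assert compute_discrimination(0.05, 0.09) == pytest.approx(-0.04)
        assert compute_discrimination(0.07, 0.07) == 0.0
        assert np.isnan(compute_discrimination(np.nan, 0.05))


class TestHaversine:
    def test_one_degree_longitude_at_equator(self):
        d = haversine_km(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(2 * np.pi * 6371.0 / 360.0, abs=1e-6)
        assert d == pytest.approx(111.19, abs=0.01)

    def test_identical_points(self):
        assert haversine_km(51.5, -0.1, 51.5, -0.1) == 0.0

    def test_invalid_coordinates_warn_nan(self):
        with pytest.warns(UserWarning, match="invalid"):
            assert np.isnan(haversine_km(95.0, 0.0, 0.0, 0.0))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(-80, 80), st.floats(-179, 179),
           st.floats(-80, 80), st.floats(-179, 179))
    def test_agrees_with_spherical_law_of_cosines(self, la1, lo1, la2, lo2):
        p1, p2 = np.radians(la1), np.radians(la2)
        dl = np.radians(lo2 - lo1)
        cosc = np.clip(np.sin(p1) * np.sin(p2)
                       + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
        expected = 6371.0 * np.arccos(cosc)
        # the law-of-cosines oracle is itself ill-conditioned below ~1 km
        assume(expected > 1.0)
        assert haversine_km(la1, lo1, la2, lo2) == pytest.approx(
            expected, abs=1e-6)


class TestGeoClusters:
    def test_k1_centroid_is_mean(self):
        tbl = pd.DataFrame({"lat": [0.0, 2.0, 4.0], "lon": [1.0, 1.0, 4.0]})
        labels, centers = assign_geo_clusters(tbl, k=1)
        np.testing.assert_allclose(centers, [[2.0, 2.0]])
        assert labels.notna().all()

    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        a = rng.normal([10, 10], 0.1, (40, 2))
        b = rng.normal([-10, -10], 0.1, (40, 2))
        tbl = pd.DataFrame(np.vstack([a, b]), columns=["lat", "lon"])
        labels, _ = assign_geo_clusters(tbl, k=2)
        assert labels[:40].nunique() == 1 and labels[40:].nunique() == 1
        assert labels[0] != labels[79]

    def test_k_reduced_with_warning(self):
        tbl = pd.DataFrame({"lat": [0.0, 1.0], "lon": [0.0, 1.0]})
        with pytest.warns(UserWarning, match="reducing k"):
            labels, centers = assign_geo_clusters(tbl, k=5)
        assert len(centers) == 2


class TestContextMerge:
    def test_passthrough_and_miss(self):
        ctx = make_state_context(seed=1)
        recs = pd.DataFrame({"state": ["AL", "", "ZZ"], "zip": ["", "", ""]})
        out = merge_context_tables(recs, ctx, zip_context=pd.DataFrame(
            columns=["zip", "zip_population", "zip_urban_pct"]))
        assert out["alcohol_tax"].iloc[0] == ctx.loc[
            ctx["state"] == "AL", "alcohol_tax"].iloc[0]
        assert out["alcohol_tax"].isna().iloc[1]
        assert out["alcohol_tax"].isna().iloc[2]
        assert "impaired_driving_death_rate" not in out.columns

    def test_malformed_context_raises(self):
        with pytest.raises(ConfigurationError, match="state context"):
            merge_context_tables(pd.DataFrame({"state": ["AL"], "zip": [""]}),
                                 pd.DataFrame({"wrong": [1]}))


class TestMatrixAssembly:
    def test_single_record_cold_start(self, default_spec):
        tbl = pd.DataFrame({
            "user_id": ["u1"], "ts_parsed": [pd.Timestamp("2015-01-01")],
            "ts_local": [pd.Timestamp("2014-12-31 19:00:00")],
            "brac": [0.09], "brac_estimate": [np.nan], "verified": [1],
            "lat": [np.nan], "lon": [np.nan], "elevation_m": [np.nan],
            "zip": [""], "state": [""], "country": [""], "note": [""],
            "drink_count": [np.nan], "has_photo": [0], "tz_name": [""],
        })
        fm = assemble_feature_matrix(tbl)
        assert len(fm) == 1
        row = fm.iloc[0]
        for f in ("prior_mean", "brac_lag1", "minutes_since_last",
                  "duration_days", "dist_prev_km", "alcohol_tax"):
            assert row[f] == SENTINEL
        assert row["label_high"] == 1
        assert row["hour_of_day"] == 19

    def test_row_conservation_and_no_nulls(self, small_clean, small_matrix):
        assert len(small_matrix) == len(small_clean)
        assert not small_matrix.isna().any().any()

    def test_matches_per_record_primitives(self, small_clean, small_matrix,
                                           default_spec):
        """The vectorized matrix agrees with a row-by-row brute-force
        recomputation from the primitive definitions."""
        df = small_clean.reset_index(drop=True)
        rng = np.random.default_rng(2)
        for i in rng.choice(len(df), 60, replace=False):
            row = df.iloc[i]
            hist = df[(df["user_id"] == row["user_id"])
                      & (df["ts_parsed"] < row["ts_parsed"])]
            got = small_matrix.iloc[i]
            exp = prior_brac_stats(hist["brac"].to_numpy())
            for k, v in exp.items():
                assert got[k] == pytest.approx(v, abs=1e-9), k
            exp = lag_features(hist["brac"].to_numpy())
            for k, v in exp.items():
                assert got[k] == pytest.approx(v), k
            assert got["n_prior_recordings"] == (
                len(hist) if len(hist) else SENTINEL)
            if len(hist):
                mins = (row["ts_parsed"] - hist["ts_parsed"].iloc[-1]
                        ).total_seconds() / 60.0
                assert got["minutes_since_last"] == pytest.approx(mins)

    def test_leakage_free_under_truncation(self, small_clean, small_matrix):
        """Appending future records never changes an earlier row's features:
        recompute each sampled row on the time-truncated table."""
        df = small_clean.reset_index(drop=True)
        rng = np.random.default_rng(3)
        feature_cols = [c for c in small_matrix.columns
                        if c not in ("user_id", "ts_utc", "label_high")]
        for i in rng.choice(len(df), 25, replace=False):
            row = df.iloc[i]
            trunc = df[(df["user_id"] == row["user_id"])
                       & (df["ts_parsed"] <= row["ts_parsed"])]
            sub = assemble_feature_matrix(trunc)
            j = sub.index[sub["ts_utc"] == row["ts_parsed"]][-1]
            pd.testing.assert_series_equal(
                sub.loc[j, feature_cols],
                small_matrix.loc[i, feature_cols], check_names=False)

    def test_sentinel_hygiene(self, small_clean, small_matrix):
        """-999 appears exactly where an input is genuinely unavailable."""
        df = small_clean.reset_index(drop=True)
        has_tz = df["ts_local"].notna().to_numpy()
        hour = small_matrix["hour_of_day"].to_numpy()
        assert ((hour == SENTINEL) == ~has_tz).all()
        est = small_matrix["brac_estimate"].to_numpy()
        assert ((est == SENTINEL) == df["brac_estimate"].isna().to_numpy()).all()
        # natural features never collide with the sentinel
        assert not (small_matrix["prior_mean"].between(-999.5, -998.5)
                    & (small_matrix["prior_mean"] != SENTINEL)).any()

    def test_unknown_feature_in_spec_raises(self, small_clean):
        spec = FeatureSpec()
        spec.features = spec.features + ["bogus_feature"]
        spec.families["bogus_feature"] = "prior_brac"
        with pytest.raises(ConfigurationError, match="bogus"):
            assemble_feature_matrix(small_clean, spec)


class TestCorrelationPruning:
    def _matrix(self, cols):
        return pd.DataFrame(cols)

    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        m = self._matrix({"a": x, "b": x.copy(), "c": rng.normal(size=300)})
        spec = FeatureSpec(features=["a", "b", "c"],
                           families={"a": "t", "b": "t", "c": "t"})
        out = select_features_by_correlation(m, spec, threshold=0.9)
        assert out.features == ["a", "c"]

    def test_independent_columns_unchanged(self):
        rng = np.random.default_rng(1)
        m = self._matrix({f"f{i}": rng.normal(size=200) for i in range(6)})
        spec = FeatureSpec(features=list(m.columns),
                           families={c: "t" for c in m.columns})
        out = select_features_by_correlation(m, spec, threshold=0.9)
        assert out.features == list(m.columns)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        m = self._matrix({"a": rng.normal(size=100),
                          "k": np.full(100, 3.0)})
        spec = FeatureSpec(features=["a", "k"],
                           families={"a": "t", "k": "t"})
        with pytest.warns(UserWarning, match="constant"):
            out = select_features_by_correlation(m, spec, threshold=0.9)
        assert out.features == ["a"]

    def test_98_to_46_reduction_by_construction(self):
        """A 98-column roster in which 52 columns are near-copies of
        earlier ones reduces to exactly the 46 independent features."""
        rng = np.random.default_rng(3)
        base = {f"g{i:02d}": rng.normal(size=400) for i in range(46)}
        cols = dict(base)
        keys = list(base)
        for j in range(52):
            src = base[keys[j % 46]]
            cols[f"dup{j:02d}"] = src + rng.normal(0, 0.01, 400)
        m = self._matrix(cols)
        spec = FeatureSpec(features=list(cols),
                           families={c: "t" for c in cols})
        out = select_features_by_correlation(m, spec, threshold=0.9)
        assert len(out.features) == 46
        assert out.features == keys
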