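"""Feature-engineering tests: medians, PDC, pruning, FCS, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskclust import features
from riskclust.errors import InputError, PipelineError
from riskclust.features import (
    MISSINGNESS_FEATURE,
    aggregate_medians,
    compute_pdc,
    correlation_prune,
    impute_fcs,
    low_variance_filter,
    missingness_count,
    pdc_features,
    standardize,
    weighted_adherence,
)
from riskclust.synthgen import FillHistory, RepeatedMeasureSeries


class TestAggregateMedians:
    def test_singleton_and_odd_length(self):
        series = [
            RepeatedMeasureSeries("p1", "albumin", ((0, 5.0),)),
            RepeatedMeasureSeries("p2", "albumin", ((0, 1.0), (10, 9.0), (20, 3.0))),
        ]
        wide = aggregate_medians(series)
        assert wide.loc["p1", "albumin"] == 5.0
        assert wide.loc["p2", "albumin"] == 3.0

    def test_even_length_midpoint(self):
        series = [RepeatedMeasureSeries("p", "glucose", ((0, 1.0), (1, 2.0)))]
        assert aggregate_medians(series).loc["p", "glucose"] == 1.5

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_matches_sort_and_pick_oracle(self, values):
        frame = pd.DataFrame(
            {
                "patient_id": "p",
                "variable": "v",
                "day": range(len(values)),
                "value": values,
            }
        )
        got = aggregate_medians(frame).loc["p", "v"]
        s = sorted(values)
        n = len(s)
        expect = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert got == pytest.approx(expect)

    def test_absent_patient_gets_missing_after_reindex(self):
        frame = pd.DataFrame(
            {"patient_id": ["p1"], "variable": ["v"], "day": [0], "value": [1.0]}
        )
        wide = aggregate_medians(frame).reindex(["p1", "p2"])
        assert np.isnan(wide.loc["p2", "v"])


class TestPdc:
    def test_full_window_fill(self):
        h = FillHistory("p", "statin", ((0, 365),), (0, 364))
        assert compute_pdc(h) == 1.0

    def test_overlapping_fills_do_not_double_count(self):
        # fills (0, 30) and (20, 30) cover days 0-49 of a 100-day window
        h = FillHistory("p", "statin", ((0, 30), (20, 30)), (0, 99))
        assert compute_pdc(h) == pytest.approx(0.50)

    def test_zero_length_window_rejected(self):
        with pytest.raises(Exception):
            FillHistory("p", "statin", ((0, 10),), (5, 4))

    def test_prescribed_but_unfilled_gets_zero_not_missing(self):
        cohort = pd.DataFrame(
            {"antihypertensive_use": [1.0, 0.0], "statin_use": [0.0, 0.0],
             "glucose_lowering_use": [0.0, 0.0]},
            index=pd.Index(["p1", "p2"], name="patient_id"),
        )
        fills = pd.DataFrame(
            columns=["patient_id", "medication_class", "start_day", "days_supplied"]
        )
        out = pdc_features(fills, cohort)
        assert out.loc["p1", "adherence_antihypertensive"] == 0.0
        assert out.loc["p1", "adherence_weighted"] == 0.0
        # p2 prescribed nothing -> missing, not zero
        assert np.isnan(out.loc["p2", "adherence_weighted"])

    def test_weighted_adherence_days_of_therapy_weights(self):
        pdcs = {"a": 1.0, "b": 0.0}
        assert weighted_adherence(pdcs, {"a": 300, "b": 100}) == pytest.approx(0.75)
        assert weighted_adherence(pdcs) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(-30, 400), st.integers(1, 120)),
            min_size=1,
            max_size=12,
        )
    )
    def test_random_fills_match_boolean_mask_oracle(self, fills):
        fills = [(s, d) for s, d in fills if s + d > 0 and s <= 364]
        if not fills:
            return
        h = FillHistory("p", "statin", tuple(fills), (0, 364))
        days = np.zeros(365, dtype=bool)
        for s, d in fills:
            days[max(s, 0) : min(s + d, 365)] = True
        assert compute_pdc(h) == pytest.approx(days.mean())


class TestLowVarianceFilter:
    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        kept, dropped = low_variance_filter(df)
        assert list(kept.columns) == ["b"]
        assert dropped[0][0] == "a"

    def test_all_above_threshold_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        kept, dropped = low_variance_filter(df)
        assert list(kept.columns) == list("abcde") and not dropped

    def test_rare_binary_dropped_at_default_cutoff(self):
        col = np.zeros(1000)
        col[:5] = 1  # prevalence 0.5% -> p(1-p) < 0.0099
        df = pd.DataFrame({"rare": col, "ok": np.arange(1000, dtype=float)})
        kept, dropped = low_variance_filter(df)
        assert [d[0] for d in dropped] == ["rare"]

    def test_matches_direct_variance_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 10)) * rng.uniform(0.01, 2, 10))
        df.columns = [f"c{i}" for i in range(10)]
        kept, dropped = low_variance_filter(df, min_variance=0.5)
        expect = [c for c in df.columns if np.var(df[c]) >= 0.5]
        assert list(kept.columns) == expect

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(PipelineError):
            low_variance_filter(df)


class TestCorrelationPrune:
    def test_duplicate_column_keeps_exactly_one(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"x": x, "x_copy": x, "y": rng.normal(size=40)})
        kept, removed = correlation_prune(df)
        assert len(kept.columns) == 2 and "y" in kept.columns
        assert len(removed) == 1 and abs(removed[0][2]) == pytest.approx(1.0)

    def test_uncorrelated_columns_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 6)))
        df.columns = [f"c{i}" for i in range(6)]
        kept, removed = correlation_prune(df)
        assert list(kept.columns) == list(df.columns) and not removed

    def test_planted_near_duplicates_postcondition(self, rng):
        base = rng.normal(size=(30, 6))
        df = pd.DataFrame(base, columns=[f"c{i}" for i in range(6)])
        df["d0"] = df["c0"] + rng.normal(0, 0.05, 30)
        df["d1"] = df["c1"] + rng.normal(0, 0.05, 30)
        kept, removed = correlation_prune(df, r_max=0.80)
        corr = kept.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.80
        dropped = {d for d, _, _ in removed}
        assert dropped <= {"c0", "d0", "c1", "d1"}

    def test_idempotent(self, rng):
        base = rng.normal(size=(60, 5))
        df = pd.DataFrame(base, columns=[f"c{i}" for i in range(5)])
        df["dup"] = df["c0"] * 1.01 + rng.normal(0, 0.01, 60)
        once, _ = correlation_prune(df)
        twice, removed = correlation_prune(once)
        assert list(twice.columns) == list(once.columns) and not removed

    def test_fewer_than_two_columns_identity(self):
        df = pd.DataFrame({"only": [1.0, 2.0, 3.0]})
        kept, removed = correlation_prune(df)
        assert list(kept.columns) == ["only"] and not removed


class TestMissingnessCount:
    def test_complete_row_zero(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]})
        assert missingness_count(df).iloc[0] == 0

    def test_saturated_row(self):
        df = pd.DataFrame({f"c{i}": [np.nan] for i in range(119)})
        assert missingness_count(df).iloc[0] == 119

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**30))
    def test_random_mask_matches_cell_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(20, 8))
        mask = rng.random((20, 8)) < 0.3
        values[mask] = np.nan
        df = pd.DataFrame(values, columns=[f"c{i}" for i in range(8)])
        got = missingness_count(df)
        assert (got.to_numpy() == mask.sum(axis=1)).all()

    def test_invariant_to_column_order(self, rng):
        values = rng.normal(size=(15, 6))
        values[rng.random((15, 6)) < 0.4] = np.nan
        df = pd.DataFrame(values, columns=list("abcdef"))
        shuffled = df[list("fedcba")]
        assert (missingness_count(df) == missingness_count(shuffled)).all()


class TestImputeFcs:
    KINDS = {"x": "continuous", "y": "continuous", "b": "binary"}

    def test_complete_matrix_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        out = impute_fcs(df, self.KINDS, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_observed_cells_bit_exact(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 2)), columns=["x", "y"])
        df.loc[df.index[:10], "x"] = np.nan
        out = impute_fcs(df, self.KINDS, seed=1)
        observed = df.notna().to_numpy()
        assert (out.to_numpy()[observed] == df.to_numpy()[observed]).all()
        assert not out.isna().any().any()

    def test_binary_columns_stay_binary(self, rng):
        df = pd.DataFrame(
            {
                "x": rng.normal(size=80),
                "b": (rng.random(80) < 0.4).astype(float),
            }
        )
        df.loc[df.index[:15], "b"] = np.nan
        out = impute_fcs(df, self.KINDS, seed=2)
        assert set(out["b"].unique()) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["x", "y"])
        df.loc[df.index[:8], "y"] = np.nan
        a = impute_fcs(df, self.KINDS, seed=3)
        b = impute_fcs(df, self.KINDS, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_fully_missing_column_named_in_error(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        with pytest.raises(InputError, match="y"):
            impute_fcs(df, self.KINDS, seed=0)

    def test_beats_mean_imputation_on_correlated_data(self):
        # bivariate normal rho=0.9, 10% MCAR on one margin: regression-based
        # imputation should recover held-out truth better than column means
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.normal(size=n)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
            df = pd.DataFrame({"x": x, "y": y})
            mask = rng.random(n) < 0.10
            masked = df.copy()
            masked.loc[mask, "y"] = np.nan
            out = impute_fcs(masked, {"x": "continuous", "y": "continuous"}, seed=seed)
            rmse_fcs = np.sqrt(np.mean((out.loc[mask, "y"] - df.loc[mask, "y"]) ** 2))
            rmse_mean = np.sqrt(
                np.mean((masked["y"].mean() - df.loc[mask, "y"]) ** 2)
            )
            wins += rmse_fcs < rmse_mean
        assert wins >= 19


class TestStandardize:
    def test_closed_form_column(self):
        df = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
        z, _ = standardize(df)
        np.testing.assert_allclose(
            z["a"].to_numpy(), [-1.22474487, 0.0, 1.22474487]
        )

    def test_fit_once_apply_many_contract(self, rng):
        df = pd.DataFrame(rng.normal(5, 2, size=(40, 3)), columns=list("abc"))
        z, tf = standardize(df)
        # re-applying the stored transform to the fitting set reproduces z;
        # re-fitting on z is a different (no-op) transform
        pd.testing.assert_frame_equal(tf.apply(df), z)
        z2, _ = standardize(z)
        assert not np.allclose(tf.apply(z).to_numpy(), z2.to_numpy() * 0 + z.to_numpy())

    def test_post_transform_moments(self, rng):
        df = pd.DataFrame(rng.normal(3, 4, size=(200, 6)))
        df.columns = [f"c{i}" for i in range(6)]
        z, _ = standardize(df)
        assert np.abs(z.mean().to_numpy()).max() < 1e-8
        assert np.abs(np.std(z.to_numpy(), axis=0) - 1).max() < 1e-8

    def test_zero_sd_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(PipelineError):
            standardize(df)


class TestBuildFeatures:
    def test_pipeline_output_complete_and_standardized(self, small_features):
        z = small_features.values
        assert not z.isna().any().any()
        assert np.abs(z.mean().to_numpy()).max() < 1e-8
        assert np.abs(np.std(z.to_numpy(), axis=0) - 1).max() < 1e-8

    def test_missingness_feature_appended(self, small_features):
        assert MISSINGNESS_FEATURE in small_features.values.columns

    def test_provenance_records_fixed_order(self, small_features):
        steps = [p["step"] for p in small_features.provenance]
        core = [s for s in steps if s in (
            "assemble", "low_variance_filter", "correlation_prune",
            "missingness_count", "impute_fcs", "standardize")]
        assert core == [
            "assemble", "low_variance_filter", "correlation_prune",
            "missingness_count", "impute_fcs", "standardize",
        ]

    def test_pruning_report_arithmetic(self, small_features):
        rep = small_features.report
        assert rep.n_original - len(rep.removed_low_variance) - len(
            rep.removed_correlated
        ) == rep.n_retained
        for _, _, r in rep.removed_correlated:
            assert abs(r) > 0.80

    def test_correlated_physiology_pruned(self):
        # on a cohort without signature shifts, the planted physiological
        # correlations exceed the 0.80 cutoff and exactly one of each pair
        # survives pruning
        from riskclust import synthgen
        from riskclust.synthgen import OutcomeModel, PlantedStructure, Signature, SubgroupSpec

        st = PlantedStructure(
            (SubgroupSpec("g", 400, (Signature("age", "sociodemographic", 0.0),),
                          OutcomeModel(0.1, 2.0, 1.0)),),
            0.0, 0,
        )
        table = synthgen.generate_cohort(st, 400, seed=21)
        measures = synthgen.generate_repeated_measures(table, seed=22)
        fills = synthgen.generate_fill_histories(table, seed=23)
        fm = features.build_features(table.data, table.dictionary, measures, fills, seed=24)
        cols = set(fm.values.columns)
        assert not {"hemoglobin", "hematocrit"} <= cols
        assert not {"creatinine", "egfr"} <= cols

    def test_write_features(self, small_features, tmp_path):
        paths = features.write_features(small_features, tmp_path)
        assert paths["matrix"].exists() and paths["report"].exists()
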