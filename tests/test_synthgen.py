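"""Generator tests: planted structure is realized exactly as configured."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskclust import synthgen
from riskclust.catalog import catalog_by_name
from riskclust.errors import ConfigurationError
from riskclust.synthgen import (
    BACKGROUND_LABEL,
    OutcomeModel,
    PlantedStructure,
    Signature,
    SubgroupSpec,
    generate_cohort,
    generate_fill_histories,
    inject_missingness,
)


def _structure(sizes, effects=None, bg=0.0, seed=0, **kwargs):
    """Small helper structure: one continuous signature per subgroup."""
    by_name = catalog_by_name()
    cont = [f.name for f in by_name.values() if f.kind == "continuous" and not f.derived]
    subs = []
    for k, size in enumerate(sizes):
        eff = (effects or {}).get(k, 3.0)
        feat = cont[k]
        subs.append(
            SubgroupSpec(
                name=f"g{k}",
                size=size,
                signature=(Signature(feat, by_name[feat].domain, eff),),
                outcomes=OutcomeModel(0.1 + 0.05 * k, 2.0 + k, 1.0),
            )
        )
    return PlantedStructure(tuple(subs), bg, seed, **kwargs)


class TestGenerateCohort:
    def test_degenerate_single_subgroup_labels_everyone(self):
        st = _structure([200])
        table = generate_cohort(st, 200, seed=1)
        assert (table.data["true_label"] == 0).all()

    def test_label_bookkeeping_matches_sizes(self, small_cohort):
        counts = small_cohort.data["true_label"].value_counts()
        for k, size in enumerate(small_cohort.structure.subgroup_sizes):
            assert counts[k] == size
        n_bg = small_cohort.n - sum(small_cohort.structure.subgroup_sizes)
        assert counts[BACKGROUND_LABEL] == n_bg

    def test_effect_realization_within_three_standard_errors(self):
        # planted continuous effect d=3.0 at size 500, checked against the
        # generative parameters via in-group vs out-group means
        st = _structure([500, 500, 500, 500, 500], bg=0.0, seed=7,
                        signature_sd=1.0)
        table = generate_cohort(st, 2500, seed=7)
        lab = table.data["true_label"].to_numpy()
        for k, g in enumerate(st.subgroups):
            feat = g.signature[0].feature
            vals = table.data[feat].to_numpy()
            inside, outside = vals[lab == k], vals[lab != k]
            diff = inside.mean() - outside.mean()
            se = np.sqrt(inside.var() / inside.size + outside.var() / outside.size)
            assert abs(diff - 3.0) < 3 * se

    def test_outcome_linkage_binomial(self):
        st = _structure([600, 600], bg=0.0, seed=3)
        table = generate_cohort(st, 1200, seed=3)
        for k, g in enumerate(st.subgroups):
            died = table.data.loc[table.data["true_label"] == k, "died_2y"]
            lo, hi = stats.binom.interval(0.999, died.size, g.outcomes.mortality_2y)
            assert lo <= died.sum() <= hi

    def test_determinism_byte_identical(self, small_structure):
        a = generate_cohort(small_structure, 800, seed=55)
        b = generate_cohort(small_structure, 800, seed=55)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_risk_percentile_at_or_above_threshold(self, small_cohort):
        assert (small_cohort.data["risk_percentile"] >= 75).all()
        assert small_cohort.data["risk_percentile"].max() <= 99

    def test_sizes_exceeding_total_rejected(self):
        st = _structure([300, 300])
        with pytest.raises(ConfigurationError):
            generate_cohort(st, 500, seed=0)

    def test_unknown_signature_feature_rejected(self):
        sig = (Signature("not_a_feature", "labs", 2.0),)
        st = PlantedStructure(
            (SubgroupSpec("g", 50, sig, OutcomeModel(0.1, 2, 1)),), 0.0, 0
        )
        with pytest.raises(ConfigurationError):
            generate_cohort(st, 50, seed=0)

    def test_outcome_counts_nonnegative_integers(self, small_cohort):
        for col in ("inpatient_days_2y", "ed_visits_2y"):
            vals = small_cohort.data[col]
            assert (vals >= 0).all()
            assert (vals == vals.astype(int)).all()


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, small_structure):
        table = generate_cohort(small_structure, 800, seed=9)
        out = inject_missingness(table, {"labs": 0.0}, "MCAR", seed=1)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_mcar_fraction_in_binomial_interval(self, small_structure):
        table = generate_cohort(small_structure, 800, seed=9)
        out = inject_missingness(table, {"labs": 0.2}, "MCAR", seed=2)
        lab_cols = [f.name for f in table.dictionary if f.domain == "labs"]
        n_cells = len(lab_cols) * table.n
        n_missing = int(out.data[lab_cols].isna().sum().sum())
        lo, hi = stats.binom.interval(0.99, n_cells, 0.2)
        assert lo <= n_missing <= hi

    def test_rate_one_saturates_domain(self, small_structure):
        table = generate_cohort(small_structure, 800, seed=9)
        out = inject_missingness(table, {"labs": 1.0}, "MCAR", seed=3)
        lab_cols = [f.name for f in table.dictionary if f.domain == "labs"]
        assert out.data[lab_cols].isna().all().all()

    def test_mar_is_monotone_in_conditioning_variable(self, small_structure):
        table = generate_cohort(small_structure, 800, seed=9)
        out = inject_missingness(
            table, {"labs": 0.3}, "MAR_on_utilization", seed=4,
            conditioning="n_primary_care_visits",
        )
        lab_cols = [f.name for f in table.dictionary if f.domain == "labs"]
        n_miss = out.data[lab_cols].isna().sum(axis=1)
        cond = table.data["n_primary_care_visits"]
        lo = n_miss[cond <= cond.median()].mean()
        hi = n_miss[cond > cond.median()].mean()
        assert lo > hi  # fewer visits -> more gaps

    def test_pre_mask_truth_retained(self, small_structure):
        table = generate_cohort(small_structure, 800, seed=9)
        out = inject_missingness(table, {"labs": 0.5}, "MCAR", seed=5)
        assert out.pre_mask is not None
        lab_cols = [f.name for f in table.dictionary if f.domain == "labs"]
        pd.testing.assert_frame_equal(
            out.pre_mask[lab_cols], table.data[lab_cols]
        )

    def test_invalid_rate_rejected(self, small_structure):
        table = generate_cohort(small_structure, 800, seed=9)
        with pytest.raises(ConfigurationError):
            inject_missingness(table, {"labs": 1.2}, "MCAR", seed=0)


def _oracle_pdc(fills: pd.DataFrame, window=(0, 364)) -> float:
    """Independent day-by-day boolean-mask PDC oracle."""
    lo, hi = window
    days = np.zeros(hi - lo + 1, dtype=bool)
    for _, row in fills.iterrows():
        start = int(row["start_day"])
        supply = int(row["days_supplied"])
        a = max(start, lo) - lo
        b = min(start + supply - 1, hi) - lo
        if b >= a:
            days[a : b + 1] = True
    return days.mean()


class TestFillHistories:
    def test_target_one_tiles_window(self):
        table = generate_cohort(_structure([100]), 100, seed=2)
        fills = generate_fill_histories(table, adherence_targets=1.0, seed=3)
        for pid, group in fills.groupby("patient_id"):
            for cls, g in group.groupby("medication_class"):
                assert _oracle_pdc(g) == 1.0

    def test_target_zero_emits_nothing(self):
        table = generate_cohort(_structure([100]), 100, seed=2)
        fills = generate_fill_histories(table, adherence_targets=0.0, seed=3)
        assert len(fills) == 0

    def test_target_half_mean_pdc_near_half(self):
        # 200 prescribed patients, 365-day window, day-by-day oracle
        st = _structure([200], bg=0.0, seed=4)
        table = generate_cohort(st, 200, seed=4)
        table.data["antihypertensive_use"] = 1.0
        fills = generate_fill_histories(
            table, classes=["antihypertensive"], adherence_targets=0.5, seed=5
        )
        pdcs = [
            _oracle_pdc(g)
            for _, g in fills.groupby("patient_id")
        ]
        # patients with zero fills contribute PDC 0
        n_without = table.n - len(pdcs)
        mean_pdc = (np.sum(pdcs) + 0.0 * n_without) / table.n
        assert 0.45 <= mean_pdc <= 0.55

    def test_gaps_and_overlaps_both_occur(self):
        table = generate_cohort(_structure([300]), 300, seed=6)
        fills = generate_fill_histories(table, adherence_targets=0.7, seed=7)
        gaps = overlaps = 0
        for (_, _), g in fills.groupby(["patient_id", "medication_class"]):
            g = g.sort_values("start_day")
            ends = (g["start_day"] + g["days_supplied"]).to_numpy()[:-1]
            starts = g["start_day"].to_numpy()[1:]
            gaps += int((starts > ends).sum())
            overlaps += int((starts < ends).sum())
        assert gaps > 0 and overlaps > 0

    def test_empty_class_list_rejected(self):
        table = generate_cohort(_structure([50]), 50, seed=2)
        with pytest.raises(ConfigurationError):
            generate_fill_histories(table, classes=[], seed=0)

    def test_determinism(self):
        table = generate_cohort(_structure([200]), 200, seed=2)
        a = generate_fill_histories(table, seed=9)
        b = generate_fill_histories(table, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestStructureValidation:
    def test_background_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            _structure([10], bg=1.0)

    def test_demo_structure_sizes_sum(self):
        st = synthgen.demo_structure(3000, 12, 0.25, seed=0)
        assert sum(st.subgroup_sizes) == 2250
        assert st.n_subgroups == 12

    def test_demo_structure_category_mix(self):
        st = synthgen.demo_structure(3000, 12, 0.25, seed=0)
        cats = [g.category for g in st.subgroups]
        assert cats.count("sociodemographic") >= 2
        assert cats.count("psychobehavioral") >= 2

    def test_write_cohort_roundtrip(self, small_inputs, tmp_path):
        cohort, measures, fills = small_inputs
        paths = synthgen.write_cohort(cohort, tmp_path, measures, fills)
        frame = pd.read_csv(paths["cohort"], index_col=0)
        assert len(frame) == cohort.n
        assert "true_label" not in frame.columns  # truth lives in the JSON
        import json

        truth = json.loads(paths["ground_truth"].read_text())
        assert len(truth["true_labels"]) == cohort.n
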