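"""ICD-10 mapping, CCI scoring, prevalence and group-comparison tables."""

import numpy as np
import pandas as pd
import pytest
import yaml
from scipy import stats

from oncoburden import (
    ComorbidityScorer,
    SeverityThresholds,
    compare_groups,
    compute_cci_score,
    default_condition_map,
    default_weight_table,
    map_icd10_to_conditions,
    prevalence_table,
)
from oncoburden.conditions import _data_path


@pytest.fixture(scope="module")
def cmap():
    return default_condition_map()


@pytest.fixture(scope="module")
def weights():
    return default_weight_table()


def raw_weights() -> dict[str, int]:
    """Weights read straight from the shipped YAML, bypassing WeightTable."""
    raw = yaml.safe_load(_data_path("cci_weights.yaml").read_text())
    return {c: int(w) for c, w in raw["weights"].items()}


class TestIcdMapping:
    def test_empty_code_set(self, cmap):
        prof = map_icd10_to_conditions([], cmap)
        assert prof.count == 0
        assert not any(prof.indicators.values())

    def test_hypertension_only(self, cmap):
        prof = map_icd10_to_conditions(["I10"], cmap)
        assert prof.positive == ("hypertension",)

    def test_dot_and_case_insensitive(self, cmap):
        a = map_icd10_to_conditions(["e11.9"], cmap)
        b = map_icd10_to_conditions(["E119"], cmap)
        assert a.indicators == b.indicators
        assert a.positive == ("diabetes",)

    def test_liver_hierarchy_severe_masks_mild(self, cmap):
        prof = map_icd10_to_conditions(["K70.0", "K72.9"], cmap)
        assert prof.indicators["moderate_severe_liver_disease"] == 1
        assert prof.indicators["mild_liver_disease"] == 0
        assert prof.count == 1

    def test_diabetes_hierarchy(self, cmap):
        prof = map_icd10_to_conditions(["E11.9", "E11.2"], cmap)
        assert prof.positive == ("diabetes_with_complications",)

    def test_cancer_codes_never_count(self, cmap):
        prof = map_icd10_to_conditions(["C34.9", "C50", "C91.0"], cmap)
        assert prof.count == 0

    def test_invalid_code_skipped_with_warning(self, cmap, caplog):
        with caplog.at_level("WARNING", logger="oncoburden.scoring"):
            prof = map_icd10_to_conditions(["??", "I10"], cmap,
                                           patient_id="P9")
        assert prof.positive == ("hypertension",)
        assert any("P9" in rec.message for rec in caplog.records)

    def test_no_double_mapping_outside_hierarchies(self, cmap):
        # every single exemplar prefix maps to exactly one condition
        for cond, prefixes in cmap.prefixes.items():
            for p in prefixes:
                assert cmap.match(p) == cond


class TestCciScore:
    def test_zero_profile(self, weights):
        res = compute_cci_score({c: 0 for c in raw_weights()}, weights)
        assert res.cci_score == 0
        assert res.severity == "none"

    def test_diabetes_plus_renal_is_three(self, weights):
        res = compute_cci_score({"diabetes": 1, "renal_disease": 1}, weights)
        assert res.cci_score == 3
        assert res.severity == "moderate"

    def test_missing_weight_is_configuration_error(self):
        from oncoburden.conditions import WeightTable
        wt = WeightTable(weights={"diabetes": 1})
        with pytest.raises(KeyError, match="missing from the weight table"):
            compute_cci_score({"diabetes": 1, "copd": 1}, wt)

    def test_1000_random_profiles_match_bruteforce_sum(self, weights):
        rng = np.random.default_rng(0)
        conds = list(raw_weights())
        w = raw_weights()
        for _ in range(1000):
            profile = {c: int(rng.integers(0, 2)) for c in conds}
            expected = sum(w[c] for c, v in profile.items() if v)
            assert compute_cci_score(profile, weights).cci_score == expected

    def test_score_additivity_over_singletons(self, weights):
        conds = ["diabetes", "renal_disease", "aids", "copd"]
        total = compute_cci_score({c: 1 for c in conds}, weights).cci_score
        parts = sum(compute_cci_score({c: 1}, weights).cci_score
                    for c in conds)
        assert total == parts

    def test_severity_monotone_in_score(self):
        grade = SeverityThresholds()
        order = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
        grades = [order[grade.grade(s)] for s in range(12)]
        assert grades == sorted(grades)
        assert grade.grade(0) == "none"
        assert grade.grade(2) == "mild"
        assert grade.grade(4) == "moderate"
        assert grade.grade(5) == "severe"


class TestScorerTransform:
    def test_union_dx_frame_path(self):
        frame = pd.DataFrame({
            "patient_id": ["A", "B"],
            "cancer_type": ["lung", "breast"],
            "union_dx": ["C34.9;I10;E11.2", ""],
        })
        scored = ComorbidityScorer().fit_transform(frame)
        assert scored.loc[0, "hypertension"] == 1
        assert scored.loc[0, "diabetes_with_complications"] == 1
        assert scored.loc[0, "comorbidity_count"] == 2
        assert scored.loc[0, "cci_score"] == 2
        assert scored.loc[1, "comorbidity_count"] == 0
        assert scored.loc[1, "severity"] == "none"

    def test_indicator_passthrough_enforces_hierarchy(self):
        cmap = default_condition_map()
        frame = pd.DataFrame({"patient_id": ["A"], "cancer_type": ["lung"]})
        for c in cmap.conditions:
            frame[c] = 0
        frame["mild_liver_disease"] = 1
        frame["moderate_severe_liver_disease"] = 1
        scored = ComorbidityScorer().fit_transform(frame)
        assert scored.loc[0, "mild_liver_disease"] == 0
        assert scored.loc[0, "comorbidity_count"] == 1
        assert scored.loc[0, "cci_score"] == 3


def _toy_scored() -> pd.DataFrame:
    """6 patients, 2 cancer types, hand-checkable counts."""
    cmap = default_condition_map()
    rows = []
    plan = [
        ("lung", {"hypertension"}),
        ("lung", {"hypertension", "diabetes"}),
        ("lung", set()),
        ("colon", {"diabetes", "renal_disease", "copd", "aids"}),
        ("colon", set()),
        ("colon", {"hypertension"}),
    ]
    for i, (ct, conds) in enumerate(plan):
        row = {"patient_id": f"T{i}", "cancer_type": ct}
        for c in cmap.conditions:
            row[c] = int(c in conds)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ComorbidityScorer().fit_transform(frame)


class TestPrevalenceTable:
    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty cohort"):
            prevalence_table(_toy_scored().iloc[:0])

    def test_counts_rates_and_conservation(self):
        tables = prevalence_table(_toy_scored())
        cc = tables.condition_counts
        assert cc.loc["hypertension", "total"] == 3
        assert cc.loc["hypertension", "lung_n"] == 2
        assert cc.loc["hypertension", "colon_n"] == 1
        # row percentages: share of the condition's patients per cancer type
        assert cc.loc["hypertension", "lung_row_pct"] == pytest.approx(200 / 3)
        # per-condition type counts sum to the total
        for cond in cc.index:
            assert (cc.loc[cond, "lung_n"] + cc.loc[cond, "colon_n"]
                    == cc.loc[cond, "total"])
        rates = tables.comorbidity_rates
        assert rates.loc["lung", "rate_pct"] == pytest.approx(200 / 3)
        assert rates.loc["overall", "with_comorbidity"] == 4
        assert (rates.loc["overall", "with_comorbidity"]
                + (6 - 4) == rates.loc["overall", "n"])

    def test_count_distribution_and_severity(self):
        tables = prevalence_table(_toy_scored())
        dist = tables.count_distribution
        assert dist.loc["1", "total"] == 2
        assert dist.loc["2", "total"] == 1
        assert dist.loc[">3", "total"] == 1
        sev = tables.severity_distribution
        assert int(sev["total"].sum()) == 6
        # aids (6) + diabetes (1) + renal (2) + copd (1) = 10 -> severe
        assert sev.loc["severe", "total"] == 1

    def test_all_zero_cohort_rates_zero(self):
        scored = _toy_scored()
        cmap = default_condition_map()
        zero = scored.copy()
        zero[list(cmap.conditions)] = 0
        zero["comorbidity_count"] = 0
        zero["cci_score"] = 0
        zero["severity"] = "none"
        tables = prevalence_table(zero)
        assert (tables.comorbidity_rates["rate_pct"] == 0).all()
        assert (tables.condition_counts["total"] == 0).all()


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        frame = _toy_scored()
        frame = pd.concat([frame, frame], ignore_index=True)
        frame["age"] = [60.0, 61.0, 62.0, 63.0, 64.0, 65.0] * 2
        frame.loc[:5, "comorbidity_count"] = 1
        frame.loc[6:, "comorbidity_count"] = 0
        out = compare_groups(frame, grouping="comorbidity",
                             continuous=["age"], categorical=[])
        row = out.iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_balanced_2x2_chi_square_zero(self):
        frame = pd.DataFrame({
            "comorbidity_count": [1] * 200 + [0] * 200,
            "sex": (["male"] * 100 + ["female"] * 100) * 2,
        })
        out = compare_groups(frame, grouping="comorbidity",
                             continuous=[], categorical=["sex"])
        assert out["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        frame = pd.DataFrame({
            "comorbidity_count": [1, 1, 0, 0],
            "age": [60.0, 60.0, 60.0, 60.0],
        })
        out = compare_groups(frame, grouping="comorbidity",
                             continuous=["age"], categorical=[])
        assert "undefined" in out["test"].iloc[0]

    def test_power_at_reported_group_gap(self):
        """With the reported group means/SDs/sizes (64.53 +/- 10.63 vs
        55.67 +/- 12.07, n = 3554 vs 1112) the age difference is detected
        at p < 0.001 in virtually every replicate."""
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(200):
            a = rng.normal(64.53, 10.63, 3554)
            b = rng.normal(55.67, 12.07, 1112)
            _, p = stats.ttest_ind(a, b, equal_var=True)
            hits += p < 0.001
        assert hits >= 198
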