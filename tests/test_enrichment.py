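"""Tests for contingency analysis, risk designation and rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hematrisk as hr
from hematrisk import datasets, enrichment
from hematrisk.errors import ConfigError, DegenerateInputError, ParameterError, SchemaError


def table(rows, index, columns, characteristic=""):
    return hr.ContingencyTable(
        counts=pd.DataFrame(rows, index=index, columns=columns), characteristic=characteristic
    )


class TestBuildContingency:
    def test_synthetic_cohort_reproduces_diagnosis_table(self, cohort):
        tab = hr.build_contingency(cohort.clinical, cohort.true_cluster, "final_diagnosis")
        expected = datasets.load_crosstab("final_diagnosis")
        got = tab.counts.reindex(index=expected.index, columns=expected.columns)
        pd.testing.assert_frame_equal(got, expected, check_names=False)
        assert tab.total == 157
        assert list(got.loc["blue"]) == [16, 1, 6, 6, 0, 26, 2]

    def test_cytology_excludes_insufficient(self, cohort):
        tab = hr.build_contingency(cohort.clinical, cohort.true_cluster, "cytology")
        assert tab.total == 139
        assert tab.excluded == 18

    def test_stage_restricted_to_uc_patients(self, cohort):
        tab = hr.build_contingency(cohort.clinical, cohort.true_cluster, "stage")
        assert tab.total == 80

    def test_empty_cohort(self):
        clinical = pd.DataFrame(
            {"final_diagnosis": pd.Series(dtype=object), "proteinuria": pd.Series(dtype=bool)}
        )
        tab = hr.build_contingency(clinical, pd.Series(dtype=object), "final_diagnosis")
        assert tab.total == 0

    def test_unknown_characteristic(self, cohort):
        with pytest.raises(SchemaError):
            hr.build_contingency(cohort.clinical, cohort.true_cluster, "shoe_size")


class TestMergeIfSparse:
    def test_stage_table_triggers_nmi_mi_merge(self, fixture_tables):
        merged = hr.merge_if_sparse(fixture_tables["stage"])
        assert list(merged.counts.columns) == ["NMI", "MI"]
        assert merged.total == fixture_tables["stage"].total
        assert merged.merge_trace

    def test_dense_table_unchanged(self):
        t = table([[10, 12], [8, 30]], ["a", "b"], ["x", "y"])
        out = hr.merge_if_sparse(t)
        pd.testing.assert_frame_equal(out.counts, t.counts)
        assert out.merge_trace == []

    def test_exact_boundary_not_triggered(self):
        # three of four cells below 5 is 75%, not strictly above 80%
        t = table([[1, 2], [3, 100]], ["a", "b"], ["x", "y"])
        out = hr.merge_if_sparse(t)
        assert list(out.counts.columns) == ["x", "y"]

    def test_final_diagnosis_table_below_threshold(self, fixture_tables):
        # 23/35 cells < 5 (66%) does not exceed the 80% rule
        out = hr.merge_if_sparse(fixture_tables["final_diagnosis"])
        assert list(out.counts.columns) == list(datasets.DIAGNOSIS_CATEGORIES)

    def test_uncovered_merge_map_rejected(self):
        t = table([[1, 1], [1, 1]], ["a", "b"], ["x", "y"])
        with pytest.raises(ConfigError):
            hr.merge_if_sparse(t, merge_map={"x": "g"})

    def test_merge_preserves_total(self, fixture_tables):
        t = fixture_tables["final_diagnosis"]
        merged = hr.merge_if_sparse(t, cell_fraction=0.5)  # force the merge
        assert merged.total == t.total
        assert list(merged.counts.columns) == ["NLT", "LT"]


class TestChiSquare:
    def test_perfect_independence(self):
        res = hr.chi_square(table([[10, 10], [10, 10]], ["a", "b"], ["x", "y"]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_2x2(self):
        # life-threatening x risk group, from the published diagnosis table
        a, b, c, d = 48, 58, 38, 13
        res = hr.chi_square(table([[a, b], [c, d]], ["low", "high"], ["LT", "NLT"]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(closed, abs=1e-10)
        assert res.dof == 1

    def test_transposition_invariance(self):
        rows = [[5, 9, 2], [11, 3, 8]]
        t1 = table(rows, ["a", "b"], ["x", "y", "z"])
        t2 = table(np.transpose(rows), ["x", "y", "z"], ["a", "b"])
        assert hr.chi_square(t1).statistic == pytest.approx(hr.chi_square(t2).statistic)

    def test_yates_correction_reduces_statistic(self):
        t = table([[12, 5], [6, 14]], ["a", "b"], ["x", "y"])
        plain = hr.chi_square(t, continuity_correction=False)
        corrected = hr.chi_square(t, continuity_correction=True)
        assert corrected.statistic < plain.statistic

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateInputError):
            hr.chi_square(table([[0, 5], [0, 7]], ["a", "b"], ["x", "y"]))


class TestRiskDesignation:
    def test_published_partition_recovered(self, fixture_tables):
        des = enrichment.designate_from_table(
            fixture_tables["proteinuria"], "proteinuria", "proteinuria"
        )
        assert sorted(des.low) == ["blue", "green"]
        assert sorted(des.high) == ["gold", "purple", "red"]

    def test_lt_rule_agrees(self, fixture_tables):
        des = enrichment.designate_from_table(
            fixture_tables["final_diagnosis"], list(datasets.LT_CATEGORIES), "lt_fraction"
        )
        assert sorted(des.low) == ["blue", "green"]

    def test_from_patient_level_data(self, cohort):
        des = hr.risk_designation(cohort.clinical, cohort.true_cluster, rule="proteinuria")
        assert sorted(des.low) == ["blue", "green"]

    def test_single_cluster_is_low(self):
        t = table([[10, 5]], ["only"], ["normal", "proteinuria"])
        des = enrichment.designate_from_table(t, "proteinuria", "proteinuria")
        assert des.labels == {"only": "low"}

    def test_uniform_prevalence_all_low(self):
        t = table([[10, 10], [20, 20]], ["a", "b"], ["normal", "proteinuria"])
        des = enrichment.designate_from_table(t, "proteinuria", "proteinuria")
        assert set(des.labels.values()) == {"low"}


class TestRiskPercentages:
    def test_patient_level_matches_published(self, cohort):
        des = hr.risk_designation(cohort.clinical, cohort.true_cluster)
        pct = hr.risk_percentages(cohort.clinical, cohort.true_cluster, des)
        assert pct["life_threatening_low"] == 45.3
        assert pct["life_threatening_high"] == 74.5
        assert pct["proteinuria_high"] == 70.6
        assert pct["mi_uc_high"] == 44.1
        assert pct["grade3_high"] == 63.6
        assert pct["malignant_cytology_high"] == 48.9

    def test_all_low_designation_leaves_high_undefined(self, fixture_tables):
        des = enrichment.RiskDesignation(
            labels={c: "low" for c in datasets.CLUSTERS},
            prevalences={},
            cohort_prevalence=0.0,
            rule="test",
        )
        pct = hr.headline_percentages(fixture_tables, des)
        assert pct["life_threatening_high"] is None
        assert pct["life_threatening_low"] is not None


def mann_whitney_exact_oracle(a, b):
    """Two-sided p by exhaustive enumeration over all rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), n1):
        r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    mean_u = n1 * (len(b)) / 2
    # two-sided: as or more extreme in |U - E[U]|
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(p)


class TestMannWhitney:
    def test_identical_samples(self):
        a = np.arange(1.0, 9.0)
        u, p = hr.mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9), rng.integers(3, 9)
        a = rng.normal(0, 1, n1)
        b = rng.normal(0.8, 1, n2)
        _, p = hr.mann_whitney(a, b)
        assert p == pytest.approx(mann_whitney_exact_oracle(a, b), abs=1e-9)

    def test_detects_stochastic_dominance(self):
        pvals = []
        for seed in range(9):
            rng = np.random.default_rng(100 + seed)
            a = rng.normal(1.0, 1.0, 50)
            b = rng.normal(0.0, 1.0, 50)
            _, p = hr.mann_whitney(a, b, alternative="greater")
            pvals.append(p)
        assert np.median(pvals) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            hr.mann_whitney([], [1.0])

    def test_tie_handling_uses_asymptotic(self):
        a = [1.0, 1.0, 2.0, 2.0] * 6
        b = [1.0, 2.0, 2.0, 3.0] * 6
        u, p = hr.mann_whitney(a, b)
        assert 0.0 <= p <= 1.0
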