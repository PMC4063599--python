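"""Coefficient of variation, rank-sum testing, and the comparison grid."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcap.metabolite_roles import MetaboliteGrouping
from fluxcap.expression_mapping import MetaboliteMapping
from fluxcap.variability_stats import (
    COMPARISONS,
    capacity_cv_comparison,
    coefficient_of_variation,
    cv_comparison_grid,
    cv_table,
    rank_sum_test,
)


class TestCoefficientOfVariation:
    def test_direct_value(self):
        res = coefficient_of_variation([2, 4, 6], exclude_first_k=0)
        assert res.value == pytest.approx(0.5)  # sd 2, mean 4
        assert res.n_used == 3

    def test_constant_series_is_zero(self):
        assert coefficient_of_variation([3, 3, 3, 3]).value == 0.0

    def test_exclusion_removes_early_transient(self):
        series = [9, 1, 7, 0.5, 8, 2] + [5.0] * 16
        assert coefficient_of_variation(series, exclude_first_k=6).value == 0.0
        assert coefficient_of_variation(series, exclude_first_k=0).value > 0.0

    def test_too_few_points_flagged(self):
        res = coefficient_of_variation([1.0], exclude_first_k=0)
        assert np.isnan(res.value) and res.reason == "too_few_points"
        res = coefficient_of_variation([1, 2, 3], exclude_first_k=2)
        assert res.reason == "too_few_points"

    def test_nonpositive_mean_flagged(self):
        res = coefficient_of_variation([-1.0, -3.0])
        assert np.isnan(res.value) and res.reason == "nonpositive_mean"

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        data=st.lists(st.floats(min_value=0.1, max_value=100), min_size=3, max_size=12),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, data):
        base = coefficient_of_variation(data).value
        scaled = coefficient_of_variation([scale * x for x in data]).value
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_not_translation_invariant(self):
        assert coefficient_of_variation([1, 2, 3]).value != pytest.approx(
            coefficient_of_variation([11, 12, 13]).value
        )


class TestRankSum:
    def test_worked_example(self):
        """{1,2,3} vs {4,5,6}: the single most extreme of C(6,3)=20 assignments."""
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(0.05, abs=1e-12)

    def test_identical_samples_not_significant(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p >= 0.5

    def test_singleton_sample_is_na(self):
        res = rank_sum_test([1.0], [2.0, 3.0])
        assert np.isnan(res.p) and res.na_reason == "sample_too_small"

    def test_exact_branch_matches_enumeration(self, ranksum_oracle):
        """Exact agreement with full enumeration for all n_a + n_b <= 12."""
        rng = np.random.default_rng(12345)
        for n_a, n_b in [
            (a, b) for a in range(2, 11) for b in range(2, 11) if a + b <= 12
        ]:
            vals = rng.permutation(np.arange(1, n_a + n_b + 1, dtype=float))
            a, b = list(vals[:n_a]), list(vals[n_a:])
            ours = rank_sum_test(a, b).p
            assert ours == pytest.approx(ranksum_oracle(a, b), abs=1e-12), (n_a, n_b)

    def test_one_sided_pair_sums_to_one_plus_point_mass(self, ranksum_oracle):
        rng = np.random.default_rng(7)
        a = list(rng.normal(size=5))
        b = list(rng.normal(size=4))
        p_ab = rank_sum_test(a, b).p
        p_ba = rank_sum_test(b, a).p
        point = ranksum_oracle(a, b) - (
            1.0 - ranksum_oracle(b, a)
        )  # P(statistic exactly at observed)
        assert p_ab + p_ba == pytest.approx(1.0 + point, abs=1e-12)

    def test_tied_data_uses_corrected_approximation(self):
        a = [1.0, 1.0, 2.0, 2.0]
        b = [2.0, 3.0, 3.0, 4.0]
        res = rank_sum_test(a, b)
        assert 0.0 < res.p < 0.5


def make_grid_inputs(n_cond=2, n_group=6, n_other=14, low=0.05, high=0.3, seed=0):
    """Synthetic CV table + groupings with a planted low-CV group."""
    rng = np.random.default_rng(seed)
    conds = [f"c{i}" for i in range(n_cond)]
    bases = [f"B{i}" for i in range(n_group + n_other)]
    mapping = MetaboliteMapping({f"m_{b}": frozenset({b}) for b in bases})
    rows = []
    for cond in conds:
        for i, b in enumerate(bases):
            cv = (low if i < n_group else high) * float(np.exp(rng.normal(0, 0.1)))
            rows.append(
                {
                    "feature": f"m_{b}",
                    "condition": cond,
                    "cv": cv,
                    "n_timepoints_used": 16,
                    "mean": 1.0,
                    "sd": cv,
                    "reason": None,
                }
            )
    cvs = pd.DataFrame(rows)
    group = frozenset(bases[:n_group])
    rest = frozenset(bases[n_group:])
    groupings = {}
    for cond in conds:
        sets = {}
        for cat in ("all", "products", "substrates"):
            sets[(cat, "in_modulator")] = group
            sets[(cat, "in_sustainer")] = group
            sets[(cat, "in_differential")] = group
            sets[(cat, "in_non_modulator")] = rest
            sets[(cat, "in_non_sustainer")] = rest
            sets[(cat, "in_non_differential")] = rest
            sets[(cat, "all_measured")] = frozenset(bases)
        groupings[cond] = MetaboliteGrouping(cond, sets)
    return cvs, groupings, mapping


class TestComparisonGrid:
    def test_row_count_is_3x6xconditions(self):
        for n_cond in (2, 8):
            cvs, groupings, mapping = make_grid_inputs(n_cond=n_cond)
            grid = cv_comparison_grid(cvs, groupings, mapping)
            assert len(grid) == 3 * len(COMPARISONS) * n_cond

    def test_planted_low_cv_group_significant(self):
        cvs, groupings, mapping = make_grid_inputs()
        grid = cv_comparison_grid(cvs, groupings, mapping)
        row = grid[
            (grid.categorization == "substrates")
            & (grid.comparison == "in_differential_vs_all_measured")
        ]
        assert (row.p < 0.05).all()
        assert row.significant.all()

    def test_empty_group_rows_are_na_with_reason(self):
        cvs, groupings, mapping = make_grid_inputs(n_cond=1)
        empty_sets = {
            k: (frozenset() if k[1].startswith("in_") and "non" not in k[1] else v)
            for k, v in groupings["c0"].sets.items()
        }
        groupings["c0"] = MetaboliteGrouping("c0", empty_sets)
        grid = cv_comparison_grid(cvs, groupings, mapping)
        na_rows = grid[grid.comparison.str.contains("in_modulator|in_sustainer|in_differential")]
        assert (na_rows.na_reason == "sample_too_small").all()
        assert na_rows.p.isna().all()

    def test_bh_column_present_and_monotone(self):
        cvs, groupings, mapping = make_grid_inputs()
        grid = cv_comparison_grid(cvs, groupings, mapping)
        ok = grid.dropna(subset=["p"])
        assert (ok.bh_q >= ok.p - 1e-12).all()


class TestCapacityCvComparison:
    def _profile(self, values):
        from fluxcap.capacity_engine import CapacityProfile

        values = np.asarray(values, dtype=float)
        return CapacityProfile(
            [f"P{i}" for i in range(values.shape[0])],
            ["c0"],
            np.arange(values.shape[2], dtype=float),
            values,
            np.full(values.shape, "optimal", dtype=object),
        )

    def _classification(self, diff_ids, all_ids):
        labels = pd.DataFrame("none", index=all_ids, columns=["c0"])
        for fid in diff_ids:
            labels.loc[fid, "c0"] = "modulator"
        n_hit = (labels != "none").sum(axis=1)
        from fluxcap.null_classifier import ClassificationTable

        # single condition: treat any labelled pathway as differential
        return ClassificationTable(labels, labels.map(lambda _: 0.0), n_hit >= 1)

    def test_flat_differential_vs_noisy_rest_significant(self):
        rng = np.random.default_rng(0)
        n, nt = 12, 10
        values = np.empty((n, 1, nt))
        for i in range(n):
            if i < 5:  # differential: flat profiles
                values[i, 0] = 10.0 + 0.01 * rng.standard_normal(nt)
            else:
                values[i, 0] = 10.0 * (1 + 0.4 * rng.standard_normal(nt))
        values = np.abs(values)
        prof = self._profile(values)
        cls = self._classification([f"P{i}" for i in range(5)], prof.function_ids)
        report = capacity_cv_comparison(
            prof, cls, roles={}, metabolite_cvs=pd.DataFrame(
                columns=["feature", "condition", "cv"]
            ), mapping=MetaboliteMapping({}), model=None,
        )
        assert report.loc[0, "p_capacity_cv_diff_lower"] < 0.05

    def test_constant_capacities_give_nonsignificant_substrate_contrast(
        self, small_dataset
    ):
        """All-zero capacity CVs: substrates cannot be lower -> p >= 0.5."""
        from fluxcap.metabolite_roles import pathway_roles

        ds = small_dataset
        nf, nc = len(ds.functions), len(ds.spec.conditions)
        nt = len(ds.spec.timepoints)
        values = np.full((nf, nc, nt), 4.2)
        from fluxcap.capacity_engine import CapacityProfile

        prof = CapacityProfile(
            [f.id for f in ds.functions],
            list(ds.spec.conditions),
            np.asarray(ds.spec.timepoints),
            values,
            np.full(values.shape, "optimal", dtype=object),
        )
        labels = pd.DataFrame(
            "none", index=prof.function_ids, columns=prof.conditions
        )
        from fluxcap.null_classifier import ClassificationTable

        cls = ClassificationTable(
            labels, labels.map(lambda _: 0.0), pd.Series(False, index=prof.function_ids)
        )
        roles = {
            fn.id: pathway_roles(fn, ds.model, ds.cofactors) for fn in ds.functions
        }
        cvs = cv_table(ds.metabolites, exclude_first_k=6)
        report = capacity_cv_comparison(
            prof, cls, roles, cvs, ds.mapping, ds.model, exclude_first_k=6
        )
        # (i) empty differential set -> NA
        assert report["na_reason_i"].notna().all()
        # (ii) substrate CVs are positive, capacity CVs zero
        assert (report["p_substrate_cv_lower_than_capacity"].dropna() >= 0.5).all()
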