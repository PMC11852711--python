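"""Normalisation, per-aptamer OLS, BH adjustment, and panel selection.

The OLS route is checked against two independent oracles: scipy's pooled
two-sample t-test and a statsmodels OLS fit with an explicit design
matrix. BH is checked against a brute-force evaluation of the step-up
definition.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aptapanel import (
    Contrast,
    CountMatrix,
    PanelSelectionConfig,
    SampleMetadata,
    adjust_bh,
    dichotomize_by_median,
    fit_two_group_ols,
    normalize_log2cpm,
    select_panel,
)


def _meta(groups, ldl=None):
    return [
        SampleMetadata(
            f"s{i}", "dev", g, 0,
            ldl=None if ldl is None else ldl[i],
            library_size=1,
        )
        for i, g in enumerate(groups)
    ]


def _abundance(a_values, b_values):
    groups = ["MASLD_no_SH"] * len(a_values) + ["MASH"] * len(b_values)
    meta = _meta(groups)
    df = pd.DataFrame(
        {"apt_1": list(a_values) + list(b_values)},
        index=[s.sample_id for s in meta],
    )
    return df, meta


CONTRAST = Contrast("sh", "group", "MASLD_no_SH", "MASH")


class TestNormalization:
    def test_formula_hand_values(self):
        counts = pd.DataFrame(
            {"a": [1000, 0], "b": [999_000, 10]}, index=["s1", "s2"]
        )
        matrix = CountMatrix(counts=counts)
        ab = normalize_log2cpm(matrix, pseudocount=1.0)
        assert ab.loc["s1", "a"] == pytest.approx(np.log2(1001), abs=1e-12)
        assert ab.loc["s1", "a"] == pytest.approx(9.9672, abs=1e-4)
        assert ab.loc["s2", "a"] == 0.0  # zero count -> log2(pseudocount) = 0

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, (4, 10)))
        counts.index = [f"s{i}" for i in range(4)]
        a = normalize_log2cpm(CountMatrix(counts=counts))
        b = normalize_log2cpm(CountMatrix(counts=counts * 2))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"a": [5, 0]}, index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            normalize_log2cpm(CountMatrix(counts=counts))


class TestDichotomize:
    def test_median_split_and_tie_rule(self):
        meta = _meta(["MASH"] * 4, ldl=[2.0, 3.0, 4.0, 5.0])
        contrast = dichotomize_by_median(meta, "ldl")
        assert contrast.threshold == 3.5
        mask_a, mask_b = contrast.masks(meta)
        assert sorted(mask_a.index[mask_a]) == ["s0", "s1"]
        assert sorted(mask_b.index[mask_b]) == ["s2", "s3"]
        # a value exactly at the median goes to level_b
        meta_tie = _meta(["MASH"] * 3, ldl=[1.0, 2.0, 3.0])
        tie = dichotomize_by_median(meta_tie, "ldl")
        _, mb = tie.masks(meta_tie)
        assert mb["s1"]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_by_median(_meta(["MASH"] * 3), "ldl")


class TestTwoGroupOLS:
    def test_coefficient_is_mean_difference(self):
        ab, meta = _abundance([1, 2, 3], [3, 4, 5])
        res = fit_two_group_ols(ab, meta, CONTRAST)
        assert res.loc["apt_1", "coefficient"] == pytest.approx(2.0, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        ab, meta = _abundance([1, 2, 3], [1, 2, 3])
        res = fit_two_group_ols(ab, meta, CONTRAST)
        assert res.loc["apt_1", "coefficient"] == 0.0
        assert res.loc["apt_1", "p_value"] == pytest.approx(1.0)

    def test_zero_residual_variance_convention(self):
        ab, meta = _abundance([2, 2], [5, 5])
        res = fit_two_group_ols(ab, meta, CONTRAST)
        assert res.loc["apt_1", "p_value"] == 0.0
        ab2, meta2 = _abundance([2, 2], [2, 2])
        res2 = fit_two_group_ols(ab2, meta2, CONTRAST)
        assert res2.loc["apt_1", "p_value"] == 1.0

    def test_matches_pooled_t_test_oracle(self, rng):
        for _ in range(25):
            n_a, n_b = rng.integers(2, 15, 2)
            a = rng.normal(0, 1, n_a)
            b = rng.normal(0.5, 1, n_b)
            ab, meta = _abundance(a, b)
            res = fit_two_group_ols(ab, meta, CONTRAST)
            t, p = stats.ttest_ind(b, a, equal_var=True)
            assert res.loc["apt_1", "coefficient"] == pytest.approx(
                b.mean() - a.mean(), abs=1e-12
            )
            assert res.loc["apt_1", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_design_matrix_fit(self, rng):
        import statsmodels.api as sm

        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        ab, meta = _abundance(a, b)
        res = fit_two_group_ols(ab, meta, CONTRAST)
        x = np.concatenate([np.zeros(6), np.ones(8)])
        fit = sm.OLS(np.concatenate([a, b]), sm.add_constant(x)).fit()
        assert res.loc["apt_1", "coefficient"] == pytest.approx(fit.params[1], abs=1e-10)
        assert res.loc["apt_1", "p_value"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_antisymmetry_under_level_swap(self, rng):
        ab, meta = _abundance(rng.normal(0, 1, 5), rng.normal(1, 1, 7))
        fwd = fit_two_group_ols(ab, meta, CONTRAST)
        rev = fit_two_group_ols(
            ab, meta, Contrast("sh_rev", "group", "MASH", "MASLD_no_SH")
        )
        assert rev["coefficient"].to_numpy() == pytest.approx(
            -fwd["coefficient"].to_numpy(), abs=1e-12
        )
        assert rev["p_value"].to_numpy() == pytest.approx(
            fwd["p_value"].to_numpy(), abs=1e-12
        )

    def test_small_group_rejected(self):
        ab, meta = _abundance([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_two_group_ols(ab, meta, CONTRAST)


def bh_bruteforce(p):
    """Step-up definition: sort ascending, q(k) = min_{j>=k} (m/j) p(j),
    cap at 1, map back."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for k in range(m):
        q_sorted[k] = min(min((m / (j + 1)) * p[order[j]] for j in range(k, m)), 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBH:
    def test_single_p_is_identity(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_hand_example(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_definition(self, p):
        got = adjust_bh(p)
        expected = bh_bruteforce(p)
        assert got == pytest.approx(expected, abs=1e-12)
        assert (got >= np.asarray(p) - 1e-15).all()
        assert (got <= 1.0).all()

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 30)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestSelectPanel:
    def _results(self, rows):
        return pd.DataFrame(
            rows, index=pd.Index([f"apt_{i}" for i in range(len(rows))], name="aptamer_id")
        )

    def test_selection_rule_and_direction(self):
        results = pd.DataFrame(
            {
                "coefficient": [0.30, 0.30, -0.40, 0.10],
                "se": [0.1] * 4,
                "p_value": [0.0001, 0.9, 0.0001, 0.0001],
            },
            index=pd.Index(["a", "b", "c", "d"], name="aptamer_id"),
        )
        panel = select_panel(results, CONTRAST, PanelSelectionConfig(top_k=4))
        # b fails on adjusted p, d fails on coefficient magnitude
        assert panel.members == ["a", "c"]
        assert panel.n_up == 1 and panel.n_down == 1
        assert panel.table.loc["a", "direction"] == "up"
        assert panel.table.loc["c", "direction"] == "down"

    def test_empty_panel_allowed(self):
        results = pd.DataFrame(
            {"coefficient": [0.01], "se": [0.1], "p_value": [0.9]},
            index=pd.Index(["a"], name="aptamer_id"),
        )
        panel = select_panel(results, CONTRAST, PanelSelectionConfig(top_k=1))
        assert panel.members == []
        assert panel.n_up == panel.n_down == 0
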