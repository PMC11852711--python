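"""PC1 projection, AUC/DeLong, Wilcoxon, AUC bands, clinical scores.

The AUC is checked against exhaustive pair counting; the DeLong variance
and CI against values computed independently with the R package pROC
(ci.auc method="delong") on a frozen score vector.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptapanel import (
    Contrast,
    SampleMetadata,
    auc_delong,
    classify_auc,
    clinical_scores,
    evaluate_comparisons,
    fit_panel_projection,
    project_scores,
    wilcoxon_test,
)


def _frame(X, members=None):
    members = members or [f"apt_{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])], columns=members)


def _labels(y):
    return pd.Series(y, index=[f"s{i}" for i in range(len(y))], dtype=float)


class TestPanelProjection:
    def test_collinear_data_gives_line_direction(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        X = np.column_stack([2 * t, -t])  # all samples on a line
        ab = _frame(X)
        model = fit_panel_projection(ab, list(ab.columns), _labels([0, 0, 1, 1]))
        direction = np.array([2.0, -1.0]) / math.sqrt(5)
        assert np.abs(model.loading @ direction) == pytest.approx(1.0, abs=1e-12)
        scores = project_scores(model, ab)
        assert scores.var(ddof=1) == pytest.approx(ab.var(ddof=1).sum(), abs=1e-9)

    def test_score_variance_equals_top_eigenvalue(self, rng):
        X = rng.normal(0, 1, (30, 5)) @ np.diag([3, 2, 1, 1, 0.5])
        ab = _frame(X)
        model = fit_panel_projection(ab, list(ab.columns), _labels(rng.integers(0, 2, 30)))
        scores = project_scores(model, ab)
        eig = np.linalg.eigvalsh(np.cov(X, rowvar=False))
        assert scores.var(ddof=1) == pytest.approx(eig.max(), rel=1e-9)

    def test_duplicating_samples_preserves_center_and_axis(self, rng):
        X = rng.normal(0, 1, (10, 3))
        ab = _frame(X)
        y = _labels(rng.integers(0, 2, 10).astype(float))
        m1 = fit_panel_projection(ab, list(ab.columns), y)
        X2 = np.vstack([X, X])
        ab2 = _frame(X2)
        y2 = pd.Series(np.concatenate([y.to_numpy()] * 2), index=ab2.index)
        m2 = fit_panel_projection(ab2, list(ab2.columns), y2)
        assert m1.center == pytest.approx(m2.center, abs=1e-12)
        assert abs(np.dot(m1.loading, m2.loading)) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_puts_positive_class_higher(self, rng):
        X = rng.normal(0, 1, (40, 4))
        y = rng.integers(0, 2, 40).astype(float)
        X[y == 1] += 1.5
        ab = _frame(X)
        model = fit_panel_projection(ab, list(ab.columns), _labels(y))
        scores = project_scores(model, ab)
        assert scores[y == 1].mean() > scores[y == 0].mean()

    def test_training_projection_reproduces_fit_scores_and_centering(self, rng):
        X = rng.normal(0, 1, (12, 4))
        ab = _frame(X)
        y = _labels([0, 1] * 6)
        model = fit_panel_projection(ab, list(ab.columns), y)
        scores = project_scores(model, ab)
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)
        # the sample equal to the training center scores exactly 0
        center_row = pd.DataFrame([model.center], index=["c"], columns=ab.columns)
        assert project_scores(model, center_row)["c"] == pytest.approx(0.0, abs=1e-12)

    def test_column_shift_moves_scores_linearly(self, rng):
        X = rng.normal(0, 1, (15, 3))
        ab = _frame(X)
        model = fit_panel_projection(ab, list(ab.columns), _labels(rng.integers(0, 2, 15)))
        shifted = ab.copy()
        shifted.iloc[:, 0] += 2.5
        delta = project_scores(model, shifted) - project_scores(model, ab)
        expected = 2.5 * model.loading[0] * model.orientation
        assert delta.to_numpy() == pytest.approx(np.full(15, expected), abs=1e-10)

    def test_constant_matrix_rejected(self):
        ab = _frame(np.ones((6, 3)))
        with pytest.raises(ValueError, match="no variance"):
            fit_panel_projection(ab, list(ab.columns), _labels([0, 1] * 3))

    def test_missing_member_rejected(self, rng):
        ab = _frame(rng.normal(0, 1, (6, 2)))
        with pytest.raises(ValueError, match="absent"):
            fit_panel_projection(ab, ["apt_0", "ghost"], _labels([0, 1] * 3))


def auc_bruteforce(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_hand_example(self):
        res = auc_delong([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation_degenerate_ci(self):
        res = auc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.variance == 0.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_label_flip_symmetry(self, rng):
        scores = rng.normal(0, 1, 25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        a = auc_delong(scores, labels)
        b = auc_delong(scores, 1 - labels)
        assert a.auc == pytest.approx(1 - b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            res = auc_delong(scores, labels)
            assert res.auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    def test_delong_matches_pROC_frozen_fixture(self):
        """Variance and CI frozen from R pROC ci.auc(method='delong')."""
        scores = [0.9, 0.8, 0.35, 0.71, 0.62, 0.58, 0.44, 0.3, 0.15, 0.95,
                  0.41, 0.22, 0.67, 0.52, 0.5, 0.5]
        labels = [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1]
        res = auc_delong(scores, labels)
        assert res.auc == pytest.approx(0.611111111111, abs=1e-10)
        assert res.variance == pytest.approx(0.025058788948, abs=1e-10)
        assert res.ci_low == pytest.approx(0.300849437940, abs=1e-9)
        assert res.ci_high == pytest.approx(0.921372784282, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([1, 2, 3], [1, 1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 20)
        labels = np.array([0, 1] * 10)
        a = auc_delong(scores, labels)
        b = auc_delong(np.exp(scores) + 3, labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        _, p1 = wilcoxon_test(scores[labels == 0], scores[labels == 1])
        _, p2 = wilcoxon_test(np.exp(scores[labels == 0]) + 3, np.exp(scores[labels == 1]) + 3)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p = wilcoxon_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)


class TestClassifyAUC:
    @pytest.mark.parametrize(
        "auc,label",
        [
            (0.83, "excellent"),
            (0.72, "acceptable"),
            (0.50, "below_acceptable"),
            (0.70, "acceptable"),
            (0.80, "excellent"),
            (0.90, "outstanding"),
            (0.95, "outstanding"),
        ],
    )
    def test_bands(self, auc, label):
        assert classify_auc(auc) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_auc(1.2)


class TestClinicalScores:
    def test_fib4_hand_value(self):
        meta = [SampleMetadata("s1", "dev", "MASH", 0, age=50.0, ast=25.0,
                               alt=30.0, platelets=250.0, library_size=1)]
        out = clinical_scores(meta)
        assert out.loc["s1", "fib4"] == pytest.approx(0.9129, abs=1e-4)

    def test_equal_transaminases_ratio_one_and_missing_propagates(self):
        meta = [SampleMetadata("s1", "dev", "MASH", 0, age=50.0, ast=40.0,
                               alt=40.0, platelets=None, library_size=1)]
        out = clinical_scores(meta)
        assert out.loc["s1", "ast_alt_ratio"] == 1.0
        assert np.isnan(out.loc["s1", "fib4"])


class TestEvaluateComparisons:
    def _setup(self, rng):
        X = rng.normal(0, 1, (20, 3))
        y = np.array([0, 1] * 10, float)
        X[y == 1] += 2.0
        meta = [
            SampleMetadata(f"s{i}", "dev", "MASH" if y[i] else "MASLD_no_SH",
                           int(3 if y[i] else 0), library_size=1)
            for i in range(20)
        ]
        ab = _frame(X)
        model = fit_panel_projection(ab, list(ab.columns), _labels(y))
        return ab, meta, model

    def test_empty_class_preserved_as_na_row(self, rng):
        ab, meta, model = self._setup(rng)
        comparisons = [
            Contrast("noSH_vs_MASH", "group", "MASLD_no_SH", "MASH"),
            Contrast("healthy_vs_noSH", "group", "healthy", "MASLD_no_SH"),
        ]
        table = evaluate_comparisons(model, {"dev": (ab, meta)}, comparisons)
        assert len(table) == 2
        na_row = table[table["comparison"] == "healthy_vs_noSH"].iloc[0]
        assert na_row["label"] == "N/A"
        assert na_row["note"] == "empty class"
        assert np.isnan(na_row["auc"])
        good = table[table["comparison"] == "noSH_vs_MASH"].iloc[0]
        assert good["auc"] > 0.9

    def test_same_cohort_twice_gives_identical_rows(self, rng):
        ab, meta, model = self._setup(rng)
        comparisons = [Contrast("noSH_vs_MASH", "group", "MASLD_no_SH", "MASH")]
        table = evaluate_comparisons(
            model, {"one": (ab, meta), "two": (ab, meta)}, comparisons
        )
        a = table[table["cohort"] == "one"].drop(columns="cohort").reset_index(drop=True)
        b = table[table["cohort"] == "two"].drop(columns="cohort").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
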