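import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from myelotype.roc import (DEFAULT_K_GRID, auc, auc_ci_bootstrap, k_grid_search,
                           roc_curve, youden_optimal)

from conftest import auc_pair_oracle


def labels_of(n_pos, n_neg):
    return np.array(["pos"] * n_pos + ["neg"] * n_neg)


class TestROCCurve:
    def test_perfect_separation_reaches_corner(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        curve = roc_curve(scores, labels_of(2, 2), positive_class="pos")
        j = curve.sensitivity + curve.specificity - 1
        assert j.max() == pytest.approx(1.0)
        assert auc(curve) == pytest.approx(1.0)

    def test_all_tied_scores_give_chance_auc(self):
        curve = roc_curve(np.ones(10), labels_of(5, 5), positive_class="pos")
        assert auc(curve) == pytest.approx(0.5)

    def test_curve_spans_both_corners(self):
        rng = np.random.default_rng(0)
        curve = roc_curve(rng.random(30), labels_of(10, 20), positive_class="pos")
        pts = set(zip(curve.fpr.round(9), curve.tpr.round(9)))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["pos", "pos"], positive_class="pos")


class TestAUC:
    @pytest.mark.parametrize("n,p_tie,seed", [(6, 0.0, 1), (25, 0.3, 2),
                                              (80, 0.1, 3), (200, 0.5, 4)])
    def test_matches_exhaustive_pair_oracle(self, n, p_tie, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, n).astype(float) if p_tie else rng.random(n)
        lab = np.where(rng.random(n) < 0.45, "pos", "neg")
        if len(set(lab)) < 2:
            lab[0], lab[1] = "pos", "neg"
        got = auc(roc_curve(scores, lab, positive_class="pos"))
        assert got == pytest.approx(auc_pair_oracle(scores, lab), abs=1e-12)

    def test_matches_sklearn_concordance(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 20, 150).astype(float)
        lab = np.where(rng.random(150) < 0.4, "pos", "neg")
        got = auc(roc_curve(scores, lab, positive_class="pos"))
        # lower scores flag positives, so negate for sklearn's convention
        ref = sklearn_metrics.roc_auc_score((lab == "pos").astype(int), -scores)
        assert got == pytest.approx(ref, abs=1e-12)

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(5)
        scores = rng.random(60)
        lab = np.where(rng.random(60) < 0.5, "pos", "neg")
        lab[:2] = ["pos", "neg"]
        a = auc(roc_curve(scores, lab, positive_class="pos"))
        b = auc(roc_curve(-scores, lab, positive_class="pos"))
        assert a + b == pytest.approx(1.0)

    def test_null_scores_give_chance_level(self):
        rng = np.random.default_rng(12)
        n = 10000
        scores = rng.random(n)
        lab = np.where(rng.random(n) < 0.5, "pos", "neg")
        assert 0.48 <= auc(roc_curve(scores, lab, positive_class="pos")) <= 0.52

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 12), min_size=4, max_size=60),
           st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, raw, seed):
        rng = np.random.default_rng(seed)
        scores = np.asarray(raw, dtype=float)
        lab = np.where(rng.random(len(raw)) < 0.5, "pos", "neg")
        lab[:2] = ["pos", "neg"]
        a = auc(roc_curve(scores, lab, positive_class="pos"))
        b = auc(roc_curve(np.exp(scores / 3.0), lab, positive_class="pos"))
        assert a == pytest.approx(b, abs=1e-12)


class TestYouden:
    def test_j_identity_holds_exactly(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 10, 40).astype(float)
        lab = np.where(rng.random(40) < 0.4, "pos", "neg")
        lab[:2] = ["pos", "neg"]
        cp = youden_optimal(roc_curve(scores, lab, positive_class="pos"))
        assert cp.youden_j == cp.sensitivity + cp.specificity - 1.0

    def test_published_style_operating_point_accuracy(self):
        """10 pos / 12 neg with max J at sens 0.9, spec 0.75 -> accuracy 0.82."""
        pos = list(range(1, 10)) + [20.0]          # 9 low, 1 high
        neg = [0.5, 0.6, 0.7] + list(range(10, 19))  # 3 low, 9 high
        scores = np.array(pos + neg, dtype=float)
        cp = youden_optimal(roc_curve(scores, labels_of(10, 12),
                                      positive_class="pos"))
        assert cp.sensitivity == pytest.approx(0.9)
        assert cp.specificity == pytest.approx(0.75)
        assert cp.accuracy == pytest.approx((0.9 * 10 + 0.75 * 12) / 22)

    def test_tie_breaks_toward_higher_specificity(self):
        # two cutoffs with J = 0.5: (sens 1, spec 0.5) and (sens 0.5, spec 1)
        scores = np.array([1.0, 2.0, 1.5, 3.0])
        cp = youden_optimal(roc_curve(scores, labels_of(2, 2),
                                      positive_class="pos"))
        assert cp.specificity == 1.0

    def test_perfect_separation_hits_j_of_one(self):
        scores = np.array([0.1, 0.2, 5.0, 6.0])
        cp = youden_optimal(roc_curve(scores, labels_of(2, 2),
                                      positive_class="pos"))
        assert cp.youden_j == pytest.approx(1.0)
        assert cp.accuracy == pytest.approx(1.0)


class TestBootstrapCI:
    def test_perfect_separation_interval_is_degenerate_high(self):
        scores = np.r_[np.zeros(20), np.ones(30)]
        lo, hi = auc_ci_bootstrap(scores, labels_of(20, 30), n_boot=200, seed=1,
                                  positive_class="pos")
        assert lo >= 0.99 and hi == pytest.approx(1.0)

    def test_single_positive_does_not_crash(self):
        scores = np.r_[0.1, np.random.default_rng(0).random(20) + 1]
        lo, hi = auc_ci_bootstrap(scores, labels_of(1, 20), n_boot=200, seed=2,
                                  positive_class="pos")
        assert 0.0 <= lo <= hi <= 1.0

    def test_fixed_seed_repeats_exactly(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        lab = labels_of(12, 18)
        a = auc_ci_bootstrap(scores, lab, n_boot=150, seed=7, positive_class="pos")
        b = auc_ci_bootstrap(scores, lab, n_boot=150, seed=7, positive_class="pos")
        assert a == b

    def test_small_n_boot_warns(self):
        scores = np.arange(10, dtype=float)
        with pytest.warns(UserWarning):
            auc_ci_bootstrap(scores, labels_of(5, 5), n_boot=50, seed=0,
                             positive_class="pos")


def volumes_table(k_values, rows_per_k):
    frames = []
    for k in k_values:
        df = pd.DataFrame(rows_per_k)
        df["k"] = k
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestKGridSearch:
    ROWS = [
        {"subject_id": "a", "group_truth": "MCMS", "t1_ml": 0.1, "ratio_pct": 0.5},
        {"subject_id": "b", "group_truth": "MCMS", "t1_ml": 0.2, "ratio_pct": 0.9},
        {"subject_id": "c", "group_truth": "TMS", "t1_ml": 2.0, "ratio_pct": 9.0},
        {"subject_id": "d", "group_truth": "TMS", "t1_ml": 3.0, "ratio_pct": 12.0},
    ]

    def test_single_k_grid_returns_that_k(self):
        res = k_grid_search(volumes_table([1.3], self.ROWS), k_values=(1.3,))
        assert res.selected_k == 1.3

    def test_missing_k_rows_raise(self):
        with pytest.raises(ValueError, match="lacks rows"):
            k_grid_search(volumes_table([1.0, 1.1], self.ROWS),
                          k_values=(1.0, 1.1, 1.2))

    def test_default_grid_matches_published_sweep(self):
        assert DEFAULT_K_GRID[0] == 1.0 and DEFAULT_K_GRID[-1] == 2.0
        assert len(DEFAULT_K_GRID) == 11

    def test_ties_resolve_to_plateau_median(self):
        # identical data at every k: all accuracies tie, median k selected
        res = k_grid_search(volumes_table(list(DEFAULT_K_GRID), self.ROWS))
        assert res.selected_k == 1.5

    def test_result_table_has_one_row_per_k(self):
        res = k_grid_search(volumes_table([1.0, 1.5], self.ROWS),
                            k_values=(1.0, 1.5))
        assert list(res.to_frame()["k"]) == [1.0, 1.5]
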