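"""Metrics, grid search, curves and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tremorkit as tk
from tremorkit.evaluate import (
    GridResult,
    Plateau,
    _metric_surfaces,
    _surfaces_from_arrays,
    make_folds,
)


def make_grid(freq, amp, y, lower_grid, thresh_grid, band_upper=12.0):
    """GridResult straight from arrays (bypasses spectral estimation)."""
    freq, amp = np.asarray(freq, float), np.asarray(amp, float)
    y = np.asarray(y, bool)
    lower_grid = np.asarray(lower_grid, float)
    thresh_grid = np.asarray(thresh_grid, float)
    tp, fp, tn, fn = _surfaces_from_arrays(freq, amp, y, lower_grid,
                                           thresh_grid, band_upper)
    p, r, s, f1 = _metric_surfaces(tp, fp, tn, fn)
    return GridResult("synthetic", band_upper, lower_grid, thresh_grid,
                      tp, fp, tn, fn, p, r, s, f1, n_segments=y.size)


class TestConfusion:
    def test_mixed_counts(self):
        c = tk.confusion(["tremor", "tremor", "no_tremor", "no_tremor"],
                         ["tremor", "no_tremor", "tremor", "no_tremor"])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_identical_and_inverted(self):
        ref = ["tremor", "no_tremor", "tremor"]
        same = tk.confusion(ref, ref)
        assert same.fp == same.fn == 0
        inv = tk.confusion(ref, ["no_tremor", "tremor", "no_tremor"])
        assert inv.tp == inv.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            tk.confusion(["tremor"], ["tremor", "tremor"])


class TestMetrics:
    def test_exhaustive_two_segment_combinations(self):
        """metrics(confusion(...)) against sklearn on all 16 label/pred pairs."""
        from sklearn.metrics import precision_score, recall_score, f1_score
        labs = ["tremor", "no_tremor"]
        for ref in itertools.product(labs, repeat=2):
            for pred in itertools.product(labs, repeat=2):
                m = tk.metrics(tk.confusion(list(ref), list(pred)))
                yt = [r == "tremor" for r in ref]
                yp = [p == "tremor" for p in pred]
                assert m.precision == pytest.approx(
                    precision_score(yt, yp, zero_division=0))
                assert m.recall == pytest.approx(
                    recall_score(yt, yp, zero_division=0))
                assert m.f1 == pytest.approx(
                    f1_score(yt, yp, zero_division=0))
                yn = [not v for v in yt]
                ypn = [not v for v in yp]
                assert m.specificity == pytest.approx(
                    recall_score(yn, ypn, zero_division=0))

    @pytest.mark.parametrize("p,r,expected", [
        (0.77, 0.76, 0.76),
        (0.95, 0.69, 0.80),
    ])
    def test_f1_harmonic_mean_rounding(self, p, r, expected):
        f1 = 2 * p * r / (p + r)
        assert round(f1, 2) == expected

    def test_degenerate_counts_report_zero(self):
        m = tk.metrics(tk.ConfusionCounts(0, 0, 3, 0))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.specificity == 1.0


class TestGridSearch:
    def test_separable_set_perfect_plateau(self, small_cohort):
        g = tk.grid_search(small_cohort, "periodogram")
        assert g.f1.max() == 1.0
        # F1=1 cells at threshold 0 form one contiguous band_lower run
        row = np.flatnonzero(np.isclose(g.f1[:, 0], 1.0))
        assert row.size > 0
        assert np.all(np.diff(row) == 1)
        # and that run separates the movement DFs from the tremor DFs
        table = tk.df_table(small_cohort, "periodogram")
        move_max = table[table.ref_label == "no_tremor"].freq_hz.max()
        tremor_min = table[table.ref_label == "tremor"].freq_hz.min()
        assert move_max < g.lower_grid[row[0]] <= g.lower_grid[row[-1]] <= tremor_min

    def test_lower_above_all_dfs_gives_zero_row(self, small_cohort):
        g = tk.grid_search(small_cohort, "periodogram",
                           lower_grid=np.array([11.9]),
                           thresh_grid=np.array([0.0]))
        assert g.f1[0, 0] == 0.0

    def test_recall_nonincreasing_in_threshold(self, small_cohort):
        g = tk.grid_search(small_cohort, "welch2")
        assert np.all(np.diff(g.recall, axis=1) <= 1e-12)

    def test_matches_naive_recompute_on_subgrid(self, small_cohort):
        """Cached-DF grid pass equals classify-then-score for every cell."""
        lower = np.array([0.0, 1.5, 3.0, 4.5, 6.0])
        thresh = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
        g = tk.grid_search(small_cohort, "welch3", lower, thresh)
        table = tk.df_table(small_cohort, "welch3")
        table = table[table.ref_label.isin(["tremor", "no_tremor"])]
        for i, lo in enumerate(lower):
            for j, th in enumerate(thresh):
                params = tk.DetectionParams(lo, 12.0, th)
                preds = tk.classify_table(table, params)["prediction"]
                m = tk.metrics(tk.confusion(table.ref_label.to_numpy(),
                                            preds.to_numpy()))
                assert m.f1 == pytest.approx(g.f1[i, j])
                assert m.specificity == pytest.approx(g.specificity[i, j])

    def test_surface_invariant_to_segment_order(self, small_cohort, rng):
        shuffled = tk.SegmentSet(
            [small_cohort[i] for i in rng.permutation(len(small_cohort))])
        g1 = tk.grid_search(small_cohort, "periodogram")
        g2 = tk.grid_search(shuffled, "periodogram")
        np.testing.assert_array_equal(g1.f1, g2.f1)

    def test_unlabeled_set_rejected(self, rng):
        segs = tk.SegmentSet([tk.Segment(rng.standard_normal(400), 100.0, "p", i)
                              for i in range(3)])
        with pytest.raises(ValueError, match="labeled"):
            tk.grid_search(segs, "periodogram")


class TestOptimalByF1:
    def test_unique_maximum(self):
        g = make_grid([5.0, 1.0], [10.0, 10.0], [True, False],
                      [0.0, 3.0, 6.0], [0.0, 50.0])
        params, plateau = tk.optimal_by_f1(g)
        assert params.band_lower == 3.0 and params.power_threshold == 0.0
        assert plateau == Plateau(3.0, 3.0, 0.0, 0.0)

    def test_plateau_reported_and_median_selected(self):
        # all tremor at 5 Hz amp 100, movement at 1 Hz: plateau 1.05..5.0
        freq = [5.0] * 5 + [1.0] * 5
        amp = [100.0] * 10
        y = [True] * 5 + [False] * 5
        lower = np.round(np.arange(0.0, 6.05, 0.5), 10)
        g = make_grid(freq, amp, y, lower, [0.0, 50.0])
        params, plateau = tk.optimal_by_f1(g)
        assert plateau.lower_min == 1.5 and plateau.lower_max == 5.0
        assert plateau.thresh_min == 0.0 and plateau.thresh_max == 50.0
        # max-margin: median threshold (0.0), median band_lower of the run
        assert params.power_threshold == 0.0
        assert plateau.lower_min < params.band_lower < plateau.lower_max

    def test_all_equal_surface_full_plateau(self):
        g = make_grid([1.0], [0.0], [True], [0.0, 1.0, 2.0], [0.0, 50.0])
        assert g.f1.max() == 0.0
        params, plateau = tk.optimal_by_f1(g)
        assert plateau == Plateau(0.0, 2.0, 0.0, 50.0)
        assert 0.0 <= params.band_lower <= 2.0


class TestCurves:
    def test_perfect_cell_distance_zero(self):
        g = make_grid([5.0, 1.0], [10.0, 10.0], [True, False],
                      [0.0, 3.0], [0.0])
        c = tk.curves(g)
        assert c.roc_optimal_point == (0.0, 1.0)
        assert c.roc_optimal_params.band_lower == 3.0
        assert set(c.frame.columns) == {
            "band_lower", "threshold", "sensitivity",
            "one_minus_specificity", "precision", "recall"}

    def test_random_predictions_near_diagonal(self):
        devs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = 200
            y = np.repeat([True, False], n // 2)
            freq = r.uniform(0, 12, n)     # random in/out of band
            amp = r.uniform(0, 100, n)
            g = make_grid(freq, amp, y, [3.0], [0.0, 25.0, 50.0, 75.0])
            devs.append(np.mean(np.abs(g.recall - (1 - g.specificity))))
        assert np.mean(devs) < 0.1

    def test_pr_and_roc_optima_can_differ(self):
        # imbalanced construction: two nested operating points A (sens .9,
        # spec .9) and B (sens .7, spec .99); ROC prefers A, PR prefers B
        freq = np.full(110, 5.0)
        amp = np.concatenate([
            np.full(7, 10.0), np.full(2, 5.0), np.full(1, 1.0),   # positives
            np.full(1, 10.0), np.full(9, 5.0), np.full(90, 1.0),  # negatives
        ])
        y = np.arange(110) < 10
        g = make_grid(freq, amp, y, [0.0], [2.0, 8.0])
        c = tk.curves(g)
        assert c.roc_optimal_params.power_threshold == 2.0
        assert c.pr_optimal_params.power_threshold == 8.0


class TestCrossValidate:
    def test_fold_sizes_single_patient(self, rng):
        segs = []
        for i in range(200):
            lab = "tremor" if i >= 100 else "no_tremor"
            segs.append(tk.Segment(rng.standard_normal(400), 100.0, "p1", i,
                                   ref_label=lab))
        ss = tk.SegmentSet(segs)
        folds = make_folds(ss)
        assert len(folds) == 4
        for f in folds:
            labs = [lab for (pid, i) in f
                    for lab in [ss.by_key()[(pid, i)].ref_label]]
            assert labs.count("tremor") == 20
            assert labs.count("no_tremor") == 20

    def test_test_blocks_disjoint(self, small_cohort):
        folds = make_folds(small_cohort)
        for a, b in itertools.combinations(folds, 2):
            assert not (a & b)

    def test_small_stratum_kept_in_training(self, rng):
        segs = [tk.Segment(rng.standard_normal(400), 100.0, "p1", i,
                           ref_label="tremor") for i in range(3)]
        segs += [tk.Segment(rng.standard_normal(400), 100.0, "p1", 3 + i,
                            ref_label="no_tremor") for i in range(20)]
        folds = make_folds(tk.SegmentSet(segs))
        tremor_keys = {("p1", i) for i in range(3)}
        for f in folds:
            assert not (f & tremor_keys)

    def test_separable_cohort_perfect_cv(self, small_cohort):
        cv = tk.cross_validate(small_cohort, "welch2")
        assert len(cv.iterations) == 4
        assert cv.mean_test_f1 == 1.0
        assert all(it.n_train + it.n_test <= len(small_cohort)
                   for it in cv.iterations)

    def test_no_segment_in_both_train_and_test(self, small_cohort):
        all_keys = {s.key for s in small_cohort.labeled()}
        for test in make_folds(small_cohort):
            train = all_keys - test
            assert not (train & test)
            assert test <= all_keys

    def test_unlabeled_set_rejected(self, rng):
        segs = tk.SegmentSet([tk.Segment(rng.standard_normal(400), 100.0,
                                         "p", i) for i in range(10)])
        with pytest.raises(ValueError, match="label"):
            tk.cross_validate(segs, "periodogram")

    def test_summary_frames(self, small_cohort):
        cv = tk.cross_validate(small_cohort, "periodogram")
        s = cv.summary()
        assert list(s["iteration"]) == [1, 2, 3, 4]
        st = cv.stats()
        assert set(st["metric"]) == {"f1", "precision", "recall", "specificity"}
        assert (st["mean"] <= 1.0).all() and (st["std"] >= 0.0).all()
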