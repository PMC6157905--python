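"""Harness correctness: folds, metric oracles, groupings, leakage hygiene."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from cogtraj.cohort import Cohort, default_roi_names
from cogtraj.evaluate import (
    DEFAULT_WORKFLOW_THRESHOLDS,
    WorkflowThresholds,
    _fit_predict_cell,
    Fold,
    build_prediction_inputs,
    compare_models,
    compute_metrics,
    nested_cv_split,
    run_experiment,
    select_followup,
    stratify_by_span,
    stratify_clinical_workflow,
)
from cogtraj.lsn import LSNConfig, PredictionInput
from cogtraj.reference import FAST_GRIDS, FeatureSpec
from cogtraj.trajectory import TrajectoryAssignment

from conftest import make_subject


def brute_force_auc(y, s):
    """All-pairs concordance count; ties score one half."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSelectFollowup:
    def _subject(self, months, score_at, ct_at):
        ct = np.full(3, 2.5)
        visits_mmse = [28.0 if m in score_at else None for m in months]
        s = make_subject("S", months=tuple(months), mmse=visits_mmse,
                         ct=[ct if m in ct_at else None for m in months])
        # make_subject wraps ct rows; rebuild None entries
        for v in s.visits:
            if v.month not in ct_at:
                v.ct = None
        return s

    def test_latest_complete_in_window(self):
        s = self._subject([0, 6, 12], {0, 6, 12}, {0, 6, 12})
        assert select_followup(s, "mmse").month == 12

    def test_falls_back_to_month_6_when_12_lacks_ct(self):
        s = self._subject([0, 6, 12], {0, 6, 12}, {0, 6})
        assert select_followup(s, "mmse").month == 6

    def test_baseline_only_gives_none(self):
        s = self._subject([0], {0}, {0})
        assert select_followup(s, "mmse") is None

    def test_visit_outside_window_ignored(self):
        s = self._subject([0, 18], {0, 18}, {0, 18})
        assert select_followup(s, "mmse") is None


class TestNestedCvSplit:
    def test_outer_folds_partition(self):
        y = np.array([0] * 60 + [1] * 40)
        folds = nested_cv_split(y, k=10, seed=0)
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test) == list(range(100))
        for f in folds:
            assert not set(f.train_idx) & set(f.test_idx)

    def test_single_cohort_stratification_counts(self):
        y = np.array([0] * 60 + [1] * 40)
        for f in nested_cv_split(y, k=10, seed=1):
            yt = y[f.test_idx]
            assert abs(np.sum(yt == 0) - 6) <= 1
            assert abs(np.sum(yt == 1) - 4) <= 1

    def test_joint_cohort_class_allocation_within_one(self):
        rng = np.random.default_rng(2)
        tags = np.where(rng.random(200) < 0.7, "ADNI", "AIBL")
        y = (rng.random(200) < 0.4).astype(int)
        k = 5
        folds = nested_cv_split(y, tags, k=k, seed=3)
        for tag in ("ADNI", "AIBL"):
            for c in (0, 1):
                cell = np.flatnonzero((tags == tag) & (y == c))
                expected = len(cell) / k
                for f in folds:
                    got = len(set(f.test_idx) & set(cell))
                    assert abs(got - expected) <= 1

    def test_inner_folds_stay_inside_outer_train(self):
        y = np.array([0, 1] * 50)
        folds = nested_cv_split(y, k=5, inner_k=3, seed=4)
        for f in folds:
            assert f.inner
            for tr, va in f.inner:
                assert set(tr) | set(va) <= set(f.train_idx)
                assert not set(tr) & set(va)

    def test_small_stratum_reported(self):
        y = np.array([0] * 98 + [1] * 2)
        with pytest.raises(ValueError, match="stratum"):
            nested_cv_split(y, k=10, seed=0)


class TestComputeMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        m = compute_metrics(y, y, s)
        assert m.accuracy == 1.0 and m.auc == 1.0

    def test_counted_pairs_example(self):
        # pos scores {0.9, 0.4}, neg {0.6, 0.1}: 3 of 4 pairs concordant
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.4, 0.6, 0.1])
        m = compute_metrics(y, (s > 0.5).astype(int), np.column_stack([1 - s, s]))
        assert m.auc == pytest.approx(0.75)

    @pytest.mark.parametrize("trial", range(20))
    def test_binary_auc_equals_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 2)  # coarse grid forces ties
        m = compute_metrics(y, (s > 0.5).astype(int), np.column_stack([1 - s, s]))
        assert m.auc == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_confusion_matrix_counting_oracle(self):
        rng = np.random.default_rng(7)
        y, p = rng.integers(0, 3, 100), rng.integers(0, 3, 100)
        m = compute_metrics(y, p, None, n_classes=3)
        for i in range(3):
            for j in range(3):
                assert m.confusion[i, j] == np.sum((y == i) & (p == j))
        assert m.accuracy == pytest.approx(np.trace(m.confusion) / 100)
        assert m.confusion.sum(axis=1).tolist() == [int(np.sum(y == i)) for i in range(3)]

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        m = compute_metrics(y, (s > 0.5).astype(int), np.column_stack([1 - s, s]))
        assert abs(m.auc - 0.5) < 0.04

    def test_single_class_truth_auc_missing_not_zero(self):
        y = np.zeros(5, dtype=int)
        s = np.random.default_rng(0).random((5, 2))
        assert compute_metrics(y, y, s).auc is None


class TestWorkflowGroups:
    def test_extreme_baseline_is_BE_regardless_of_followup(self):
        assert stratify_clinical_workflow(30, 10, "mmse") == "BE"
        assert stratify_clinical_workflow(20, 20, "mmse") == "BE"

    def test_midrange_no_change_is_CC(self):
        assert stratify_clinical_workflow(27, 27, "mmse") == "CC"

    def test_exhaustive_grid_matches_rule_table_and_partitions(self):
        t = DEFAULT_WORKFLOW_THRESHOLDS["mmse"]
        for s0, s1 in itertools.product(range(31), range(31)):
            got = stratify_clinical_workflow(s0, s1, "mmse", t)
            if s0 < t.low_baseline or s0 > t.high_baseline:
                expect = "BE"
            elif abs(s1 - s0) >= t.followup_change:
                expect = "FE"
            else:
                expect = "CC"
            assert got == expect

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            WorkflowThresholds(5, 40, 2).validate("mmse")


class TestSpanGroups:
    def _assignment(self, sid, months):
        return TrajectoryAssignment(subject_id=sid, label="stable",
                                    distances={"stable": 0.0}, months_used=months,
                                    span_months=max(months) - min(months))

    def test_near_and_distant_bands(self):
        a = [self._assignment("A", [0, 12, 24]), self._assignment("B", [0, 36, 72]),
             self._assignment("C", [0, 24, 36])]
        g = stratify_by_span(a)
        assert g == {"A": "near_future", "B": "distant_future", "C": "near_future"}

    def test_gap_between_bands_flagged(self):
        g = stratify_by_span([self._assignment("G", [0, 18, 40])])
        assert g["G"] is None

    def test_group_sizes_match_brute_force(self):
        rng = np.random.default_rng(6)
        asg = [self._assignment(f"S{i}", sorted({0, int(rng.integers(13, 73))} | {18}))
               for i in range(100)]
        g = stratify_by_span(asg)
        near = sum(1 for a in asg if max(a.months_used) <= 36)
        far = sum(1 for a in asg if max(a.months_used) >= 48)
        assert sum(v == "near_future" for v in g.values()) == near
        assert sum(v == "distant_future" for v in g.values()) == far


class TestCompareModels:
    def test_identical_samples_p_maximal(self):
        p = compare_models([0.8, 0.81, 0.79, 0.8, 0.82], [0.8, 0.81, 0.79, 0.8, 0.82])
        assert p > 0.65

    def test_exact_p_matches_full_permutation_enumeration(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [6.0, 7.0, 8.0, 9.0, 10.0]
        p = compare_models(a, b)
        # enumerate all C(10,5) allocations of the pooled ranks
        pooled = np.array(a + b)
        ranks = pooled.argsort().argsort() + 1

        def u_stat(idx_a):
            ra = ranks[list(idx_a)].sum()
            return ra - len(idx_a) * (len(idx_a) + 1) / 2

        observed = u_stat(range(5))
        n_extreme = 0
        combos = list(itertools.combinations(range(10), 5))
        for c in combos:
            u = u_stat(c)
            # two-sided: as or more extreme in either direction
            if min(u, 25 - u) <= min(observed, 25 - observed):
                n_extreme += 1
        assert p == pytest.approx(n_extreme / len(combos), abs=1e-12)

    def test_rejection_rate_under_shift_matches_reference(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(10)
        rej_ours, rej_ref = 0, 0
        trials = 300
        for _ in range(trials):
            a = rng.normal(0, 1, 8)
            b = rng.normal(1.2, 1, 8)
            rej_ours += compare_models(a, b) < 0.05
            rej_ref += mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue < 0.05
        se = np.sqrt(0.25 / trials)
        assert abs(rej_ours - rej_ref) / trials <= 3 * se

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1, 2], [3, 4, 5])


def small_inputs(n=60, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    inputs, y = [], []
    for i in range(n):
        label = i % 2
        base = rng.normal(2.5, 0.25, 78)
        drop = np.zeros(78)
        if label and signal:
            drop[:10] = 0.15
        inputs.append(PredictionInput(
            ct_t0=base, ct_t1=base - drop + rng.normal(0, 0.02, 78),
            score_t0=float(np.clip(rng.normal(27 - 2 * label * signal, 1), 0, 30)),
            score_t1=float(np.clip(rng.normal(27 - 3 * label * signal, 1), 0, 30)),
            age=float(rng.normal(73, 7)), apoe4=int(rng.integers(0, 3)),
        ))
        y.append(label)
    return inputs, np.array(y)


class TestRunExperiment:
    def test_smoke_run_and_report_invariants(self):
        inputs, y = small_inputs()
        ids = [f"S{i}" for i in range(len(y))]
        report = run_experiment(
            inputs, ids, y, ["stable", "decline"], "mmse",
            models=("LR", "LSN"), k=3, inner_folds=0, seed=0,
            grids=FAST_GRIDS, lsn_config=LSNConfig(max_epochs=40, seed=0),
        )
        assert set(report.cells) == {
            "LR|CA|baseline", "LR|CT|baseline", "LR|CA_CT|baseline",
            "LR|CA|baseline_followup", "LR|CT|baseline_followup",
            "LR|CA_CT|baseline_followup", "LSN|CA_CT|baseline_followup",
        }
        for cell in report.cells.values():
            assert cell.error is None
            assert cell.pooled_confusion.sum() == len(y)
            # confusion row sums equal per-class counts
            assert cell.pooled_confusion.sum(axis=1).tolist() == [
                int(np.sum(y == c)) for c in range(2)]
        # fold test sets partition the cohort
        flat = [s for fold in report.fold_membership["test"] for s in fold]
        assert sorted(flat) == sorted(ids)

    def test_group_metrics_equal_direct_recomputation(self):
        inputs, y = small_inputs(seed=2)
        ids = [f"S{i}" for i in range(len(y))]
        report = run_experiment(
            inputs, ids, y, ["stable", "decline"], "mmse",
            models=("RF",), k=3, inner_folds=0, seed=1, grids=FAST_GRIDS,
        )
        groups = {sid: ("even" if i % 2 == 0 else "odd") for i, sid in enumerate(ids)}
        cell = report.cells["RF|CA_CT|baseline_followup"]
        gm = report.group_metrics("RF|CA_CT|baseline_followup", groups)
        mask = np.array([i % 2 == 0 for i in range(len(ids))])
        direct = compute_metrics(cell.y_true[mask], cell.y_pred[mask],
                                 cell.scores[mask], n_classes=2)
        assert gm["even"].accuracy == direct.accuracy
        assert gm["even"].auc == direct.auc

    def test_bit_identical_reports_for_fixed_seed(self):
        inputs, y = small_inputs(seed=3)
        ids = [f"S{i}" for i in range(len(y))]
        kw = dict(models=("LR", "LSN"), k=3, inner_folds=0, seed=5,
                  grids=FAST_GRIDS, lsn_config=LSNConfig(max_epochs=30, seed=5))
        r1 = run_experiment(inputs, ids, y, ["s", "d"], "mmse", **kw)
        r2 = run_experiment(inputs, ids, y, ["s", "d"], "mmse", **kw)
        assert r1.to_json() == r2.to_json()

    def test_leakage_canary_garbage_test_rows_change_nothing(self):
        """Flipping test-fold labels must not affect training or selection.

        Canary copies of the test subjects carry inverted labels; if any
        test-fold label reached standardization, grid search, or the fit,
        the predictions for those subjects would shift.
        """
        inputs, y = small_inputs(seed=4)
        folds = [Fold(train_idx=np.arange(0, 40), test_idx=np.arange(40, 60))]
        spec = FeatureSpec("CA_CT", "baseline_followup", "mmse")
        pred_clean, _, _ = _fit_predict_cell(
            "SVM", spec, inputs, y, folds, 2, seed=0, grids=FAST_GRIDS,
            lsn_config=None, inner_folds=3)
        poisoned = list(inputs)
        rng = np.random.default_rng(99)
        for i in range(40, 60):
            x = inputs[i]
            poisoned[i] = PredictionInput(
                ct_t0=x.ct_t0, ct_t1=x.ct_t1, score_t0=x.score_t0,
                score_t1=x.score_t1, age=x.age, apoe4=x.apoe4)
        # flip canary labels too: training must never see them
        y_poisoned = y.copy()
        y_poisoned[40:60] = 1 - y_poisoned[40:60]
        pred_poisoned, _, _ = _fit_predict_cell(
            "SVM", spec, poisoned, y_poisoned, folds, 2, seed=0, grids=FAST_GRIDS,
            lsn_config=None, inner_folds=3)
        # identical inputs at test rows, flipped labels: predictions identical
        assert np.array_equal(pred_clean[40:60], pred_poisoned[40:60])

    def test_per_cell_failure_logged_not_raised(self):
        inputs, y = small_inputs(n=30, seed=5)
        ids = [f"S{i}" for i in range(len(y))]
        # drop follow-up CT so two-timepoint CT cells fail while others run
        for x in inputs:
            x.ct_t1 = None
        report = run_experiment(
            inputs, ids, y, ["s", "d"], "mmse",
            models=("LR",), k=3, inner_folds=0, seed=0, grids=FAST_GRIDS,
        )
        assert report.cells["LR|CT|baseline_followup"].error is not None
        assert report.cells["LR|CA|baseline"].error is None
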