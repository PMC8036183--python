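"""Cross-validation, confusion metrics, majority voting, external test."""

import numpy as np
import pytest

import amycnn as a
from conftest import make_stack


class TestStratifiedKFold:
    def _labels(self, n_neg, n_pos):
        d = {f"n{i}": 0 for i in range(n_neg)}
        d.update({f"p{i}": 1 for i in range(n_pos)})
        return d

    def test_cohort_fold_sizes_and_stratification(self):
        """101 negatives / 32 positives into 5 folds: totals
        {27, 27, 27, 26, 26} and 6 or 7 positives per fold."""
        folds = a.stratified_kfold(self._labels(101, 32), k=5, rng_seed=0)
        labels = self._labels(101, 32)
        sizes = sorted(len(folds.fold_ids(f)) for f in range(5))
        assert sizes == [26, 26, 27, 27, 27]
        pos_per_fold = [sum(labels[s] for s in folds.fold_ids(f))
                        for f in range(5)]
        assert set(pos_per_fold) <= {6, 7} and sum(pos_per_fold) == 32

    def test_balanced_tiny_case(self):
        folds = a.stratified_kfold(self._labels(5, 5), k=5, rng_seed=1)
        for f in range(5):
            ids = folds.fold_ids(f)
            assert len(ids) == 2 and sum(self._labels(5, 5)[s] for s in ids) == 1

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(ValueError, match="fewer than k"):
            a.stratified_kfold(self._labels(10, 4), k=5, rng_seed=0)

    @pytest.mark.parametrize("seed", [0, 3, 17, 255])
    def test_partition_property_any_seed(self, seed):
        """Every scan lands in exactly one fold; per-fold class counts stay
        within +/-1 of proportional allocation."""
        labels = self._labels(23, 11)
        folds = a.stratified_kfold(labels, k=4, rng_seed=seed)
        all_ids = [sid for f in range(4) for sid in folds.fold_ids(f)]
        assert sorted(all_ids) == sorted(labels)
        for cls, total in ((0, 23), (1, 11)):
            for f in range(4):
                n = sum(1 for s in folds.fold_ids(f) if labels[s] == cls)
                assert np.floor(total / 4) <= n <= np.ceil(total / 4)

    def test_deterministic_per_seed(self):
        l = self._labels(12, 8)
        f1 = a.stratified_kfold(l, k=4, rng_seed=9)
        f2 = a.stratified_kfold(l, k=4, rng_seed=9)
        assert f1.fold_index == f2.fold_index


class TestConfusionMetrics:
    def test_external_cohort_worked_example(self):
        """13 negatives with one false positive, 9 positives all caught:
        accuracy 95.0%, sensitivity 100.0%, specificity 92.3%."""
        true = [0] * 13 + [1] * 9
        pred = [1] + [0] * 12 + [1] * 9
        m = a.confusion_metrics(pred, true)
        assert m.sensitivity == pytest.approx(100.0)
        assert m.specificity == pytest.approx(92.3, abs=0.05)
        assert m.accuracy == pytest.approx(100 * 21 / 22, abs=1e-9)
        assert (m.tp, m.fp, m.tn, m.fn) == (9, 1, 12, 0)

    def test_all_correct(self):
        m = a.confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m.accuracy, m.sensitivity, m.specificity) == (100, 100, 100)

    def test_matches_bruteforce_counting(self, rng):
        """1,000 random prediction/truth vectors against an explicit loop."""
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            pred = rng.integers(0, 2, n)
            true = rng.integers(0, 2, n)
            m = a.confusion_metrics(pred, true)
            tp = fp = tn = fn = 0
            for p, t in zip(pred, true):
                if p == 1 and t == 1:
                    tp += 1
                elif p == 1 and t == 0:
                    fp += 1
                elif p == 0 and t == 0:
                    tn += 1
                else:
                    fn += 1
            assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix
        pred = rng.integers(0, 2, 200)
        true = rng.integers(0, 2, 200)
        m = a.confusion_metrics(pred, true)
        tn, fp, fn, tp = confusion_matrix(true, pred).ravel()
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)

    def test_degenerate_metrics_undefined(self):
        m = a.confusion_metrics([0, 0], [0, 0])
        assert m.sensitivity is None and m.specificity == 100.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            a.confusion_metrics([0, 1], [0])


class TestMajorityVote:
    def test_two_of_three_positive(self):
        assert a.majority_vote(0.9, 0.8, 0.2) == 1

    def test_none_positive(self):
        assert a.majority_vote(0.1, 0.2, 0.3) == 0

    def test_all_eight_patterns_match_mode(self):
        for bits in range(8):
            votes = [(bits >> i) & 1 for i in range(3)]
            probs = [0.9 if v else 0.1 for v in votes]
            expected = int(sum(votes) >= 2)  # mode of binary votes
            assert a.majority_vote(*probs) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="probability"):
            a.majority_vote(1.2, 0.5, 0.5)


class TestCVResultAggregation:
    def _metrics(self, tp, fp, tn, fn):
        return a.Metrics(tp=tp, fp=fp, tn=tn, fn=fn)

    def test_mean_equals_arithmetic_mean(self):
        folds = [self._metrics(5, 0, 20, 1), self._metrics(6, 1, 19, 0),
                 self._metrics(6, 0, 20, 0)]
        r = a.CVResult(fold_metrics=folds, probabilities={}, fold_of={})
        expected = np.mean([m.accuracy for m in folds])
        assert r.mean_accuracy == pytest.approx(expected, abs=1e-12)
        assert r.sd_accuracy == pytest.approx(
            np.std([m.accuracy for m in folds], ddof=1), abs=1e-12)

    def test_constant_metric_sd_zero(self):
        folds = [self._metrics(6, 0, 20, 0)] * 5
        r = a.CVResult(fold_metrics=folds, probabilities={}, fold_of={})
        assert r.mean_specificity == 100.0 and r.sd_specificity == 0.0

    def test_undefined_fold_excluded_from_mean(self):
        folds = [self._metrics(0, 0, 10, 0),  # no positives: sens undefined
                 self._metrics(5, 0, 5, 0)]
        r = a.CVResult(fold_metrics=folds, probabilities={}, fold_of={})
        assert r.mean_sensitivity == 100.0


@pytest.fixture(scope="module")
def small_cv(tiny_separable_dataset):
    labels = {s.scan_id: lab for s, lab in tiny_separable_dataset.items}
    folds = a.stratified_kfold(labels, k=3, rng_seed=5)
    cfg = a.CNNConfig(conv_filters=(4, 4, 8, 8), epochs=120, rng_seed=5)
    return a.run_cv(tiny_separable_dataset, "sagittal", cfg, folds)


class TestRunCVAndExternal:
    def test_one_model_per_fold(self, small_cv):
        assert len(small_cv.models) == 3
        assert len(small_cv.fold_metrics) == 3

    def test_every_scan_scored_once(self, small_cv, tiny_separable_dataset):
        assert set(small_cv.probabilities) \
            == {s.scan_id for s, _ in tiny_separable_dataset.items}

    def test_separable_cohort_classified_perfectly(self, small_cv):
        assert small_cv.mean_accuracy == 100.0
        assert small_cv.sd_accuracy == 0.0

    def test_rerun_identical(self, tiny_separable_dataset, small_cv):
        labels = {s.scan_id: lab for s, lab in tiny_separable_dataset.items}
        folds = a.stratified_kfold(labels, k=3, rng_seed=5)
        cfg = a.CNNConfig(conv_filters=(4, 4, 8, 8), epochs=120, rng_seed=5)
        again = a.run_cv(tiny_separable_dataset, "sagittal", cfg, folds,
                         keep_models=False)
        assert again.probabilities == small_cv.probabilities
        assert [m.as_dict() for m in again.fold_metrics] \
            == [m.as_dict() for m in small_cv.fold_metrics]

    def test_external_evaluation_ensemble(self, small_cv):
        spec = a.PhantomSpec(grid_shape=(16, 16, 12), noise_cv=0.05,
                             between_subject_sd=0.0)
        test_scans = a.generate_cohort(spec, 3, 2, seed=77)
        test_ds = a.scans_to_suvr_datasets(test_scans,
                                           ("sagittal",))["sagittal"]
        metrics, probs = a.evaluate_external(small_cv.models, test_ds)
        assert len(probs) == 5
        assert metrics.n == 5
        assert metrics.accuracy == 100.0

    def test_external_empty_raises(self, small_cv):
        with pytest.raises(ValueError, match="empty"):
            a.evaluate_external(small_cv.models, a.Dataset(items=[]))

    def test_external_single_scan_defined(self, small_cv,
                                          tiny_separable_dataset):
        one = a.Dataset(items=tiny_separable_dataset.items[:1])
        metrics, probs = a.evaluate_external(small_cv.models[0], one)
        assert metrics.n == 1 and len(probs) == 1
        assert metrics.accuracy in (0.0, 100.0)


def test_select_best_axis_ranking():
    def result(acc, sens, spec):
        m = a.Metrics(tp=0, fp=0, tn=1, fn=0)
        r = a.CVResult(fold_metrics=[m], probabilities={}, fold_of={})
        # bypass computed properties via a stub
        class Stub:
            mean_accuracy, mean_sensitivity, mean_specificity = acc, sens, spec
        return Stub()
    results = {"axial": result(97.0, 87.0, 100.0),
               "coronal": result(95.0, 83.0, 99.0),
               "sagittal": result(99.0, 97.0, 100.0)}
    assert a.select_best_axis(results) == "sagittal"
    results["axial"] = result(99.0, 98.0, 100.0)
    assert a.select_best_axis(results) == "axial"  # tie on accuracy: sens
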