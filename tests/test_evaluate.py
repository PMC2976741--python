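"""Metric identities, partition hygiene, balancing, and the CV protocol."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hypowatch.evaluate import (
    ExperimentConfig,
    auc_rank,
    balance_by_subsampling,
    classification_metrics,
    partition_by_record,
    regression_metrics,
    run_experiment,
)
from hypowatch.windows import WindowSpec, compile_multiple


class TestPartition:
    def _examples(self, n_records, per_record=3):
        from conftest import make_flat_record

        out = []
        for i in range(n_records):
            record = make_flat_record(300, record_id=f"r{i}")
            out.extend(compile_multiple(record, WindowSpec(30, 60)))
        return out

    def test_ten_records_five_folds_two_each(self):
        examples = self._examples(10)
        folds = partition_by_record(examples, 5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert (counts == 2).all()

    def test_no_record_in_two_folds(self):
        examples = self._examples(7)
        folds = partition_by_record(examples, 3, seed=1)
        assert set(folds) == {f"r{i}" for i in range(7)}
        assert all(isinstance(v, int) for v in folds.values())

    def test_seed_determinism(self):
        examples = self._examples(9)
        assert partition_by_record(examples, 4, seed=5) == partition_by_record(
            examples, 4, seed=5
        )

    def test_too_few_records_rejected(self):
        examples = self._examples(3)
        with pytest.raises(ValueError, match="distinct records"):
            partition_by_record(examples, 5, seed=0)


class TestBalancing:
    def _mixed(self, n_ctrl, n_hypo):
        from hypowatch.windows import LabeledExample

        def make(i, label):
            return LabeledExample(
                record_id=f"r{i}",
                target_start=90,
                label=label,
                target_median_map=55.0 if label == "hypotensive" else 80.0,
                obs_slices={},
            )

        return [make(i, "control") for i in range(n_ctrl)] + [
            make(1000 + i, "hypotensive") for i in range(n_hypo)
        ]

    def test_hundred_to_ten_gives_twenty(self):
        balanced = balance_by_subsampling(self._mixed(100, 10), seed=0)
        assert len(balanced) == 20
        assert sum(ex.is_hypotensive for ex in balanced) == 10

    def test_already_balanced_unchanged_up_to_order(self):
        examples = self._mixed(5, 5)
        balanced = balance_by_subsampling(examples, seed=1)
        assert sorted(ex.record_id for ex in balanced) == sorted(
            ex.record_id for ex in examples
        )

    def test_sample_without_replacement(self):
        balanced = balance_by_subsampling(self._mixed(50, 30), seed=2)
        ids = [ex.record_id for ex in balanced if not ex.is_hypotensive]
        assert len(ids) == len(set(ids)) == 30

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balance_by_subsampling(self._mixed(10, 0), seed=0)


class TestClassificationMetrics:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auc_rank(scores, labels) == 1.0

    def test_confusion_matrix_arithmetic(self):
        """TP 10, FP 90, TN 810, FN 2 -> PPV 0.1, sensitivity 10/12."""
        scores = np.concatenate(
            [np.full(10, 0.9), np.full(2, 0.1), np.full(90, 0.9), np.full(810, 0.1)]
        )
        labels = np.concatenate([np.ones(12), np.zeros(900)]).astype(int)
        m = classification_metrics(scores, labels, threshold=0.5)
        assert m["ppv"] == pytest.approx(0.1)
        assert m["sensitivity"] == pytest.approx(10 / 12)
        assert m["specificity"] == pytest.approx(810 / 900)
        assert m["npv"] == pytest.approx(810 / 812)
        assert m["accuracy"] == pytest.approx(820 / 912)

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_auc_equals_trapezoidal(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        labels = (rng.random(n) < 0.3).astype(int)
        labels[:2] = [0, 1]
        scores = rng.random(n).round(2)  # duplicate scores exercise tie handling
        assert auc_rank(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-10
        )

    def test_ppv_prevalence_identity(self):
        """PPV = sens*p / (sens*p + (1-spec)(1-p)) on synthetic confusion matrices."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_pos = int(rng.integers(5, 50))
            n_neg = int(rng.integers(50, 2000))
            tp = int(rng.integers(1, n_pos + 1))
            fp = int(rng.integers(1, n_neg))
            scores = np.concatenate([
                np.full(tp, 0.9), np.full(n_pos - tp, 0.1),
                np.full(fp, 0.9), np.full(n_neg - fp, 0.1),
            ])
            labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(int)
            m = classification_metrics(scores, labels, threshold=0.5)
            p = n_pos / (n_pos + n_neg)
            sens, spec = m["sensitivity"], m["specificity"]
            expected_ppv = sens * p / (sens * p + (1 - spec) * (1 - p))
            assert m["ppv"] == pytest.approx(expected_ppv, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            auc_rank(np.array([0.5, 0.6]), np.array([1, 1]))


class TestRegressionMetrics:
    def test_perfect_fit(self):
        y = np.array([60.0, 75.0, 90.0, 105.0])
        m = regression_metrics(y, y)
        assert m["mae_pct"] == 0.0
        assert m["pearson_r"] == pytest.approx(1.0)
        assert m["slope"] == pytest.approx(1.0, abs=1e-8)
        assert m["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_mae_hand_arithmetic(self):
        m = regression_metrics(np.array([50.0, 90.0, 80.0]), np.array([100.0, 90.0, 80.0]))
        assert m["mae_pct"] == pytest.approx(50.0 / 3)

    def test_bisquare_resists_gross_outlier(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(60, 100, 60)
        pred = 1.5 * y - 10.0
        pred_out = pred.copy()
        pred_out[0] = 500.0  # one gross outlier
        robust = regression_metrics(pred_out, y)["slope"]
        ols = np.polyfit(y, pred_out, 1)[0]
        assert robust == pytest.approx(1.5, rel=0.01)
        assert abs(ols - 1.5) > abs(robust - 1.5)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            regression_metrics(np.ones(3), np.array([1.0, 0.0, 2.0]))

    def test_length_contract(self):
        with pytest.raises(ValueError, match="length"):
            regression_metrics(np.ones(2), np.ones(2))


class TestRunExperiment:
    def test_protocol_shape_and_hygiene(self, clean_cohort):
        config = ExperimentConfig(
            spec=WindowSpec(30, 60), mode="multiple", task="classification",
            n_folds=3, n_subsamples=2, seed=0,
        )
        report = run_experiment(clean_cohort.records, config)
        assert len(report.runs) == 6  # n_folds * n_subsamples
        assert set(report.runs["fold"]) == {0, 1, 2}
        agg = report.aggregate
        assert (agg["sd"].dropna() >= 0).all()
        finite = report.runs["auc"].dropna()
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_single_mode_runs(self, clean_cohort):
        config = ExperimentConfig(
            spec=WindowSpec(30, 60), mode="single", task="classification",
            n_folds=3, n_subsamples=2, seed=1,
        )
        report = run_experiment(clean_cohort.records, config)
        assert report.n_examples <= len(clean_cohort.records)
        assert len(report.runs) == 6

    def test_regression_task(self, clean_cohort):
        config = ExperimentConfig(
            spec=WindowSpec(30, 60), mode="multiple", task="regression",
            n_folds=3, n_subsamples=2, regression_train_size=200, seed=2,
        )
        report = run_experiment(clean_cohort.records, config)
        assert {"mae_pct", "pearson_r", "slope", "intercept"} <= set(report.runs.columns)
        assert (report.runs["mae_pct"].dropna() >= 0).all()

    def test_summary_mentions_protocol(self, clean_cohort):
        config = ExperimentConfig(
            spec=WindowSpec(30, 60), mode="multiple", task="classification",
            n_folds=3, n_subsamples=2, seed=0,
        )
        text = run_experiment(clean_cohort.records, config).summary()
        assert "classification" in text and "auc" in text
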