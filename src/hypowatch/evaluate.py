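"""Record-level cross-validated evaluation with balanced sub-sampling.

The protocol: records (never individual examples) are split into folds, so
examples from one ICU stay are exclusively training or test. Within each
fold's training set, class imbalance is handled — for classification — by
sampling the majority (control) class without replacement down to the
minority size, repeated ``n_subsamples`` times; the test set keeps its
natural prevalence. For regression a fixed-size training subset is redrawn
instead. Normalization + PCA are refit for every training-set variant.

Metrics per run: AUC (rank statistic), accuracy, sensitivity, specificity,
PPV, NPV for classification; percentage mean absolute error
``(1/N) sum |yhat_i - y_i| / y_i * 100``, Pearson r, and the slope and
intercept of a bisquare-reweighted robust line (predicted vs. true) for
regression. Aggregates are mean ± SD over all fold × sub-sample runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .features import extract_features
from .models import predict_map, predict_probability, train_classifier, train_regressor
from .records import HemodynamicRecord
from .reduce import apply_reducer, fit_reducer
from .windows import LabeledExample, WindowSpec, compile_multiple, compile_single

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "partition_by_record",
    "balance_by_subsampling",
    "classification_metrics",
    "regression_metrics",
    "auc_rank",
    "run_experiment",
]

logger = logging.getLogger(__name__)

CLASSIFICATION_METRICS = ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv")
REGRESSION_METRICS = ("mae_pct", "pearson_r", "slope", "intercept")


@dataclass(frozen=True)
class ExperimentConfig:
    """The cross-validation protocol; defaults follow the study design."""

    spec: WindowSpec = field(default_factory=WindowSpec)
    mode: str = "multiple"  # "single" | "multiple"
    task: str = "classification"  # "classification" | "regression"
    n_folds: int = 5
    n_subsamples: int = 10
    regression_train_size: int = 2500  # multiple mode only
    variance_target: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multiple"):
            raise ValueError(f"mode must be 'single' or 'multiple', got {self.mode!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_folds < 2 or self.n_subsamples < 1:
            raise ValueError("need n_folds >= 2 and n_subsamples >= 1")


def partition_by_record(
    examples: list[LabeledExample], n_folds: int, seed: int
) -> dict[str, int]:
    """Randomly assign each record id to one of ``n_folds`` near-equal folds."""
    record_ids = sorted({ex.record_id for ex in examples})
    if len(record_ids) < n_folds:
        raise ValueError(
            f"need >= {n_folds} distinct records, got {len(record_ids)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(record_ids))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[record_ids[idx]] = pos % n_folds
    return assignment


def balance_by_subsampling(
    train_examples: list[LabeledExample], seed: int
) -> list[LabeledExample]:
    """All minority-class examples plus an equal-size majority sample.

    The majority sample is drawn without replacement; output order is
    minority then sampled majority.
    """
    hypo = [ex for ex in train_examples if ex.is_hypotensive]
    ctrl = [ex for ex in train_examples if not ex.is_hypotensive]
    if not hypo or not ctrl:
        raise ValueError("balancing requires both classes in the training set")
    minority, majority = (hypo, ctrl) if len(hypo) <= len(ctrl) else (ctrl, hypo)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(majority), size=len(minority), replace=False)
    return list(minority) + [majority[i] for i in picked]


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney U) statistic, with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """AUC plus the confusion-matrix metrics at ``threshold``.

    PPV/NPV are NaN when no positive/negative call is made (degenerate
    confusion matrix); callers exclude NaNs from aggregation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    called = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int((called & pos).sum())
    fp = int((called & neg).sum())
    tn = int((~called & neg).sum())
    fn = int((~called & pos).sum())
    return {
        "auc": auc_rank(scores, labels),
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def regression_metrics(predicted: np.ndarray, true: np.ndarray) -> dict[str, float]:
    """Percentage MAE, Pearson r, and the robust (bisquare) line fit.

    The robust line regresses predicted on true MAP by iteratively
    reweighted least squares with Tukey's biweight; a perfect regressor
    gives slope 1, intercept 0.
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape or len(true) < 3:
        raise ValueError("regression metrics need matching arrays of length >= 3")
    if np.any(true <= 0):
        raise ValueError("true MAP values must be positive (MAE is relative)")
    mae = float(np.mean(np.abs(predicted - true) / true) * 100.0)
    r = float(stats.pearsonr(predicted, true).statistic)
    rlm = sm.RLM(predicted, sm.add_constant(true), M=sm.robust.norms.TukeyBiweight())
    fit = rlm.fit()
    intercept, slope = (float(v) for v in fit.params)
    return {"mae_pct": mae, "pearson_r": r, "slope": slope, "intercept": intercept}


@dataclass
class EvaluationReport:
    """Per-run metrics and their mean ± SD aggregate."""

    runs: pd.DataFrame  # one row per fold x sub-sample
    config: ExperimentConfig
    n_examples: int
    prevalence: float

    @property
    def metric_names(self) -> tuple[str, ...]:
        return (
            CLASSIFICATION_METRICS
            if self.config.task == "classification"
            else REGRESSION_METRICS
        )

    @property
    def aggregate(self) -> pd.DataFrame:
        """Mean and sample SD per metric over all runs (NaN runs excluded)."""
        cols = list(self.metric_names)
        return pd.DataFrame(
            {"mean": self.runs[cols].mean(), "sd": self.runs[cols].std(ddof=1)}
        )

    def summary(self) -> str:
        lines = [
            f"{self.config.task} | mode={self.config.mode} "
            f"obs={self.config.spec.obs_minutes} gap={self.config.spec.gap_minutes}",
            f"examples={self.n_examples} (hypotensive prevalence {self.prevalence:.3%}) "
            f"runs={len(self.runs)}",
            f"{'metric':<12}{'mean':>9}{'sd':>9}",
        ]
        agg = self.aggregate
        for name in self.metric_names:
            lines.append(f"{name:<12}{agg.loc[name, 'mean']:>9.3f}{agg.loc[name, 'sd']:>9.3f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "config": asdict(self.config),
            "n_examples": self.n_examples,
            "prevalence": self.prevalence,
            "runs": self.runs.to_dict(orient="records"),
            "aggregate": {
                name: {
                    "mean": float(self.aggregate.loc[name, "mean"]),
                    "sd": float(self.aggregate.loc[name, "sd"]),
                }
                for name in self.metric_names
            },
        }


def compile_cohort(
    records: list[HemodynamicRecord], config: ExperimentConfig
) -> list[LabeledExample]:
    """Compile every record under the configured mode and window geometry."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(records))
    examples: list[LabeledExample] = []
    for record, seq in zip(records, seeds):
        if config.mode == "multiple":
            examples.extend(compile_multiple(record, config.spec))
        else:
            one = compile_single(record, config.spec, int(seq.generate_state(1)[0] % 2**31))
            if one is not None:
                examples.append(one)
    return examples


def _feature_matrix(
    examples: list[LabeledExample], records: list[HemodynamicRecord]
) -> np.ndarray:
    by_id = {r.record_id: r for r in records}
    return np.array([extract_features(ex, by_id[ex.record_id]) for ex in examples])


def run_experiment(
    records: list[HemodynamicRecord], config: ExperimentConfig
) -> EvaluationReport:
    """The full protocol: compile, partition, balance, train, evaluate.

    Per fold and sub-sample: the reducer is refit on that run's training
    variant, a fresh network is trained, and the fold's untouched (unbalanced)
    test examples are scored. Runs whose test fold lacks a class are recorded
    as NaN (with a warning) and excluded from aggregation.
    """
    examples = compile_cohort(records, config)
    if not examples:
        raise ValueError("cohort compiled to an empty example set")
    labels = np.array([int(ex.is_hypotensive) for ex in examples])
    if config.task == "classification" and len(np.unique(labels)) < 2:
        raise ValueError("cohort contains a single class; classification impossible")

    features = _feature_matrix(examples, records)
    targets = np.array([ex.target_median_map for ex in examples])

    root = np.random.SeedSequence(config.seed)
    part_seed, run_root = root.spawn(2)
    fold_of_record = partition_by_record(
        examples, config.n_folds, int(part_seed.generate_state(1)[0] % 2**31)
    )
    fold_of_example = np.array([fold_of_record[ex.record_id] for ex in examples])
    run_seeds = run_root.spawn(config.n_folds * config.n_subsamples)

    rows = []
    for fold in range(config.n_folds):
        train_mask = fold_of_example != fold
        test_mask = ~train_mask
        test_records = {ex.record_id for ex, m in zip(examples, test_mask) if m}
        train_records = {ex.record_id for ex, m in zip(examples, train_mask) if m}
        assert not test_records & train_records  # record-level hygiene
        for sub in range(config.n_subsamples):
            seq = run_seeds[fold * config.n_subsamples + sub]
            sub_seed, net_seed = (int(s % 2**31) for s in seq.generate_state(2))
            row = {"fold": fold, "subsample": sub}
            try:
                if config.task == "classification":
                    row.update(
                        _classification_run(
                            examples, features, labels, train_mask, test_mask,
                            config, sub_seed, net_seed,
                        )
                    )
                else:
                    row.update(
                        _regression_run(
                            features, targets, train_mask, test_mask,
                            config, sub_seed, net_seed,
                        )
                    )
            except ValueError as exc:
                logger.warning("fold %d sub %d undefined: %s", fold, sub, exc)
                row.update({name: float("nan") for name in (
                    CLASSIFICATION_METRICS if config.task == "classification" else REGRESSION_METRICS
                )})
            rows.append(row)

    return EvaluationReport(
        runs=pd.DataFrame(rows),
        config=config,
        n_examples=len(examples),
        prevalence=float(labels.mean()),
    )


def _classification_run(
    examples, features, labels, train_mask, test_mask, config, sub_seed, net_seed
) -> dict[str, float]:
    train_idx = np.flatnonzero(train_mask)
    train_examples = [examples[i] for i in train_idx]
    balanced = balance_by_subsampling(train_examples, sub_seed)
    pos_of = {id(ex): i for ex, i in zip(examples, range(len(examples)))}
    bal_idx = np.array([pos_of[id(ex)] for ex in balanced])
    reducer = fit_reducer(features[bal_idx], config.variance_target)
    model = train_classifier(
        apply_reducer(reducer, features[bal_idx]), labels[bal_idx], net_seed
    )
    test_idx = np.flatnonzero(test_mask)
    scores = predict_probability(model, apply_reducer(reducer, features[test_idx]))
    return classification_metrics(scores, labels[test_idx], model.threshold)


def _regression_run(
    features, targets, train_mask, test_mask, config, sub_seed, net_seed
) -> dict[str, float]:
    train_idx = np.flatnonzero(train_mask)
    if config.mode == "multiple" and len(train_idx) > config.regression_train_size:
        rng = np.random.default_rng(sub_seed)
        train_idx = train_idx[
            rng.choice(len(train_idx), size=config.regression_train_size, replace=False)
        ]
    reducer = fit_reducer(features[train_idx], config.variance_target)
    model = train_regressor(
        apply_reducer(reducer, features[train_idx]), targets[train_idx], net_seed
    )
    test_idx = np.flatnonzero(test_mask)
    predicted = predict_map(model, apply_reducer(reducer, features[test_idx]))
    return regression_metrics(predicted, targets[test_idx])
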