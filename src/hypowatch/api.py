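"""Model/Results front end tying the pipeline together.

``HypotensionModel`` is constructed from a cohort of records plus the window
geometry and compilation mode; ``fit`` compiles the labeled examples,
extracts the 102 features, fits the normalization + PCA reducer, and trains
the classifier/regressor pair, returning a ``HypotensionResults`` that can
score new records minute-by-minute and print a summary. ``cross_validate``
runs the full record-level CV protocol and returns an
:class:`~hypowatch.evaluate.EvaluationReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluate import (
    EvaluationReport,
    ExperimentConfig,
    balance_by_subsampling,
    compile_cohort,
    run_experiment,
)
from .features import extract_features
from .models import (
    ClassifierModel,
    RegressorModel,
    predict_map,
    predict_probability,
    train_classifier,
    train_regressor,
)
from .records import HemodynamicRecord, list_record_prefixes, read_record
from .reduce import FittedReducer, apply_reducer, fit_reducer
from .windows import WindowSpec
from . import monitor as _monitor

__all__ = ["HypotensionModel", "HypotensionResults"]


class HypotensionModel:
    """Impending-hypotension prediction on minute-by-minute hemodynamics."""

    def __init__(
        self,
        records: list[HemodynamicRecord],
        window_spec: WindowSpec | None = None,
        mode: str = "multiple",
        variance_target: float = 0.90,
    ):
        if mode not in ("single", "multiple"):
            raise ValueError(f"mode must be 'single' or 'multiple', got {mode!r}")
        self.records = list(records)
        self.window_spec = window_spec or WindowSpec()
        self.mode = mode
        self.variance_target = variance_target

    @classmethod
    def from_directory(cls, path, **kwargs) -> "HypotensionModel":
        records = [read_record(p) for p in list_record_prefixes(path)]
        if not records:
            raise ValueError(f"no record bundles found under {path}")
        return cls(records, **kwargs)

    def _base_config(self, seed: int) -> ExperimentConfig:
        return ExperimentConfig(
            spec=self.window_spec,
            mode=self.mode,
            variance_target=self.variance_target,
            seed=seed,
        )

    def fit(self, seed: int = 0, regression_train_size: int = 2500) -> "HypotensionResults":
        """Train one classifier/regressor pair on the whole cohort.

        The classifier is trained on one balanced sub-sample (all hypotensive
        examples plus an equal-size control draw); the regressor on up to
        ``regression_train_size`` examples. Both share one reducer fitted on
        the balanced set, so a single projection serves both at monitoring
        time.
        """
        config = self._base_config(seed)
        examples = compile_cohort(self.records, config)
        if not examples:
            raise ValueError("cohort compiled to an empty example set")
        by_id = {r.record_id: r for r in self.records}
        root = np.random.SeedSequence(seed)
        bal_seed, net_seed, reg_seed, sub_seed = (
            int(s % 2**31) for s in root.generate_state(4)
        )

        balanced = balance_by_subsampling(examples, bal_seed)
        X_bal = np.array([extract_features(ex, by_id[ex.record_id]) for ex in balanced])
        y_bal = np.array([int(ex.is_hypotensive) for ex in balanced])
        reducer = fit_reducer(X_bal, self.variance_target)
        classifier = train_classifier(apply_reducer(reducer, X_bal), y_bal, net_seed)

        reg_examples = examples
        if len(reg_examples) > regression_train_size:
            rng = np.random.default_rng(sub_seed)
            idx = rng.choice(len(reg_examples), size=regression_train_size, replace=False)
            reg_examples = [reg_examples[i] for i in idx]
        X_reg = np.array([extract_features(ex, by_id[ex.record_id]) for ex in reg_examples])
        t_reg = np.array([ex.target_median_map for ex in reg_examples])
        regressor = train_regressor(apply_reducer(reducer, X_reg), t_reg, reg_seed)

        return HypotensionResults(
            model=self,
            reducer=reducer,
            classifier=classifier,
            regressor=regressor,
            n_examples=len(examples),
            n_hypotensive=sum(ex.is_hypotensive for ex in examples),
            seed=seed,
        )

    def cross_validate(
        self,
        task: str = "classification",
        n_folds: int = 5,
        n_subsamples: int = 10,
        seed: int = 0,
        regression_train_size: int = 2500,
    ) -> EvaluationReport:
        """Record-level cross-validation with balanced sub-sampling."""
        config = replace(
            self._base_config(seed),
            task=task,
            n_folds=n_folds,
            n_subsamples=n_subsamples,
            regression_train_size=regression_train_size,
        )
        return run_experiment(self.records, config)


@dataclass
class HypotensionResults:
    """A fitted classifier/regressor pair and everything needed to apply it."""

    model: HypotensionModel
    reducer: FittedReducer
    classifier: ClassifierModel
    regressor: RegressorModel
    n_examples: int
    n_hypotensive: int
    seed: int

    def predict_examples(self, examples, records) -> tuple[np.ndarray, np.ndarray]:
        """(probability, predicted median MAP) for compiled examples."""
        by_id = {r.record_id: r for r in records}
        X = np.array([extract_features(ex, by_id[ex.record_id]) for ex in examples])
        reduced = apply_reducer(self.reducer, X)
        return predict_probability(self.classifier, reduced), predict_map(
            self.regressor, reduced
        )

    def monitor(self, record: HemodynamicRecord) -> _monitor.MonitorTrace:
        """Minute-by-minute continuous prediction over one record."""
        return _monitor.continuous_predict(
            record, self.classifier, self.regressor, self.reducer, self.model.window_spec
        )

    def summary(self) -> str:
        spec = self.model.window_spec
        lines = [
            "HypotensionModel results",
            "========================",
            f"compilation mode      : {self.model.mode}",
            f"observation window    : {spec.obs_minutes} min",
            f"gap (lead time)       : {spec.gap_minutes} min",
            f"examples compiled     : {self.n_examples} "
            f"({self.n_hypotensive} hypotensive, "
            f"prevalence {self.n_hypotensive / self.n_examples:.3%})",
            f"PCA components kept   : {self.reducer.k} "
            f"({self.reducer.cumulative_variance:.1%} of variance)",
            f"decision threshold    : {self.classifier.threshold:.3f}",
            f"classifier epochs     : {self.classifier.epochs_run} "
            f"({self.classifier.stopping_reason})",
            f"regressor epochs      : {self.regressor.epochs_run} "
            f"({self.regressor.stopping_reason})",
            f"seed                  : {self.seed}",
        ]
        return "\n".join(lines)
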