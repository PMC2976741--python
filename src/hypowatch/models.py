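"""Feed-forward networks for hypotension classification and MAP regression.

Both tasks share one small 3-layer topology: k reduced features -> 20 hidden
units -> 1 output. The classifier uses logistic (log-sigmoid) activations in
both the hidden and output layers, so its output is a posterior probability
of the impending-hypotension class; its hard decision applies a threshold
chosen on training data by maximizing sensitivity + specificity over the
ROC curve. The regressor swaps in tanh hidden units and a linear output to
get the dynamic range needed for mmHg targets (standardized during training,
de-standardized at prediction).

Training is gradient-based (Adam) with a seeded random 20% validation
holdout and early stopping; the scikit-learn multilayer perceptrons stand
behind these wrappers, and all randomness is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier, MLPRegressor

__all__ = [
    "ClassifierModel",
    "RegressorModel",
    "train_classifier",
    "train_regressor",
    "select_threshold",
    "predict_probability",
    "predict_map",
]

HIDDEN_UNITS = 20
MAX_EPOCHS = 500
PATIENCE = 10
VALIDATION_FRACTION = 0.2
BATCH_SIZE = 32
LEARNING_RATE = 0.005


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Optimal probability threshold: argmax of sensitivity + specificity.

    Candidate thresholds are every distinct score plus 0 and 1; a case is
    called positive when ``score >= threshold``. Ties in the objective break
    toward the smallest threshold (favoring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = labels == 1, labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold selection requires both classes")
    candidates = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best_th, best_obj = 0.0, -np.inf
    for th in candidates:
        called = scores >= th
        sens = (called & pos).sum() / n_pos
        spec = (~called & neg).sum() / n_neg
        obj = sens + spec
        if obj > best_obj + 1e-12:
            best_obj, best_th = obj, float(th)
    return best_th


@dataclass
class ClassifierModel:
    """Trained hypotension classifier: network + decision threshold + metadata."""

    mlp: MLPClassifier
    threshold: float
    seed: int
    epochs_run: int
    stopping_reason: str

    @property
    def n_inputs(self) -> int:
        return self.mlp.coefs_[0].shape[0]


@dataclass
class RegressorModel:
    """Trained median-MAP regressor with target-standardization parameters."""

    mlp: MLPRegressor
    target_mean: float
    target_sd: float
    seed: int
    epochs_run: int
    stopping_reason: str

    @property
    def n_inputs(self) -> int:
        return self.mlp.coefs_[0].shape[0]


def _stopping_reason(mlp, max_epochs: int) -> str:
    return "max_epochs" if mlp.n_iter_ == max_epochs else "early_stopping"


def train_classifier(
    train_reduced: np.ndarray,
    labels: np.ndarray,
    seed: int,
    max_epochs: int = MAX_EPOCHS,
    patience: int = PATIENCE,
    hidden_units: int = HIDDEN_UNITS,
) -> ClassifierModel:
    """Fit the classifier and its decision threshold.

    Cross-entropy objective, Adam updates, seeded 20% validation holdout
    with early stopping after ``patience`` non-improving epochs. The
    threshold is then selected on the full training rows.
    """
    X = np.asarray(train_reduced, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    mlp = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        solver="adam",
        batch_size=min(BATCH_SIZE, len(y)),
        learning_rate_init=LEARNING_RATE,
        max_iter=max_epochs,
        early_stopping=True,
        validation_fraction=VALIDATION_FRACTION,
        n_iter_no_change=patience,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)
    scores = mlp.predict_proba(X)[:, 1]
    threshold = select_threshold(scores, y)
    return ClassifierModel(
        mlp=mlp,
        threshold=threshold,
        seed=int(seed),
        epochs_run=int(mlp.n_iter_),
        stopping_reason=_stopping_reason(mlp, max_epochs),
    )


def predict_probability(model: ClassifierModel, reduced_rows: np.ndarray) -> np.ndarray:
    """Posterior probability of the hypotensive class for each row."""
    X = np.atleast_2d(np.asarray(reduced_rows, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    return model.mlp.predict_proba(X)[:, 1]


def predict_label(model: ClassifierModel, reduced_rows: np.ndarray) -> np.ndarray:
    """Hard decision: probability >= threshold."""
    return (predict_probability(model, reduced_rows) >= model.threshold).astype(int)


def train_regressor(
    train_reduced: np.ndarray,
    target_map: np.ndarray,
    seed: int,
    max_epochs: int = MAX_EPOCHS,
    patience: int = PATIENCE,
    hidden_units: int = HIDDEN_UNITS,
) -> RegressorModel:
    """Fit the median-MAP regressor on standardized targets (MSE objective)."""
    X = np.asarray(train_reduced, dtype=float)
    y = np.asarray(target_map, dtype=float)
    if len(y) < 10:
        raise ValueError("regressor training needs >= 10 rows")
    t_mean, t_sd = float(y.mean()), float(y.std())
    if t_sd == 0.0:
        raise ValueError("regression targets are constant")
    mlp = MLPRegressor(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="adam",
        batch_size=min(BATCH_SIZE, len(y)),
        learning_rate_init=LEARNING_RATE,
        max_iter=max_epochs,
        early_stopping=True,
        validation_fraction=VALIDATION_FRACTION,
        n_iter_no_change=patience,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, (y - t_mean) / t_sd)
    return RegressorModel(
        mlp=mlp,
        target_mean=t_mean,
        target_sd=t_sd,
        seed=int(seed),
        epochs_run=int(mlp.n_iter_),
        stopping_reason=_stopping_reason(mlp, max_epochs),
    )


def predict_map(model: RegressorModel, reduced_rows: np.ndarray) -> np.ndarray:
    """Predicted target-window median MAP in mmHg for each row."""
    X = np.atleast_2d(np.asarray(reduced_rows, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    return model.mlp.predict(X) * model.target_sd + model.target_mean
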