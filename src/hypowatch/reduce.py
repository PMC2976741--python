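"""Feature normalization and PCA projection fitted on training data only.

Features are standardized to zero mean / unit variance using training-set
statistics, then projected onto the principal components with the largest
eigenvalues that capture (at least) a target fraction of total variance —
90% by default, which lands in the low tens of components for these
feature vectors. Test data always reuse the training normalization and
loadings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["FittedReducer", "fit_reducer", "apply_reducer"]


@dataclass
class FittedReducer:
    """Training-set normalization statistics plus retained PCA loadings."""

    means: np.ndarray  # (p,)
    sds: np.ndarray  # (p,) constant features carry 1.0
    loadings: np.ndarray  # (p, k), orthonormal columns
    k: int
    explained_variance_ratio: np.ndarray  # (k,)
    cumulative_variance: float  # at k

    @property
    def n_features(self) -> int:
        return len(self.means)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "k": self.k,
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "cumulative_variance": self.cumulative_variance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedReducer":
        payload = json.loads(Path(path).read_text())
        return cls(
            means=np.asarray(payload["means"]),
            sds=np.asarray(payload["sds"]),
            loadings=np.asarray(payload["loadings"]),
            k=int(payload["k"]),
            explained_variance_ratio=np.asarray(payload["explained_variance_ratio"]),
            cumulative_variance=float(payload["cumulative_variance"]),
        )


def fit_reducer(train_features: np.ndarray, variance_target: float = 0.90) -> FittedReducer:
    """Fit normalization + PCA on training rows.

    ``k`` is the smallest component count whose cumulative explained-variance
    ratio reaches ``variance_target``. Constant features (zero training SD)
    are left unscaled (divisor 1) with a warning. Loading signs are fixed so
    each column's largest-magnitude element is positive.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_reducer needs a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        raise ValueError("fit_reducer does not accept missing entries")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    constant = sds == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) left unscaled",
            stacklevel=2,
        )
        sds = np.where(constant, 1.0, sds)
    Z = (X - means) / sds

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, variance_target) + 1)
    k = min(k, len(ratios))

    loadings = pca.components_[:k].T.copy()  # (p, k)
    for j in range(k):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]

    return FittedReducer(
        means=means,
        sds=sds,
        loadings=loadings,
        k=k,
        explained_variance_ratio=ratios[:k].copy(),
        cumulative_variance=float(cumulative[k - 1]),
    )


def apply_reducer(reducer: FittedReducer, features: np.ndarray) -> np.ndarray:
    """Project rows onto the retained components: ``((x - mean) / sd) @ loadings``."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != reducer.n_features:
        raise ValueError(
            f"expected {reducer.n_features} feature columns, got {X.shape[1]}"
        )
    return (X - reducer.means) / reducer.sds @ reducer.loadings
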