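"""Classical baseline classifiers compared against the PCA-LSTM.

The baselines are not sequence models, so they receive the PCA scores
averaged over the window axis. Hyperparameters are fixed, documented
defaults: RBF-kernel SVM (C = 1, gamma = 1/k), random forest (500 trees),
k-NN (k = 5) and gradient-boosted trees (300 rounds, depth 4, eta 0.1).
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = ["BASELINE_KINDS", "train_baseline", "flatten_sequences"]

BASELINE_KINDS = ("SVM", "RF", "kNN", "XGBoost")


def flatten_sequences(X: np.ndarray) -> np.ndarray:
    """Collapse (n, T, k) sequences to (n, k) by averaging over windows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n, T, k) sequences")
    return X.mean(axis=1)


class _ConstantClassifier:
    """Degenerate single-class fallback: predicts the only seen class."""

    def __init__(self, label: int):
        self.label = int(label)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def train_baseline(kind: str, X_flat: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one baseline on flattened PCA scores. Unknown kind raises."""
    X_flat = np.asarray(X_flat, dtype=float)
    y = np.asarray(y, dtype=int)
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind: {kind!r}")
    if np.unique(y).size == 1:
        return _ConstantClassifier(y[0]).fit(X_flat, y)
    if kind == "SVM":
        model = SVC(kernel="rbf", C=1.0, gamma="auto", random_state=seed)
    elif kind == "RF":
        model = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif kind == "kNN":
        model = KNeighborsClassifier(n_neighbors=5)
    elif kind == "XGBoost":
        model = XGBClassifier(
            n_estimators=300,
            max_depth=4,
            learning_rate=0.1,
            objective="multi:softprob",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    else:
        raise ValueError(f"unknown baseline kind: {kind!r}")
    model.fit(X_flat, y)
    return model
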