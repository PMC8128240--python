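"""Four binary sepsis classifiers under one train / score / predict contract.

* DT  — single CART decision tree (cost-complexity defaults)
* RF  — random forest: 500 bagged trees with sqrt(G) feature subsetting
* SVM — RBF-kernel soft-margin machine, gamma = 1/G, C = 1; scores are a
        monotone (logistic) calibration of the signed decision values, so the
        0.5 score threshold coincides with the SVM's native decision boundary
* DNN — the regularized multi-layer perceptron in :mod:`sepsismeta._mlp`

All methods are trained on a sample-by-gene matrix with binary labels
(positive class 'sepsis') and return probability-like scores in [0, 1].
Scoring a matrix whose gene list differs from the training gene list is an
error; a consistent reordering of the genes is accepted and realigned.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._mlp import DNNConfig, MLPBinaryClassifier

__all__ = [
    "METHODS",
    "TrainingError",
    "InputError",
    "ScoringError",
    "ClassifierHandle",
    "DNNConfig",
    "train",
    "score",
    "predict",
    "save_handle",
    "load_handle",
]

METHODS = ("DT", "RF", "SVM", "DNN")
POSITIVE_CLASS = "sepsis"


class TrainingError(ValueError):
    pass


class InputError(ValueError):
    pass


class ScoringError(ValueError):
    pass


@dataclass
class ClassifierHandle:
    """Opaque trained classifier plus the gene list it expects."""

    method: str
    model: Any
    gene_list: pd.Index
    seed: int


def _as_binary(y) -> np.ndarray:
    y = pd.Series(y)
    values = set(y.unique())
    if values <= {0, 1}:
        return y.to_numpy(dtype=int)
    if POSITIVE_CLASS in values and len(values) <= 2:
        return (y == POSITIVE_CLASS).to_numpy(dtype=int)
    raise TrainingError(f"labels must be binary with '{POSITIVE_CLASS}' positive: {values}")


def train(
    method: str,
    X: pd.DataFrame,
    y,
    config: DNNConfig | None = None,
    seed: int = 0,
) -> ClassifierHandle:
    """Fit one of the four methods on a sample-by-gene matrix.

    ``X`` has samples as rows and gene identifiers as columns; ``y`` holds
    binary labels.  Deterministic for a fixed seed (which also seeds the
    DNN when ``config`` carries no explicit seed override).
    """
    if method not in METHODS:
        raise TrainingError(f"unknown method {method!r}; expected one of {METHODS}")
    if not isinstance(X, pd.DataFrame):
        raise InputError("X must be a sample-by-gene DataFrame")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("X contains non-finite values")
    y01 = _as_binary(y)
    if len(y01) != len(X):
        raise InputError("X and y lengths differ")
    if len(np.unique(y01)) < 2:
        raise TrainingError("training labels contain a single class")
    if np.bincount(y01, minlength=2).min() < 2:
        raise TrainingError("each class needs at least 2 training samples")

    G = X.shape[1]
    if method == "DT":
        model = DecisionTreeClassifier(random_state=seed).fit(values, y01)
    elif method == "RF":
        model = RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
        ).fit(values, y01)
    elif method == "SVM":
        model = SVC(kernel="rbf", gamma=1.0 / G, C=1.0, random_state=seed).fit(
            values, y01
        )
    else:  # DNN
        cfg = config or DNNConfig(seed=seed)
        model = MLPBinaryClassifier(n_features=G, config=cfg).fit(values, y01)
    return ClassifierHandle(method=method, model=model, gene_list=X.columns, seed=seed)


def _align(handle: ClassifierHandle, X: pd.DataFrame) -> np.ndarray:
    if not isinstance(X, pd.DataFrame):
        raise ScoringError("X must be a sample-by-gene DataFrame")
    if X.columns.equals(handle.gene_list):
        aligned = X
    else:
        missing = handle.gene_list.difference(X.columns)
        extra = X.columns.difference(handle.gene_list)
        if len(missing) or len(extra):
            raise ScoringError(
                f"gene list mismatch: missing {list(missing[:5])}, "
                f"extra {list(extra[:5])}"
            )
        aligned = X.loc[:, handle.gene_list]
    values = aligned.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise InputError("X contains non-finite values")
    return values


def score(handle: ClassifierHandle, X: pd.DataFrame) -> np.ndarray:
    """Per-sample sepsis probability in [0, 1]."""
    values = _align(handle, X)
    if handle.method in ("DT", "RF"):
        return handle.model.predict_proba(values)[:, 1]
    if handle.method == "SVM":
        return expit(handle.model.decision_function(values))
    return handle.model.predict_proba(values)


def predict(handle: ClassifierHandle, X: pd.DataFrame) -> np.ndarray:
    """Binary prediction: score >= 0.5 -> sepsis (1)."""
    return (score(handle, X) >= 0.5).astype(int)


def save_handle(handle: ClassifierHandle, path) -> None:
    """Serialize a trained classifier: method tag, gene list, seed and the
    fitted parameters/weights, for the pre-trained-network deployment
    scenario (load once, predict new samples instantly)."""
    payload = {
        "method": handle.method,
        "gene_list": list(handle.gene_list),
        "seed": handle.seed,
        "model": handle.model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_handle(path) -> ClassifierHandle:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return ClassifierHandle(
        method=payload["method"],
        model=payload["model"],
        gene_list=pd.Index(payload["gene_list"]),
        seed=payload["seed"],
    )
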