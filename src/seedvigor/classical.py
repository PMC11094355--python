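"""Classical spectral classifiers: RBF-SVM with grid search, and an ELM.

The SVM tunes the penalty coefficient ``c`` and RBF kernel parameter ``g``
over the power-of-two grid 2^-8 .. 2^8 (17 x 17 = 289 pairs at exponent step
1) by stratified cross-validated accuracy; ties break to smaller c, then
smaller g.

The extreme learning machine draws hidden weights/biases from U(-1, 1) once,
never trains them, and solves the output layer in a single least-squares
step: beta = pinv(H) @ one_hot(y) with H = act(X W + b).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .preprocess import SpectrumMatrix

__all__ = [
    "SvmGridResult",
    "svm_grid_train",
    "default_svm_grid",
    "ElmModel",
    "elm_train",
    "elm_predict",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


def default_svm_grid(step: int = 1) -> list[float]:
    """Powers of two spanning 2^-8 .. 2^8 at integer exponent ``step``."""
    return [2.0**e for e in range(-8, 9, step)]


@dataclass
class SvmGridResult:
    model: SVC
    c: float
    g: float
    cv_table: np.ndarray  # len(c_grid) x len(g_grid) CV accuracies
    c_grid: list[float]
    g_grid: list[float]


def svm_grid_train(
    train: SpectrumMatrix,
    folds: int = 5,
    rng_seed: int = 0,
    exponent_step: int = 1,
) -> SvmGridResult:
    """Exhaustive (c, g) grid search for an RBF SVM by stratified CV accuracy."""
    X, y = train.X, train.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples, "
            f"fewer than {folds} folds"
        )
    grid = default_svm_grid(exponent_step)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    table = np.empty((len(grid), len(grid)))
    best = (-1.0, None)
    for i, c in enumerate(grid):
        for j, g in enumerate(grid):
            acc = cross_val_score(
                SVC(C=c, gamma=g, kernel="rbf"), X, y, cv=skf, scoring="accuracy"
            ).mean()
            table[i, j] = acc
            # strict > keeps the first (smallest c, then smallest g) maximizer
            if acc > best[0]:
                best = (acc, (c, g))
    c, g = best[1]
    model = SVC(C=c, gamma=g, kernel="rbf").fit(X, y)
    return SvmGridResult(model, c, g, table, grid, grid)


@dataclass
class ElmModel:
    """Single-hidden-layer network with random fixed hidden weights."""

    W: np.ndarray  # n_features x N
    b: np.ndarray  # N
    beta: np.ndarray  # N x n_classes
    classes: np.ndarray
    activation: str = "sigmoid"
    rng_seed: int = 0

    def hidden(self, X: np.ndarray) -> np.ndarray:
        H = _ACTIVATIONS[self.activation](X @ self.W + self.b)
        if not np.all(np.isfinite(H)):
            raise FloatingPointError("non-finite hidden activations")
        return H

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "seedvigor.elm/1",
                    "W": self.W.tolist(),
                    "b": self.b.tolist(),
                    "beta": self.beta.tolist(),
                    "classes": self.classes.tolist(),
                    "activation": self.activation,
                    "rng_seed": self.rng_seed,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "ElmModel":
        o = json.loads(Path(path).read_text())
        return cls(
            np.array(o["W"]), np.array(o["b"]), np.array(o["beta"]),
            np.array(o["classes"]), o["activation"], o["rng_seed"],
        )


def elm_train(
    train: SpectrumMatrix,
    n_hidden: int,
    activation: str = "sigmoid",
    rng_seed: int = 0,
) -> ElmModel:
    """Fit an ELM: random U(-1,1) hidden layer, one least-squares beta solve."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    X, y = train.X, train.labels
    rng = np.random.default_rng(rng_seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    model = ElmModel(W, b, np.zeros((n_hidden, len(classes))), classes,
                     activation, rng_seed)
    H = model.hidden(X)
    model.beta = np.linalg.pinv(H) @ Y
    return model


def elm_predict(model: ElmModel, X: SpectrumMatrix | np.ndarray) -> np.ndarray:
    """Argmax over class scores H beta; ties go to the lowest class index."""
    Xa = X.X if isinstance(X, SpectrumMatrix) else np.asarray(X, dtype=float)
    if Xa.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature count {Xa.shape[1]} does not match training "
            f"({model.W.shape[0]})"
        )
    scores = model.hidden(Xa) @ model.beta
    return model.classes[np.argmax(scores, axis=1)]  # argmax: first max wins


def elm_hidden_sweep(
    train: SpectrumMatrix,
    val: SpectrumMatrix,
    sizes: tuple[int, ...] = (50, 100, 200, 500),
    activation: str = "sigmoid",
    rng_seed: int = 0,
) -> tuple[ElmModel, dict[int, float]]:
    """Pick the hidden-layer size maximizing validation accuracy."""
    scores: dict[int, float] = {}
    best: tuple[float, ElmModel | None] = (-1.0, None)
    for n in sizes:
        m = elm_train(train, n, activation, rng_seed)
        acc = float(np.mean(elm_predict(m, val) == val.labels))
        scores[n] = acc
        if acc > best[0]:
            best = (acc, m)
    return best[1], scores
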