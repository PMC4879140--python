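"""Two-class linear discriminant analysis and repeated k-fold cross-validation.

The discriminant is the textbook pooled-covariance Bayes rule: with class
means μ₀, μ₁, pooled within-class covariance Σ and priors π₀, π₁,

    w = Σ⁻¹ (μ₁ − μ₀)
    b = −½ (μ₁ + μ₀)ᵀ w + log(π₁/π₀)

and a sample x is assigned class 1 iff wᵀx + b > 0.  Exact boundary ties go
to the class with the larger prior, then to class 0.  The pooled covariance
uses the unbiased (n − 2) denominator; a small ridge ε·(trace Σ / d) on the
diagonal (default ε = 1e-8) guards against singular covariance from
degenerate features and can be disabled for exact-oracle comparisons.

Cross-validation repeats stratified k-fold ``runs`` times; each run shuffles
with a seed derived from the master seed, so results are reproducible and the
runs differ.  Accuracy is the grand mean over all runs × folds (identical to
the mean of run means when folds are equal-sized).  An optional fold-safe
mode refits min-max scaling on each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["LDAModel", "CVSpec", "CVResult", "lda_fit", "lda_predict", "cross_validate"]


@dataclass
class LDAModel:
    class_means: np.ndarray  # (2, d), rows = class 0, class 1
    pooled_cov: np.ndarray  # (d, d)
    weights: np.ndarray  # (d,)
    bias: float
    priors: np.ndarray  # (2,)
    ridge: float


@dataclass
class CVSpec:
    """k folds × runs repetitions; stratified by class unless disabled."""

    k: int = 10
    runs: int = 10
    seed: int = 0
    stratified: bool = True
    scale_in_fold: bool = False  # refit min-max scaling on each training fold

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class CVResult:
    fold_accuracies: np.ndarray  # (runs, k), percent
    mean_accuracy: float  # percent, grand mean over runs x folds
    spec: CVSpec
    n_samples: int


def lda_fit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> LDAModel:
    """Fit the pooled-covariance discriminant; both classes must be present."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"need both classes 0 and 1, got classes {classes.tolist()}")
    n, d = X.shape
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need >= 2 samples per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S0 = (X0 - mu0).T @ (X0 - mu0)
    S1 = (X1 - mu1).T @ (X1 - mu1)
    cov = (S0 + S1) / (n - 2)
    if ridge:
        cov = cov + np.eye(d) * ridge * np.trace(cov) / d
    try:
        w = np.linalg.solve(cov, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; supply a ridge > 0"
        ) from err
    priors = np.array([len(X0) / n, len(X1) / n])
    b = -0.5 * (mu1 + mu0) @ w + np.log(priors[1] / priors[0])
    return LDAModel(
        class_means=np.stack([mu0, mu1]),
        pooled_cov=cov,
        weights=w,
        bias=float(b),
        priors=priors,
        ridge=ridge,
    )


def lda_decision(model: LDAModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature count mismatch: model has {model.weights.size}, X has {X.shape[1]}"
        )
    return X @ model.weights + model.bias


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Class labels; exact-zero scores break toward the larger prior, then class 0."""
    score = lda_decision(model, X)
    pred = (score > 0).astype(int)
    tie_class = int(model.priors[1] > model.priors[0])
    pred[score == 0] = tie_class
    return pred


def _fold_iterator(spec: CVSpec, run: int):
    seed = (int(spec.seed) * 100003 + run) % (2**31)
    cls = StratifiedKFold if spec.stratified else KFold
    return cls(n_splits=spec.k, shuffle=True, random_state=seed)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: CVSpec | None = None,
    ridge: float = 1e-8,
) -> CVResult:
    """Repeated (stratified) k-fold accuracy of the discriminant, in percent."""
    spec = spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds n={n}")
    if spec.stratified and min(np.bincount(y, minlength=2)) < spec.k:
        raise ValueError("each class needs at least k samples for stratified folds")
    acc = np.empty((spec.runs, spec.k))
    for run in range(spec.runs):
        splitter = _fold_iterator(spec, run)
        for fold, (train, test) in enumerate(splitter.split(X, y)):
            Xtr, Xte = X[train], X[test]
            if spec.scale_in_fold:
                lo, hi = Xtr.min(axis=0), Xtr.max(axis=0)
                span = np.where(hi > lo, hi - lo, 1.0)
                Xtr = (Xtr - lo) / span
                Xte = (Xte - lo) / span
            model = lda_fit(Xtr, y[train], ridge=ridge)
            pred = lda_predict(model, Xte)
            acc[run, fold] = 100.0 * np.mean(pred == y[test])
    return CVResult(
        fold_accuracies=acc,
        mean_accuracy=float(acc.mean()),
        spec=spec,
        n_samples=n,
    )
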