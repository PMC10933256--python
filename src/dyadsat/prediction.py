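"""Cross-validated prediction of pair-level outcomes from similarity features.

A linear epsilon-SVR (libsvm, via scikit-learn, default C=1, epsilon=0.1) or
ridge regression (alpha=1, unpenalized intercept) predicts a per-pair target
from the P×N similarity matrix under repeated 10-fold cross-validation.
Accuracy is the RMSE over out-of-fold predictions, averaged across repeats;
significance comes from a permutation test that refits the entire repeated
cross-validation on label-permuted data and reports the fraction of null
RMSEs at or below the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR

from ._rng import substream

__all__ = [
    "ModelSpec",
    "LinearModel",
    "SimilarityRegressor",
    "rmse",
    "make_folds",
    "fit_model",
    "repeated_cv",
    "permutation_test",
    "PredictionResult",
    "PermutationResult",
]


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the linear predictive model.

    family
        ``"linear_svr"`` (epsilon-insensitive loss, libsvm) or ``"ridge"``
        (closed-form L2, unpenalized intercept).
    C, epsilon
        SVR penalty and insensitivity (toolkit defaults 1.0 / 0.1).
    alpha
        Ridge penalty (toolkit default 1.0).
    standardize
        Z-score features on the training fold before fitting (off by
        default; similarity features are already bounded in [-1, 1]).
    tol
        Optional solver tolerance override for the SVR.
    """

    family: str = "linear_svr"
    C: float = 1.0
    epsilon: float = 0.1
    alpha: float = 1.0
    standardize: bool = False
    tol: float | None = None

    def __post_init__(self):
        if self.family not in ("linear_svr", "ridge"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.C <= 0 or self.epsilon < 0 or self.alpha < 0:
            raise ValueError("require C > 0, epsilon >= 0, alpha >= 0")


@dataclass
class LinearModel:
    """A fitted linear predictor in the original feature space."""

    weights: np.ndarray
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


class SimilarityRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn style linear regressor over similarity features.

    Thin estimator facade over the two model families; after ``fit`` the
    attributes ``coef_`` and ``intercept_`` hold the linear model in the
    original (unstandardized) feature space.
    """

    def __init__(
        self,
        family: str = "linear_svr",
        C: float = 1.0,
        epsilon: float = 0.1,
        alpha: float = 1.0,
        standardize: bool = False,
        tol: float | None = None,
    ):
        self.family = family
        self.C = C
        self.epsilon = epsilon
        self.alpha = alpha
        self.standardize = standardize
        self.tol = tol

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            family=self.family,
            C=self.C,
            epsilon=self.epsilon,
            alpha=self.alpha,
            standardize=self.standardize,
            tol=self.tol,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per target value")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in X or y")
        spec = self._spec()

        if spec.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xf = (X - mu) / sd
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
            Xf = X

        if spec.family == "linear_svr":
            kwargs = {}
            if spec.tol is not None:
                kwargs["tol"] = spec.tol
            svr = SVR(kernel="linear", C=spec.C, epsilon=spec.epsilon, **kwargs)
            svr.fit(Xf, y)
            w = np.asarray(svr.coef_).ravel()
            b = float(np.asarray(svr.intercept_).ravel()[0])
        else:
            w, b = _ridge_solve(Xf, y, spec.alpha)

        # map back to the original feature scale
        self.coef_ = w / sd
        self.intercept_ = float(b - (w * mu / sd).sum())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def _ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float):
    """Exact ridge with unpenalized intercept (matches sklearn Ridge).

    Uses the dual (kernel) form when samples < features, which is the usual
    regime here (≤29 pairs, ≥62 regions).
    """
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    n, p = Xc.shape
    if n <= p:
        K = Xc @ Xc.T
        K.flat[:: n + 1] += alpha
        w = Xc.T @ np.linalg.solve(K, yc)
    else:
        A = Xc.T @ Xc
        A.flat[:: p + 1] += alpha
        w = np.linalg.solve(A, Xc.T @ yc)
    b = ym - xm @ w
    return w, float(b)


def rmse(observed, predicted) -> float:
    """Root-mean-square error between observed and predicted scores."""
    observed = np.asarray(observed, dtype=float).reshape(-1)
    predicted = np.asarray(predicted, dtype=float).reshape(-1)
    if observed.size == 0:
        raise ValueError("empty input")
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def make_folds(n_items: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random k-fold partition; returns a length-n array of fold labels.

    Fold sizes differ by at most one (for 29 items in 10 folds: nine folds
    of 3 and one of 2, i.e. training sets of 26 or 27 pairs).
    """
    if k > n_items:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    if k < 2:
        raise ValueError("need at least 2 folds")
    perm = rng.permutation(n_items)
    labels = np.empty(n_items, dtype=int)
    for fold, idx in enumerate(np.array_split(perm, k)):
        labels[idx] = fold
    return labels


def fit_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Fit one linear model on a training fold."""
    est = SimilarityRegressor(**vars(spec)).fit(X, y)
    return LinearModel(weights=est.coef_, intercept=est.intercept_)


@dataclass
class PredictionResult:
    """Outcome of one repeated cross-validation run."""

    per_repeat_rmse: np.ndarray
    mean_rmse: float
    predictions: np.ndarray  # (n_repeats, P) out-of-fold predictions
    fold_assignments: np.ndarray  # (n_repeats, P) fold labels
    seed: int | None = None
    models: list | None = None  # per repeat: list of k LinearModel
    importances: np.ndarray | None = None  # (n_repeats, k, N)


def _importance_on_fold(model, X_test, y_test, K, rng):
    # local import keeps the module dependency one-way
    from .interpretation import permutation_importance

    return permutation_importance(model, X_test, y_test, K=K, rng=rng)


def repeated_cv(
    X,
    y,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    n_repeats: int = 20,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    collect_models: bool = False,
    importance_K: int | None = None,
) -> PredictionResult:
    """Repeated k-fold cross-validation scored by out-of-fold RMSE.

    Each repeat draws a fresh random partition, fits one model per fold, and
    scores a single RMSE over all held-out predictions of that repeat; the
    headline accuracy is the mean over repeats.  Optionally collects the
    per-fold fitted models and per-fold permutation feature importances
    (evaluated on each test fold with ``importance_K`` shuffles).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of pairs")
    n = y.shape[0]
    if rng is None:
        rng = substream(seed, "cv")
    per_repeat = np.empty(n_repeats)
    predictions = np.empty((n_repeats, n))
    assignments = np.empty((n_repeats, n), dtype=int)
    models = [] if collect_models else None
    importances = (
        np.empty((n_repeats, k, X.shape[1])) if importance_K is not None else None
    )
    for r in range(n_repeats):
        folds = make_folds(n, k, rng)
        assignments[r] = folds
        fold_models = []
        for fold in range(k):
            test = folds == fold
            model = fit_model(spec, X[~test], y[~test])
            predictions[r, test] = model.predict(X[test])
            if collect_models:
                fold_models.append(model)
            if importance_K is not None:
                importances[r, fold] = _importance_on_fold(
                    model, X[test], y[test], importance_K, rng
                )
        if collect_models:
            models.append(fold_models)
        per_repeat[r] = rmse(y, predictions[r])
    return PredictionResult(
        per_repeat_rmse=per_repeat,
        mean_rmse=float(per_repeat.mean()),
        predictions=predictions,
        fold_assignments=assignments,
        seed=seed,
        models=models,
        importances=importances,
    )


@dataclass
class PermutationResult:
    """Permutation-test summary for a repeated-CV accuracy."""

    null_rmses: np.ndarray
    mean_rmse: float
    p_value: float
    p_smoothed: float = field(default=float("nan"))
    n_perm: int = 0


def permutation_test(
    X,
    y,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    n_repeats: int = 20,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of repeated-CV accuracy.

    Each of the ``n_perm`` iterations permutes the full target vector once
    (the similarity matrix keeps its structure), reruns the entire repeated
    cross-validation on the permuted data, and records the null mean RMSE.
    The p-value is the plain proportion of null RMSEs less than or equal to
    the observed one; p = 0 therefore means "< 1/n_perm", and ``p_smoothed``
    = (1 + count) / (1 + n_perm) is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float).reshape(-1)
    actual = repeated_cv(
        X, y, spec, k=k, n_repeats=n_repeats, rng=substream(seed, "actual")
    )
    perm_rng = substream(seed, "perm-labels")
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = perm_rng.permutation(y)
        nulls[b] = repeated_cv(
            X, y_perm, spec, k=k, n_repeats=n_repeats, rng=substream(seed, "null", b)
        ).mean_rmse
    count = int(np.sum(nulls <= actual.mean_rmse))
    return PermutationResult(
        null_rmses=nulls,
        mean_rmse=actual.mean_rmse,
        p_value=count / n_perm,
        p_smoothed=(1 + count) / (1 + n_perm),
        n_perm=n_perm,
    )
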