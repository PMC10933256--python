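"""Model interpretation: fold-averaged coefficients and permutation importance.

Two complementary views of which similarity features drive prediction:

* **Coefficients** — the 10 per-fold models of each repeat are averaged,
  the 20 repeat means averaged again, and the resulting mean weights are
  compared against null models refit on label-permuted data.  A feature is
  flagged when its mean coefficient falls outside the [2.5, 97.5] percentile
  band of the null coefficients (an operationalization of the original
  "visual deviation from null medians" reading; a reporting convention, not
  a formal test).

* **Permutation importance** — on each held-out fold, feature j's test
  column is shuffled K times and the importance is
  ``i_j = s - (1/K) * sum_k s_kj`` with s the intact-test RMSE.  Because the
  metric is an error, negative importance marks a contributive feature.
  Importances are fold- then repeat-averaged and compared against baselines
  from label-permuted refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .prediction import LinearModel, ModelSpec, repeated_cv, rmse

__all__ = [
    "average_models",
    "coefficient_report",
    "permutation_importance",
    "aggregate_importance",
    "importance_report",
    "CoefficientReport",
    "ImportanceReport",
]


def average_models(models) -> LinearModel:
    """Elementwise mean of linear models (weights and intercepts).

    With equal fold counts per repeat, averaging the 10 fold models within
    each repeat and then the 20 repeat means equals the flat grand mean over
    all 200 models.
    """
    models = list(models)
    if not models:
        raise ValueError("cannot average an empty model list")
    n = models[0].weights.shape[0]
    if any(m.weights.shape[0] != n for m in models):
        raise ValueError("models disagree on feature count")
    weights = np.mean([m.weights for m in models], axis=0)
    intercept = float(np.mean([m.intercept for m in models]))
    return LinearModel(weights=weights, intercept=intercept)


@dataclass
class CoefficientReport:
    """Fold-averaged coefficients with permutation-null reference bands."""

    mean_weights: np.ndarray
    mean_intercept: float
    null_median: np.ndarray
    null_lower: np.ndarray
    null_upper: np.ndarray
    flagged: np.ndarray  # bool: actual outside the null percentile band
    null_weights: np.ndarray  # (n_null, N)
    feature_labels: list | None = None


def _mean_model_of_run(result) -> LinearModel:
    return average_models(
        [average_models(fold_models) for fold_models in result.models]
    )


def coefficient_report(
    X,
    y,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    n_repeats: int = 20,
    n_null: int = 100,
    seed: int = 0,
    percentiles=(2.5, 97.5),
    feature_labels=None,
) -> CoefficientReport:
    """Mean predictive model plus null-model coefficient bands.

    The actual run and every null run use the full repeated k-fold
    procedure; each null permutes the target once and keeps the similarity
    matrix intact.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    y = np.asarray(y, dtype=float).reshape(-1)
    actual = repeated_cv(
        X, y, spec, k=k, n_repeats=n_repeats,
        rng=substream(seed, "coef-actual"), collect_models=True,
    )
    mean_model = _mean_model_of_run(actual)
    perm_rng = substream(seed, "coef-perm-labels")
    null_weights = np.empty((n_null, X.shape[1]))
    for b in range(n_null):
        y_perm = perm_rng.permutation(y)
        res = repeated_cv(
            X, y_perm, spec, k=k, n_repeats=n_repeats,
            rng=substream(seed, "coef-null", b), collect_models=True,
        )
        null_weights[b] = _mean_model_of_run(res).weights
    lower = np.percentile(null_weights, percentiles[0], axis=0)
    upper = np.percentile(null_weights, percentiles[1], axis=0)
    flagged = (mean_model.weights < lower) | (mean_model.weights > upper)
    return CoefficientReport(
        mean_weights=mean_model.weights,
        mean_intercept=mean_model.intercept,
        null_median=np.median(null_weights, axis=0),
        null_lower=lower,
        null_upper=upper,
        flagged=flagged,
        null_weights=null_weights,
        feature_labels=feature_labels,
    )


def permutation_importance(
    model: LinearModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    K: int = 5,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Permutation feature importance of one model on one test set.

    ``i_j = s - (1/K) * sum_k s_kj`` where s is the RMSE on the intact test
    data and s_kj the RMSE after the k-th shuffle of test column j.  A
    feature with weight exactly zero cannot change the predictions, so its
    importance is exactly zero.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float).reshape(-1)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    if rng is None:
        rng = substream(seed, "importance")
    base_pred = model.predict(X_test)
    s = rmse(y_test, base_pred)
    n, n_features = X_test.shape
    base_err = base_pred - y_test
    out = np.empty(n_features)
    for j in range(n_features):
        # K independent shuffles at once; the stream position does not
        # depend on the weight values, so results stay reproducible
        perms = np.argsort(rng.random((K, n)), axis=1)
        wj = model.weights[j]
        if wj == 0.0:
            out[j] = 0.0  # predictions cannot change
            continue
        col = X_test[:, j]
        # only feature j moves: adjust the linear prediction directly
        err = base_err[None, :] + wj * (col[perms] - col[None, :])
        out[j] = s - float(np.mean(np.sqrt(np.mean(err**2, axis=1))))
    return out


def aggregate_importance(per_fold_importances) -> np.ndarray:
    """Fold-then-repeat mean of per-fold importance vectors.

    Accepts an (n_repeats, k, N) array (or nested lists of that shape) and
    returns the length-N grand mean; ragged input is rejected.
    """
    arr = np.asarray(per_fold_importances, dtype=float)
    if arr.ndim != 3:
        raise ValueError(
            "expected per-fold importances shaped (n_repeats, k, n_features)"
        )
    return arr.mean(axis=1).mean(axis=0)


@dataclass
class ImportanceReport:
    """Repeat-averaged permutation importance with null baselines."""

    importance: np.ndarray
    K: int
    baseline: np.ndarray  # (n_null, N) baseline importances
    baseline_median: np.ndarray
    baseline_lower: np.ndarray
    baseline_upper: np.ndarray
    flagged: np.ndarray  # bool: contributive (below the lower baseline band)
    feature_labels: list | None = None


def importance_baseline(
    X,
    y,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    n_repeats: int = 20,
    K: int = 5,
    n_null: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null-label importance distribution: (n_null, N) baseline values.

    Each baseline permutes the target, reruns the repeated cross-validation,
    and aggregates the per-fold importances exactly as the actual run does.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    y = np.asarray(y, dtype=float).reshape(-1)
    perm_rng = substream(seed, "imp-perm-labels")
    out = np.empty((n_null, np.asarray(X).shape[1]))
    for b in range(n_null):
        y_perm = perm_rng.permutation(y)
        res = repeated_cv(
            X, y_perm, spec, k=k, n_repeats=n_repeats,
            rng=substream(seed, "imp-null", b), importance_K=K,
        )
        out[b] = aggregate_importance(res.importances)
    return out


def importance_report(
    X,
    y,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    n_repeats: int = 20,
    K: int = 5,
    n_null: int = 100,
    seed: int = 0,
    percentiles=(2.5, 97.5),
    feature_labels=None,
) -> ImportanceReport:
    """Actual repeat-averaged importance plus null baseline bands.

    A feature is flagged contributive when its importance falls below the
    lower baseline percentile (importance is an RMSE difference; negative
    values mark features whose shuffling hurts prediction).
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    actual = repeated_cv(
        X, y, spec, k=k, n_repeats=n_repeats,
        rng=substream(seed, "imp-actual"), importance_K=K,
    )
    importance = aggregate_importance(actual.importances)
    baseline = importance_baseline(
        X, y, spec, k=k, n_repeats=n_repeats, K=K, n_null=n_null, seed=seed
    )
    lower = np.percentile(baseline, percentiles[0], axis=0)
    upper = np.percentile(baseline, percentiles[1], axis=0)
    return ImportanceReport(
        importance=importance,
        K=K,
        baseline=baseline,
        baseline_median=np.median(baseline, axis=0),
        baseline_lower=lower,
        baseline_upper=upper,
        flagged=importance < lower,
        feature_labels=feature_labels,
    )
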