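"""Nested-CV kernel ridge prediction with Haufe activation patterns.

The predictor is connectome-based: features are vectorized upper-triangle
Fisher-z connectivity profiles, the kernel is the Pearson correlation between
profiles, and a prediction for a test subject is the regularized
similarity-weighted average of training targets. All estimation
(covariate deconfounding, kernel statistics, lambda selection) happens
strictly inside training folds; the :class:`CVEngine` caches every
target-independent quantity per fold so permutation nulls re-run only the
cheap dual solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "vectorize_conn",
    "devectorize_conn",
    "correlation_kernel",
    "deconfound",
    "krr_fit_predict",
    "CVEngine",
    "nested_cv",
    "run_prediction",
    "permutation_null",
    "haufe_weights",
    "aggregate_weights",
    "PredictionResult",
    "HaufeWeights",
]

#: Spans under- to over-regularized on the correlation-kernel scale.
DEFAULT_LAMBDA_GRID = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)


def vectorize_conn(values: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) vectorization of a symmetric matrix."""
    values = np.asarray(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def devectorize_conn(vec: np.ndarray, n_parcels: int) -> np.ndarray:
    """Inverse of :func:`vectorize_conn`; symmetric with zero diagonal."""
    out = np.zeros((n_parcels, n_parcels))
    iu = np.triu_indices(n_parcels, k=1)
    out[iu] = vec
    return out + out.T


def correlation_kernel(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between rows of ``a`` and rows of ``b``."""
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def deconfound(
    features: np.ndarray, covariates: np.ndarray, train_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize features on covariates, fitted on training rows only.

    A per-feature linear regression on the covariates (plus intercept) is fit
    on ``train_index`` rows; residuals for all rows use those training
    coefficients. Returns ``(residuals, coefficients)``.
    """
    features = np.asarray(features, dtype=float)
    x = np.column_stack([np.asarray(covariates, dtype=float),
                         np.ones(len(features))])
    xt = x[train_index]
    if np.linalg.matrix_rank(xt) < xt.shape[1]:
        raise ValueError("covariate matrix is rank deficient on training rows")
    beta, *_ = np.linalg.lstsq(xt, features[train_index], rcond=None)
    return features - x @ beta, beta


def krr_fit_predict(
    k_train: np.ndarray,
    y_train: np.ndarray,
    k_test_train: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Dual-form kernel ridge: alpha = (K + lambda I)^-1 y; pred = K* alpha."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    k_train = np.asarray(k_train, dtype=float)
    k_train = (k_train + k_train.T) / 2
    try:
        alpha = np.linalg.solve(k_train + lam * np.eye(len(k_train)), y_train)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular kernel system; use lambda > 0 with a rank-deficient kernel"
        ) from exc
    return np.asarray(k_test_train, dtype=float) @ alpha


def _accuracy(y_true: np.ndarray, scores: np.ndarray, majority: float) -> float:
    pred = np.where(scores > 0, 1.0, -1.0)
    pred[scores == 0] = majority
    return float(np.mean(pred == y_true))


def _pearson_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    if np.std(scores) == 0 or np.std(y_true) == 0:
        return -np.inf
    return float(np.corrcoef(y_true, scores)[0, 1])


def _inner_folds_of(train_rows: np.ndarray, n_inner: int, rng: np.random.Generator):
    perm = train_rows[rng.permutation(len(train_rows))]
    return [perm[g::n_inner] for g in range(n_inner)]


class CVEngine:
    """Precomputed fold structure for repeated (e.g. permuted) evaluations.

    All target-independent work — deconfounding per (outer, inner) training
    set and the corresponding correlation kernels — is done once at
    construction; :meth:`run` then needs only small linear solves per target
    vector, which makes 1,000-fold permutation nulls affordable.
    """

    def __init__(
        self,
        features: np.ndarray,
        covariates: np.ndarray | None,
        fold_assign: np.ndarray,
        n_inner: int = 5,
        inner_seed: int = 0,
    ):
        features = np.asarray(features, dtype=float)
        self.n = len(features)
        self.fold_assign = np.asarray(fold_assign)
        self.folds = np.unique(self.fold_assign)
        if len(self.folds) < 2:
            raise ValueError("need at least 2 folds")
        rng = np.random.default_rng(inner_seed)
        self.outer: list[dict] = []
        for f in self.folds:
            test = np.flatnonzero(self.fold_assign == f)
            train = np.flatnonzero(self.fold_assign != f)
            resid = self._resid(features, covariates, train)
            k_full = correlation_kernel(resid)
            inner_val = _inner_folds_of(train, n_inner, rng)
            inners = []
            for val_rows in inner_val:
                tr_rows = np.setdiff1d(train, val_rows)
                r_in = self._resid(features, covariates, tr_rows)
                k_in = correlation_kernel(r_in[np.concatenate([tr_rows, val_rows])])
                inners.append(
                    {
                        "train": tr_rows,
                        "val": val_rows,
                        "k_tt": k_in[: len(tr_rows), : len(tr_rows)],
                        "k_vt": k_in[len(tr_rows) :, : len(tr_rows)],
                    }
                )
            self.outer.append(
                {"test": test, "train": train, "K": k_full, "inner": inners}
            )

    @staticmethod
    def _resid(features, covariates, train_rows):
        if covariates is None:
            return features
        resid, _ = deconfound(features, covariates, train_rows)
        return resid

    def run(self, y: np.ndarray, lambda_grid, task: str) -> "CVRunResult":
        y = np.asarray(y, dtype=float)
        if task == "classification":
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError("classification target must have exactly 2 classes")
            y = np.where(y == classes.max(), 1.0, -1.0)
        lambda_grid = list(lambda_grid)
        if not lambda_grid:
            raise ValueError("lambda grid is empty")
        fold_acc, chosen, train_arts, predictions = [], [], [], {}
        for fold in self.outer:
            train, test = fold["train"], fold["test"]
            if task == "classification" and len(np.unique(y[train])) < 2:
                raise ValueError("a training fold contains a single class")
            majority = 1.0 if (y[train] == 1).sum() * 2 >= len(train) else -1.0
            if len(lambda_grid) == 1:
                best_lam = lambda_grid[0]
            else:
                mean_scores = []
                for lam in lambda_grid:
                    scores = []
                    for g in fold["inner"]:
                        if task == "classification" and len(np.unique(y[g["train"]])) < 2:
                            raise ValueError("an inner fold contains a single class")
                        try:
                            pred = krr_fit_predict(g["k_tt"], y[g["train"]], g["k_vt"], lam)
                        except np.linalg.LinAlgError:
                            # deconfounding leaves the kernel rank-deficient:
                            # an unregularized solve is infeasible, not fatal
                            scores.append(-np.inf)
                            continue
                        if task == "classification":
                            maj = 1.0 if (y[g["train"]] == 1).sum() * 2 >= len(g["train"]) else -1.0
                            scores.append(_accuracy(y[g["val"]], pred, maj))
                        else:
                            scores.append(_pearson_score(y[g["val"]], pred))
                    mean_scores.append(np.mean(scores))
                if not np.isfinite(np.max(mean_scores)):
                    raise np.linalg.LinAlgError(
                        "every lambda in the grid failed; add lambda > 0"
                    )
                best_lam = lambda_grid[int(np.argmax(mean_scores))]
            k = fold["K"]
            pred_test = krr_fit_predict(
                k[np.ix_(train, train)], y[train], k[np.ix_(test, train)], best_lam
            )
            pred_train = krr_fit_predict(
                k[np.ix_(train, train)], y[train], k[np.ix_(train, train)], best_lam
            )
            if task == "classification":
                fold_acc.append(_accuracy(y[test], pred_test, majority))
            else:
                fold_acc.append(_pearson_score(y[test], pred_test))
            chosen.append(best_lam)
            train_arts.append((train, pred_train))
            for row, val in zip(test, pred_test):
                predictions[int(row)] = float(val)
        return CVRunResult(
            fold_accuracy=fold_acc,
            chosen_lambda=chosen,
            train_artifacts=train_arts,
            predictions=predictions,
            task=task,
        )


@dataclass
class CVRunResult:
    """One nested-CV pass: per-fold accuracy and training artifacts."""

    fold_accuracy: list[float]
    chosen_lambda: list[float]
    train_artifacts: list[tuple[np.ndarray, np.ndarray]]
    predictions: dict[int, float]
    task: str

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))


def nested_cv(
    features: np.ndarray,
    targets: np.ndarray,
    covariates: np.ndarray | None,
    fold_assign: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    task: str = "classification",
    n_inner: int = 5,
    inner_seed: int = 0,
) -> CVRunResult:
    """Single-split nested cross-validation (see :class:`CVEngine`)."""
    engine = CVEngine(features, covariates, fold_assign, n_inner, inner_seed)
    return engine.run(targets, lambda_grid, task)


@dataclass
class PredictionResult:
    """Accuracy over split replicates plus averaged Haufe activations."""

    replicate_accuracy: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    task: str
    haufe_edgewise: np.ndarray | None = None
    permutation_p: float | None = None
    null_accuracies: np.ndarray | None = None


@dataclass
class HaufeWeights:
    """Signed activation patterns at edge, network and regional level."""

    edgewise: np.ndarray
    network_level: np.ndarray | None = None
    regional: np.ndarray | None = None


def haufe_weights(features_train: np.ndarray, predicted_train: np.ndarray) -> np.ndarray:
    """Per-feature covariance between demeaned features and predicted scores.

    This is the activation pattern of the decoder: features that merely
    cancel noise in the decoding solution get near-zero covariance with the
    model output, while genuinely informative features keep their signed
    contribution.
    """
    f = np.asarray(features_train, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 training rows")
    yhat = np.asarray(predicted_train, dtype=float)
    if np.std(yhat) == 0:
        warnings.warn("constant predictions: Haufe weights are all zero")
        return np.zeros(f.shape[1])
    fc = f - f.mean(axis=0, keepdims=True)
    yc = yhat - yhat.mean()
    return fc.T @ yc / (len(f) - 1)


def aggregate_weights(
    edgewise: np.ndarray, network_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Summarize an edgewise weight matrix to network blocks and regions.

    Network block (m, n) is the mean over edges whose endpoints lie in
    networks m and n (self-edges excluded); the regional map is the row mean
    of the edgewise matrix over the other parcels.
    """
    w = np.asarray(edgewise, dtype=float)
    labels = np.asarray(network_labels)
    nets = np.unique(labels)
    n_parcels = w.shape[0]
    off_diag = ~np.eye(n_parcels, dtype=bool)
    for na in nets:
        if not (labels == na).any():
            raise ValueError(f"network {na!r} has no parcels")
    network_level = np.empty((len(nets), len(nets)))
    for a, na in enumerate(nets):
        in_a = labels == na
        for b, nb in enumerate(nets):
            mask = np.outer(in_a, labels == nb) & off_diag
            mask = mask | mask.T
            network_level[a, b] = w[mask].mean()
    regional = w.sum(axis=1) / (n_parcels - 1)
    return network_level, regional


def run_prediction(
    features: np.ndarray,
    targets: np.ndarray,
    covariates: np.ndarray | None,
    fold_assignments: list[np.ndarray],
    lambda_grid=DEFAULT_LAMBDA_GRID,
    task: str = "classification",
    n_parcels: int | None = None,
    engines: list[CVEngine] | None = None,
) -> tuple[PredictionResult, list[CVEngine]]:
    """Nested CV over split replicates; Haufe patterns averaged over all
    training folds of all replicates. Returns the result and the (reusable)
    per-replicate engines."""
    if engines is None:
        engines = [
            CVEngine(features, covariates, fa, inner_seed=i)
            for i, fa in enumerate(fold_assignments)
        ]
    accs, haufe_acc = [], None
    count = 0
    for engine in engines:
        res = engine.run(targets, lambda_grid, task)
        accs.append(res.accuracy)
        for train, yhat in res.train_artifacts:
            w = haufe_weights(features[train], yhat)
            haufe_acc = w if haufe_acc is None else haufe_acc + w
            count += 1
    edgewise = None
    if n_parcels is not None:
        edgewise = devectorize_conn(haufe_acc / count, n_parcels)
    result = PredictionResult(
        replicate_accuracy=np.asarray(accs),
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        task=task,
        haufe_edgewise=edgewise,
    )
    return result, engines


def permutation_null(
    engines: list[CVEngine],
    targets: np.ndarray,
    true_accuracy: float,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    task: str = "classification",
    n_perm: int = 1000,
    seed: int = 0,
    pairs: list[tuple[int, int]] | None = None,
    conservative: bool = False,
) -> tuple[float, np.ndarray]:
    """Permutation p for a prediction pipeline.

    Targets are permuted ``n_perm`` times (within matched pairs when
    ``pairs`` row-index tuples are given — each pair's two labels swap with
    probability 1/2, preserving the matched design under the null) and the
    full nested-CV pipeline re-run on the cached engines. p is the strict
    proportion of null accuracies exceeding the true accuracy (so it can be
    exactly 0); ``conservative`` applies the (k + 1) / (n + 1) correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(targets, dtype=float)
    null_acc = np.empty(n_perm)
    for p in range(n_perm):
        yp = y.copy()
        if pairs is not None:
            flip = rng.random(len(pairs)) < 0.5
            for (i, j), do in zip(pairs, flip):
                if do:
                    yp[i], yp[j] = yp[j], yp[i]
        else:
            yp = y[rng.permutation(len(y))]
        null_acc[p] = np.mean([e.run(yp, lambda_grid, task).accuracy for e in engines])
    exceed = int(np.sum(null_acc > true_accuracy))
    p_val = (exceed + 1) / (n_perm + 1) if conservative else exceed / n_perm
    return float(p_val), null_acc
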