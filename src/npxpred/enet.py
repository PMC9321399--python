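"""Elastic-net penalized logistic regression with inner k-fold lambda
tuning.

The penalty uses the glmnet parameterisation (per-observation averaged
log-likelihood; ``(1 - alpha)/2`` on the ridge term), so ``alpha = 0.9``
means 90% L1 / 10% L2.  Features are expected to be column-standardised
upstream; no internal rescaling is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _solver

__all__ = [
    "ElasticNetFit",
    "lambda_max",
    "lambda_path",
    "fit_enet_logistic",
    "fit_enet_path",
    "tune_lambda_cv",
    "nonzero_features",
    "stratified_folds",
    "enet_objective",
]

DEFAULT_TOL = 1e-7
MAX_PASSES = 100_000
MAX_IRLS = 100


@dataclass
class ElasticNetFit:
    """A fitted penalized logistic model."""

    feature_ids: tuple[str, ...]
    beta: np.ndarray
    intercept: float
    alpha: float
    lam: float
    converged: bool = True
    cv_curve: dict = field(default=None, repr=False)  # lambda -> mean CV score

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.feature_ids),):
            raise ValueError("beta length must match feature ids")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_scores(X)))

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_ids),
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "converged": bool(self.converged),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ElasticNetFit":
        return cls(
            feature_ids=tuple(d["features"]),
            beta=np.asarray(d["beta"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            converged=bool(d.get("converged", True)),
        )


def _check_Xy(X, y):
    X = np.asfortranarray(X, dtype=float)  # column access dominates the kernel
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise ValueError("y must contain both classes coded 0/1")
    return X, y


def lambda_max(X, y, alpha: float) -> float:
    """Smallest lambda at which every penalized coefficient is zero."""
    X, y = _check_Xy(X, y)
    n = X.shape[0]
    resid = y - y.mean()
    a = max(alpha, 1e-3)  # glmnet's guard for near-ridge alpha
    # tiny relative nudge so the solution AT lambda_max is exactly zero
    # despite float round-off at the KKT boundary
    return float(np.abs(X.T @ resid).max() / (n * a)) * (1 + 1e-9)


def lambda_path(
    X, y, alpha: float, n_lambdas: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    lmax = lambda_max(X, y, alpha)
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def fit_enet_path(
    X, y, alpha: float, lambdas, tol: float = DEFAULT_TOL
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Warm-started path fit; returns (intercepts, betas, converged)."""
    X, y = _check_Xy(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    return _solver.fit_path(
        X, y, float(alpha), lambdas, tol, MAX_PASSES, MAX_IRLS, True
    )


def fit_enet_logistic(
    X,
    y,
    alpha: float,
    lam: float,
    *,
    feature_ids=None,
    tol: float = DEFAULT_TOL,
) -> ElasticNetFit:
    """Fit one penalized logistic model at fixed (alpha, lambda).

    Approached through a short warm-start path from lambda_max for
    stability at small lambda.
    """
    X, y = _check_Xy(X, y)
    if feature_ids is None:
        feature_ids = tuple(f"f{j}" for j in range(X.shape[1]))
    lmax = lambda_max(X, y, alpha)
    if lam >= lmax:
        path = np.array([lam])
    else:
        lo = max(lam, lmax * 1e-6)
        path = np.geomspace(lmax, lo, 20)
        path[-1] = lam  # exact target (handles lam == 0)
    b0, betas, conv = _solver.fit_path(
        X, y, float(alpha), path, tol, MAX_PASSES, MAX_IRLS, False
    )
    return ElasticNetFit(
        feature_ids=tuple(feature_ids),
        beta=betas[-1],
        intercept=float(b0[-1]),
        alpha=float(alpha),
        lam=float(lam),
        converged=bool(conv[-1]),
    )


def enet_objective(X, y, beta, intercept, alpha: float, lam: float) -> float:
    """The penalized objective value (for verification)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = X @ beta + intercept
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * np.sum((1 - alpha) * beta**2 / 2 + alpha * np.abs(beta))
    return float(nll + pen)


def stratified_folds(y, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample, stratified by class (round-robin after a
    within-class shuffle)."""
    y = np.asarray(y).astype(int)
    n = y.size
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}]")
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) + offset) % n_folds
        offset += idx.size
    return folds


def _deviance_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean binomial deviance of each column of decision scores."""
    # -2 * loglik with log(1+e^eta) evaluated stably
    return 2.0 * np.mean(
        np.logaddexp(0.0, scores) - y[:, None] * scores, axis=0
    )


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each column of ``scores`` against labels."""
    from scipy.stats import rankdata

    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(scores, axis=0)
    pos_sum = ranks[y == 1].sum(axis=0)
    return (pos_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def tune_lambda_cv(
    X,
    y,
    alpha: float,
    n_folds: int = 10,
    *,
    n_lambdas: int = 100,
    min_ratio: float = 1e-4,
    criterion: str = "auc",
    one_se: bool = False,
    rng: np.random.Generator | None = None,
    feature_ids=None,
    tol: float = DEFAULT_TOL,
    cv_tol: float = 1e-5,
) -> tuple[float, ElasticNetFit]:
    """Tune lambda along a log-spaced path by stratified k-fold CV, then
    refit on all data at the winner.

    The default criterion maximises mean out-of-fold AUC; when a fold's
    held-out part has a single class (e.g. leave-one-out), out-of-fold
    scores are pooled across folds before computing AUC.  Ties prefer
    the larger (sparser) lambda.  Fold fits use the looser ``cv_tol``
    (lambda selection is insensitive to it); the final refit uses
    ``tol``.
    """
    X, y = _check_Xy(X, y)
    if rng is None:
        rng = np.random.default_rng()
    folds = stratified_folds(y, n_folds, rng)
    lambdas = lambda_path(X, y, alpha, n_lambdas, min_ratio)
    n = X.shape[0]
    oof = np.empty((n, lambdas.size))
    fold_scores = []
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError(f"fold {f}: training part has a single class")
        b0, betas, _ = _solver.fit_path(
            np.asfortranarray(X[train]),
            y[train],
            float(alpha),
            lambdas,
            cv_tol,
            MAX_PASSES,
            MAX_IRLS,
            True,
        )
        scores = X[test] @ betas.T + b0  # (n_test, n_lambdas)
        oof[test] = scores
        yt = y[test]
        if np.unique(yt).size == 2:
            if criterion == "auc":
                fold_scores.append(_auc_columns(scores, yt))
            else:
                fold_scores.append(-_deviance_columns(scores, yt))
    if fold_scores:
        arr = np.asarray(fold_scores)
        mean_score = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(lambdas.size)
    else:  # pooled fallback (leave-one-out style)
        if criterion == "auc":
            mean_score = _auc_columns(oof, y)
        else:
            mean_score = -_deviance_columns(oof, y)
        se = np.zeros(lambdas.size)
    best = float(mean_score.max())
    if one_se:
        i_best = int(np.argmax(mean_score))
        ok = np.flatnonzero(mean_score >= best - se[i_best])
    else:
        ok = np.flatnonzero(mean_score >= best - 1e-12)
    idx = int(ok.min())  # lambdas descend: smallest index = largest lambda
    lam_star = float(lambdas[idx])
    fit = fit_enet_logistic(
        X, y, alpha, lam_star, feature_ids=feature_ids, tol=tol
    )
    fit.cv_curve = {float(l): float(s) for l, s in zip(lambdas, mean_score)}
    return lam_star, fit


def nonzero_features(fit: ElasticNetFit) -> set[str]:
    """Feature ids with exactly nonzero coefficients."""
    return {f for f, b in zip(fit.feature_ids, fit.beta) if b != 0.0}
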