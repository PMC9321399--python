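"""Resampling-based feature importance and nested cross-validated
stepwise model selection.

Two procedures drive biomarker discovery:

1. ``feature_importance`` — repeated stratified 80/20 splits; on each
   split an elastic-net logistic model (alpha = 0.9, lambda tuned by
   inner 10-fold CV) is fitted on the training part, and if its test
   AUC beats random (> 0.5) its selected features are recorded.  A
   feature's importance is the fraction of resamples in which it was
   recorded.

2. ``stepwise_nested_cv`` — starting from the clinical base features
   (gender, baseline DAS), proteins are added one by one in decreasing
   importance order; each candidate feature set is evaluated with
   stratified outer folds whose training halves tune lambda by inner
   10-fold CV, keeping every outer-test sample model-blind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enet import nonzero_features, stratified_folds, tune_lambda_cv
from .ingest import ReferenceStats
from .metrics import roc_auc, roc_curve, youden_best_point

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureImportance",
    "NestedCvCurve",
    "FinalModel",
    "feature_importance",
    "stepwise_nested_cv",
    "select_k",
    "fit_final",
]

ALPHA = 0.9  # 90% lasso / 10% ridge throughout the pipeline
INNER_FOLDS = 10


@dataclass
class FeatureImportance:
    """Selection frequency of each feature over gated resamples."""

    frequency: dict[str, float]
    n_simulations: int
    n_gated: int
    seed: int
    mean_abs_coef: dict[str, float] = field(default_factory=dict)

    def ranked(self, subset=None) -> list[str]:
        """Features by descending frequency; ties broken by descending
        mean |coefficient| over gated models, then feature id."""
        feats = list(self.frequency) if subset is None else [
            f for f in self.frequency if f in set(subset)
        ]
        return sorted(
            feats,
            key=lambda f: (
                -self.frequency[f],
                -self.mean_abs_coef.get(f, 0.0),
                f,
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        order = self.ranked()
        return pd.DataFrame(
            {
                "feature": order,
                "frequency": [self.frequency[f] for f in order],
                "mean_abs_coef": [self.mean_abs_coef.get(f, 0.0) for f in order],
            }
        )


@dataclass
class NestedCvCurve:
    """Mean outer-fold train/test AUC for each protein count k."""

    k_values: np.ndarray
    train_auc: np.ndarray
    test_auc: np.ndarray
    protein_order: list[str]
    base_features: list[str]
    fold_details: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (
            len(self.k_values) == len(self.train_auc) == len(self.test_auc)
        ):
            raise ValueError("curve arrays must align")
        for a in (self.train_auc, self.test_auc):
            if ((a < 0) | (a > 1)).any():
                raise ValueError("AUC outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "train_auc": self.train_auc,
                "test_auc": self.test_auc,
            }
        )


@dataclass
class FinalModel:
    """Full-data fit plus the Youden decision threshold and the
    reference standardisation statistics needed to score new patients."""

    feature_ids: tuple[str, ...]
    beta: np.ndarray
    intercept: float
    threshold: float
    reference: ReferenceStats | None
    alpha: float
    lam: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.feature_ids),):
            raise ValueError("one coefficient per feature required")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.intercept

    def to_dict(self) -> dict:
        d = {
            "features": list(self.feature_ids),
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "alpha": self.alpha,
            "lambda": self.lam,
            "seed": self.seed,
        }
        if self.reference is not None:
            d["reference"] = {
                "features": list(self.reference.feature_ids),
                "mean": np.asarray(self.reference.mean).tolist(),
                "sd": np.asarray(self.reference.sd).tolist(),
                "n_cohort": self.reference.n_cohort,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FinalModel":
        ref = None
        if d.get("reference"):
            r = d["reference"]
            ref = ReferenceStats(
                feature_ids=tuple(r["features"]),
                mean=np.asarray(r["mean"], dtype=float),
                sd=np.asarray(r["sd"], dtype=float),
                n_cohort=int(r.get("n_cohort", 0)),
            )
        return cls(
            feature_ids=tuple(d["features"]),
            beta=np.asarray(d["beta"], dtype=float),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            reference=ref,
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            seed=d.get("seed"),
        )

    @classmethod
    def from_json(cls, path) -> "FinalModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _stratified_split(y, train_frac, rng):
    """Index arrays (train, test) of a class-stratified random split."""
    train_idx = []
    test_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def feature_importance(
    X: pd.DataFrame,
    y,
    n_sim: int = 500,
    train_frac: float = 0.8,
    seed: int = 200,
    *,
    auc_gate: float = 0.5,
    sim_tol: float = 1e-4,
    cv_criterion: str = "auc",
) -> FeatureImportance:
    """Selection-frequency feature importance over random 80/20 splits.

    Splits are stratified by class.  Each simulation tunes lambda by
    inner 10-fold CV (alpha = 0.9) on the training part; if the fitted
    model's AUC on the held-out 20% exceeds ``auc_gate`` its nonzero
    features enter the tally.  Frequency = tally / ``n_sim``.
    ``cv_criterion`` selects the inner-CV loss for lambda ("auc" or
    "deviance"); AUC saturates on strong signals and then prefers very
    sparse models, so deviance recovers marginal informative features
    more completely.
    """
    feature_ids = list(X.columns)
    Xv = np.asfortranarray(X.to_numpy(dtype=float))
    y = np.asarray(y).astype(float)
    rng = np.random.default_rng(seed)
    counts = {f: 0 for f in feature_ids}
    coef_sums = {f: 0.0 for f in feature_ids}
    n_gated = 0
    for sim in range(n_sim):
        for attempt in range(100):
            train, test = _stratified_split(y, train_frac, rng)
            if np.unique(y[train]).size == 2 and np.unique(y[test]).size == 2:
                break
            logger.warning("simulation %d: degenerate split, resampling", sim)
        else:  # pragma: no cover - unreachable with stratification
            raise RuntimeError("could not obtain a two-class split")
        _, fit = tune_lambda_cv(
            Xv[train],
            y[train],
            ALPHA,
            INNER_FOLDS,
            criterion=cv_criterion,
            rng=rng,
            feature_ids=feature_ids,
            tol=sim_tol,
            cv_tol=sim_tol,
        )
        test_scores = fit.decision_scores(Xv[test])
        auc = roc_auc(test_scores, y[test])
        if auc > auc_gate:
            n_gated += 1
            for f in nonzero_features(fit):
                counts[f] += 1
                coef_sums[f] += abs(fit.beta[feature_ids.index(f)])
        logger.debug("sim %d: test AUC %.3f, gated=%s", sim, auc, auc > auc_gate)
    freq = {f: counts[f] / n_sim for f in feature_ids}
    mean_abs = {
        f: (coef_sums[f] / counts[f]) if counts[f] else 0.0 for f in feature_ids
    }
    return FeatureImportance(
        frequency=freq,
        n_simulations=n_sim,
        n_gated=n_gated,
        seed=seed,
        mean_abs_coef=mean_abs,
    )


def stepwise_nested_cv(
    X_clinical: pd.DataFrame,
    X_proteins: pd.DataFrame,
    y,
    fi: FeatureImportance,
    k_max: int = 30,
    outer_folds: int = 5,
    *,
    seed: int = 200,
    sim_tol: float = 1e-4,
) -> NestedCvCurve:
    """Stepwise protein inclusion evaluated by nested cross-validation.

    For each k the feature set is the clinical base plus the top-k
    proteins by importance; outer folds are fixed across k so curves
    are comparable.
    """
    base = list(X_clinical.columns)
    order = fi.ranked(subset=X_proteins.columns)
    if k_max > len(order):
        logger.warning(
            "k_max=%d exceeds available proteins (%d); clamping", k_max, len(order)
        )
        k_max = len(order)
    y = np.asarray(y).astype(float)
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, outer_folds, rng)
    X_all = pd.concat([X_clinical, X_proteins], axis=1)
    records = []
    for k in range(k_max + 1):
        feats = base + order[:k]
        Xk = np.asfortranarray(X_all[feats].to_numpy(dtype=float))
        for f in range(outer_folds):
            test = folds == f
            train = ~test
            _, fit = tune_lambda_cv(
                Xk[train],
                y[train],
                ALPHA,
                INNER_FOLDS,
                rng=rng,
                feature_ids=feats,
                tol=sim_tol,
                cv_tol=sim_tol,
            )
            records.append(
                {
                    "k": k,
                    "fold": f,
                    "train_auc": roc_auc(fit.decision_scores(Xk[train]), y[train]),
                    "test_auc": roc_auc(fit.decision_scores(Xk[test]), y[test]),
                    "lambda": fit.lam,
                    "n_nonzero": int((fit.beta != 0).sum()),
                }
            )
    detail = pd.DataFrame(records)
    means = detail.groupby("k")[["train_auc", "test_auc"]].mean()
    return NestedCvCurve(
        k_values=means.index.to_numpy(),
        train_auc=means["train_auc"].to_numpy(),
        test_auc=means["test_auc"].to_numpy(),
        protein_order=order[:k_max],
        base_features=base,
        fold_details=detail,
    )


def select_k(curve: NestedCvCurve, rule: str = "no-train-decrease") -> int:
    """Pick the protein count from a nested-CV curve.

    Default rule: restrict to k whose mean train AUC did not drop
    relative to k - 1, then take the smallest k maximising mean test
    AUC.  ``rule='argmax'`` ignores the train constraint.
    """
    test = curve.test_auc
    if rule == "argmax":
        candidates = np.arange(test.size)
    elif rule == "no-train-decrease":
        train = curve.train_auc
        keep = np.ones(test.size, dtype=bool)
        keep[1:] = train[1:] >= train[:-1] - 1e-12
        candidates = np.flatnonzero(keep)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    best = test[candidates].max()
    k_idx = candidates[test[candidates] >= best - 1e-12].min()
    return int(curve.k_values[k_idx])


def fit_final(
    X: pd.DataFrame,
    y,
    selected_features,
    *,
    reference: ReferenceStats | None = None,
    seed: int = 200,
) -> FinalModel:
    """Full-cohort elastic-net fit on the selected features, with the
    decision threshold set at the Youden best point of the full-cohort
    score ROC."""
    missing = [f for f in selected_features if f not in X.columns]
    if missing:
        raise ValueError(f"selected features absent from X: {missing}")
    feats = list(selected_features)
    Xk = np.asfortranarray(X[feats].to_numpy(dtype=float))
    y = np.asarray(y).astype(float)
    rng = np.random.default_rng(seed)
    lam, fit = tune_lambda_cv(
        Xk, y, ALPHA, INNER_FOLDS, rng=rng, feature_ids=feats
    )
    if not fit.converged:
        raise RuntimeError(
            f"final fit did not converge (lambda={lam:.4g}, alpha={ALPHA})"
        )
    scores = fit.decision_scores(Xk)
    thr, _, _ = youden_best_point(roc_curve(scores, y.astype(int)))
    return FinalModel(
        feature_ids=tuple(feats),
        beta=fit.beta,
        intercept=fit.intercept,
        threshold=float(thr),
        reference=reference,
        alpha=ALPHA,
        lam=lam,
        seed=seed,
    )
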