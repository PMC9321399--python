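"""PCA-based endotype discovery.

Patients are split into two molecular sub-groups by the sign of their
score on a chosen principal component (the published analysis used the
third).  Leave-one-out PRESS curves support the choice of component
count; the 'pseudoinverse' variant reconstructs each held-out cell
without using it, avoiding the self-prediction bias of the naive
projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import ClinicalTable
from .metrics import two_group_tests

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "EndotypeAssignment",
    "pca",
    "loocv_press",
    "assign_endotypes",
    "compare_endotypes",
]


@dataclass
class PcaResult:
    """SVD-based PCA: orthonormal loadings, scores U·D, variance fractions."""

    loadings: np.ndarray  # (p, n_components)
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray  # column means removed before the SVD
    sample_ids: list

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        evr = self.explained_variance_ratio
        if (np.diff(evr) > 1e-12).any() or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions invalid")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class EndotypeAssignment:
    labels: pd.Series  # patient id -> {1, 2}
    component: int  # 1-based
    flipped: bool  # orientation applied to the raw component

    def __post_init__(self) -> None:
        if not self.labels.isin([1, 2]).all():
            raise ValueError("labels must be 1 or 2")


def pca(z: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA via SVD of the column-centered matrix."""
    X = z.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("PCA requires a complete matrix")
    n, p = X.shape
    max_comp = min(n, p)
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        logger.warning(
            "requested %d components > min(n, p)=%d; clamping", n_components, max_comp
        )
        n_components = max_comp
    mean = X.mean(axis=0)
    Xc = X - mean
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = d**2 / (d**2).sum()
    return PcaResult(
        loadings=Vt[:n_components].T,
        scores=U[:, :n_components] * d[:n_components],
        explained_variance_ratio=evr[:n_components],
        mean=mean,
        sample_ids=list(z.index),
    )


def _press_naive(X: np.ndarray, max_pcs: int) -> np.ndarray:
    """PRESS(q) projecting each held-out row onto training loadings."""
    n, p = X.shape
    press = np.zeros(max_pcs + 1)
    for i in range(n):
        train = np.delete(X, i, axis=0)
        mu = train.mean(axis=0)
        _, _, Vt = np.linalg.svd(train - mu, full_matrices=False)
        xc = X[i] - mu
        press[0] += xc @ xc
        recon = np.zeros(p)
        for q in range(1, max_pcs + 1):
            v = Vt[q - 1]
            recon = recon + (xc @ v) * v
            err = xc - recon
            press[q] += err @ err
    return press


def _press_pseudoinverse(X: np.ndarray, max_pcs: int) -> np.ndarray:
    """PRESS(q) with per-cell reconstruction that excludes the cell.

    Held-out row scores are estimated by least squares on the loadings
    with coordinate j removed, so x_ij never predicts itself.
    """
    n, p = X.shape
    press = np.zeros(max_pcs + 1)
    for i in range(n):
        train = np.delete(X, i, axis=0)
        mu = train.mean(axis=0)
        _, _, Vt = np.linalg.svd(train - mu, full_matrices=False)
        xc = X[i] - mu
        press[0] += xc @ xc
        for q in range(1, max_pcs + 1):
            V = Vt[:q].T  # (p, q)
            for j in range(p):
                mask = np.ones(p, dtype=bool)
                mask[j] = False
                t, *_ = np.linalg.lstsq(V[mask], xc[mask], rcond=None)
                press[q] += (xc[j] - V[j] @ t) ** 2
    return press


def loocv_press(
    matrix: pd.DataFrame | np.ndarray,
    max_pcs: int = 20,
    method: str = "pseudoinverse",
) -> tuple[np.ndarray, int]:
    """Leave-one-out PRESS per component count q = 0..max_pcs.

    Returns the PRESS curve and its argmin (the suggested number of
    components).  PRESS(0) is the total LOO-centered sum of squares.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out PRESS")
    max_pcs = min(max_pcs, min(n - 1, p))
    if method == "naive":
        press = _press_naive(X, max_pcs)
    elif method == "pseudoinverse":
        press = _press_pseudoinverse(X, max_pcs)
    else:
        raise ValueError(f"unknown method {method!r}")
    return press, int(np.argmin(press))


def assign_endotypes(
    pca_result: PcaResult,
    component: int = 3,
    clinical: ClinicalTable | None = None,
) -> EndotypeAssignment:
    """Two-group assignment by the sign of the chosen component score.

    Endotype 1 is score > 0 after orientation; SVD sign indeterminacy is
    resolved so that the positive-score group has the higher mean
    baseline DAS when clinical data is given, otherwise so that the
    largest-|loading| protein loads positively.  Exact zero scores go to
    endotype 2.
    """
    if component < 1 or component > pca_result.n_components:
        raise ValueError(
            f"component {component} not in 1..{pca_result.n_components}"
        )
    raw = pca_result.scores[:, component - 1]
    flipped = False
    if clinical is not None:
        das = clinical.frame.set_index("patient_id")["baseline_das"]
        das = das.reindex(pca_result.sample_ids).to_numpy(dtype=float)
        pos, neg = raw > 0, raw < 0
        if pos.any() and neg.any() and das[pos].mean() < das[neg].mean():
            flipped = True
    else:
        load = pca_result.loadings[:, component - 1]
        if load[np.argmax(np.abs(load))] < 0:
            flipped = True
    oriented = -raw if flipped else raw
    if (oriented == 0).any():
        logger.warning(
            "%d sample(s) with exactly zero score assigned endotype 2",
            int((oriented == 0).sum()),
        )
    labels = pd.Series(
        np.where(oriented > 0, 1, 2), index=pca_result.sample_ids, name="endotype"
    )
    return EndotypeAssignment(labels=labels, component=component, flipped=flipped)


def compare_endotypes(
    assignment: EndotypeAssignment, clinical: ClinicalTable, **test_kwargs
) -> pd.DataFrame:
    """Clinical comparison of the two endotypes (group means and
    t-test / chi-square p-values)."""
    frame = clinical.frame.set_index("patient_id")
    labels = assignment.labels.reindex(frame.index)
    if labels.isna().any():
        raise ValueError("assignment does not cover every patient")
    if (labels == 1).sum() == 0 or (labels == 2).sum() == 0:
        raise ValueError("one endotype is empty")
    grouping = (labels == 1).astype(int).to_numpy()
    return two_group_tests(frame.reset_index(), grouping, **test_kwargs)
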