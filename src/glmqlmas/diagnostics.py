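"""Low-dimensional separability diagnostics.

These analyses illustrate how well ALNM+ and ALNM- samples separate in
reduced coordinates before and after gene selection; they are resubstitution
descriptions, not predictive models. Provided: PCA of log-CPM, two-class
unregularized logistic regression with confusion-matrix metrics, a paired
principal-component sweep (2..20 components, before vs after selection),
and the one-dimensional Fisher discriminant (LDA1) projection of top-ranked
genes. Any external 2-D embedding (e.g. a precomputed t-SNE) can be
substituted for the PCA coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntegrityError

log = logging.getLogger("glmqlmas")


@dataclass
class EmbeddingMatrix:
    """Samples-by-d coordinates with a provenance tag (PCA, LDA, external)."""

    coordinates: np.ndarray
    provenance: str = "PCA"
    explained_variance: np.ndarray | None = None
    loadings: np.ndarray | None = None  # feature-space directions (rows = components)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if not np.all(np.isfinite(c)):
            raise IntegrityError("embedding coordinates must be finite")
        self.coordinates = c


@dataclass
class ClassificationMetrics:
    """Confusion-matrix summary with ALNM+ as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float
    separation_flagged: bool = False


def _standardize_genes(logcpm: np.ndarray) -> np.ndarray:
    """Center and unit-scale each gene row; drop zero-variance genes."""
    X = np.asarray(logcpm, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        log.warning("dropping %d zero-variance gene(s) before projection",
                    int((~keep).sum()))
    return (X[keep] - mu[keep]) / sd[keep]


def pca(logcpm: np.ndarray, k: int, scale: bool = True) -> EmbeddingMatrix:
    """Principal components of a genes-by-samples log-CPM matrix.

    Genes are centered (and unit-scaled by default), the sample-space
    scores come from the SVD, components are ordered by decreasing
    variance, and each component's sign is fixed so its largest-magnitude
    gene loading is positive.
    """
    X = np.asarray(logcpm, dtype=float)
    n = X.shape[1]
    if not 1 <= k <= min(n - 1, X.shape[0]):
        raise IntegrityError("k must be in [1, min(samples-1, genes)]")
    if scale:
        Z = _standardize_genes(X)
    else:
        Z = X - X.mean(axis=1, keepdims=True)
    # columns (samples) as observations: SVD of Z.T = U S Vt
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = (U * S) * signs[None, :]
    explained = S**2 / (n - 1)
    return EmbeddingMatrix(scores[:, :k], "PCA", explained[:k], (Vt * signs[:, None])[:k])


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney U) formulation with tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise IntegrityError("both classes required for AUC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def logistic_metrics(embedding: EmbeddingMatrix | np.ndarray, labels: np.ndarray) -> ClassificationMetrics:
    """Unregularized maximum-likelihood logistic fit and resubstitution
    metrics at probability threshold 0.5.

    Newton iterations (tol 1e-10, cap 100); perfect separation is flagged
    (diverging coefficients) and metrics are still reported from the capped
    fit. ALNM+ (label 1) is the positive class.
    """
    X = embedding.coordinates if isinstance(embedding, EmbeddingMatrix) else np.atleast_2d(embedding)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise IntegrityError("labels must contain both classes, coded 0/1")
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    beta = np.zeros(Xd.shape[1])
    flagged = False
    for _ in range(100):
        eta = Xd @ beta
        p = _sigmoid(np.clip(eta, -35, 35))
        w = np.maximum(p * (1 - p), 1e-12)
        H = (Xd * w[:, None]).T @ Xd + 1e-12 * np.eye(Xd.shape[1])
        grad = Xd.T @ (y - p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
        if np.max(np.abs(beta)) > 1e4:
            flagged = True
            break
    eta = Xd @ beta
    if np.max(np.abs(eta)) > 30:  # fitted log-odds diverging: separation
        flagged = True
    prob = _sigmoid(np.clip(eta, -500, 500))
    pred = (prob > 0.5).astype(int)
    yi = y.astype(int)
    tp = int(np.sum((pred == 1) & (yi == 1)))
    fp = int(np.sum((pred == 1) & (yi == 0)))
    tn = int(np.sum((pred == 0) & (yi == 0)))
    fn = int(np.sum((pred == 0) & (yi == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return ClassificationMetrics(
        tp, fp, tn, fn, sens, spec, acc, f1,
        auc_mann_whitney(prob, yi), flagged,
    )


def pc_sweep(
    logcpm_before: np.ndarray,
    logcpm_after: np.ndarray,
    labels: np.ndarray,
    k_range: range | list[int] = range(2, 21),
) -> pd.DataFrame:
    """Paired metric curves over principal-component counts.

    For each k: logistic metrics on PCA(k) of the full-gene matrix
    ("before" selection) and of the selected-gene matrix ("after").
    """
    if logcpm_before.shape[1] != logcpm_after.shape[1]:
        raise IntegrityError("before/after matrices must share samples")
    rows = []
    for k in k_range:
        for tag, mat in (("before", logcpm_before), ("after", logcpm_after)):
            m = logistic_metrics(pca(mat, k), labels)
            rows.append(
                {
                    "k": k,
                    "stage": tag,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                    "f1": m.f1,
                    "auc": m.auc,
                }
            )
    return pd.DataFrame(rows)


def lda1(
    expr_topn: np.ndarray, labels: np.ndarray, ridge: float = 1e-6
) -> tuple[EmbeddingMatrix, float]:
    """One-dimensional Fisher discriminant of a genes-by-samples matrix.

    Direction ``w = (S_pooled + lambda I)^-1 (mu+ - mu-)`` with ridge
    ``lambda = ridge * mean(diag(S_pooled))``; the returned
    separation_fraction is the accuracy of the midpoint-threshold rule on
    the projection. Singular pooled covariance falls back to the
    pseudo-inverse with a warning.
    """
    X = np.asarray(expr_topn, dtype=float).T  # samples x genes
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) != 2 or min(np.bincount(y)) < 2:
        raise IntegrityError("need two classes with >= 2 samples each")
    mu_pos = X[y == 1].mean(axis=0)
    mu_neg = X[y == 0].mean(axis=0)
    Xc = np.vstack([X[y == 1] - mu_pos, X[y == 0] - mu_neg])
    S = Xc.T @ Xc / (len(y) - 2)
    lam = ridge * np.mean(np.diag(S))
    if lam <= 0:
        lam = ridge
    try:
        w = np.linalg.solve(S + lam * np.eye(S.shape[0]), mu_pos - mu_neg)
    except np.linalg.LinAlgError:
        log.warning("pooled covariance singular despite ridge; pseudo-inverse fallback")
        w = np.linalg.pinv(S + lam * np.eye(S.shape[0])) @ (mu_pos - mu_neg)
    proj = X @ w
    mid = 0.5 * (proj[y == 1].mean() + proj[y == 0].mean())
    sign = 1.0 if proj[y == 1].mean() >= proj[y == 0].mean() else -1.0
    pred = (sign * (proj - mid) > 0).astype(int)
    separation = float(np.mean(pred == y))
    return EmbeddingMatrix(proj[:, None], "LDA", loadings=w[None, :]), separation
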