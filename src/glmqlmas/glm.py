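"""Negative-binomial GLM fitting and the quasi-likelihood F-test.

The statistical core of the pipeline, implemented from first principles:

* log-link NB GLM per gene with offsets (log effective library sizes),
  fitted by iteratively reweighted least squares, vectorized over genes;
* a single common NB dispersion phi estimated by maximizing the sum of
  Cox-Reid adjusted profile log-likelihoods (gene-wise variability is
  carried by the quasi-likelihood dispersions, not phi);
* per-gene quasi-dispersions s2_g = deviance / residual df, moderated by
  empirical-Bayes moment matching of log s2 against a scaled-F spread
  (trigamma inversion), shrinking each s2_g toward a common prior;
* the QL F statistic (deviance drop of the group effect over the moderated
  dispersion) referred to F(1, d0 + d_g);
* Benjamini-Hochberg and Bonferroni adjustments.

Variance model: Var(y) = mu + phi * mu^2; phi = 0 degenerates to Poisson.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import f as f_dist

from .config import RunConfig
from .containers import CountMatrix, IntegrityError, SampleAnnotation
from .tmm import NormalizationFactors, log_cpm, tmm_normalize

log = logging.getLogger("glmqlmas")

LN2 = np.log(2.0)
_MIN_P = 1e-300
_ETA_CLIP = 50.0  # linear-predictor bound; keeps mu in (e^-50, e^50)
_PHI_BOUNDS = (1e-8, 10.0)


@dataclass
class DesignMatrix:
    """Samples-by-coefficients design: intercept + ALNM+ indicator.

    ALNM- is the reference level, so a positive group coefficient means
    higher expression in ALNM+ samples. ``reduced`` is intercept-only.
    """

    matrix: np.ndarray
    columns: tuple[str, ...] = ("intercept", "group")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or np.linalg.matrix_rank(m) < m.shape[1]:
            raise IntegrityError("design matrix must be full column rank")
        self.matrix = m

    @property
    def reduced(self) -> np.ndarray:
        return self.matrix[:, :1]

    @property
    def group(self) -> np.ndarray:
        return self.matrix[:, 1].astype(np.int64)


@dataclass
class GLMFit:
    """Per-gene NB GLM fits (vectorized over genes)."""

    coefficients: np.ndarray  # (genes, p), natural-log scale
    fitted: np.ndarray  # (genes, samples)
    deviance: np.ndarray  # (genes,)
    df_residual: int
    converged: np.ndarray  # (genes,) bool
    iterations: int


@dataclass
class QLFit:
    """Quasi-likelihood dispersions and their empirical-Bayes moderation."""

    nb_dispersion: float
    s2_raw: np.ndarray
    prior_df: float  # d0, may be +inf
    prior_s2: float  # s2_0
    s2_post: np.ndarray
    df_residual: int


def build_design(
    annotation: SampleAnnotation, sample_ids: list[str] | None = None
) -> DesignMatrix:
    """Intercept + group-indicator design from ALNM labels."""
    group = annotation.group_indicator(sample_ids)
    if group.sum() == 0 or group.sum() == group.size:
        raise IntegrityError("both ALNM groups must be non-empty")
    return DesignMatrix(np.column_stack([np.ones(group.size), group]))


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Unit NB deviance summed over samples; Poisson limit at phi=0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi <= 0:
        dev = ylogy - (y - mu)
    else:
        r = 1.0 / phi
        dev = ylogy - (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * dev.sum(axis=-1)


def _irls(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized IRLS over genes. Returns (beta, mu, deviance, converged, iters)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    p = X.shape[1]
    off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))

    if beta0 is None:
        mu0 = np.maximum(Y, 0.5)
        z0 = np.log(mu0) - off
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ z0.T).T
    else:
        beta = np.array(beta0, dtype=float, copy=True)

    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = eta - off + (Y - mu) / mu
        XtWX = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True)
        XtWz = np.einsum("gn,np,gn->gp", w, X, z, optimize=True)
        XtWX += 1e-12 * np.eye(p)[None, :, :]
        beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        new_dev = nb_deviance(Y, mu, phi)
        rel = np.abs(new_dev - dev) / (np.abs(new_dev) + 1.0)
        # require the score equations themselves to be satisfied, not just a
        # deviance plateau (high-count genes can plateau early)
        score = np.einsum("np,gn->gp", X, (Y - mu) / (1.0 + phi * mu), optimize=True)
        converged = (rel < tol) & (np.max(np.abs(score), axis=1) < 1e-7)
        dev = new_dev
        if converged.all():
            break
    return beta, mu, dev, converged, it


def fit_nb_glm(
    y: np.ndarray,
    design: DesignMatrix | np.ndarray,
    offset: np.ndarray,
    phi: float,
) -> GLMFit:
    """Fit the log-link NB GLM for one gene or a genes-by-samples matrix.

    Convergence: relative deviance change < 1e-10 (cap 100 iterations); at
    convergence the weighted score equations
    ``sum_i x_i (y_i - mu_i) / (1 + phi mu_i) = 0`` hold to numerical
    tolerance. Non-convergence is flagged, not fatal.
    """
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design, float)
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if not np.all(np.isfinite(offset)):
        raise IntegrityError("offsets must be finite")
    beta, mu, dev, converged, iters = _irls(Y, X, offset, phi)
    if not converged.all():
        log.warning("%d gene fit(s) did not converge in 100 IRLS iterations",
                    int((~converged).sum()))
    return GLMFit(
        coefficients=beta,
        fitted=mu,
        deviance=dev,
        df_residual=Y.shape[1] - X.shape[1],
        converged=converged,
        iterations=iters,
    )


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood (Poisson at phi ~ 0)."""
    mu = np.maximum(mu, 1e-12)
    if phi < 1e-10:
        ll = Y * np.log(mu) - mu - gammaln(Y + 1.0)
    else:
        r = 1.0 / phi
        ll = (
            gammaln(Y + r)
            - gammaln(r)
            - gammaln(Y + 1.0)
            + r * np.log(r / (r + mu))
            + Y * np.log(mu / (r + mu))
        )
    return ll.sum(axis=-1)


def _cox_reid_apl(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
                  beta0: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Summed Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    beta, mu, _, _, _ = _irls(Y, X, offset, phi, beta0=beta0)
    ll = _nb_loglik(Y, mu, phi)
    w = mu / (1.0 + phi * mu)
    XtWX = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True)
    sign, logdet = np.linalg.slogdet(XtWX)
    apl = ll - 0.5 * logdet
    return float(apl.sum()), beta


def estimate_common_dispersion(
    counts: np.ndarray,
    design: DesignMatrix | np.ndarray,
    offsets: np.ndarray,
) -> float:
    """Common NB dispersion maximizing the Cox-Reid adjusted profile
    log-likelihood, searched on the log scale over [1e-8, 10].

    Falls back to a method-of-moments estimate if the search fails.
    """
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design, float)
    Y = np.atleast_2d(np.asarray(counts, dtype=float))
    if Y.shape[1] - X.shape[1] < 2:
        raise IntegrityError("need at least 2 residual degrees of freedom")
    state: dict = {"beta": None}

    def neg_apl(log_phi: float) -> float:
        apl, beta = _cox_reid_apl(Y, X, offsets, float(np.exp(log_phi)), state["beta"])
        state["beta"] = beta
        return -apl

    try:
        res = minimize_scalar(
            neg_apl,
            bounds=(np.log(_PHI_BOUNDS[0]), np.log(_PHI_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if not res.success or not np.isfinite(res.fun):
            raise RuntimeError(res.message)
        return float(np.exp(res.x))
    except Exception as exc:  # pragma: no cover - defensive fallback
        log.warning("dispersion optimization failed (%s); method-of-moments fallback", exc)
        fit = fit_nb_glm(Y, X, offsets, 0.0)
        mu = np.maximum(fit.fitted, 1e-8)
        num = ((Y - mu) ** 2 - mu) / (mu**2)
        phi = float(np.clip(np.mean(num), *_PHI_BOUNDS))
        return phi


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s2_0) to observed dispersions.

    Treats each ``s2_g`` as ``s2_true_g * chi2(df)/df`` with ``s2_true_g``
    drawn from a scaled inverse chi-square prior; matching mean and
    variance of ``log s2`` via digamma/trigamma identities yields the prior
    degrees of freedom d0 (possibly +inf) and prior value s2_0.
    """
    s2_safe = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2_safe)
    e = z - float(digamma(df / 2.0)) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s2_0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square noise: infinite prior df; the
        # unbiased scale estimate is the plain mean, which also makes a
        # degenerate all-equal input an exact fixed point
        d0 = np.inf
        s2_0 = float(np.mean(s2_safe))
    return d0, s2_0


def ql_moderate(fit: GLMFit, min_genes: int = 10) -> QLFit:
    """Empirical-Bayes moderation of the per-gene quasi-dispersions.

    Raw dispersions ``s2_g = D_g / d_g`` are treated as scaled chi-square;
    the prior ``(d0, s2_0)`` is obtained by moment-matching the mean and
    spread of ``log s2_g`` (digamma/trigamma identities), and each gene's
    moderated value is the df-weighted average
    ``(d0 s2_0 + d_g s2_g) / (d0 + d_g)``.

    If the observed spread of ``log s2`` is no larger than its theoretical
    chi-square component (underdispersed), ``d0`` is infinite and every
    moderated value equals ``s2_0``.
    """
    G = fit.deviance.shape[0]
    if G < min_genes:
        raise IntegrityError(f"need >= {min_genes} genes to estimate the QL prior")
    dg = float(fit.df_residual)
    if dg < 1:
        raise IntegrityError("residual df must be >= 1")
    s2 = fit.deviance / dg
    d0, s2_0 = fit_f_prior(s2, dg)
    if np.isinf(d0):
        log.warning("log-dispersions underdispersed; prior df set to infinity")
        s2_post = np.full(G, s2_0)
    else:
        s2_post = (d0 * s2_0 + dg * s2) / (d0 + dg)
    s2_post = np.maximum(s2_post, 1e-10)
    return QLFit(
        nb_dispersion=np.nan,
        s2_raw=s2,
        prior_df=d0,
        prior_s2=s2_0,
        s2_post=s2_post,
        df_residual=fit.df_residual,
    )


def ql_f_test(full: GLMFit, reduced: GLMFit, ql: QLFit, df_test: int = 1) -> pd.DataFrame:
    """QL F-test of the group effect: deviance drop over the moderated
    dispersion, referred to F(df_test, d0 + d_g)."""
    diff = reduced.deviance - full.deviance
    if np.any(diff < -1e-8):
        raise IntegrityError("reduced-model deviance below full-model deviance")
    diff = np.maximum(diff, 0.0)
    F = (diff / df_test) / ql.s2_post
    df2 = ql.prior_df + full.df_residual
    df2 = min(df2, 1e8)  # F(1, inf) limit handled by a large df2
    p = f_dist.sf(F, df_test, df2)
    p = np.clip(p, _MIN_P, 1.0)
    return pd.DataFrame(
        {
            "log2FC": full.coefficients[:, 1] / LN2,
            "F": F,
            "p": p,
        }
    )


def adjust_pvalues(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise IntegrityError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "BH":
        raise ValueError(f"unknown correction {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def de_analysis(
    counts: CountMatrix,
    annotation: SampleAnnotation,
    factors: NormalizationFactors | None = None,
    config: RunConfig | None = None,
    phi: float | None = None,
) -> pd.DataFrame:
    """Full per-gene DE table: TMM offsets, common dispersion, NB GLM fits
    for the full and intercept-only models, QL moderation, F-test, BH and
    Bonferroni adjustment, and a direction call under the configured gates.

    Returns a DataFrame with columns gene, log2FC, avg_logCPM, F, p, p_BH,
    p_bonf, direction.
    """
    config = config or RunConfig()
    if factors is None:
        factors = tmm_normalize(counts)
    design = build_design(annotation, counts.sample_ids)
    offsets = np.log(factors.effective_library_size)
    Y = counts.values.astype(float)
    if phi is None:
        phi = estimate_common_dispersion(Y, design, offsets)
    full = fit_nb_glm(Y, design, offsets, phi)
    reduced = fit_nb_glm(Y, design.reduced, offsets, phi)
    ql = ql_moderate(full)
    ql.nb_dispersion = phi
    table = ql_f_test(full, reduced, ql)
    table.insert(0, "gene", counts.gene_ids)
    table.insert(2, "avg_logCPM", log_cpm(counts, factors).mean(axis=1))
    table["p_BH"] = adjust_pvalues(table["p"].to_numpy(), "BH")
    table["p_bonf"] = adjust_pvalues(table["p"].to_numpy(), "bonferroni")
    p_adj = table["p_BH"] if config.correction == "BH" else table["p_bonf"]
    sig = p_adj.to_numpy() < config.alpha
    lfc = table["log2FC"].to_numpy()
    direction = np.where(
        sig & (lfc > config.lfc_threshold),
        "up",
        np.where(sig & (lfc < -config.lfc_threshold), "down", "none"),
    )
    table["direction"] = direction
    return table
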