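"""Magnitude-Altitude Score (MAS) ranking of differential-expression results.

MAS combines effect size and statistical strength into one composite,

    MAS = |log2FC|^M * |log10 p_adj|^A,

with hyperparameters M and A (default 1 and 1: equal weight). Genes are
gated by adjusted-p significance and a |log2FC| threshold, classified as
up- or down-regulated, and ranked by MAS descending. A threshold sweep
demonstrates that the top-ranked set is stable in the gate threshold: the
top-k at threshold t equals the threshold-0 ranking restricted to genes
passing t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntegrityError

_CORRECTION_COLUMN = {"BH": "p_BH", "bonferroni": "p_bonf", "raw": "p"}


@dataclass
class MASParams:
    """MAS exponents plus the significance and fold-change gates."""

    M: float = 1.0
    A: float = 1.0
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    correction: str = "BH"

    def __post_init__(self) -> None:
        if self.M < 0 or self.A < 0:
            raise ValueError("M and A must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if self.correction not in _CORRECTION_COLUMN:
            raise ValueError("correction must be one of BH, bonferroni, raw")

    @property
    def p_column(self) -> str:
        return _CORRECTION_COLUMN[self.correction]


def mas_score(
    log2fc: float | np.ndarray, p_adj: float | np.ndarray, params: MASParams | None = None
) -> float | np.ndarray:
    """``|log2fc|^M * |log10 p_adj|^A``; zero when p_adj = 1 or log2fc = 0."""
    params = params or MASParams()
    p = np.asarray(p_adj, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise IntegrityError("adjusted p-values must lie in (0, 1]")
    lfc = np.abs(np.asarray(log2fc, dtype=float))
    with np.errstate(divide="ignore"):
        score = np.where(lfc == 0, 0.0, lfc**params.M) * np.abs(np.log10(p)) ** params.A
    return float(score) if score.ndim == 0 else score


def rank_and_classify(de: pd.DataFrame, params: MASParams | None = None) -> pd.DataFrame:
    """Gate, score, classify and rank a DE table.

    Keeps genes with ``p_adj < alpha`` and ``|log2FC| > lfc_threshold``
    (strict), labels direction by the sign of log2FC against the threshold,
    sorts by MAS descending with ties broken by larger |log2FC| then
    lexicographic gene ID, and returns columns
    gene, log2FC, p_adj, MAS, direction, rank.
    """
    params = params or MASParams()
    p_adj = de[params.p_column].to_numpy(dtype=float)
    lfc = de["log2FC"].to_numpy(dtype=float)
    scores = mas_score(lfc, p_adj, params)
    keep = (p_adj < params.alpha) & (np.abs(lfc) > params.lfc_threshold)
    out = pd.DataFrame(
        {
            "gene": de["gene"].to_numpy()[keep],
            "log2FC": lfc[keep],
            "p_adj": p_adj[keep],
            "MAS": scores[keep],
            "direction": np.where(lfc[keep] > 0, "up", "down"),
        }
    )
    out["_abs_lfc"] = out["log2FC"].abs()
    out = (
        out.sort_values(["MAS", "_abs_lfc", "gene"], ascending=[False, False, True])
        .drop(columns="_abs_lfc")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def threshold_sweep(
    de: pd.DataFrame,
    thresholds: np.ndarray | list[float] | None = None,
    top_k: int = 10,
    params: MASParams | None = None,
) -> pd.DataFrame:
    """Fig-4-style stability sweep over |log2FC| gate thresholds.

    For each threshold t: counts of significant up (log2FC > t) and down
    (log2FC < -t) genes and the comma-joined top-``top_k`` gene IDs per
    direction by MAS. Counts are non-increasing in t.
    """
    params = params or MASParams()
    if thresholds is None:
        thresholds = np.arange(0.0, 7.5, 0.5)
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    rows = []
    for t in thresholds:
        pt = MASParams(params.M, params.A, params.alpha, float(t), params.correction)
        ranked = rank_and_classify(de, pt)
        up = ranked[ranked["direction"] == "up"]
        down = ranked[ranked["direction"] == "down"]
        rows.append(
            {
                "threshold": t,
                "n_up": len(up),
                "n_down": len(down),
                "top_up": ",".join(up["gene"].head(top_k)),
                "top_down": ",".join(down["gene"].head(top_k)),
            }
        )
    return pd.DataFrame(rows)
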