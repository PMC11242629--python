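"""Trimmed-mean-of-M-values (TMM) between-sample normalization.

Computed from the defining formulas: per-gene log ratios (M) and average
log abundances (A) against a reference sample, doubly trimmed, then
averaged with inverse asymptotic-variance (delta-method binomial) weights.
Factors are rescaled to geometric mean 1; effective library size =
raw library size x factor.

Defaults (30% M-trim, 5% A-trim, upper-quartile reference choice) follow
the method's published description and are exposed as arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import CountMatrix, IntegrityError

log = logging.getLogger("glmqlmas")


@dataclass
class NormalizationFactors:
    """Per-sample library sizes, TMM factors (geometric mean 1) and
    effective library sizes."""

    sample_ids: list[str]
    library_size: np.ndarray
    tmm_factor: np.ndarray
    effective_library_size: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.tmm_factor <= 0) or not np.all(np.isfinite(self.tmm_factor)):
            raise IntegrityError("TMM factors must be finite and positive")


def choose_reference(counts: CountMatrix) -> int:
    """Pick the reference sample: the one whose 75th percentile of
    library-size-scaled counts is closest to the mean of those upper
    quartiles. Ties break to the lowest sample index."""
    if counts.n_samples < 2:
        raise IntegrityError("TMM needs at least two samples")
    lib = counts.library_sizes().astype(float)
    if np.any(lib == 0):
        raise IntegrityError("all-zero sample column")
    uq = np.percentile(counts.values / lib[None, :], 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factor(
    test: np.ndarray,
    ref: np.ndarray,
    lib_test: float,
    lib_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM scale factor of ``test`` against ``ref``.

    Only genes with positive counts in both samples enter; the top and
    bottom ``trim_m`` fraction by M and ``trim_a`` fraction by A are
    dropped (survivors = intersection); the remaining M values are averaged
    with inverse-variance weights and the factor is ``2**mean``. A sample
    against itself is exactly 1; if nothing survives trimming the factor
    falls back to 1 with a warning.
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise IntegrityError("count vectors differ in length")
    if lib_test <= 0 or lib_ref <= 0:
        raise IntegrityError("library sizes must be positive")
    if np.array_equal(test, ref) and lib_test == lib_ref:
        return 1.0

    pos = (test > 0) & (ref > 0)
    yt, yr = test[pos], ref[pos]
    if yt.size == 0:
        log.warning("no genes shared between test and reference; TMM factor set to 1")
        return 1.0
    pt, pr = yt / lib_test, yr / lib_ref
    m = np.log2(pt / pr)
    a = 0.5 * np.log2(pt * pr)
    w = 1.0 / ((lib_test - yt) / (lib_test * yt) + (lib_ref - yr) / (lib_ref * yr))

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        log.warning("no genes survive TMM trimming; factor set to 1")
        return 1.0
    mean_m = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(mean_m):
        log.warning("non-finite trimmed mean in TMM; factor set to 1")
        return 1.0
    return float(2.0**mean_m)


def tmm_normalize(
    counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Factor per sample against the chosen reference, rescaled so the
    factors have geometric mean exactly 1."""
    ref_idx = choose_reference(counts)
    lib = counts.library_sizes().astype(float)
    ref_col = counts.values[:, ref_idx]
    factors = np.array(
        [
            tmm_factor(counts.values[:, j], ref_col, lib[j], lib[ref_idx], trim_m, trim_a)
            if j != ref_idx
            else 1.0
            for j in range(counts.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        sample_ids=list(counts.sample_ids),
        library_size=lib,
        tmm_factor=factors,
        effective_library_size=lib * factors,
    )


def log_cpm(
    counts: CountMatrix, factors: NormalizationFactors, prior: float = 1.0
) -> np.ndarray:
    """Stabilized log2 counts-per-million on effective library sizes.

    With effective library ``L_i`` and mean effective library ``Lbar``, the
    per-sample prior is ``p_i = prior * L_i / Lbar`` and

        logCPM_gi = log2( 1e6 * (y_gi + p_i) / (L_i + 2 * p_i) )

    which is strictly monotone in ``y`` and equals plain log2-CPM for
    large counts.
    """
    if prior <= 0:
        raise IntegrityError("prior count must be positive")
    if list(counts.sample_ids) != list(factors.sample_ids):
        raise IntegrityError("factors do not match count matrix samples")
    eff = factors.effective_library_size.astype(float)
    p = prior * eff / eff.mean()
    return np.log2(1e6 * (counts.values + p[None, :]) / (eff + 2 * p)[None, :])
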