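"""Synthetic two-group RNA-seq cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
gene-by-sample matrix of discrete, overdispersed counts for a breast-cancer
cohort split into ALNM- and ALNM+ groups (default 65 vs 42 eligible
samples), with a protein-coding subset of the gene universe, variable
library sizes, optional one-group composition bias, and a planted fraction
of truly differential genes with known signed log2 fold changes.

Counts follow a negative binomial with mean ``lambda_g * s_i * 2**(x_i *
beta_g)`` (``x_i`` the ALNM+ indicator, ``beta_g`` the planted log2FC) and
variance ``mu + phi * mu**2``; ``phi = 0`` degenerates to Poisson. The
generator also emits ground-truth tables so recovery tests can score the
pipeline against what was planted.

Reproducibility: one master seed; each stochastic component draws from its
own substream at a fixed documented offset, so components are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ALNM_MISSING,
    ALNM_NEGATIVE,
    ALNM_POSITIVE,
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    SampleAnnotation,
)

# Fixed substream offsets added to the master seed (documented contract).
_OFFSET_STRUCTURE = 0  # baseline means, biotype layout, DE gene choice
_OFFSET_LIBSIZE = 1  # library-size factors
_OFFSET_COUNTS = 2  # count sampling
_OFFSET_GENESETS = 3  # random gene-set construction


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: a 60,660-gene annotated universe of
    which 19,938 are protein-coding, 65 ALNM- vs 42 ALNM+ untreated
    samples, gene-wise NB overdispersion, and log-uniform baseline means
    spanning e^1..e^8 expected counts so both shallow and deep genes
    exercise the normalization trimming and count discreteness.
    """

    n_genes: int = 60660
    n_coding: int = 19938
    group_sizes: tuple[int, int] = (65, 42)  # (ALNM-, ALNM+)
    baseline_log_mean_range: tuple[float, float] = (1.0, 8.0)  # natural log
    dispersion: float | np.ndarray = 0.1
    libsize_factors: np.ndarray | None = None  # default: lognormal(0, 0.3)
    libsize_sigma: float = 0.3
    de_fraction: float = 0.05
    de_log2fc_magnitudes: tuple[float, ...] = (1.0, 2.0, 3.0)
    composition_bias_fraction: float = 0.0
    composition_bias_factor: float = 20.0
    missing_alnm_count: int = 0
    treated_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or not (0 < self.n_coding <= self.n_genes):
            raise ValueError("need 1 <= n_coding <= n_genes")
        if min(self.group_sizes) < 1:
            raise ValueError("group sizes must be positive")
        phi = np.asarray(self.dispersion, dtype=float)
        if not np.all(np.isfinite(phi)) or np.any(phi < 0):
            raise ValueError("dispersion must be finite and >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.composition_bias_fraction < 1.0:
            raise ValueError("composition_bias_fraction must be in [0, 1)")
        if any(m <= 0 for m in self.de_log2fc_magnitudes):
            raise ValueError("log2FC magnitudes must be positive")
        if self.missing_alnm_count < 0 or self.treated_count < 0:
            raise ValueError("extra-sample counts must be non-negative")
        if self.libsize_factors is not None:
            lf = np.asarray(self.libsize_factors, dtype=float)
            if np.any(~np.isfinite(lf)) or np.any(lf <= 0):
                raise ValueError("libsize factors must be finite and > 0")
            if lf.size != self.n_samples:
                raise ValueError("libsize_factors length must equal total sample count")
            self.libsize_factors = lf

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes) + self.missing_alnm_count + self.treated_count

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort.

    ``genes`` has one row per gene: ``gene_id``, ``is_de``, ``true_log2fc``
    (signed, 0 when not DE), ``biotype``, ``composition_bias`` (True for
    one-group high expressors that are not counted as planted DE).
    ``sample_scales`` is the true per-sample sequencing-depth factor the
    normalization stage should recover (up to a constant).
    """

    genes: pd.DataFrame
    sample_scales: np.ndarray = field(default=None)

    @property
    def de_gene_ids(self) -> list[str]:
        return self.genes.loc[self.genes["is_de"], "gene_id"].tolist()


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + phi*mu^2; phi=0 is Poisson."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        shape = 1.0 / phi[~pois]
        lam = rng.gamma(shape, mu[~pois] * phi[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def generate_cohort(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleAnnotation, GeneAnnotation, TruthTable]:
    """Simulate a cohort under ``config``; deterministic given its seed.

    Extra samples requested via ``missing_alnm_count`` / ``treated_count``
    are appended after the eligible groups with baseline (ALNM-) expression;
    they exist to exercise the cohort filters and carry the literal missing
    status or treatment flags.
    """
    rng_struct = np.random.default_rng(config.seed + _OFFSET_STRUCTURE)
    rng_lib = np.random.default_rng(config.seed + _OFFSET_LIBSIZE)
    rng_counts = np.random.default_rng(config.seed + _OFFSET_COUNTS)

    G, S = config.n_genes, config.n_samples
    n_neg, n_pos = config.group_sizes
    gene_ids = [f"G{str(i).zfill(len(str(G)))}" for i in range(1, G + 1)]
    sample_ids = [f"S{str(i).zfill(len(str(S)))}" for i in range(1, S + 1)]

    # Biotypes: the first n_coding genes are protein-coding after a fixed
    # shuffle, so coding genes are spread over the expression range.
    order = rng_struct.permutation(G)
    biotype = np.full(G, "other", dtype=object)
    coding_idx = order[: config.n_coding]
    biotype[coding_idx] = "protein_coding"
    noncoding_idx = order[config.n_coding :]
    if noncoding_idx.size:
        other_types = rng_struct.choice(
            ["lncRNA", "miRNA", "pseudogene", "other"], size=noncoding_idx.size
        )
        biotype[noncoding_idx] = other_types

    lo, hi = config.baseline_log_mean_range
    baseline = np.exp(rng_struct.uniform(lo, hi, size=G))

    # Planted DE genes are drawn from the protein-coding subset so recovery
    # remains observable after the coding restriction.
    n_de = config.n_de
    if n_de > config.n_coding:
        raise ValueError("de_fraction implies more DE genes than protein-coding genes")
    de_idx = rng_struct.choice(coding_idx, size=n_de, replace=False)
    magnitudes = rng_struct.choice(np.asarray(config.de_log2fc_magnitudes), size=n_de)
    signs = rng_struct.choice([-1.0, 1.0], size=n_de)
    true_log2fc = np.zeros(G)
    true_log2fc[de_idx] = magnitudes * signs

    # Composition-bias genes: expressed at `composition_bias_factor` x
    # baseline only in the ALNM+ group; disjoint from planted DE genes.
    comp_mask = np.zeros(G, dtype=bool)
    n_comp = int(round(config.composition_bias_fraction * G))
    if n_comp:
        candidates = np.setdiff1d(np.arange(G), de_idx, assume_unique=False)
        comp_idx = rng_struct.choice(candidates, size=n_comp, replace=False)
        comp_mask[comp_idx] = True

    if config.libsize_factors is not None:
        scales = np.asarray(config.libsize_factors, dtype=float)
    else:
        scales = np.exp(rng_lib.normal(0.0, config.libsize_sigma, size=S))

    group = np.zeros(S, dtype=np.int64)  # ALNM+ indicator
    group[n_neg : n_neg + n_pos] = 1

    mu = baseline[:, None] * scales[None, :]
    mu = mu * np.exp2(true_log2fc[:, None] * group[None, :])
    if n_comp:
        bias = np.ones((G, S))
        bias[np.ix_(comp_mask, group == 1)] = config.composition_bias_factor
        mu = mu * bias

    phi = np.asarray(config.dispersion, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    counts = _nb_sample(rng_counts, mu, np.broadcast_to(phi, mu.shape))

    status = np.where(group == 1, ALNM_POSITIVE, ALNM_NEGATIVE).astype(object)
    chemo = np.zeros(S, dtype=bool)
    radio = np.zeros(S, dtype=bool)
    extra_start = n_neg + n_pos
    miss_end = extra_start + config.missing_alnm_count
    status[extra_start:miss_end] = ALNM_MISSING
    for j in range(miss_end, S):  # treated extras alternate chemo/radio
        if (j - miss_end) % 2 == 0:
            chemo[j] = True
        else:
            radio[j] = True

    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "alnm_status": status,
                "prior_chemo": chemo,
                "prior_radio": radio,
            }
        )
    )
    genes = GeneAnnotation(pd.DataFrame({"gene_id": gene_ids, "biotype": biotype}))
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_de": true_log2fc != 0.0,
                "true_log2fc": true_log2fc,
                "biotype": biotype,
                "composition_bias": comp_mask,
            }
        ),
        sample_scales=scales,
    )
    return CountMatrix(gene_ids, sample_ids, counts), annotation, genes, truth


def generate_gene_sets(
    gene_ids: list[str],
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 50),
    planted_set_from: TruthTable | None = None,
    planted_fraction: float = 0.8,
    planted_size: int | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Build a random GMT-style collection over ``gene_ids``.

    Sets are drawn without replacement within each set. When
    ``planted_set_from`` is given, the first set ("PLANTED_DE") contains
    ``planted_fraction`` true-DE genes (rounded) and random fillers, giving
    enrichment tests a set that must rank first.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    lo, hi = set_size_range
    if hi > len(gene_ids):
        raise ValueError("set size range exceeds gene universe")
    rng = np.random.default_rng(seed + _OFFSET_GENESETS)
    universe = np.asarray(gene_ids, dtype=object)
    collection = GeneSetCollection()

    if planted_set_from is not None:
        de_ids = [g for g in planted_set_from.de_gene_ids if g in set(gene_ids)]
        size = planted_size if planted_size is not None else min(hi, max(lo, 20))
        n_true = int(round(planted_fraction * size))
        n_true = min(n_true, len(de_ids))
        chosen_de = rng.choice(np.asarray(de_ids, dtype=object), size=n_true, replace=False)
        fillers = np.setdiff1d(universe, chosen_de)
        filler = rng.choice(fillers, size=size - n_true, replace=False)
        members = list(chosen_de) + list(filler)
        collection.sets["PLANTED_DE"] = members
        collection.descriptions["PLANTED_DE"] = "synthetic set enriched for planted DE genes"

    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        name = f"RANDOM_SET_{k + 1:03d}"
        collection.sets[name] = list(members)
        collection.descriptions[name] = "synthetic random gene set"
    return collection
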