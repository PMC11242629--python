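"""Cohort and gene-universe filters applied before testing.

The study design keeps only untreated samples with a known axillary
lymph-node status, restricts the gene universe to protein-coding genes and
drops genes with zero counts everywhere (inestimable in a log-link GLM).
All filters are idempotent and report what they removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import (
    ALNM_MISSING,
    CountMatrix,
    GeneAnnotation,
    IntegrityError,
    SampleAnnotation,
)

log = logging.getLogger("glmqlmas")


@dataclass
class CohortReport:
    """Counts removed at each cohort-filter step, applied in order:
    missing ALNM status first, then prior treatment."""

    n_input: int
    n_missing_alnm: int
    n_treated: int
    n_retained: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_missing_alnm": self.n_missing_alnm,
            "removed_treated": self.n_treated,
            "n_retained": self.n_retained,
        }


def filter_cohort(annotation: SampleAnnotation) -> tuple[SampleAnnotation, CohortReport]:
    """Keep samples with known ALNM status and no prior chemo/radiotherapy."""
    t = annotation.table
    if t.empty:
        raise IntegrityError("sample annotation is empty")
    known = t["alnm_status"] != ALNM_MISSING
    untreated = ~(t["prior_chemo"] | t["prior_radio"])
    kept = t[known & untreated].reset_index(drop=True)
    report = CohortReport(
        n_input=len(t),
        n_missing_alnm=int((~known).sum()),
        n_treated=int((known & ~untreated).sum()),
        n_retained=len(kept),
    )
    if report.n_retained == 0:
        log.warning("cohort filter removed every sample")
    return SampleAnnotation(kept), report


def filter_protein_coding(counts: CountMatrix, genes: GeneAnnotation) -> CountMatrix:
    """Restrict count rows to protein-coding genes, preserving order."""
    biotype = genes.biotype_of()
    missing = [g for g in counts.gene_ids if g not in biotype.index]
    if missing:
        raise IntegrityError(f"unannotated gene IDs in count matrix: {missing[:5]}")
    keep = np.array([biotype[g] == "protein_coding" for g in counts.gene_ids])
    if not keep.any():
        log.warning("no protein-coding genes in count matrix")
    return counts.subset_genes(keep)


def drop_unexpressed(counts: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Remove genes whose total count over all samples is zero."""
    totals = counts.values.sum(axis=1)
    keep = totals > 0
    removed = [g for g, k in zip(counts.gene_ids, keep) if not k]
    if not keep.any():
        log.warning("all genes are unexpressed")
    return counts.subset_genes(keep), removed
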