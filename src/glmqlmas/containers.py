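"""Core in-memory containers shared across the pipeline.

Counts are stored genes-in-rows, the prevailing convention for bulk
expression matrices. Sample and gene annotations are thin frames with a
validated column contract; the heavier per-gene result tables (DE tables,
resampling summaries, enrichment results) are plain pandas DataFrames
documented where they are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleAnnotation",
    "GeneAnnotation",
    "GeneSetCollection",
    "DuplicateIDError",
    "IntegrityError",
]

#: alnm_status levels used internally; on disk they map to ALNM+/ALNM-/NA.
ALNM_POSITIVE = "positive"
ALNM_NEGATIVE = "negative"
ALNM_MISSING = "missing"

BIOTYPES = ("protein_coding", "lncRNA", "miRNA", "pseudogene", "other")


class DuplicateIDError(ValueError):
    """Raised when gene or sample identifiers are not unique."""


class IntegrityError(ValueError):
    """Raised when a table violates its declared value contract
    (negative counts, non-integer entries, ragged rows, unknown labels)."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()[:5]
        raise DuplicateIDError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample count matrix.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers.
    values
        ``(n_genes, n_samples)`` integer array, all entries >= 0.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise IntegrityError(
                f"count matrix shape {v.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.issubdtype(v.dtype, np.floating):
            if not np.all(np.isfinite(v)) or np.any(v != np.round(v)):
                raise IntegrityError("counts must be finite integers")
            v = v.astype(np.int64)
        if np.any(v < 0):
            raise IntegrityError("counts must be non-negative")
        self.values = np.ascontiguousarray(v, dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums."""
        return self.values.sum(axis=0)

    def subset_genes(self, keep: np.ndarray | list) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:  # gene IDs
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return CountMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, keep: np.ndarray | list) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return CountMatrix(
            list(self.gene_ids), [self.sample_ids[i] for i in idx], self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SampleAnnotation:
    """Per-sample phenotype table.

    ``table`` columns: ``sample_id`` (unique), ``alnm_status`` in
    {positive, negative, missing}, ``prior_chemo`` and ``prior_radio``
    booleans (any prior chemo-/radiotherapy).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        required = {"sample_id", "alnm_status", "prior_chemo", "prior_radio"}
        missing = required - set(t.columns)
        if missing:
            raise IntegrityError(f"sample annotation missing columns: {sorted(missing)}")
        _check_unique(t["sample_id"], "sample")
        bad = ~t["alnm_status"].isin([ALNM_POSITIVE, ALNM_NEGATIVE, ALNM_MISSING])
        if bad.any():
            row = t.index[bad][0]
            raise IntegrityError(
                f"unknown ALNM status {t.loc[row, 'alnm_status']!r} "
                f"for sample {t.loc[row, 'sample_id']!r} (row {row})"
            )
        t["prior_chemo"] = t["prior_chemo"].astype(bool)
        t["prior_radio"] = t["prior_radio"].astype(bool)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_indicator(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """0/1 vector, 1 = ALNM positive. Missing-status samples are rejected."""
        t = self.table.set_index("sample_id")
        ids = sample_ids if sample_ids is not None else self.sample_ids
        status = t.loc[ids, "alnm_status"]
        if (status == ALNM_MISSING).any():
            raise IntegrityError("group indicator requested for samples with missing ALNM status")
        return (status == ALNM_POSITIVE).to_numpy().astype(np.int64)

    def subset(self, sample_ids: list[str]) -> "SampleAnnotation":
        t = self.table.set_index("sample_id").loc[sample_ids].reset_index()
        return SampleAnnotation(t)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: ``gene_id`` (unique) and ``biotype``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        if not {"gene_id", "biotype"} <= set(t.columns):
            raise IntegrityError("gene annotation requires gene_id and biotype columns")
        _check_unique(t["gene_id"], "gene")
        bad = ~t["biotype"].isin(BIOTYPES)
        if bad.any():
            raise IntegrityError(
                f"unknown biotype(s): {sorted(t.loc[bad, 'biotype'].unique())}"
            )
        self.table = t

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def biotype_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["biotype"]


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-like or Hallmark-like), as read from GMT.

    ``sets`` maps set name -> ordered unique member IDs; ``descriptions``
    keeps the GMT description field.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])
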