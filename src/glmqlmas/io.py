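"""Readers and writers for the on-disk formats used by the pipeline.

Counts, annotations and result tables travel as tab-separated text; gene
sets travel as GMT. Writers emit a deterministic column order with floats
at 12 significant digits, so equal configurations yield byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ALNM_MISSING,
    ALNM_NEGATIVE,
    ALNM_POSITIVE,
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    IntegrityError,
    SampleAnnotation,
)

log = logging.getLogger("glmqlmas")

FLOAT_FORMAT = "%.12g"

_STATUS_TO_LABEL = {ALNM_POSITIVE: "ALNM+", ALNM_NEGATIVE: "ALNM-", ALNM_MISSING: "NA"}
_LABEL_TO_STATUS = {v: k for k, v in _STATUS_TO_LABEL.items()}


class GMTFormatError(ValueError):
    """Raised for GMT lines with fewer than three tab-separated fields."""


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene-by-sample count TSV (header = sample IDs, first column =
    gene IDs). Raises :class:`IntegrityError` for ragged rows, negative or
    non-integer entries, and :class:`DuplicateIDError` for repeated IDs."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n_col = len(header)
        gene_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_col:
                raise IntegrityError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_col})"
                )
            gene_ids.append(fields[0])
            rows.append(fields[1:])
    try:
        values = np.array(rows, dtype=np.float64)
    except ValueError as exc:
        raise IntegrityError(f"{path}: non-numeric count entry ({exc})") from None
    if values.size and (np.any(values < 0) or np.any(values != np.round(values))):
        raise IntegrityError(f"{path}: counts must be non-negative integers")
    values = values.astype(np.int64).reshape(len(gene_ids), len(sample_ids))
    return CountMatrix(gene_ids, sample_ids, values)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Read the sample annotation TSV (sample_id, alnm_status as
    ALNM+/ALNM-/NA, prior_chemo, prior_radio)."""
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    if "alnm_status" not in t.columns:
        raise IntegrityError(f"{path}: missing alnm_status column")
    bad = ~t["alnm_status"].isin(_LABEL_TO_STATUS)
    if bad.any():
        row = t.index[bad][0]
        raise IntegrityError(
            f"{path}: unknown ALNM label {t.loc[row, 'alnm_status']!r} at row {row + 2} "
            f"(sample {t.loc[row].get('sample_id', '?')!r})"
        )
    t = t.copy()
    t["alnm_status"] = t["alnm_status"].map(_LABEL_TO_STATUS)
    for col in ("prior_chemo", "prior_radio"):
        if t[col].dtype == object:
            t[col] = t[col].map({"True": True, "False": False, "1": True, "0": False})
    return SampleAnnotation(t)


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    t = annotation.table.copy()
    t["alnm_status"] = t["alnm_status"].map(_STATUS_TO_LABEL)
    t.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a line are deduplicated (order preserved) with
    a logged warning; a line with fewer than three fields raises
    :class:`GMTFormatError`.
    """
    collection = GeneSetCollection()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < sum(1 for m in members if m):
                log.warning("GMT set %s has duplicate members; deduplicated", name)
            collection.sets[name] = unique
            collection.descriptions[name] = desc
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with fixed 12-significant-digit floats."""
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path: str | Path) -> dict:
    """Read a flat key-value configuration file (YAML-compatible subset)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise IntegrityError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_manifest(out_dir: str | Path, inputs: dict, config: dict) -> Path:
    """Write a run manifest (inputs, configuration, seed, versions) next to
    the outputs so every run is traceable."""
    import glmqlmas

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "versions": {
            "glmqlmas": glmqlmas.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
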