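"""End-to-end orchestration of the GLMQL-MAS analysis.

Chains the pipeline stages in the study's order: cohort and gene filters,
TMM normalization, NB quasi-likelihood differential expression, MAS gating
and ranking with a threshold sweep (Case 1), balanced resampling with the
directional-consistency rule (Case 2), the Case-1/Case-2 intersection,
over-representation analysis of the significant lists and separability
diagnostics. All randomness flows from the supplied seeds, so two runs on
equal inputs produce identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .cohort import CohortReport, drop_unexpressed, filter_cohort, filter_protein_coding
from .config import RunConfig
from .containers import CountMatrix, GeneAnnotation, GeneSetCollection, SampleAnnotation
from .diagnostics import lda1, pc_sweep
from .enrich import ora, results_to_frame
from .glm import de_analysis
from .mas import MASParams, rank_and_classify, threshold_sweep
from .resample import ResamplingConfig, intersect_cases, qualify, run_resampling
from .tmm import NormalizationFactors, log_cpm, tmm_normalize

log = logging.getLogger("glmqlmas")


@dataclass
class PipelineResult:
    """Everything one pipeline run computes."""

    counts: CountMatrix
    annotation: SampleAnnotation
    cohort_report: CohortReport
    dropped_genes: list[str]
    factors: NormalizationFactors
    de_table: pd.DataFrame
    ranked: pd.DataFrame
    sweep: pd.DataFrame
    resampling: pd.DataFrame | None = None
    biomarkers: pd.DataFrame | None = None
    intersection: dict | None = None
    enrichment: pd.DataFrame | None = None
    pc_curves: pd.DataFrame | None = None
    lda_separation: float | None = None
    extras: dict = field(default_factory=dict)


def run_pipeline(
    counts: CountMatrix,
    samples: SampleAnnotation,
    genes: GeneAnnotation,
    gene_sets: GeneSetCollection | None = None,
    run_config: RunConfig | None = None,
    resampling: ResamplingConfig | None = None,
    top_n_diagnostics: int = 100,
    pc_range: range = range(2, 21),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; optionally write all result tables under
    ``out_dir`` (deterministic formatting, plus a run manifest)."""
    run_config = run_config or RunConfig()

    kept, report = filter_cohort(samples)
    counts = counts.subset_samples(kept.sample_ids)
    counts = filter_protein_coding(counts, genes)
    counts, dropped = drop_unexpressed(counts)
    log.info(
        "cohort: %d samples retained; %d protein-coding genes analyzed",
        counts.n_samples, counts.n_genes,
    )

    factors = tmm_normalize(counts)
    de = de_analysis(counts, kept, factors, run_config)
    params = MASParams(
        M=run_config.mas_M,
        A=run_config.mas_A,
        alpha=run_config.alpha,
        lfc_threshold=run_config.lfc_threshold,
        correction=run_config.correction,
    )
    ranked = rank_and_classify(de, params)
    sweep = threshold_sweep(de, params=params)

    result = PipelineResult(
        counts=counts,
        annotation=kept,
        cohort_report=report,
        dropped_genes=dropped,
        factors=factors,
        de_table=de,
        ranked=ranked,
        sweep=sweep,
    )

    if resampling is not None:
        summary = run_resampling(counts, kept, resampling, run_config)
        result.resampling = summary.to_frame()
        biomarkers = qualify(summary, resampling)
        result.biomarkers = biomarkers
        first_thr = biomarkers[biomarkers["threshold"] == summary.thresholds[0]]
        result.intersection = intersect_cases(ranked, first_thr)

    if gene_sets is not None and len(gene_sets):
        sig = ranked["gene"].tolist()
        universe = counts.gene_ids
        enr = ora(sig, universe, gene_sets)
        result.enrichment = results_to_frame(enr)

    labels = kept.group_indicator(counts.sample_ids)
    lcpm = log_cpm(counts, factors)
    selected = ranked["gene"].head(top_n_diagnostics).tolist()
    if len(selected) >= 2:
        sel_idx = [counts.gene_ids.index(g) for g in selected]
        k_max = min(counts.n_samples - 1, len(sel_idx))
        ks = [k for k in pc_range if k <= k_max]
        if ks:
            result.pc_curves = pc_sweep(lcpm, lcpm[sel_idx], labels, ks)
        _, sep = lda1(lcpm[sel_idx], labels)
        result.lda_separation = sep
    else:
        log.warning("fewer than 2 selected genes; diagnostics skipped")

    if out_dir is not None:
        _write_outputs(result, Path(out_dir), run_config)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, run_config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    gio.write_table(result.de_table, out_dir / "de_table.tsv")
    gio.write_table(result.ranked, out_dir / "mas_ranked.tsv")
    gio.write_table(result.sweep, out_dir / "threshold_sweep.tsv")
    factors = result.factors
    gio.write_table(
        pd.DataFrame(
            {
                "sample_id": factors.sample_ids,
                "lib_size": factors.library_size.astype(np.int64),
                "tmm_factor": factors.tmm_factor,
                "eff_lib_size": factors.effective_library_size,
            }
        ),
        out_dir / "normalization_factors.tsv",
    )
    gio.write_table(
        pd.DataFrame([result.cohort_report.as_dict()]), out_dir / "cohort_report.tsv"
    )
    if result.resampling is not None:
        gio.write_table(result.resampling, out_dir / "resampling_counts.tsv")
        gio.write_table(result.biomarkers, out_dir / "biomarkers.tsv")
    if result.enrichment is not None:
        gio.write_table(result.enrichment, out_dir / "enrichment.tsv")
    if result.pc_curves is not None:
        gio.write_table(result.pc_curves, out_dir / "pc_sweep.tsv")
    gio.write_manifest(
        out_dir,
        inputs={"n_genes": result.counts.n_genes, "n_samples": result.counts.n_samples},
        config={
            "alpha": run_config.alpha,
            "mas_M": run_config.mas_M,
            "mas_A": run_config.mas_A,
            "lfc_threshold": run_config.lfc_threshold,
            "correction": run_config.correction,
            "seed": run_config.seed,
        },
    )
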