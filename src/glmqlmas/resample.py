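"""Balanced-resampling directional-consistency biomarker selection.

The full cohort comparison (Case 1) is unbalanced (65 ALNM- vs 42 ALNM+).
Case 2 repeatedly draws a random balanced control group: in each of R
iterations (default 500) a subsample of the majority group equal in size
to the minority group is taken, the whole analysis (TMM normalization, NB
quasi-likelihood GLM, BH correction) is re-run on that balanced cohort,
and each gene's significant up/down calls are counted per |log2FC|
threshold. A gene qualifies as a biomarker candidate when it is
BH-significant in the same direction in at least half the iterations with
no opposite-direction occurrence; genes consistent in all R iterations
form the strongest tier.

Iterations are independent given their derived seeds (base_seed + i), so
any execution order yields identical summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import ALNM_NEGATIVE, ALNM_POSITIVE, CountMatrix, IntegrityError, SampleAnnotation
from .cohort import drop_unexpressed
from .glm import de_analysis
from .tmm import tmm_normalize

log = logging.getLogger("glmqlmas")


@dataclass
class ResamplingConfig:
    """Balanced-resampling settings.

    R
        Number of balanced iterations (default 500).
    subsample_size
        Majority-group samples drawn per iteration; defaults to the
        minority group size (42 in the emulated cohort).
    min_count
        Same-direction significant iterations required to qualify
        (default ceil(R/2), i.e. 250 of 500).
    lfc_thresholds
        |log2FC| gates at which up/down occurrences are counted
        (default 1..6).
    allow_opposite_count
        When False (default) any opposite-direction occurrence
        disqualifies a gene; when True the laxer reading applies
        (opposite occurrences < min_count).
    """

    R: int = 500
    subsample_size: int | None = None
    min_count: int | None = None
    lfc_thresholds: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    base_seed: int = 0
    allow_opposite_count: bool = False

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be positive")
        if self.min_count is None:
            self.min_count = int(np.ceil(self.R / 2))
        if not 0 < self.min_count <= self.R:
            raise ValueError("min_count must be in [1, R]")
        if any(t < 0 for t in self.lfc_thresholds):
            raise ValueError("thresholds must be non-negative")


@dataclass
class ResamplingSummary:
    """Per-gene, per-threshold counts of BH-significant up/down calls."""

    gene_ids: list[str]
    thresholds: tuple[float, ...]
    up_counts: np.ndarray  # (genes, thresholds)
    down_counts: np.ndarray
    R: int
    config: ResamplingConfig = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, t in enumerate(self.thresholds):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.gene_ids,
                        "threshold": t,
                        "up_count": self.up_counts[:, j],
                        "down_count": self.down_counts[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_resampling(
    counts: CountMatrix,
    annotation: SampleAnnotation,
    config: ResamplingConfig | None = None,
    run_config: RunConfig | None = None,
) -> ResamplingSummary:
    """Run R balanced iterations and count directional significant calls.

    Iteration i draws its majority subsample with seed ``base_seed + i``,
    re-normalizes, refits the GLMQL model and applies BH within that
    iteration's analyzed genes. Genes dropped in an iteration (all-zero in
    the subsample) count as not significant there.
    """
    config = config or ResamplingConfig()
    run_config = run_config or RunConfig()
    ann = annotation.subset(counts.sample_ids)
    status = ann.table.set_index("sample_id")["alnm_status"]
    pos_ids = [s for s in counts.sample_ids if status[s] == ALNM_POSITIVE]
    neg_ids = [s for s in counts.sample_ids if status[s] == ALNM_NEGATIVE]
    if not pos_ids or not neg_ids:
        raise IntegrityError("both ALNM groups must be present")
    if len(pos_ids) <= len(neg_ids):
        minority, majority = pos_ids, neg_ids
    else:
        minority, majority = neg_ids, pos_ids
    k = config.subsample_size or len(minority)
    if k > len(majority):
        raise IntegrityError("subsample size exceeds majority group size")

    G = counts.n_genes
    T = len(config.lfc_thresholds)
    up = np.zeros((G, T), dtype=np.int64)
    down = np.zeros((G, T), dtype=np.int64)
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    thr = np.asarray(config.lfc_thresholds)

    for i in range(config.R):
        rng = np.random.default_rng(config.base_seed + i)
        drawn = list(np.asarray(majority, dtype=object)[
            rng.choice(len(majority), size=k, replace=False)
        ])
        cohort_ids = minority + drawn
        sub = counts.subset_samples(cohort_ids)
        sub, _ = drop_unexpressed(sub)
        factors = tmm_normalize(sub)
        de = de_analysis(sub, ann.subset(cohort_ids), factors, run_config)
        sig = de["p_BH"].to_numpy() < run_config.alpha
        lfc = de["log2FC"].to_numpy()
        idx = np.array([gene_pos[g] for g in de["gene"]])
        for j, t in enumerate(thr):
            up[idx[sig & (lfc > t)], j] += 1
            down[idx[sig & (lfc < -t)], j] += 1
        if (i + 1) % 10 == 0:
            log.info("resampling iteration %d/%d", i + 1, config.R)

    return ResamplingSummary(
        gene_ids=list(counts.gene_ids),
        thresholds=tuple(config.lfc_thresholds),
        up_counts=up,
        down_counts=down,
        R=config.R,
        config=config,
    )


def qualify(summary: ResamplingSummary, config: ResamplingConfig | None = None) -> pd.DataFrame:
    """Apply the directional-consistency rule per gene and threshold.

    A gene qualifies UP when ``up_count >= min_count`` and (strict reading)
    ``down_count == 0``; DOWN symmetrically. ``tier`` is "strongest" when
    the qualifying count equals R, else "candidate"; non-qualifying genes
    carry direction "none". No gene qualifies in both directions.
    """
    config = config or summary.config or ResamplingConfig(R=summary.R)
    rows = []
    for j, t in enumerate(summary.thresholds):
        u = summary.up_counts[:, j]
        d = summary.down_counts[:, j]
        if config.allow_opposite_count:
            up_ok = (u >= config.min_count) & (d < config.min_count)
            down_ok = (d >= config.min_count) & (u < config.min_count)
        else:
            up_ok = (u >= config.min_count) & (d == 0)
            down_ok = (d >= config.min_count) & (u == 0)
        direction = np.where(up_ok, "up", np.where(down_ok, "down", "none"))
        qcount = np.where(up_ok, u, np.where(down_ok, d, 0))
        tier = np.where(
            (up_ok | down_ok) & (qcount == summary.R), "strongest",
            np.where(up_ok | down_ok, "candidate", "none"),
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene": summary.gene_ids,
                    "threshold": t,
                    "up_count": u,
                    "down_count": d,
                    "qualified": up_ok | down_ok,
                    "direction": direction,
                    "tier": tier,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def intersect_cases(case1_ranked: pd.DataFrame, case2_table: pd.DataFrame) -> dict[str, list[str]]:
    """Genes significant in both the full comparison (Case 1, MAS-ranked)
    and the resampling selection (Case 2), per direction, in Case-1 MAS
    order."""
    out: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        c1 = case1_ranked.loc[case1_ranked["direction"] == direction, "gene"].tolist()
        c2 = set(
            case2_table.loc[
                case2_table["qualified"] & (case2_table["direction"] == direction), "gene"
            ]
        )
        out[direction] = [g for g in c1 if g in c2]
    return out
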