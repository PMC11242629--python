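"""Separability diagnostics: before vs after gene selection.

With only 1% of 3,000 genes weakly differential, principal components of
the full matrix barely separate the groups; after selecting the top-100 MAS
genes the same logistic model separates them almost perfectly. LDA1
projects the selected genes onto one axis for the same story. These are
resubstitution metrics — illustrations of separability, not predictions.
"""

from glmqlmas import (
    MASParams,
    SimulationConfig,
    de_analysis,
    drop_unexpressed,
    generate_cohort,
    lda1,
    rank_and_classify,
    tmm_normalize,
)
from glmqlmas.diagnostics import pc_sweep
from glmqlmas.tmm import log_cpm

cfg = SimulationConfig(
    n_genes=3000, n_coding=3000, group_sizes=(65, 42),
    de_fraction=0.01, de_log2fc_magnitudes=(1.0, 1.5), dispersion=0.4, seed=5,
)
counts, samples, _, _ = generate_cohort(cfg)
counts, _ = drop_unexpressed(counts)
factors = tmm_normalize(counts)
de = de_analysis(counts, samples, factors)

selected = rank_and_classify(de, MASParams(lfc_threshold=0.5))["gene"].head(100).tolist()
idx = [counts.gene_ids.index(g) for g in selected]
lcpm = log_cpm(counts, factors)
labels = samples.group_indicator(counts.sample_ids)

curves = pc_sweep(lcpm, lcpm[idx], labels, k_range=range(2, 21, 2))
print(curves.pivot(index="k", columns="stage",
                   values="sensitivity").rename_axis(None, axis=1))

_, separation = lda1(lcpm[idx], labels)
print(f"\nLDA1 separation fraction on the top-100 selected genes: {separation:.3f}")
# sensitivity("after") should dominate sensitivity("before") across k: the
# selection concentrates the group signal that the full matrix dilutes
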