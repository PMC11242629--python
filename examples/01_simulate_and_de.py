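"""Simulate a two-group RNA-seq cohort and run the NB quasi-likelihood DE test.

Builds a 65 vs 42 cohort (the ALNM-/ALNM+ design) with 10% of genes planted
at |log2FC| = 2, TMM-normalizes it and fits the per-gene GLMQL model. The
printed table shows each top gene's fold change, F statistic and adjusted
p-value; recall/FDR report how well the BH + |log2FC| > 1 gate recovers the
planted truth.
"""

import numpy as np

from glmqlmas import (
    SimulationConfig,
    de_analysis,
    drop_unexpressed,
    generate_cohort,
    tmm_normalize,
)

cfg = SimulationConfig(
    n_genes=2000, n_coding=2000, group_sizes=(65, 42),
    de_fraction=0.10, de_log2fc_magnitudes=(2.0,), dispersion=0.1, seed=1,
)
counts, samples, genes, truth = generate_cohort(cfg)
counts, _ = drop_unexpressed(counts)

factors = tmm_normalize(counts)
de = de_analysis(counts, samples, factors)

sig = de["p_BH"].to_numpy() < 0.05
called = sig & (de["log2FC"].abs().to_numpy() > 1.0)
is_de = truth.genes.set_index("gene_id").loc[de["gene"], "is_de"].to_numpy()

print(de.sort_values("p").head(8).to_string(index=False))
print(f"\nBH-significant: {sig.sum()} of {len(de)} genes "
      f"({100 * sig.mean():.1f}%)")
print(f"recall of planted genes: {(called & is_de).sum() / is_de.sum():.3f}")
print(f"empirical FDR of the gated call set: "
      f"{(called & ~is_de).sum() / max(called.sum(), 1):.3f}")
# recall near 1 and FDR near 0 mean the planted effects are found without
# flooding the list with false positives
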