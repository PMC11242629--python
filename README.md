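# glmqlmas

Differential-expression analysis and biomarker ranking for two-group bulk
RNA-seq cohorts, built around the **GLMQL-MAS** procedure: negative-binomial
quasi-likelihood F-tests combined with **Magnitude-Altitude Score** ranking,
balanced-resampling consistency selection, gene-set over-representation and
low-dimensional separability diagnostics.

The motivating problem is axillary lymph-node metastasis (ALNM) in breast
cancer: given raw RNA-seq counts for ALNM− and ALNM+ patients (an unbalanced
65 vs 42 design after removing treated samples and samples with unknown nodal
status), find protein-coding genes whose expression robustly distinguishes
the groups. The package ships a synthetic-cohort generator that emulates this
design with planted ground truth, so every stage can be validated end to end
without any external download.

## The method

1. **Cohort and gene filters** — keep untreated samples with known ALNM
   status; restrict to protein-coding genes; drop genes with zero counts
   everywhere.
2. **TMM normalization** — per-sample scale factors from the doubly trimmed,
   precision-weighted mean of per-gene log ratios (M) against a reference
   sample, correcting library-size and composition differences; effective
   library size = library size × factor.
3. **GLMQL differential expression** — per gene *g*, counts follow a
   log-link negative binomial, `log mu_gi = beta_0g + beta_1g x_i + log N_i`
   (`x_i` = ALNM+ indicator, `N_i` = effective library size), with variance
   `mu + phi mu^2`. A common `phi` is estimated by Cox–Reid adjusted profile
   likelihood; per-gene quasi-dispersions `s2_g = deviance/df` are shrunk by
   empirical Bayes toward a common prior; the group effect is tested with
   `F_g = (D_reduced - D_full) / s2_g,post ~ F(1, d0 + d_g)`; p-values get
   Benjamini–Hochberg (and Bonferroni) adjustment.
4. **MAS ranking** — for genes passing `p_BH < 0.05` and `|log2FC| > 1`,
   `MAS = |log2FC|^M · |log10 p_BH|^A` with `M = A = 1`, so effect size and
   statistical strength weigh equally; ranking is stable in the |log2FC|
   threshold by construction.
5. **Balanced resampling (Case 2)** — 500 iterations (tests use a scaled-down
   50) each draw 42 of the 65 majority samples, re-run the full analysis and
   count directional significant calls; genes significant the same way in at
   least half the iterations with zero opposite calls qualify, and 100%
   consistency marks the strongest tier.
6. **ORA** — hypergeometric upper-tail enrichment of the significant list
   against GMT collections with BH q-values.
7. **Separability diagnostics** — PCA + unregularized logistic regression
   curves (2–20 components) before vs after gene selection, and the
   one-dimensional Fisher discriminant (LDA1) of the top-ranked genes.
   Resubstitution metrics: illustrations of separability, not prediction.

## Worked example

```python
from glmqlmas import (SimulationConfig, generate_cohort, drop_unexpressed,
                      tmm_normalize, de_analysis, rank_and_classify)

cfg = SimulationConfig(n_genes=2000, n_coding=2000, group_sizes=(65, 42),
                       de_fraction=0.10, de_log2fc_magnitudes=(2.0,),
                       dispersion=0.1, seed=1)
counts, samples, genes, truth = generate_cohort(cfg)
counts, _ = drop_unexpressed(counts)
de = de_analysis(counts, samples, tmm_normalize(counts))
print(rank_and_classify(de).head(3))
```

prints (seed 1):

```
    gene    log2FC          p_adj         MAS direction  rank
0  G0163  2.160373  2.533730e-109  234.608346        up     1
1  G0879  2.144093  4.118164e-108  230.244087        up     2
2  G1246  2.139785  1.526849e-107  228.563664        up     3
```

i.e. the top-ranked genes pair a ~4–5-fold expression change with
vanishingly small adjusted p-values; on this cohort 212/2000 genes (10.6%)
are BH-significant, recall of the planted genes is 1.000 and the empirical
FDR of the gated call set is 0.000 (see `examples/01_simulate_and_de.py`,
whose output these numbers are).

Each script in `examples/` demonstrates one capability (simulation + DE,
MAS ranking, resampling biomarkers, enrichment, separability) and prints a
short interpretation of its numbers.

A thin CLI mirrors the stages:

```bash
glmqlmas simulate --n-genes 2000 --seed 1 --out-dir data/
glmqlmas all --counts data/counts.tsv --samples data/samples.tsv \
             --genes data/genes.tsv --gmt data/gene_sets.gmt \
             --iterations 50 --seed 1 --out-dir results/
```

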