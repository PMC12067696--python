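# migretix

Analysis pipeline for two-timepoint interictal migraine transcriptomics:
cross-timepoint replication of differential expression, preranked
gene-set enrichment with leading-edge extraction, and a drug-discovery
scoring layer over the genes driving replicated pathways.

Built for studies that measure case/control expression twice in the same
cohort (time points S1, S2) and need: (1) a replicability readout — the
fraction of genes whose log2 fold-change keeps its sign across time
points under a given covariate correction; (2) pathways that are
significantly enriched, in the same direction, at **both** time points;
and (3) drug candidates ranked by predicted binding to those pathways'
leading-edge genes.

## The statistics at the core

**Sign concordance.** Over a common gene universe, gene *g* is
concordant when sign(log2FC<sub>S1</sub>) = sign(log2FC<sub>S2</sub>) ≠ 0;
the discordant fraction (50% under independence) measures replicability.

**Preranked GSEA.** Genes ranked by sign(log2FC)·−log10(p); the
enrichment score is the weighted Kolmogorov–Smirnov running-sum extreme,
ES = max deviation of
Σ<sub>hits ≤ i</sub> |r|/Σ<sub>set</sub>|r| − Σ<sub>misses ≤ i</sub> 1/(N−N<sub>set</sub>).
Gene-label permutations give empirical p (add-one, sign-conditional),
NES = ES / mean|ES<sub>perm, same sign</sub>|, BH FDR across sets of
effective size 15–500. The leading edge is the set genes at/before the
running-sum peak (mirrored for negative ES); a pathway replicates when
FDR ≤ 0.05 at both time points with concordant NES sign. Leading-edge
genes are tiered by |mean log2FC| ≥ 2 and ≥ 0.5.

**Drug scoring.** Docking affinities are z-scored per drug against a
random-protein reference panel (z = (μ<sub>ref</sub> − affinity)/σ<sub>ref</sub>,
right-tail p, Bonferroni over tests). Predicted drug×protein scores
aggregate to genes by the per-gene maximum; drugs in more than 10
per-gene top-10 lists are excluded as promiscuous; remaining scores are
standardised per drug against its all-protein score distribution. A
drug's pathway score is the expression-weighted L2 norm
sqrt(Σ<sub>g∈pathway</sub> (z<sub>g</sub>·w<sub>g</sub>)²) with
w<sub>g</sub> = mean |log2FC|, with empirical p from seeded permutations
of the gene→score assignment.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import pandas as pd
from migretix import (
    bonferroni_threshold, chi2_yates, sign_concordance,
    rank_genes, gsea_preranked, replicate_pathways,
)
from migretix.synthetic import (
    SyntheticDesign, GeneSetDesign,
    simulate_two_timepoint_de, simulate_gene_sets,
)

stat, p = chi2_yates([[14, 16], [5, 17]])       # cohort sex table
print(f"sex table: chi2 = {stat:.4f}, p = {p:.3f}")
print(f"genome-wide threshold: {bonferroni_threshold(0.05, 13650):.3g}")

# synthetic two-timepoint experiment: 150 of 1,000 genes share a
# -1.5-SD down-regulation at both time points; 3 of 103 gene sets
# are planted on those genes
design = SyntheticDesign(n_genes=1000, n_de=150, effect_mean=-0.75,
                         effect_sd=0.0, noise_sd=0.1, seed=1)
s1, s2, truth = simulate_two_timepoint_de(design)
print(f"discordance: {100 * sign_concordance(s1, s2).discordant_fraction:.2f}%")

sets, planted = simulate_gene_sets(
    truth, GeneSetDesign(n_sets=103, n_planted=3, set_size_range=(20, 30), seed=2))
res1 = gsea_preranked(rank_genes(s1), sets, nperm=10_000, seed=3)
res2 = gsea_preranked(rank_genes(s2), sets, nperm=10_000, seed=4)
rep = replicate_pathways(res1, res2)
print(rep[["pathway", "mean_nes", "fdr_s1", "fdr_s2"]].to_string(index=False))
```

prints

```
sex table: chi2 = 2.1895, p = 0.139
genome-wide threshold: 3.66e-06
discordance: 43.70%
        pathway  mean_nes   fdr_s1   fdr_s2
planted_set_000 -2.343553 0.005227 0.005118
planted_set_002 -2.218907 0.005227 0.005118
planted_set_001 -2.214523 0.005227 0.005118
```

The chi-squared (Yates-corrected) and Bonferroni values reproduce
printed cohort statistics. The discordance sits between 0% (perfectly
shared signal) and 50% (independent noise) because 15% of genes carry a
shared effect. Replication recovers exactly the three planted
down-regulated pathways — strongly negative mean NES, FDR well under
0.05 at both time points — with no false positives.

The same flows are scriptable via the `migretix` CLI
(`concordance`, `gsea`, `replicate`, `dock-norm`, `dti-aggregate`,
`dti-filter`, `pathway-score`, `snp-map`, `simulate`); see
`migretix --help`.

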