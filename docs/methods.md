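# Methods

## Study design being modelled

The pipeline analyses case/control differential expression (DE) measured
twice in the same cohort during symptom-free (interictal) periods, time
points S1 and S2, under several covariate corrections (age+sex up to
age+sex+allergy+smoking). Because single-gene effects in small migraine
cohorts are weak, inference proceeds at three levels: replicability of
per-gene fold-change *signs* across time points, pathway-level enrichment
replicated at both time points, and a drug-scoring layer over the genes
driving the replicated pathways.

The package consumes post-model DE tables (gene, log2FC, p, FDR); it does
not refit the count model. Docking affinity tables and predicted
drug–protein score matrices are likewise consumed as data: pose
generation and binding-predictor training are outside the package, kept
behind a plain score-matrix interface.

## Sign concordance

Over a universe of genes present in every table, a gene is concordant if
its log2FC has the same nonzero sign at both time points; an exact zero
is counted discordant (its sign is undefined; the choice is conservative
and measure-zero for continuous effect estimates). Optional magnitude
filters (|log2FC| ≥ 0.001, 0.05, …) must hold at **both** time points by
default — the stricter, symmetric reading — with `require_both=False`
available for the one-sided variant. Under independent null tables the
discordant fraction is Binomial(n, 1/2)/n; tests check agreement within
three binomial standard errors.

## Preranked gene-set enrichment

Genes are ranked by a signed statistic; the default metric is
`sign(log2FC) · −log10(p)` with p floored at 1e-300 (uses both effect
direction and evidence; the ranking metric is configurable because DE
pipelines differ here). Ties break by |log2FC| descending then gene id,
so ordering is reproducible.

The enrichment score (ES) is the classic weighted Kolmogorov–Smirnov
running sum: at a set gene the sum rises by `|stat|^w / Σ_set |stat|^w`
(weight exponent w = 1), at a non-set gene it falls by `1/(N − N_set)`;
ES is the signed deviation of maximal absolute value, with the first
index attaining the extreme used on ties. If every set stat is exactly
zero the hit increments fall back to uniform `1/N_set`. The leading edge
of a positive enrichment is the set genes at or before the peak; for
negative ES the definition mirrors (at or after the trough).

Significance uses gene-label permutations: random same-size gene sets,
one null of `nperm` scores per distinct set size, shared by all sets of
that size. Permutation ES values are computed from sorted hit positions
in O(set size) per permutation (the running sum's extremes can only
occur just before or just after a hit), drawn in blocks of 500
permutations to bound memory. The empirical p-value is add-one and
sign-conditional, `p = (1 + #{|ES_perm| ≥ |ES|, same sign}) /
(1 + #{same-sign perms})`, NES divides ES by the mean |ES_perm| of
same-sign permutations, and FDR is Benjamini–Hochberg across retained
sets (15 ≤ effective size ≤ 500). Results are bit-identical for a fixed
seed: per-size generators derive from `SeedSequence(seed, (size,))`, so
they do not depend on set iteration order. The adaptive multilevel
p-refinement some GSEA implementations add is deliberately not
reproduced; consequently the smallest attainable p is about
`2/nperm`, and analyses that must resolve BH FDR near 0.05 across ~100
sets need `nperm` of order 10⁴ (the planted-recovery analyses use
10,000; routine exploration is fine at the default 1,000).

A pathway *replicates* when FDR ≤ 0.05 at both time points and the NES
signs agree; replicated pathways are reported with the arithmetic mean
NES, ordered by |mean NES| (a flag selects signed ordering), and the
union of the two leading edges. Leading-edge genes (LEGs) are tiered by
mean |log2FC| across time points: ≥ 2 ("LEG5" tier, substantially
altered) and ≥ 0.5 (the broader "LEG69" tier); the mean is the plain
arithmetic mean of the two time points, which reproduces published
per-gene values exactly.

## Drug scoring

**Docking normalisation.** Best-pose affinities (kcal/mol, lower =
stronger) are not comparable across ligands, so each (drug, protein)
affinity is standardised against the drug's affinities to a random
reference panel (~100 proteins in the emulated design):
`z = (mean_ref − affinity)/sd_ref`, so stronger-than-random binding
gives z > 0 and a right-tail one-sided p = 1 − Φ(z). The z-sign
convention is fixed here so that "energetically more favourable" is the
upper tail. Significance is flagged under Bonferroni with m = number of
(drug, protein) tests actually performed. A reference panel with zero
spread is an error naming the drug.

**Gene-level aggregation.** A drug's score on a gene is the maximum of
its predicted scores over the gene's proteins. Promiscuous binders are
removed before candidate ranking: for each gene the top-10 drugs are
counted (ties at the 10th score all count — inclusive is the only
order-free reading), and drugs appearing more than 10 times across genes
are excluded. These two constants are kept at the published rule; note
the rule's behaviour depends on the drug:gene ratio through the baseline
appearance rate `n_genes · top_k / n_drugs`, which should be well below
the exclusion cap for the rule to isolate a promiscuous tail. Remaining
(drug, LEG gene) scores are standardised per drug against that drug's
scores to *all* proteins (a hypothetical average protein), giving
right-tail p-values and BH FDR within each drug across its LEG genes.

**Pathway-level scores.** Each gene's normalised binding z is weighted
by the gene's mean |log2FC| and aggregated over a pathway with the L2
norm, `sqrt(Σ (z_g · w_g)²)`, over genes having both a binding score and
an expression weight; the genes used are counted and reported. The
weight table is user-supplied, keeping the choice of correction variant
(the source analysis used the allergy-corrected comparison) with the
caller.

**Empirical p-values.** The published description ("Monte Carlo integral
of the ranked p-values list") is under-specified; it is implemented here
as a permutation null over the gene → z-score assignment: z columns are
relabelled uniformly at random (weights and pathway membership stay with
their genes), every pathway L2 score is recomputed, and
`p = (1 + #{null ≥ observed})/(1 + B)` with B ≥ 99 seeded replicates.
This is an interpretation, flagged as such; it preserves the quantity
being tested (is this drug's weighted binding concentrated in this
pathway beyond a random gene assignment?) and is exactly reproducible.
The reporting threshold defaults to the published 0.0005, which is only
attainable for B ≥ 1999.

## SNP windows

SNPs are assigned to a gene when they lie on the same chromosome within
a symmetric 10 kbp flank of the gene span, closed 1-based intervals
(`start − flank ≤ pos ≤ end + flank`). BED input (0-based half-open) is
converted on read. Strand is ignored; the window is per gene span, not
per transcript. A SNP may map to several genes.

## Statistical kernels

BH FDR is the step-up procedure with q-values capped at 1 (backed by
statsmodels, verified in tests against an independent step-up oracle on
exhaustive p-value grids). The 2×2 chi-squared applies the Yates
continuity correction by default — `Σ max(|O−E|−0.5, 0)²/E`, 1 df —
because that convention reproduces published cohort statistics
(2.1895 for the sex table; the uncorrected value is ≈3.14); a flag
disables it. The Mann–Whitney U is reported with the min-U convention
(`min(U_x, U_y)`), exact p for combined n ≤ 20 without ties and normal
approximation with tie correction otherwise; published tables print
single U values without naming a convention, and min-U matches common
reporting practice.

## Synthetic data

The generators produce what the analysis assumes, not what sequencing
produces:

* **Two-timepoint DE** — signal genes share one N(effect_mean,
  effect_sd) log2FC across time points plus independent N(0, noise_sd)
  per-timepoint noise; null genes draw independent N(0, null_sd = 0.5)
  log2FC. P-values are the two-sided normal tail of `log2FC/null_sd`,
  exactly uniform for nulls and monotone in |log2FC|. Defaults: 10,765
  genes (the study's common universe), 500 signal genes (~5%, a typical
  bulk-DE fraction), noise_sd 0.2 (moderate between-visit variability).
* **Gene sets** — planted sets sample only signal genes of a chosen
  sign; null sets sample uniformly; sizes uniform in [15, 50] to match
  the retained-size regime.
* **Binding matrices** — background scores i.i.d. Beta(2, 8)
  (right-skewed, like classifier scores); planted binders overwrite
  their gene's protein cells; promiscuous drugs draw Uniform(0.9, 1)
  across all proteins; two proteins per gene by default.
* **Docking references** — per drug, 100 i.i.d. N(−6, 1.5) kcal/mol
  affinities, a typical small-molecule docking range.

What passing recovery tests shows — and does not. The generators have
independent genes, exactly normal effects and exactly uniform null
p-values; real expression data has correlated genes, heavy-tailed
effects and winner's-curse structure, and real binding predictors have
correlated errors across similar proteins. Recovery and calibration
results therefore validate the *procedures* (scores, permutation nulls,
filters, thresholds behave as designed), not the study's biological
findings, which would require the deposited raw data.

## Problem sizes and numerical choices

Planted-pathway recovery runs 20 seeded repetitions of 1,000 genes /
103 sets / 10,000 permutations per time point; binder recovery 10
repetitions of a 500-drug × 200-protein matrix; null calibrations 200
sets on a 2,000-gene list and a 40×200 z-table with B = 499 — sizes
chosen so the full battery completes in well under a minute on one core
while leaving every statistical margin intact. Probability floors:
p-values are floored at 1e-300 before log-ranking; permutation p-values
are add-one so they are never zero. Degenerate inputs (zero-spread
references, sets covering the whole list, empty intersections) raise
errors naming the offending entity rather than producing NaN.

## Known limitations

* Empirical pathway p-values are exchangeable-permutation based; the
  published Monte-Carlo description may differ in detail.
* NES normalisation uses the same-sign permutation mean; sets whose
  permutation null never matches the observed sign get p = 1 and
  NES = 0 by convention.
* The promiscuity rule's constants are ratio-sensitive (above); apply it
  only in regimes where baseline top-k membership is well below the cap.
* Exact Mann–Whitney p-values are unavailable under ties (the normal
  approximation with tie correction is used instead).
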