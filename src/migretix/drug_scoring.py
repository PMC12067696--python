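"""Drug-discovery scoring statistics.

Two complementary score sources feed this module:

* **Docking affinities** (kcal/mol, best pose, lower = stronger). Raw
  docking scores are not comparable across ligands, so each drug's
  affinity to a candidate protein is normalised against that drug's
  affinities to a random reference panel of proteins:
  ``z = (mean_ref - affinity) / sd_ref``, so energetically
  more favourable binding than random gives a positive z and a
  right-tail one-sided p-value.

* **Predicted drug-target interaction (DTI) scores** in [0, 1] over a
  drug x protein matrix with a protein-to-gene map. A drug's score on a
  gene is the maximum over the gene's proteins. Drugs appearing too
  often in per-gene top-10 lists are promiscuous binders and excluded.
  Remaining scores are normalised per drug against that drug's scores
  to all proteins (z against a hypothetical average protein) with
  right-sided p-values and per-drug BH FDR over the leading-edge genes.

Pathway-level scores weight each gene's normalised binding by the
gene's mean |log2FC| and aggregate over the pathway with the L2 norm;
significance comes from a seeded permutation null over the gene-to-
score assignment (an interpretation of a Monte-Carlo integral over the
ranked score list; see docs/methods.md).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats_core import bh_fdr, upper_tail_p_from_z

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_docking",
    "gene_binding_scores",
    "promiscuity_filter",
    "drug_gene_significance",
    "pathway_drug_score",
    "pathway_drug_scores",
    "empirical_pathway_p",
]


def normalize_docking(
    records: pd.DataFrame,
    random_scores: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Z-score docking affinities against per-drug random-protein panels.

    Parameters
    ----------
    records : DataFrame
        Columns ``drug``, ``protein``, ``affinity`` (kcal/mol, best
        pose); one row per (drug, protein) pair under test.
    random_scores : DataFrame
        Columns ``drug``, ``affinity``: each drug's affinities to a
        random reference protein panel (>= 2 rows per drug, positive
        spread). Emulates docking each drug against ~100 random
        proteins.
    alpha : float
        Family-wise error rate for the Bonferroni flag; the number of
        tests is the number of rows in ``records``.

    Returns
    -------
    DataFrame with columns ``drug``, ``protein``, ``affinity``, ``z``,
    ``p_one_sided``, ``significant``, sorted by p ascending. ``z`` is
    ``(mean_ref - affinity) / sd_ref`` (positive = stronger than
    random); ``p_one_sided = 1 - Phi(z)``.
    """
    if records.duplicated(subset=["drug", "protein"]).any():
        raise ValueError("duplicate (drug, protein) docking records")
    stats_ref = random_scores.groupby("drug")["affinity"].agg(["mean", "std", "count"])
    out = records.loc[:, ["drug", "protein", "affinity"]].copy()
    missing = sorted(set(out["drug"]) - set(stats_ref.index))
    if missing:
        raise ValueError(f"drugs without a reference sample: {missing}")
    bad = stats_ref.loc[stats_ref.index.isin(out["drug"])]
    degenerate = bad.index[(bad["count"] < 2) | ~(bad["std"] > 0)].tolist()
    if degenerate:
        raise ValueError(
            f"degenerate reference sample (need >= 2 values with SD > 0): {degenerate}"
        )
    mu = stats_ref["mean"].reindex(out["drug"]).to_numpy()
    sd = stats_ref["std"].reindex(out["drug"]).to_numpy()
    out["z"] = (mu - out["affinity"].to_numpy(dtype=float)) / sd
    out["p_one_sided"] = upper_tail_p_from_z(out["z"].to_numpy())
    m = len(out)
    out["significant"] = out["p_one_sided"] <= alpha / m
    out = out.sort_values(["p_one_sided", "drug", "protein"], kind="stable")
    return out.reset_index(drop=True)


def gene_binding_scores(
    scores: pd.DataFrame,
    protein_to_gene: dict[str, str],
) -> pd.DataFrame:
    """Aggregate a drug x protein score matrix to drug x gene.

    A drug's score on a gene is the maximum predicted binding score
    over the gene's proteins. Proteins absent from the map are dropped
    (logged); the output covers every gene with at least one protein in
    the matrix.

    Parameters
    ----------
    scores : DataFrame
        Drugs as index, proteins as columns, values in [0, 1].
    protein_to_gene : dict
        Each protein maps to exactly one gene.
    """
    known = [p for p in scores.columns if p in protein_to_gene]
    dropped = len(scores.columns) - len(known)
    if dropped:
        logger.info("gene_binding_scores: %d proteins without a gene mapping dropped", dropped)
    if not known:
        raise ValueError("no protein in the matrix has a gene mapping")
    genes = pd.Index([protein_to_gene[p] for p in known])
    return scores[known].T.groupby(genes).max().T.sort_index(axis=1)


def promiscuity_filter(
    gene_scores: pd.DataFrame,
    top_k: int = 10,
    max_appearances: int = 10,
) -> tuple[set[str], pd.DataFrame]:
    """Exclude drugs that rank in too many genes' top-k binding lists.

    For each gene, the per-gene top-k drugs are those whose score is at
    least the k-th largest (boundary ties all counted). Drugs appearing
    in more than ``max_appearances`` genes' top-k lists are excluded as
    promiscuous binders.

    Returns
    -------
    (excluded, retained)
        The excluded drug set and the gene-score table restricted to
        retained drugs.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    vals = gene_scores.to_numpy(dtype=float)
    n_drugs = vals.shape[0]
    if n_drugs <= top_k:
        counts = pd.Series(gene_scores.shape[1], index=gene_scores.index)
    else:
        # k-th largest per gene column; ties at the cutoff are inclusive
        kth = np.partition(vals, n_drugs - top_k, axis=0)[n_drugs - top_k, :]
        counts = pd.Series((vals >= kth).sum(axis=1), index=gene_scores.index)
    excluded = set(counts.index[counts > max_appearances])
    retained = gene_scores.loc[[d for d in gene_scores.index if d not in excluded]]
    return excluded, retained


def drug_gene_significance(
    scores: pd.DataFrame,
    gene_scores: pd.DataFrame,
    leg_genes,
) -> pd.DataFrame:
    """Per-drug normalised binding of leading-edge genes.

    Each drug's gene-level scores are standardised against the drug's
    predicted scores to *all* proteins (mean mu_d, SD sigma_d), giving
    ``z = (score - mu_d) / sigma_d`` and a right-sided
    ``p = 1 - Phi(z)``: how much more strongly the drug binds this gene
    than a hypothetical average protein. BH FDR is computed within each
    drug across its leading-edge genes.

    Parameters
    ----------
    scores : DataFrame
        Full drug x protein matrix (normalisation reference).
    gene_scores : DataFrame
        Drug x gene max-aggregated scores (possibly promiscuity-filtered;
        its drugs must be a subset of ``scores``' drugs).
    leg_genes : collection of str
        Leading-edge gene list to test.

    Returns a long DataFrame ``drug, gene, score, z, p_right, fdr``.
    """
    legs = [g for g in sorted(set(leg_genes)) if g in gene_scores.columns]
    if not legs:
        raise ValueError("no leading-edge gene present in the score table")
    rows = []
    for drug in gene_scores.index:
        ref = scores.loc[drug].to_numpy(dtype=float)
        if ref.size < 2 or not (ref.std(ddof=1) > 0):
            raise ValueError(f"degenerate protein-score distribution for drug {drug!r}")
        mu, sigma = ref.mean(), ref.std(ddof=1)
        sc = gene_scores.loc[drug, legs].to_numpy(dtype=float)
        z = (sc - mu) / sigma
        p = np.atleast_1d(upper_tail_p_from_z(z))
        fdr = bh_fdr(p)
        for g, s, zz, pp, qq in zip(legs, sc, z, p, fdr):
            rows.append((drug, g, s, zz, pp, qq))
    return pd.DataFrame(rows, columns=["drug", "gene", "score", "z", "p_right", "fdr"])


def pathway_drug_score(
    z_scores: pd.Series,
    weights: pd.Series,
    pathway_genes,
) -> tuple[float, int]:
    """Expression-weighted L2 binding score of one drug on one pathway.

    ``sqrt(sum_g (z_g * w_g)^2)`` over the pathway genes that have both
    a normalised binding score and an expression weight (mean |log2FC|).

    Returns ``(l2_score, n_genes_used)``; raises ``ValueError`` when no
    pathway gene has both values.
    """
    avail = [g for g in pathway_genes if g in z_scores.index and g in weights.index]
    if not avail:
        raise ValueError("no pathway gene has both binding and expression values")
    terms = z_scores.loc[avail].to_numpy(dtype=float) * weights.loc[avail].to_numpy(dtype=float)
    return float(np.sqrt(np.sum(terms**2))), len(avail)


def _pathway_blocks(
    z_table: pd.DataFrame,
    weights: pd.Series,
    pathways: dict[str, set[str]],
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per-pathway (name, column indices, weight vector) with usable genes."""
    col_pos = {g: i for i, g in enumerate(z_table.columns)}
    usable = set(weights.dropna().index) & set(col_pos)
    blocks = []
    for name in sorted(pathways):
        avail = sorted(set(pathways[name]) & usable)
        if not avail:
            logger.info("pathway %s has no gene with both values; dropped", name)
            continue
        idx = np.array([col_pos[g] for g in avail], dtype=int)
        w = weights.loc[avail].to_numpy(dtype=float)
        blocks.append((name, idx, w))
    if not blocks:
        raise ValueError("no pathway has genes with both binding and expression values")
    return blocks


def pathway_drug_scores(
    z_table: pd.DataFrame,
    weights: pd.Series,
    pathways: dict[str, set[str]],
) -> pd.DataFrame:
    """L2 pathway scores for every drug x pathway pair.

    ``z_table`` is drug x gene normalised binding; ``weights`` maps gene
    to mean |log2FC|. Pathways with no usable gene are dropped (logged).
    Returns a long DataFrame ``drug, pathway, l2_score, n_genes_used``.
    """
    Z = z_table.to_numpy(dtype=float)
    rows = []
    for name, idx, w in _pathway_blocks(z_table, weights, pathways):
        l2 = np.sqrt(((Z[:, idx] * w) ** 2).sum(axis=1))
        for drug, v in zip(z_table.index, l2):
            rows.append((drug, name, float(v), idx.size))
    return pd.DataFrame(rows, columns=["drug", "pathway", "l2_score", "n_genes_used"])


def empirical_pathway_p(
    z_table: pd.DataFrame,
    weights: pd.Series,
    pathways: dict[str, set[str]],
    n_null: int = 999,
    seed: int = 0,
    threshold: float = 0.0005,
) -> pd.DataFrame:
    """Permutation empirical p-values for pathway-level drug scores.

    The null distribution permutes the gene-to-z-score assignment
    (z columns reassigned to genes; weights and pathway membership stay
    attached to their genes) ``n_null`` times and recomputes every
    pathway L2 score; ``empirical_p = (1 + #{null >= observed}) /
    (1 + n_null)`` per (drug, pathway). Deterministic for a fixed seed.

    Returns the observed score table with ``empirical_p`` and
    ``significant`` (empirical_p <= threshold) columns appended.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    blocks = _pathway_blocks(z_table, weights, pathways)
    Z = z_table.to_numpy(dtype=float)
    n_genes = Z.shape[1]
    obs = {name: np.sqrt(((Z[:, idx] * w) ** 2).sum(axis=1)) for name, idx, w in blocks}
    exceed = {name: np.zeros(Z.shape[0], dtype=int) for name, _, _ in blocks}
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        perm = rng.permutation(n_genes)
        for name, idx, w in blocks:
            null_l2 = np.sqrt(((Z[:, perm[idx]] * w) ** 2).sum(axis=1))
            exceed[name] += null_l2 >= obs[name]
    rows = []
    for name, idx, w in blocks:
        p = (1 + exceed[name]) / (1 + n_null)
        for i, drug in enumerate(z_table.index):
            rows.append((drug, name, float(obs[name][i]), idx.size, float(p[i])))
    out = pd.DataFrame(
        rows, columns=["drug", "pathway", "l2_score", "n_genes_used", "empirical_p"]
    )
    out["significant"] = out["empirical_p"] <= threshold
    return out
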