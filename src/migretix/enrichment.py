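"""Preranked gene-set enrichment with leading-edge extraction.

The enrichment statistic is the classic weighted Kolmogorov-Smirnov
running sum over a gene list ranked by a signed statistic: walking down
the list, the sum increases by ``|stat|^w / sum_set |stat|^w`` at a
set gene and decreases by ``1/(N - N_set)`` otherwise; the enrichment
score (ES) is the signed deviation of maximal absolute value. Set
significance comes from gene-label permutations (random same-size gene
sets), the normalised enrichment score (NES) rescales the ES by the mean
magnitude of same-sign permutation scores, and Benjamini-Hochberg FDR is
applied across the retained sets.

The leading edge of a positively enriched set is the set genes ranked at
or before the running sum's peak (mirrored for negative enrichment):
the genes actually driving the signal. A pathway *replicates* across the
study's two time points when its FDR is at most 0.05 at both and the NES
signs agree.

Only the permutation estimator is implemented; no adaptive multilevel
p-value refinement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats_core import bh_fdr

__all__ = [
    "rank_genes",
    "enrichment_score",
    "leading_edge",
    "gsea_preranked",
    "replicate_pathways",
]

_PVALUE_FLOOR = 1e-300
_PERM_CHUNK = 500  # permutations drawn per block, caps peak memory


def rank_genes(de: pd.DataFrame, metric: str = "signed_logp") -> pd.DataFrame:
    """Build a ranked gene list from a DE table.

    Metrics
    -------
    signed_logp (default)
        ``sign(log2fc) * -log10(pvalue)`` with the p-value floored at
        1e-300 so a reported zero stays finite.
    log2fc
        The log2 fold-change itself.
    stat_column
        A precomputed ``stat`` column in the table.

    Ties are broken by ``|log2fc|`` descending, then ``gene_id``
    ascending, so the order is stable across runs.

    Returns a DataFrame with columns ``gene_id``, ``stat`` sorted by
    ``stat`` descending.
    """
    if len(de) < 2:
        raise ValueError("ranking requires at least two genes")
    if metric == "signed_logp":
        for col in ("log2fc", "pvalue"):
            if col not in de.columns:
                raise ValueError(f"metric 'signed_logp' needs column {col!r}")
        p = np.maximum(de["pvalue"].to_numpy(dtype=float), _PVALUE_FLOOR)
        stat = np.sign(de["log2fc"].to_numpy(dtype=float)) * -np.log10(p)
    elif metric == "log2fc":
        if "log2fc" not in de.columns:
            raise ValueError("metric 'log2fc' needs column 'log2fc'")
        stat = de["log2fc"].to_numpy(dtype=float)
    elif metric == "stat_column":
        if "stat" not in de.columns:
            raise ValueError("metric 'stat_column' needs column 'stat'")
        stat = de["stat"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    abs_lfc = (
        np.abs(de["log2fc"].to_numpy(dtype=float))
        if "log2fc" in de.columns
        else np.zeros(len(de))
    )
    gene_id = de["gene_id"].to_numpy()
    # lexsort: last key is primary
    order = np.lexsort((gene_id, -abs_lfc, -stat))
    out = pd.DataFrame({"gene_id": gene_id[order], "stat": stat[order]})
    if out["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in ranking input")
    return out.reset_index(drop=True)


def _hit_weights(abs_stat_pow: np.ndarray) -> np.ndarray:
    """Normalised hit increments; uniform if every set stat is zero."""
    total = abs_stat_pow.sum()
    if total <= 0:
        return np.full(abs_stat_pow.shape, 1.0 / abs_stat_pow.shape[-1])
    return abs_stat_pow / total


def enrichment_score(
    ranked: pd.DataFrame,
    set_genes,
    weight_exponent: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """Weighted KS running-sum enrichment score of one gene set.

    Parameters
    ----------
    ranked : DataFrame
        Ranked gene list (``gene_id``, ``stat``), stat descending.
    set_genes : collection of str
        The gene set; only members present in the ranked list count.
    weight_exponent : float
        Exponent on ``|stat|`` for hit increments (1 = classic weighted).

    Returns
    -------
    (es, peak_index, running_sum)
        ``es`` is the signed extreme deviation, ``peak_index`` the
        0-based position where it is attained (first occurrence on
        ties), ``running_sum`` the full length-N profile.
    """
    genes = ranked["gene_id"].to_numpy()
    stat = ranked["stat"].to_numpy(dtype=float)
    n = genes.size
    hit = np.isin(genes, list(set_genes))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if k == n:
        raise ValueError("gene set covers the entire ranked list")
    steps = np.full(n, -1.0 / (n - k))
    steps[hit] = _hit_weights(np.abs(stat[hit]) ** weight_exponent)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    v_max, v_min = running[i_max], running[i_min]
    if abs(v_max) > abs(v_min):
        es, peak = v_max, i_max
    elif abs(v_min) > abs(v_max):
        es, peak = v_min, i_min
    else:
        peak = min(i_max, i_min)
        es = running[peak]
    return float(es), peak, running


def leading_edge(
    ranked: pd.DataFrame,
    set_genes,
    es: float,
    peak_index: int,
) -> list[str]:
    """Set genes at/before the peak (es > 0) or at/after it (es < 0).

    Preserves ranked order; empty for ``es == 0``.
    """
    if es == 0:
        return []
    genes = ranked["gene_id"].to_numpy()
    members = set(set_genes)
    if es > 0:
        window = genes[: peak_index + 1]
    else:
        window = genes[peak_index:]
    return [g for g in window if g in members]


def _perm_es(
    abs_stat_pow: np.ndarray,
    k: int,
    nperm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of ``nperm`` random size-``k`` gene sets.

    Uses the O(k)-per-permutation identity that the running sum's
    extremes occur just after or just before a hit: with sorted hit
    positions p_0 < ... < p_{k-1}, the value just after hit j is
    ``cumw_j - (p_j - j) * miss`` and just before it is the same with
    ``cumw_{j-1}``.
    """
    n = abs_stat_pow.size
    miss = 1.0 / (n - k)
    out = np.empty(nperm)
    done = 0
    while done < nperm:
        b = min(_PERM_CHUNK, nperm - done)
        keys = rng.random((b, n))
        pos = np.sort(keys.argpartition(k, axis=1)[:, :k], axis=1)
        w = abs_stat_pow[pos]
        cumw = np.cumsum(w, axis=1)
        total = cumw[:, -1:]
        zero = total <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            cw = np.where(zero, np.cumsum(np.full_like(w, 1.0 / k), axis=1), cumw / np.where(zero, 1.0, total))
            wn = np.where(zero, 1.0 / k, w / np.where(zero, 1.0, total))
        drift = (pos - np.arange(k)) * miss
        after = cw - drift
        before = (cw - wn) - drift
        v_max = after.max(axis=1)
        v_min = before.min(axis=1)
        out[done : done + b] = np.where(v_max >= -v_min, v_max, v_min)
        done += b
    return out


def gsea_preranked(
    ranked: pd.DataFrame,
    collection: dict[str, set[str]],
    min_size: int = 15,
    max_size: int = 500,
    nperm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Sets are first intersected with the ranked universe and retained
    only if their effective size lies in ``[min_size, max_size]``. Per
    retained set, the empirical p-value counts same-sign permutation
    scores at least as extreme as the observed ES (add-one rule) and the
    NES divides the ES by the mean magnitude of same-sign permutation
    scores. FDR is Benjamini-Hochberg across retained sets. Results are
    bit-identical for a fixed seed.

    Returns a DataFrame with columns ``pathway``, ``es``, ``nes``,
    ``pvalue``, ``fdr``, ``size``, ``leading_edge`` sorted by ``pvalue``.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    genes = ranked["gene_id"].to_numpy()
    stat = ranked["stat"].to_numpy(dtype=float)
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    abs_stat_pow = np.abs(stat) ** weight_exponent

    retained: list[tuple[str, np.ndarray]] = []
    for name in sorted(collection):
        idx = np.array(sorted(gene_pos[g] for g in collection[name] if g in gene_pos), dtype=int)
        if min_size <= idx.size <= max_size and idx.size < n:
            retained.append((name, idx))
    if not retained:
        raise ValueError("no gene sets survive the size filter")

    # one permutation null per distinct set size, shared by all sets of
    # that size; child seeds derive from (seed, size) so results do not
    # depend on iteration order
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({idx.size for _, idx in retained}):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(size,)))
        null_by_size[size] = _perm_es(abs_stat_pow, size, nperm, rng)

    rows = []
    for name, idx in retained:
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        steps = np.full(n, -1.0 / (n - idx.size))
        steps[hit] = _hit_weights(abs_stat_pow[idx])
        running = np.cumsum(steps)
        i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
        if abs(running[i_max]) > abs(running[i_min]):
            es, peak = float(running[i_max]), i_max
        elif abs(running[i_min]) > abs(running[i_max]):
            es, peak = float(running[i_min]), i_min
        else:
            peak = min(i_max, i_min)
            es = float(running[peak])
        null = null_by_size[idx.size]
        same_sign = null > 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            pvalue, nes = 1.0, 0.0
        else:
            extreme = int((same_sign & (np.abs(null) >= abs(es))).sum())
            pvalue = (1 + extreme) / (1 + n_same)
            nes = es / float(np.abs(null[same_sign]).mean())
        le = leading_edge(ranked, {genes[i] for i in idx}, es, peak)
        rows.append((name, es, nes, pvalue, idx.size, le))

    res = pd.DataFrame(rows, columns=["pathway", "es", "nes", "pvalue", "size", "leading_edge"])
    res["fdr"] = bh_fdr(res["pvalue"].to_numpy())
    res = res.sort_values(["pvalue", "pathway"], kind="stable").reset_index(drop=True)
    return res[["pathway", "es", "nes", "pvalue", "fdr", "size", "leading_edge"]]


def replicate_pathways(
    res_s1: pd.DataFrame,
    res_s2: pd.DataFrame,
    fdr_max: float = 0.05,
    order_by: str = "abs_mean_nes",
) -> pd.DataFrame:
    """Pathways significant and direction-concordant at both time points.

    Keeps pathways present in both result tables with FDR at most
    ``fdr_max`` at both time points and NES of the same sign; reports
    the arithmetic mean NES and the union of the two leading edges.
    Sorted by ``|mean_nes|`` descending by default
    (``order_by="mean_nes"`` sorts by the signed mean instead).
    """
    merged = res_s1.merge(res_s2, on="pathway", suffixes=("_s1", "_s2"))
    keep = (
        (merged["fdr_s1"] <= fdr_max)
        & (merged["fdr_s2"] <= fdr_max)
        & (np.sign(merged["nes_s1"]) == np.sign(merged["nes_s2"]))
        & (merged["nes_s1"] != 0)
    )
    kept = merged.loc[keep].copy()
    kept["mean_nes"] = (kept["nes_s1"] + kept["nes_s2"]) / 2.0
    kept["leading_edge_union"] = [
        sorted(set(a) | set(b))
        for a, b in zip(kept["leading_edge_s1"], kept["leading_edge_s2"])
    ]
    key = kept["mean_nes"].abs() if order_by == "abs_mean_nes" else kept["mean_nes"]
    kept = kept.iloc[np.argsort(-key.to_numpy(), kind="stable")]
    cols = ["pathway", "mean_nes", "fdr_s1", "fdr_s2", "leading_edge_union"]
    return kept[cols].reset_index(drop=True)
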