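"""Seeded generators emulating the pipeline's inputs.

The real study consumes post-model differential-expression tables at
two interictal time points, MSigDB-style gene-set collections, predicted
drug x protein binding matrices and docking affinity tables. These
generators produce inputs with the same statistical structure — shared
cross-timepoint effects plus independent noise, planted enriched sets,
planted strong and promiscuous binders, normal docking references — with
truth tables so recovery can be measured exactly. Everything is
bit-reproducible under a fixed seed.

The DE p-value model is deliberately simple: a gene's p-value is the
two-sided normal tail of ``log2fc / null_sd``, so null genes (log2FC ~
N(0, null_sd)) get exactly uniform p-values and the p-to-effect link is
monotone. The count-model machinery of a real DE fit is not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import bh_fdr

__all__ = [
    "SyntheticDesign",
    "GeneSetDesign",
    "SyntheticBindingDesign",
    "simulate_two_timepoint_de",
    "simulate_gene_sets",
    "simulate_binding_matrix",
    "simulate_docking_references",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Two-timepoint DE generator settings.

    ``n_genes`` defaults to the study's common gene universe (10,765).
    Signal genes draw one effect from N(effect_mean, effect_sd), shared
    across time points; each time point adds independent N(0, noise_sd)
    noise. Null genes draw independent N(0, null_sd) log2FC at each time
    point. All scales are log2 units.
    """

    n_genes: int = 10_765
    n_de: int = 500
    effect_mean: float = 0.0
    effect_sd: float = 1.0
    noise_sd: float = 0.2
    null_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_de <= self.n_genes):
            raise ValueError("need 0 <= n_de <= n_genes")
        if min(self.effect_sd, self.noise_sd) < 0 or self.null_sd <= 0:
            raise ValueError("effect_sd, noise_sd >= 0 and null_sd > 0 required")


@dataclass(frozen=True)
class GeneSetDesign:
    """Gene-set collection generator settings.

    ``n_planted`` sets preferentially sample signal genes whose effect
    sign equals ``planted_direction``; the remaining sets sample genes
    uniformly. Set sizes are drawn uniformly from ``set_size_range``.
    """

    n_sets: int = 100
    set_size_range: tuple[int, int] = (15, 50)
    n_planted: int = 0
    planted_direction: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi):
            raise ValueError("set sizes must satisfy 2 <= lo <= hi")
        if not (0 <= self.n_planted <= self.n_sets):
            raise ValueError("need 0 <= n_planted <= n_sets")
        if self.planted_direction not in (-1, 1):
            raise ValueError("planted_direction must be -1 or +1")


@dataclass(frozen=True)
class SyntheticBindingDesign:
    """Drug x protein binding-matrix generator settings.

    Background scores are i.i.d. Beta(a, b) — right-skewed by default,
    as classifier scores typically are. Planted binder cells are
    overwritten with their stated score; promiscuous drugs get uniformly
    high scores across every protein.
    """

    n_drugs: int = 50
    n_genes: int = 200
    proteins_per_gene: int = 2
    background: tuple[float, float] = (2.0, 8.0)
    planted_binders: tuple[tuple[str, str, float], ...] = ()
    promiscuous_drugs: tuple[str, ...] = ()
    promiscuous_low: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_genes, self.proteins_per_gene) < 1:
            raise ValueError("counts must be positive")
        cells = [(d, g) for d, g, _ in self.planted_binders]
        if len(cells) != len(set(cells)):
            raise ValueError("duplicate planted (drug, gene) cells")
        for d, g, s in self.planted_binders:
            if not (0 <= s <= 1):
                raise ValueError(f"planted score for ({d}, {g}) outside [0, 1]")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def simulate_two_timepoint_de(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate DE tables for two time points plus the truth table.

    Returns ``(s1, s2, truth)``; the DE tables carry ``gene_id, log2fc,
    pvalue, fdr``, the truth table ``gene_id, is_signal, effect``.
    """
    rng = np.random.default_rng(design.seed)
    genes = np.array(_gene_ids(design.n_genes))
    is_signal = np.zeros(design.n_genes, dtype=bool)
    is_signal[rng.choice(design.n_genes, size=design.n_de, replace=False)] = True
    effect = np.zeros(design.n_genes)
    effect[is_signal] = rng.normal(design.effect_mean, design.effect_sd, design.n_de)

    tables = []
    for _ in range(2):
        lfc = np.where(
            is_signal,
            effect + rng.normal(0.0, design.noise_sd, design.n_genes),
            rng.normal(0.0, design.null_sd, design.n_genes),
        )
        p = 2.0 * stats.norm.sf(np.abs(lfc) / design.null_sd)
        tables.append(
            pd.DataFrame(
                {"gene_id": genes, "log2fc": lfc, "pvalue": p, "fdr": bh_fdr(p)}
            )
        )
    truth = pd.DataFrame({"gene_id": genes, "is_signal": is_signal, "effect": effect})
    return tables[0], tables[1], truth


def simulate_gene_sets(
    truth: pd.DataFrame,
    design: GeneSetDesign,
) -> tuple[dict[str, set[str]], dict[str, bool]]:
    """Generate a gene-set collection over a simulated gene universe.

    Planted sets sample only signal genes whose effect sign matches
    ``planted_direction``; null sets sample uniformly from all genes.
    Returns ``(sets, planted_flags)``.
    """
    rng = np.random.default_rng(design.seed)
    genes = truth["gene_id"].to_numpy()
    directional = genes[
        truth["is_signal"].to_numpy()
        & (np.sign(truth["effect"].to_numpy()) == design.planted_direction)
    ]
    lo, hi = design.set_size_range
    sets: dict[str, set[str]] = {}
    planted: dict[str, bool] = {}
    for i in range(design.n_sets):
        size = int(rng.integers(lo, hi + 1))
        is_planted = i < design.n_planted
        if is_planted:
            if size > directional.size:
                raise ValueError(
                    f"planted set of size {size} exceeds the {directional.size} "
                    "available signal genes of the requested sign"
                )
            members = rng.choice(directional, size=size, replace=False)
        else:
            members = rng.choice(genes, size=size, replace=False)
        name = f"{'planted' if is_planted else 'null'}_set_{i:03d}"
        sets[name] = set(members)
        planted[name] = is_planted
    return sets, planted


def simulate_binding_matrix(
    design: SyntheticBindingDesign,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Generate a drug x protein score matrix with a protein-gene map.

    Returns ``(scores, protein_to_gene, truth)`` where truth lists one
    row per (drug, entity, kind) for planted binders and promiscuous
    drugs.
    """
    rng = np.random.default_rng(design.seed)
    drugs = [f"drug{i:03d}" for i in range(design.n_drugs)]
    genes = _gene_ids(design.n_genes)
    proteins, protein_to_gene = [], {}
    for g in genes:
        for j in range(design.proteins_per_gene):
            pid = f"{g}_p{j}"
            proteins.append(pid)
            protein_to_gene[pid] = g
    a, b = design.background
    scores = pd.DataFrame(
        rng.beta(a, b, size=(len(drugs), len(proteins))), index=drugs, columns=proteins
    )
    truth_rows = []
    for d in design.promiscuous_drugs:
        if d not in scores.index:
            raise ValueError(f"promiscuous drug {d!r} not in the matrix")
        scores.loc[d] = rng.uniform(design.promiscuous_low, 1.0, len(proteins))
        truth_rows.append((d, "", "promiscuous"))
    for d, g, s in design.planted_binders:
        if d not in scores.index or g not in genes:
            raise ValueError(f"planted binder ({d!r}, {g!r}) references unknown ids")
        for pid in (p for p, gg in protein_to_gene.items() if gg == g):
            scores.loc[d, pid] = s
        truth_rows.append((d, g, "binder"))
    truth = pd.DataFrame(truth_rows, columns=["drug", "gene", "kind"])
    return scores, protein_to_gene, truth


def simulate_docking_references(
    n_drugs: int,
    n_ref: int = 100,
    mean: float = -6.0,
    sd: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-protein docking reference panels, one per drug.

    Emulates docking each drug against ``n_ref`` randomly chosen
    proteins: affinities are i.i.d. N(mean, sd) kcal/mol. Defaults are a
    typical small-molecule docking range (about -6 +/- 1.5 kcal/mol).
    Returns a long DataFrame ``drug, protein, affinity``.
    """
    if n_ref < 2:
        raise ValueError("n_ref must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_drugs):
        drug = f"drug{i:03d}"
        aff = rng.normal(mean, sd, n_ref)
        rows.extend((drug, f"ref{j:03d}", float(a)) for j, a in enumerate(aff))
    return pd.DataFrame(rows, columns=["drug", "protein", "affinity"])
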