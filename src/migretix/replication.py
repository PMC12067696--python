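"""Cross-timepoint replication of differential expression.

The study design samples the same individuals at two interictal time
points (S1, S2) and fits a case/control differential-expression model at
each, under several covariate corrections. A gene whose log2 fold-change
keeps its sign at both time points is *concordant*; the discordant
fraction over a common gene universe measures how replicable the
expression signal is under a given correction. Leading-edge genes (LEGs)
surviving enrichment replication are further tiered by the magnitude of
their mean log2 fold-change across time points.

DE tables are pandas DataFrames with columns ``gene_id``, ``log2fc``,
``pvalue``, ``fdr`` (see :mod:`migretix.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "fdr")

# |mean log2FC| tiers for leading-edge genes: >= 2 marks substantially
# altered genes (LEG5 tier), >= 0.5 the broader literature cutoff (LEG69).
LEG_HIGH_THRESHOLD = 2.0
LEG_LOW_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConcordanceSummary:
    """Sign-concordance counts between two time points."""

    n_common: int
    n_concordant: int
    n_discordant: int
    discordant_fraction: float
    min_abs_lfc: float

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_discordant != self.n_common:
            raise ValueError("concordant + discordant must equal common count")
        if not (0.0 <= self.discordant_fraction <= 1.0):
            raise ValueError("discordant_fraction outside [0, 1]")


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check DE-table invariants; returns the table unchanged.

    Gene ids must be unique, p-values and FDRs in [0, 1], log2
    fold-changes finite.
    """
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in DE table: {dup!r}")
    for col in ("pvalue", "fdr"):
        v = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or np.any((v < 0) | (v > 1)):
            raise ValueError(f"column {col!r} must be within [0, 1]")
    if not np.all(np.isfinite(df["log2fc"].to_numpy(dtype=float))):
        raise ValueError("log2fc must be finite")
    return df


def common_gene_universe(tables: list[pd.DataFrame]) -> list[str]:
    """Genes present in every table, in lexicographic order.

    Raises ``ValueError`` for fewer than two tables or an empty
    intersection.
    """
    if len(tables) < 2:
        raise ValueError("need at least two DE tables")
    common: set[str] | None = None
    for t in tables:
        validate_de_table(t)
        genes = set(t["gene_id"])
        common = genes if common is None else common & genes
    assert common is not None
    if not common:
        raise ValueError("no genes common to all tables")
    return sorted(common)


def sign_concordance(
    s1: pd.DataFrame,
    s2: pd.DataFrame,
    universe: list[str] | None = None,
    min_abs_lfc: float = 0.0,
    require_both: bool = True,
) -> ConcordanceSummary:
    """Sign-concordance of log2 fold-changes between two time points.

    A gene enters the comparison only if ``|log2fc| >= min_abs_lfc``
    (at both time points when ``require_both``, the default; at either
    otherwise). A gene is concordant iff its log2FC has the same nonzero
    sign at both time points; an exact zero at either time point counts
    as discordant (sign undefined, conservative).

    Parameters
    ----------
    s1, s2 : DataFrame
        DE tables for the two time points.
    universe : list of str, optional
        Gene universe to compare over (must be contained in both
        tables); defaults to the two tables' common genes.
    min_abs_lfc : float
        Magnitude filter in log2 units (0 admits every universe gene).
    require_both : bool
        Whether the magnitude filter must hold at both time points.
    """
    validate_de_table(s1)
    validate_de_table(s2)
    if min_abs_lfc < 0:
        raise ValueError("min_abs_lfc must be >= 0")
    if universe is None:
        universe = common_gene_universe([s1, s2])
    a = s1.set_index("gene_id")["log2fc"]
    b = s2.set_index("gene_id")["log2fc"]
    missing = [g for g in universe if g not in a.index or g not in b.index]
    if missing:
        raise ValueError(f"universe genes absent from a table: {missing[:5]}")
    lfc1 = a.loc[universe].to_numpy(dtype=float)
    lfc2 = b.loc[universe].to_numpy(dtype=float)
    if require_both:
        enter = (np.abs(lfc1) >= min_abs_lfc) & (np.abs(lfc2) >= min_abs_lfc)
    else:
        enter = (np.abs(lfc1) >= min_abs_lfc) | (np.abs(lfc2) >= min_abs_lfc)
    n_common = int(enter.sum())
    if n_common == 0:
        raise ValueError("no genes pass the |log2FC| filter")
    s1_sign = np.sign(lfc1[enter])
    s2_sign = np.sign(lfc2[enter])
    concordant = (s1_sign == s2_sign) & (s1_sign != 0)
    n_conc = int(concordant.sum())
    return ConcordanceSummary(
        n_common=n_common,
        n_concordant=n_conc,
        n_discordant=n_common - n_conc,
        discordant_fraction=(n_common - n_conc) / n_common,
        min_abs_lfc=float(min_abs_lfc),
    )


def leg_filter(
    candidates: pd.DataFrame,
    t_high: float = LEG_HIGH_THRESHOLD,
    t_low: float = LEG_LOW_THRESHOLD,
) -> pd.DataFrame:
    """Tier leading-edge genes by mean cross-timepoint |log2FC|.

    ``candidates`` needs columns ``gene_id``, ``log2fc_s1``, ``log2fc_s2``.
    The mean log2FC is the arithmetic mean of the two time points; the
    tier is ``LEG5`` for ``|mean| >= t_high``, ``LEG69`` for
    ``|mean| >= t_low``, else ``none`` (so every LEG5 gene also meets the
    LEG69 criterion). Output is sorted by ``|mean_log2fc|`` descending.
    """
    if not (t_high > t_low > 0):
        raise ValueError("thresholds must satisfy t_high > t_low > 0")
    out = candidates.loc[:, ["gene_id", "log2fc_s1", "log2fc_s2"]].copy()
    out["mean_log2fc"] = (out["log2fc_s1"] + out["log2fc_s2"]) / 2.0
    mag = out["mean_log2fc"].abs()
    out["tier"] = np.select(
        [mag >= t_high, mag >= t_low], ["LEG5", "LEG69"], default="none"
    )
    out = out.iloc[np.argsort(-mag.to_numpy(), kind="stable")]
    return out.reset_index(drop=True)
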