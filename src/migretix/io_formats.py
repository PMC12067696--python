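"""Readers and writers for pipeline file formats, plus SNP-window mapping.

All tabular formats are plain tab-separated text. Coordinates are
handled 1-based closed (the UCSC gene-track convention); BED input
(0-based half-open) is converted on read. Readers validate invariants
and report the file, line number and offending field on malformed rows;
writers emit a deterministic column order so round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .replication import validate_de_table

__all__ = [
    "GeneInterval",
    "PipelineConfig",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_docking_tsv",
    "write_docking_tsv",
    "read_binding_matrix",
    "write_binding_matrix",
    "read_protein_gene_map",
    "read_bed_intervals",
    "read_snp_table",
    "snp_window_map",
]

DE_HEADER = ["gene_id", "log2fc", "pvalue", "fdr"]
DOCKING_HEADER = ["drug", "protein", "affinity_kcal_mol"]


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic span, 1-based closed coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class PipelineConfig:
    """Thresholds, seeds and labels shared across the pipeline."""

    seed: int = 0
    fdr_max: float = 0.05
    leg_high_threshold: float = 2.0
    leg_low_threshold: float = 0.5
    top_k: int = 10
    max_appearances: int = 10
    empirical_threshold: float = 0.0005
    min_set_size: int = 15
    max_set_size: int = 500
    nperm: int = 1000
    snp_flank: int = 10_000
    corrections: list[str] = field(
        default_factory=lambda: ["age+sex", "age+sex+allergy+smoking"]
    )

    def __post_init__(self) -> None:
        for name, v, lo, hi in [
            ("fdr_max", self.fdr_max, 0, 1),
            ("empirical_threshold", self.empirical_threshold, 0, 1),
        ]:
            if not (lo < v <= hi):
                raise ValueError(f"{name} must be in ({lo}, {hi}]")
        if self.leg_high_threshold <= self.leg_low_threshold <= 0:
            raise ValueError("LEG thresholds must satisfy high > low > 0")
        if min(self.top_k, self.max_appearances, self.nperm) < 1 or self.snp_flank < 0:
            raise ValueError("counts must be positive, snp_flank non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _format_error(path, lineno: int, message: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {message}")


def _read_tsv(path: str | Path, header: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != header:
        raise _format_error(path, 1, f"expected header {header}, got {list(df.columns)}")
    return df


def _parse_float_column(df, col, path, lo=None, hi=None) -> np.ndarray:
    raw = df[col]
    values = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if lo is not None:
        bad |= values < lo
    if hi is not None:
        bad |= values > hi
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise _format_error(path, i + 2, f"invalid {col}: {raw.iloc[i]!r}")
    return values


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE table TSV (``gene_id log2fc pvalue fdr``)."""
    df = _read_tsv(path, DE_HEADER)
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "log2fc": _parse_float_column(df, "log2fc", path),
            "pvalue": _parse_float_column(df, "pvalue", path, 0, 1),
            "fdr": _parse_float_column(df, "fdr", path, 0, 1),
        }
    )
    return validate_de_table(out)


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_de_table(df)
    df.loc[:, DE_HEADER].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT gene-set file.

    Returns ``(sets, descriptions)``: pathway name -> gene set and
    pathway name -> description (second GMT column).
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise _format_error(path, lineno, "GMT line needs name, description, >= 1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise _format_error(path, lineno, f"duplicate set name {name!r}")
            if not genes:
                raise _format_error(path, lineno, f"set {name!r} has no genes")
            sets[name] = set(genes)
            descriptions[name] = desc
    if not sets:
        raise _format_error(path, 1, "empty GMT file")
    return sets, descriptions


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{descriptions.get(name, name)}\t{genes}\n")


def read_rnk(path: str | Path) -> pd.DataFrame:
    """Read a headerless RNK file (gene, stat), re-sorted stat descending."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "stat"], dtype=str)
    stat = _parse_float_column(df, "stat", path)
    out = pd.DataFrame({"gene_id": df["gene_id"], "stat": stat})
    if out["gene_id"].duplicated().any():
        raise _format_error(path, 1, "duplicate gene ids in RNK file")
    order = np.lexsort((out["gene_id"].to_numpy(), -stat))
    return out.iloc[order].reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path: str | Path) -> None:
    ranked.loc[:, ["gene_id", "stat"]].to_csv(path, sep="\t", index=False, header=False)


def read_docking_tsv(path: str | Path) -> pd.DataFrame:
    """Read a docking affinity TSV (``drug protein affinity_kcal_mol``)."""
    df = _read_tsv(path, DOCKING_HEADER)
    return pd.DataFrame(
        {
            "drug": df["drug"],
            "protein": df["protein"],
            "affinity": _parse_float_column(df, "affinity_kcal_mol", path),
        }
    )


def write_docking_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.loc[:, ["drug", "protein", "affinity"]].copy()
    out.columns = DOCKING_HEADER
    out.to_csv(path, sep="\t", index=False)


def read_binding_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide drug x protein score matrix (first column ``drug``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise _format_error(path, 1, "binding matrix contains missing/non-finite scores")
    if np.any((values < 0) | (values > 1)):
        raise _format_error(path, 1, "binding scores must lie in [0, 1]")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise _format_error(path, 1, "duplicate drug or protein ids")
    return df.astype(float)


def write_binding_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="drug")


def read_protein_gene_map(path: str | Path) -> dict[str, str]:
    """Read a ``protein  gene`` two-column TSV with header."""
    df = _read_tsv(path, ["protein", "gene"])
    if df["protein"].duplicated().any():
        dup = df.loc[df["protein"].duplicated(), "protein"].iloc[0]
        raise _format_error(path, 1, f"protein {dup!r} maps to more than one gene")
    return dict(zip(df["protein"], df["gene"]))


def read_bed_intervals(path: str | Path) -> list[GeneInterval]:
    """Read gene spans from BED (0-based half-open -> 1-based closed)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise _format_error(path, lineno, "BED needs chrom, start, end, name")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            strand = parts[5] if len(parts) > 5 else "."
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise _format_error(path, lineno, f"non-integer coordinates {start!r}/{end!r}")
            if start_i >= end_i:
                raise _format_error(path, lineno, "BED start must be < end")
            intervals.append(GeneInterval(name, chrom, start_i + 1, end_i, strand))
    if not intervals:
        raise _format_error(path, 1, "no intervals found")
    return intervals


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a SNP position TSV (``snp_id chrom pos``, 1-based)."""
    df = _read_tsv(path, ["snp_id", "chrom", "pos"])
    pos = _parse_float_column(df, "pos", path, lo=1)
    if np.any(pos != np.floor(pos)):
        i = int(np.flatnonzero(pos != np.floor(pos))[0])
        raise _format_error(path, i + 2, f"non-integer position {df['pos'].iloc[i]!r}")
    return pd.DataFrame({"snp_id": df["snp_id"], "chrom": df["chrom"], "pos": pos.astype(int)})


def snp_window_map(
    genes: list[GeneInterval],
    snps: pd.DataFrame,
    flank: int = 10_000,
) -> dict[str, list[str]]:
    """Assign SNPs to genes within a symmetric flank.

    A SNP maps to a gene iff it lies on the same chromosome with
    ``start - flank <= pos <= end + flank`` (closed, 1-based); a SNP may
    map to several genes. Strand is ignored (the flank is symmetric).
    Per gene, SNP ids are ordered by position then id.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    snps = snps.sort_values(["pos", "snp_id"], kind="stable")
    chrom_arr = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy(dtype=np.int64)
    ids = snps["snp_id"].to_numpy()
    out: dict[str, list[str]] = {}
    for g in genes:
        mask = (chrom_arr == g.chrom) & (pos >= g.start - flank) & (pos <= g.end + flank)
        out[g.gene_id] = list(ids[mask])
    return out
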