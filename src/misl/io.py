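"""Readers and writers for every external table the pipeline touches.

All tables are tab-separated text with a header row, except the gene model
(BED4, headerless) and gene sets (GMT).  Readers return validated pandas
DataFrames with fixed column contracts; each reader has a paired writer and
the pair round-trips (``read(write(df)) == df`` after normalisation).

Conventions enforced here so downstream code never revisits them:

* genomic coordinates are 0-based half-open internally; the segment reader
  converts from 1-based inclusive input on request;
* gene identity is the symbol string, uppercased and whitespace-stripped;
  no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MUTATION_TYPES = ("missense", "nonsense", "frameshift", "splice_site", "other")

# Tolerant mapping from the strings seen in MAF-like exports to the internal
# enum.  Keys are compared after lowercasing and replacing spaces/hyphens
# with underscores; anything unmapped becomes "other" with a warning.
_MUTATION_TYPE_MAP = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "stop_gained": "nonsense",
    "frameshift": "frameshift",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift_deletion": "frameshift",
    "frameshift_insertion": "frameshift",
    "frameshift_variant": "frameshift",
    "splice_site": "splice_site",
    "splice_region": "splice_site",
    "splice_site_mutation": "splice_site",
    "other": "other",
}

_SAMPLE_ALIASES = ("sample_id", "sample", "tumor_sample_barcode")
_GENE_ALIASES = ("gene", "hugo_symbol", "gene_symbol")
_TYPE_ALIASES = ("mutation_type", "variant_classification", "type")

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "n_markers", "segment_mean"]


def normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


def normalize_mutation_type(raw: str) -> str:
    key = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
    mapped = _MUTATION_TYPE_MAP.get(key)
    if mapped is None:
        logger.warning("unknown mutation type %r mapped to 'other'", raw)
        return "other"
    return mapped


def _find_column(df: pd.DataFrame, aliases, what: str, path) -> str:
    lowered = {c.lower(): c for c in df.columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(
        f"{path}: missing required {what} column (one of {', '.join(aliases)})"
    )


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-like TSV into a normalized mutation table.

    Returns a DataFrame with columns ``sample_id, gene, mutation_type``,
    deduplicated, genes uppercased, unknown mutation types mapped to
    ``other``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    s = _find_column(df, _SAMPLE_ALIASES, "sample", path)
    g = _find_column(df, _GENE_ALIASES, "gene", path)
    t = _find_column(df, _TYPE_ALIASES, "mutation-type", path)
    out = pd.DataFrame(
        {
            "sample_id": df[s].astype(str).str.strip(),
            "gene": df[g].map(normalize_gene),
            "mutation_type": df[t].map(normalize_mutation_type),
        }
    )
    if (out["gene"] == "").any():
        raise FormatError(f"{path}: empty gene symbol in mutation table")
    out = out.drop_duplicates(ignore_index=True)
    return out


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_segments(path, coordinate_convention: str = "bed0") -> pd.DataFrame:
    """Read a SEG-like TSV; coordinates are converted to 0-based half-open.

    ``coordinate_convention`` is ``bed0`` (already half-open) or
    ``one_based_inclusive`` (SEG convention; start is decremented).
    """
    if coordinate_convention not in ("bed0", "one_based_inclusive"):
        raise ValueError(f"unknown coordinate convention {coordinate_convention!r}")
    df = pd.read_csv(path, sep="\t")
    s = _find_column(df, _SAMPLE_ALIASES, "sample", path)
    cols = {c.lower(): c for c in df.columns}

    def col(*aliases, what):
        for a in aliases:
            if a in cols:
                return cols[a]
        raise FormatError(f"{path}: missing required {what} column")

    out = pd.DataFrame(
        {
            "sample_id": df[s].astype(str).str.strip(),
            "chrom": df[col("chrom", "chromosome", what="chrom")].astype(str),
            "start": df[col("start", "loc.start", what="start")].astype(np.int64),
            "end": df[col("end", "loc.end", what="end")].astype(np.int64),
            "n_markers": df[col("n_markers", "num_mark", what="n_markers")].astype(np.int64),
            "segment_mean": df[col("segment_mean", "seg.mean", what="segment_mean")].astype(float),
        }
    )
    if coordinate_convention == "one_based_inclusive":
        out["start"] = out["start"] - 1
    bad = out.index[(out["end"] <= out["start"]) | (out["start"] < 0)]
    if len(bad):
        raise FormatError(
            f"{path}: segment end <= start (or negative start) after conversion "
            f"at row {int(bad[0]) + 2}"  # +2: header line + 1-based
        )
    if (out["n_markers"] <= 0).any():
        raise FormatError(f"{path}: non-positive n_markers")
    return out.reset_index(drop=True)


def write_segments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2-expression matrix (first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_gene(g) for g in df.index]
    df.index.name = "gene"
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise FormatError(f"{path}: duplicate genes in expression matrix: {dup_genes}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise FormatError(f"{path}: duplicate samples in expression matrix: {dup_samples}")
    df = df.astype(float)
    if not np.isfinite(df.to_numpy()).all():
        raise FormatError(f"{path}: non-finite values in expression matrix")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene")


def read_gene_model(path) -> pd.DataFrame:
    """Read a BED4 gene model into columns ``gene, chrom, start, end``."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene": str},
        comment="#",
    )
    df["gene"] = df["gene"].map(normalize_gene)
    if (df["end"] <= df["start"]).any() or (df["start"] < 0).any():
        raise FormatError(f"{path}: invalid gene coordinates")
    dups = df["gene"][df["gene"].duplicated()].unique().tolist()
    if dups:
        raise FormatError(f"{path}: duplicate genes in gene model: {dups}")
    return df[["gene", "chrom", "start", "end"]].reset_index(drop=True)


def write_gene_model(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (name, description, members...) into a dict of sets."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{line_no}: GMT line needs name, description, >=1 member")
        name = parts[0]
        members = {normalize_gene(g) for g in parts[2:] if g.strip()}
        if not members:
            raise FormatError(f"{path}:{line_no}: empty gene set {name!r}")
        if name in sets:
            raise FormatError(f"{path}:{line_no}: duplicate gene set {name!r}")
        sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_drug_gene(path) -> pd.DataFrame:
    """Read a drug-gene interaction TSV (columns drug, gene, interaction)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("drug", "gene", "interaction"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column {c!r}")
    out = pd.DataFrame(
        {
            "drug": df["drug"].astype(str).str.strip(),
            "gene": df["gene"].map(normalize_gene),
            "interaction": df["interaction"]
            .astype(str)
            .str.strip()
            .str.lower()
            .map(lambda s: "inhibits" if s in ("inhibits", "inhibitor", "inhibition") else "other"),
        }
    )
    if out.duplicated(["drug", "gene"]).any():
        raise FormatError(f"{path}: duplicate (drug, gene) rows")
    return out


def write_drug_gene(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pharmacology(path) -> pd.DataFrame:
    """Read cell-line pharmacology (columns cell_line, tissue, drug, ic50)."""
    df = pd.read_csv(path, sep="\t")
    for c in ("cell_line", "tissue", "drug", "ic50"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column {c!r}")
    out = df[["cell_line", "tissue", "drug", "ic50"]].copy()
    out["cell_line"] = out["cell_line"].astype(str).str.strip()
    out["drug"] = out["drug"].astype(str).str.strip()
    out["ic50"] = out["ic50"].astype(float)
    if (out["ic50"] <= 0).any():
        raise FormatError(f"{path}: non-positive IC50")
    if out.duplicated(["cell_line", "drug"]).any():
        raise FormatError(f"{path}: duplicate (cell_line, drug) rows")
    return out.reset_index(drop=True)


def write_pharmacology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_screen(path) -> pd.DataFrame:
    """Read an shRNA screen table: construct_id, gene, then condition columns."""
    df = pd.read_csv(path, sep="\t")
    for c in ("construct_id", "gene"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing required column {c!r}")
    df = df.copy()
    df["construct_id"] = df["construct_id"].astype(str)
    df["gene"] = df["gene"].map(normalize_gene)
    if df["construct_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate construct ids")
    return df


def write_screen(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bool_matrix(path) -> pd.DataFrame:
    """Read a genes/variables x samples 0/1 matrix written by write_bool_matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int).astype(bool)


def write_bool_matrix(df: pd.DataFrame, path) -> None:
    df.astype(int).to_csv(path, sep="\t", index=True, index_label=df.index.name or "gene")
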