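"""Readers and writers for the pipeline's plain-text formats.

All gene symbols pass through :func:`normalize_symbol` (trim + uppercase) at
ingest, the single harmonization choke point across the three platforms.
Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "normalize_symbol",
    "infer_groups",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "write_manifest",
    "read_tss_table",
    "write_tss_table",
    "read_probe_map",
    "write_probe_map",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "write_json",
    "read_json",
]


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def infer_groups(columns: Iterable[str]) -> dict[str, str]:
    """Map sample names like ``RA_03`` to their group label (``RA``).

    The group is the token before the first underscore.
    """
    return {c: c.split("_", 1)[0] for c in columns}


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (beta values or intensities)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.4f") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_manifest(path) -> pd.DataFrame:
    """Read a 4-column BED-like locus manifest: chrom, start, end, locus_id."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "locus_id"],
                     dtype={"chrom": str, "start": int, "end": int, "locus_id": str})
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "locus_id"]].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path) -> pd.DataFrame:
    """Read the TSS table: gene, chrom, strand, tss_position, transcript_label."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str,
                                            "tss_position": int, "transcript_label": str})
    df["gene"] = df["gene"].map(normalize_symbol)
    return df


def write_tss_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    """Read the probe -> gene map TSV (columns probe_id, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["gene"] = df["gene"].map(normalize_symbol)
    return df


def write_probe_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list, normalized, blank lines skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(normalize_symbol(line))
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT pathway collection: name, description, tab-separated members."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        name = fields[0].strip()
        pathways[name] = {normalize_symbol(g) for g in fields[2:] if g.strip()}
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, genes in pathways.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc] + sorted(set(genes))))
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
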