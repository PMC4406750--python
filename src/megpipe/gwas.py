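"""GWAS-catalog parsing and trait gene extraction.

The catalog dialect is a TSV with header columns DISEASE/TRAIT, SNPS,
P-VALUE and REPORTED GENE(S).  Reported-gene cells may list several symbols
("GENE1, GENE2"), or carry a placeholder (NR, intergenic, "-", empty) that
yields no genes.  Trait selection is case-insensitive substring matching by
default; the disease gene set is the union of reported genes over matching
rows plus an optional supplementary list (e.g. meta-analysis hits).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .io import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = ["CatalogRow", "read_catalog", "rows_from_frame", "parse_gene_cell",
           "extract_trait_genes", "catalog_background"]

#: tokens in a reported-gene cell meaning "no gene reported"
PLACEHOLDER_TOKENS = {"", "-", "NR", "INTERGENIC", "NONE", "NA"}

REQUIRED_COLUMNS = ("DISEASE/TRAIT", "SNPS", "P-VALUE", "REPORTED GENE(S)")


@dataclass
class CatalogRow:
    trait: str
    snp_ids: list[str] = field(default_factory=list)
    p_value: float = float("nan")
    reported_genes: list[str] = field(default_factory=list)


def parse_gene_cell(cell: str) -> list[str]:
    """Split a reported-gene cell on commas/semicolons; placeholders give []."""
    genes = []
    for token in re.split(r"[,;]", cell or ""):
        sym = normalize_symbol(token)
        if sym and sym not in PLACEHOLDER_TOKENS:
            genes.append(sym)
    return genes


def read_catalog(path) -> list[CatalogRow]:
    """Parse a catalog TSV; rows with the wrong column count are skipped with a warning."""
    rows: list[CatalogRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        try:
            idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        except ValueError as exc:
            raise ValueError(f"catalog header missing a required column: {exc}") from exc
        n_bad = 0
        for lineno, fields in enumerate(reader, start=2):
            if len(fields) != len(header):
                n_bad += 1
                logger.warning("%s:%d: expected %d columns, got %d — row skipped",
                               Path(path).name, lineno, len(header), len(fields))
                continue
            try:
                p = float(fields[idx["P-VALUE"]])
            except ValueError:
                p = float("nan")
            rows.append(CatalogRow(
                trait=fields[idx["DISEASE/TRAIT"]].strip(),
                snp_ids=[s.strip() for s in fields[idx["SNPS"]].split(",") if s.strip()],
                p_value=p,
                reported_genes=parse_gene_cell(fields[idx["REPORTED GENE(S)"]]),
            ))
        if n_bad:
            logger.warning("%s: skipped %d malformed rows", Path(path).name, n_bad)
    return rows


def rows_from_frame(df) -> list[CatalogRow]:
    """Build catalog rows from an in-memory DataFrame with the catalog columns."""
    rows = []
    for trait, snps, p, cell in df[list(REQUIRED_COLUMNS)].itertuples(index=False):
        try:
            pv = float(p)
        except (TypeError, ValueError):
            pv = float("nan")
        rows.append(CatalogRow(
            trait=str(trait).strip(),
            snp_ids=[s.strip() for s in str(snps).split(",") if s.strip()],
            p_value=pv,
            reported_genes=parse_gene_cell(str(cell)),
        ))
    return rows


def extract_trait_genes(catalog_rows: list[CatalogRow],
                        trait_patterns=("rheumatoid arthritis",),
                        supplement=(), exact: bool = False) -> set[str]:
    """Union of reported genes over trait-matching rows, plus the supplement.

    Matching is case-insensitive substring by default (``exact=True`` for
    whole-trait equality).  The result is a deduplicated symbol set.
    """
    patterns = [p.lower() for p in trait_patterns]
    if not patterns:
        raise ValueError("need at least one trait pattern")
    genes: set[str] = set()
    for row in catalog_rows:
        trait = row.trait.lower()
        if any((trait == p) if exact else (p in trait) for p in patterns):
            genes.update(row.reported_genes)
    genes.update(normalize_symbol(g) for g in supplement)
    return genes


def catalog_background(catalog_rows: list[CatalogRow]) -> set[str]:
    """All genes reported anywhere in the catalog, regardless of trait.

    This is the 'identifiable' GWAS gene universe used by the overlap
    permutation null.
    """
    genes: set[str] = set()
    for row in catalog_rows:
        genes.update(row.reported_genes)
    return genes
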