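"""Evidence integration: the per-gene ledger, Venn counts, MEG sets.

A multi-evidence gene (MEG) is implicated by at least two of the three
genome-wide measures: promoter differential methylation (DMG), differential
expression (DEG), and GWAS association.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["build_ledger", "meg_set", "venn_counts", "VENN_REGIONS"]

VENN_REGIONS = ("dmg_only", "deg_only", "gwas_only", "dmg_deg",
                "dmg_gwas", "deg_gwas", "dmg_deg_gwas")


def build_ledger(dmg: set[str], deg: set[str], gwas: set[str]) -> pd.DataFrame:
    """Per-gene evidence flags over the union of the three sets.

    Rows are sorted lexicographically by gene so serialized output is
    deterministic.
    """
    genes = sorted(set(dmg) | set(deg) | set(gwas))
    ledger = pd.DataFrame({
        "in_dmg": [g in dmg for g in genes],
        "in_deg": [g in deg for g in genes],
        "in_gwas": [g in gwas for g in genes],
    }, index=pd.Index(genes, name="gene"))
    ledger["evidence_count"] = ledger[["in_dmg", "in_deg", "in_gwas"]].sum(axis=1)
    return ledger


def meg_set(ledger: pd.DataFrame, min_evidence: int = 2) -> set[str]:
    """Genes with at least ``min_evidence`` of the three evidence flags."""
    if min_evidence not in (2, 3):
        raise ValueError("min_evidence must be 2 or 3")
    return set(ledger.index[ledger["evidence_count"] >= min_evidence])


def venn_counts(ledger: pd.DataFrame) -> dict[str, int]:
    """Counts of the 7 exclusive regions of the DMG/DEG/GWAS Venn diagram."""
    d, e, g = (ledger["in_dmg"], ledger["in_deg"], ledger["in_gwas"])
    return {
        "dmg_only": int((d & ~e & ~g).sum()),
        "deg_only": int((~d & e & ~g).sum()),
        "gwas_only": int((~d & ~e & g).sum()),
        "dmg_deg": int((d & e & ~g).sum()),
        "dmg_gwas": int((d & ~e & g).sum()),
        "deg_gwas": int((~d & e & g).sum()),
        "dmg_deg_gwas": int((d & e & g).sum()),
    }
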