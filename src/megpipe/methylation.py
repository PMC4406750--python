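"""Differential methylation: locus tests, promoter windows, DMG calling.

A locus is differentially methylated (DML) in a comparison when its BH
q-value is < 0.05 and the absolute group mean beta difference exceeds 0.1
(both strict).  A gene is a DMG when at least one DML falls inside one of its
promoter windows, defined as -2500 bp to +500 bp around a TSS in the
direction of transcription.  Genes with several TSSs get one window per TSS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bh_adjust, welch_t_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "test_all_loci",
    "classify_dml",
    "build_promoter_windows",
    "loci_in_windows",
    "dml_to_dmg",
    "combined_dmg",
]

#: promoter window extent, in bp relative to the TSS in transcription direction
PROMOTER_UPSTREAM = 2500
PROMOTER_DOWNSTREAM = 500


def _group_columns(columns, groups: dict[str, str], label: str) -> list[str]:
    cols = [c for c in columns if groups.get(c) == label]
    if len(cols) < 2:
        raise ValueError(f"group {label!r} needs >=2 samples, found {len(cols)}")
    return cols


def classify_dml(q_values, deltas, q_threshold: float = 0.05,
                 delta_threshold: float = 0.1) -> np.ndarray:
    """DML rule: q < threshold AND |mean difference| > threshold, both strict."""
    q = np.asarray(q_values, dtype=float)
    d = np.asarray(deltas, dtype=float)
    return (q < q_threshold) & (np.abs(d) > delta_threshold)


def test_all_loci(beta: pd.DataFrame, groups: dict[str, str],
                  comparison: tuple[str, str], q_threshold: float = 0.05,
                  delta_threshold: float = 0.1) -> pd.DataFrame:
    """Welch-test every locus between the two groups of ``comparison``.

    ``beta`` is loci x samples; ``groups`` maps sample name -> group label.
    Loci with missing values in the compared samples are skipped (counted in
    the log).  q-values are computed across all tested loci of this
    comparison.  Returns a DataFrame with one row per tested locus.
    """
    ga, gb = comparison
    cols_a = _group_columns(beta.columns, groups, ga)
    cols_b = _group_columns(beta.columns, groups, gb)
    sub = beta[cols_a + cols_b]
    complete = ~sub.isna().any(axis=1)
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.warning("%s vs %s: skipped %d loci with missing values", ga, gb, n_skipped)
    sub = sub.loc[complete]
    res = welch_t_matrix(sub[cols_a].to_numpy(), sub[cols_b].to_numpy())
    q = bh_adjust(res["p"])
    out = pd.DataFrame({
        "locus_id": sub.index.to_numpy(),
        "comparison": f"{ga}_vs_{gb}",
        "mean_a": res["mean_a"],
        "mean_b": res["mean_b"],
        "delta": res["delta"],
        "t_stat": res["t"],
        "df": res["df"],
        "p_value": res["p"],
        "q_value": q,
        "is_dml": classify_dml(q, res["delta"], q_threshold, delta_threshold),
    })
    return out


def build_promoter_windows(tss: pd.DataFrame, upstream: int = PROMOTER_UPSTREAM,
                           downstream: int = PROMOTER_DOWNSTREAM) -> pd.DataFrame:
    """One promoter window per TSS row, strand-aware, 0-based half-open.

    On + strands the window is [TSS-upstream, TSS+downstream); on - strands it
    is mirrored to [TSS-downstream, TSS+upstream) so that it still spans
    ``upstream`` bp before and ``downstream`` bp after the TSS in the
    direction of transcription.
    """
    strands = tss["strand"].to_numpy()
    bad = ~np.isin(strands, ["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol(s): {sorted(set(strands[bad]))}")
    pos = tss["tss_position"].to_numpy()
    plus = strands == "+"
    start = np.where(plus, pos - upstream, pos - downstream)
    end = np.where(plus, pos + downstream, pos + upstream)
    return pd.DataFrame({
        "gene": tss["gene"].to_numpy(),
        "chrom": tss["chrom"].to_numpy(),
        "strand": strands,
        "start": start,
        "end": end,
        "source_tss": pos,
    })


def loci_in_windows(manifest: pd.DataFrame, windows: pd.DataFrame,
                    locus_ids=None) -> set[str]:
    """Genes with at least one manifest locus start inside one of their windows.

    Membership is by the locus *start* coordinate, half-open on the window
    end.  If ``locus_ids`` is given, only those loci are considered.
    """
    loci = manifest if locus_ids is None else manifest[manifest["locus_id"].isin(set(locus_ids))]
    genes: set[str] = set()
    if loci.empty or windows.empty:
        return genes
    for chrom, wchr in windows.groupby("chrom", sort=False):
        starts = np.sort(loci.loc[loci["chrom"] == chrom, "start"].to_numpy())
        if starts.size == 0:
            continue
        lo = np.searchsorted(starts, wchr["start"].to_numpy(), side="left")
        hi = np.searchsorted(starts, wchr["end"].to_numpy(), side="left")
        genes.update(wchr["gene"].to_numpy()[hi > lo])
    return genes


def dml_to_dmg(dml: pd.DataFrame, windows: pd.DataFrame,
               manifest: pd.DataFrame) -> set[str]:
    """Map called DMLs to DMGs: genes with >=1 DML in a promoter window."""
    hits = dml.loc[dml["is_dml"], "locus_id"]
    missing = set(hits) - set(manifest["locus_id"])
    if missing:
        raise ValueError(f"{len(missing)} DML loci absent from the coordinate manifest, "
                         f"e.g. {sorted(missing)[:3]}")
    return loci_in_windows(manifest, windows, locus_ids=hits)


def combined_dmg(per_comparison_dmgs: list[set[str]]) -> set[str]:
    """Union of per-comparison DMG sets (the 'combined' DMG set)."""
    if not per_comparison_dmgs:
        return set()
    return set().union(*per_comparison_dmgs)
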