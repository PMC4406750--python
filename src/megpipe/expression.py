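"""Differential expression: per-probe tests, any-probe gene calling.

A probe is differentially expressed when its fold change exceeds 2 and its
*uncorrected* Welch p-value is below 0.05 (no multiple-testing correction:
with high intra-sample variation a corrected threshold would be too
conservative, and the fold-change filter does the heavy lifting).  Probes for
the same gene are tested separately, never averaged — different probes can
interrogate different exons — and a gene is a DEG as soon as any one of its
probes passes (the any-probe rule).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import welch_t_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "test_all_probes",
    "classify_deg_probe",
    "probes_to_deg",
    "combined_deg",
]


def classify_deg_probe(fold_changes, p_values, fold_threshold: float = 2.0,
                       p_threshold: float = 0.05) -> np.ndarray:
    """DEG-probe rule: fold change > threshold AND p < threshold, both strict."""
    fc = np.asarray(fold_changes, dtype=float)
    p = np.asarray(p_values, dtype=float)
    return (fc > fold_threshold) & (p < p_threshold)


def test_all_probes(expr: pd.DataFrame, probe_map: pd.DataFrame,
                    groups: dict[str, str], comparison: tuple[str, str],
                    log2_input: bool = False, test_on_log: bool = True,
                    fold_threshold: float = 2.0,
                    p_threshold: float = 0.05) -> pd.DataFrame:
    """Welch-test every probe between the two groups of ``comparison``.

    ``expr`` is probes x samples, on linear scale unless ``log2_input``.
    Fold change is the max of the ratio and inverse ratio of the linear-scale
    group means (symmetric in the group order); the t-test runs on log2
    values by default for variance stabilization.  Probes without a gene
    mapping are retained with gene=NA and can never contribute a DEG.
    """
    ga, gb = comparison
    cols_a = [c for c in expr.columns if groups.get(c) == ga]
    cols_b = [c for c in expr.columns if groups.get(c) == gb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"comparison {ga} vs {gb} needs >=2 samples per group")
    values = expr[cols_a + cols_b].to_numpy(dtype=float)
    linear = np.exp2(values) if log2_input else values
    if np.any(linear <= 0):
        raise ValueError("nonpositive intensities: linear-scale fold change undefined")
    log2v = values if log2_input else np.log2(linear)
    tested = log2v if test_on_log else linear
    res = welch_t_matrix(tested[:, :len(cols_a)], tested[:, len(cols_a):])
    lin_a = linear[:, :len(cols_a)].mean(axis=1)
    lin_b = linear[:, len(cols_a):].mean(axis=1)
    ratio = lin_a / lin_b
    fold = np.maximum(ratio, 1.0 / ratio)
    gene_of = dict(zip(probe_map["probe_id"], probe_map["gene"]))
    genes = np.array([gene_of.get(p) for p in expr.index], dtype=object)
    n_unmapped = int(sum(g is None for g in genes))
    if n_unmapped:
        logger.info("%s vs %s: %d probes without a gene mapping (retained, flagged)",
                    ga, gb, n_unmapped)
    return pd.DataFrame({
        "probe_id": expr.index.to_numpy(),
        "gene": genes,
        "comparison": f"{ga}_vs_{gb}",
        "mean_a": lin_a,
        "mean_b": lin_b,
        "fold_change": fold,
        "t_stat": res["t"],
        "df": res["df"],
        "p_value": res["p"],
        "is_deg_probe": classify_deg_probe(fold, res["p"], fold_threshold, p_threshold),
    })


def probes_to_deg(records: pd.DataFrame) -> set[str]:
    """Any-probe rule: a gene is a DEG iff >=1 of its mapped probes passes."""
    hits = records.loc[records["is_deg_probe"], "gene"]
    return {g for g in hits if g is not None and not pd.isna(g)}


def combined_deg(per_comparison_degs: list[set[str]]) -> set[str]:
    """Union of per-comparison DEG sets (the 'combined' DEG set)."""
    if not per_comparison_degs:
        return set()
    return set().union(*per_comparison_degs)
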