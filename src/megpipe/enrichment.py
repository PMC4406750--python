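"""Hypergeometric pathway enrichment of the MEG set.

Per pathway, with background size N: K = pathway genes in the background,
m = query (MEG) genes in the background, k = their overlap.  The p-value is
the hypergeometric upper tail P(X >= k); fold enrichment is (k/m)/(K/N);
q-values are BH across all tested pathways and pathways with q < 0.05 are
reported as significant.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import HypergeomParams, bh_adjust, fold_enrichment, hypergeom_upper_tail

logger = logging.getLogger(__name__)

__all__ = ["enrich", "filter_significant"]


def enrich(meg: Iterable[str], pathways: Mapping[str, Iterable[str]],
           background: Iterable[str], restrict_to_background: bool = True,
           min_pathway_size: int = 1) -> pd.DataFrame:
    """Hypergeometric enrichment of ``meg`` in each pathway over ``background``.

    Query genes outside the background are dropped (logged).  By default
    pathway membership is restricted to the background before counting
    (``K = |pathway ∩ background|``); set ``restrict_to_background=False``
    to use raw pathway sizes.  Pathways with K below ``min_pathway_size``
    are skipped.  Rows are sorted by (q, p, pathway).
    """
    if not pathways:
        raise ValueError("empty pathway collection")
    background = set(background)
    if not background:
        raise ValueError("empty background")
    meg = set(meg)
    dropped = meg - background
    if dropped:
        logger.warning("dropping %d query genes outside the background", len(dropped))
    meg &= background
    N, m = len(background), len(meg)
    rows = []
    for name, genes in pathways.items():
        genes = set(genes)
        in_bg = genes & background
        K = len(in_bg) if restrict_to_background else len(genes)
        if K < max(min_pathway_size, 1):
            continue
        k = len(meg & in_bg)
        params = HypergeomParams(N=N, K=min(K, N), m=m, k=k)
        p = hypergeom_upper_tail(params) if m > 0 else 1.0
        fold = fold_enrichment(params) if (m > 0 and K > 0) else 0.0
        rows.append((name, k, K, m, N, fold, p))
    table = pd.DataFrame(rows, columns=["pathway", "k", "K", "m", "N", "fold", "p_hyper"])
    table["q_value"] = bh_adjust(table["p_hyper"].to_numpy()) if len(table) else np.array([])
    table = table.sort_values(["q_value", "p_hyper", "pathway"], kind="mergesort")
    return table.reset_index(drop=True)


def filter_significant(records: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Pathways with q strictly below the threshold, order preserved."""
    return records[records["q_value"] < q_threshold].reset_index(drop=True)
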