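"""Independent reference implementations used only as test oracles.

Each function here recomputes a quantity by a route deliberately different
from the package's (enumeration, hand-rolled step-up, brute-force loops) so
tests compare two independent derivations.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def hypergeom_tail_brute(N: int, K: int, m: int, k: int) -> float:
    """P(X >= k) by direct pmf summation with exact integer binomials."""
    denom = comb(N, m)
    total = sum(comb(K, i) * comb(N - K, m - i)
                for i in range(k, min(K, m) + 1))
    return total / denom


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, textbook loop implementation."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = running_min
    return q


def overlap_null_pmf_exhaustive(universe: list, draws: list[int]) -> dict[int, float]:
    """Exact null pmf of the k-way intersection size of uniform draws.

    Enumerates every combination of subsets (feasible only for tiny
    universes); each assay draws uniformly from the full universe.
    """
    combos = [list(itertools.combinations(universe, d)) for d in draws]
    total = 1
    for c in combos:
        total *= len(c)
    pmf: dict[int, float] = {}
    for picks in itertools.product(*combos):
        overlap = len(set.intersection(*(set(p) for p in picks)))
        pmf[overlap] = pmf.get(overlap, 0) + 1
    return {k: v / total for k, v in pmf.items()}


def genes_with_dml_brute(manifest, windows, dml_locus_ids) -> set:
    """Brute-force double loop over (locus, window) pairs."""
    dml_ids = set(dml_locus_ids)
    loci = [(row.chrom, row.start) for row in manifest.itertuples()
            if row.locus_id in dml_ids]
    genes = set()
    for w in windows.itertuples():
        for chrom, start in loci:
            if chrom == w.chrom and w.start <= start < w.end:
                genes.add(w.gene)
    return genes


def degs_brute(records) -> set:
    """Brute-force any-probe grouping."""
    genes = set()
    for row in records.itertuples():
        if row.is_deg_probe and isinstance(row.gene, str):
            genes.add(row.gene)
    return genes
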