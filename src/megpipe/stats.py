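"""Shared statistical primitives.

Every downstream stage of the pipeline (locus/probe testing, pathway
enrichment) funnels through the four primitives here: Welch's unequal-variance
t-test, Benjamini–Hochberg q-values, the hypergeometric upper tail and fold
enrichment.  Welch's test is implemented directly so the degenerate
zero-variance contracts are explicit; the t tail probability comes from
``scipy.stats.t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoSampleResult",
    "HypergeomParams",
    "welch_t_test",
    "welch_t_matrix",
    "bh_adjust",
    "hypergeom_upper_tail",
    "fold_enrichment",
]


@dataclass(frozen=True)
class TwoSampleResult:
    """Result of a two-sample Welch t-test.

    ``delta`` is always ``mean_a - mean_b``; swapping the groups negates
    ``t_stat`` and ``delta`` but leaves ``p_value`` unchanged.  ``degenerate``
    marks the zero-variance contracts (both variances zero: p=1/t=0 when the
    means agree, p=0 with infinite t when they differ); no field is ever NaN.
    """

    mean_a: float
    mean_b: float
    delta: float
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class HypergeomParams:
    """Counts for a hypergeometric overlap test.

    N: background size; K: category (pathway) genes in the background;
    m: query-set size in the background; k: overlap between query and category.
    """

    N: int
    K: int
    m: int
    k: int

    def __post_init__(self) -> None:
        if min(self.N, self.K, self.m, self.k) < 0:
            raise ValueError("hypergeometric counts must be nonnegative")
        if self.K > self.N or self.m > self.N:
            raise ValueError("K and m cannot exceed the background size N")
        if self.k > min(self.K, self.m):
            raise ValueError("overlap k cannot exceed min(K, m)")


def welch_t_test(a, b) -> TwoSampleResult:
    """Two-sided Welch t-test between samples ``a`` and ``b``.

    Uses the Welch–Satterthwaite degrees of freedom.  Requires at least two
    observations per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    delta = ma - mb
    if va == 0.0 and vb == 0.0:
        # Both groups constant: the test statistic is formally 0/0.  We adopt
        # the limit contract: equal means -> no evidence (t=0, p=1); unequal
        # means -> arbitrarily strong evidence (t=+/-inf, p=0).
        df = float(na + nb - 2)
        if delta == 0.0:
            return TwoSampleResult(ma, mb, 0.0, 0.0, df, 1.0, degenerate=True)
        t = math.inf if delta > 0 else -math.inf
        return TwoSampleResult(ma, mb, delta, t, df, 0.0, degenerate=True)
    sea, seb = va / na, vb / nb
    se2 = sea + seb
    t = delta / math.sqrt(se2)
    df = se2 ** 2 / (sea ** 2 / (na - 1) + seb ** 2 / (nb - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TwoSampleResult(ma, mb, delta, t, df, min(p, 1.0))


def welch_t_matrix(a: np.ndarray, b: np.ndarray) -> dict:
    """Row-wise Welch t-tests for two matrices of shape (features, samples).

    Vectorized twin of :func:`welch_t_test`; identical results row by row,
    including the zero-variance contracts.  Returns arrays ``mean_a``,
    ``mean_b``, ``delta``, ``t``, ``df``, ``p``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("expected two (features, samples) matrices with equal row counts")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    delta = ma - mb
    sea, seb = va / na, vb / nb
    se2 = sea + seb
    degen = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2 ** 2 / (sea ** 2 / (na - 1) + seb ** 2 / (nb - 1))
        p = 2.0 * _sps.t.sf(np.abs(t), np.where(degen, 1.0, df))
    p = np.minimum(p, 1.0)
    if degen.any():
        eq = degen & (delta == 0.0)
        ne = degen & (delta != 0.0)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.where(delta[ne] > 0, np.inf, -np.inf)
        p[ne] = 0.0
        df[degen] = float(na + nb - 2)
    return {"mean_a": ma, "mean_b": mb, "delta": delta, "t": t, "df": df,
            "p": p, "degenerate": degen}


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjusted q-values (Benjamini–Hochberg step-up by default).

    ``method`` accepts any ``statsmodels.stats.multitest`` method name, but BH
    is what the pipeline's q-value thresholds are calibrated against.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def hypergeom_upper_tail(params: HypergeomParams) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, m): draw m, count category hits."""
    return float(_sps.hypergeom.sf(params.k - 1, params.N, params.K, params.m))


def fold_enrichment(params: HypergeomParams) -> float:
    """Fold enrichment (k/m)/(K/N): the query's in-category rate over the background's."""
    if params.K == 0 or params.m == 0 or params.N == 0:
        raise ValueError("fold enrichment requires K > 0, m > 0 and N > 0")
    return (params.k / params.m) / (params.K / params.N)
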