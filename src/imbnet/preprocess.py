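"""Inputs to network learning: informative genes, discretization, cis calls.

Bayesian-network learning here operates on a three-state (low/medium/high)
discretization of expression, restricted to genes that either vary enough
to be informative or carry a genetic anchor: a significant positive
association between a gene's expression and its own copy number (a
"cis-CNA" gene). Cis genes are special because copy number is causally
upstream of expression, which the structure prior exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CisCnaResult",
    "select_informative_genes",
    "discretize_expression",
    "detect_cis_cna",
]


@dataclass
class CisCnaResult:
    gene: str
    correlation: float
    p: float
    q: float
    is_cis: bool


def select_informative_genes(
    expression: pd.DataFrame,
    cis: list[CisCnaResult] | None = None,
    top_frac: float = 0.5,
    clinical: pd.DataFrame | None = None,
) -> list[str]:
    """Union of the top variance fraction of genes and all cis-CNA genes.

    Returned in the row order of ``expression`` (stable, no duplicates).
    ``clinical`` is accepted for future trait-anchored selection rules but
    is not used by the default rule.
    """
    if expression.empty:
        raise ValueError("expression matrix is empty")
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    variances = expression.var(axis=1, ddof=1)
    k = max(1, int(round(top_frac * len(variances))))
    top = set(variances.sort_values(ascending=False, kind="stable").index[:k])
    cis_genes = {c.gene for c in (cis or []) if c.is_cis}
    keep = top | (cis_genes & set(expression.index))
    return [g for g in expression.index if g in keep]


def _kmeans_1d_three(values: np.ndarray) -> np.ndarray:
    """Exact 1-D k-means with k=3.

    In one dimension the optimal k-means clusters are contiguous intervals
    of the sorted values, so the global optimum is found by scanning all
    pairs of breakpoints over the unique values (prefix-sum costs). Tied
    values always share a state; states are numbered by ascending cluster
    mean. Deterministic and invariant to increasing affine transforms.
    """
    uniq, counts = np.unique(values, return_counts=True)
    m = len(uniq)
    # prefix sums over unique values weighted by multiplicity
    cw = np.concatenate([[0.0], np.cumsum(counts)])
    cs = np.concatenate([[0.0], np.cumsum(counts * uniq)])
    cs2 = np.concatenate([[0.0], np.cumsum(counts * uniq**2)])

    def seg_cost(i, j):  # within-cluster SS of uniq[i:j], vectorized in j
        n = cw[j] - cw[i]
        s = cs[j] - cs[i]
        s2 = cs2[j] - cs2[i]
        return s2 - np.where(n > 0, s * s / np.maximum(n, 1), 0.0)

    best, best_ab = np.inf, (1, 2)
    for a in range(1, m - 1):
        bs = np.arange(a + 1, m)
        cost = seg_cost(0, a) + seg_cost(a, bs) + seg_cost(bs, m)
        k = int(np.argmin(cost))
        if cost[k] < best - 1e-12:
            best, best_ab = float(cost[k]), (a, int(bs[k]))
    a, b = best_ab
    state_of_value = np.empty(m, dtype=int)
    state_of_value[:a] = 0
    state_of_value[a:b] = 1
    state_of_value[b:] = 2
    idx = np.searchsorted(uniq, values)
    return state_of_value[idx]


def discretize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene three-state discretization by exact 1-D k-means (k=3).

    Genes with fewer than 3 distinct values are mapped entirely to the
    middle state (1). Non-finite input is rejected.
    """
    values = expression.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression contains non-finite values")
    states = np.empty(values.shape, dtype=np.int8)
    for i in range(values.shape[0]):
        row = values[i]
        if len(np.unique(row)) < 3:
            states[i] = 1
        else:
            states[i] = _kmeans_1d_three(row)
    return pd.DataFrame(states, index=expression.index, columns=expression.columns)


def detect_cis_cna(
    expression: pd.DataFrame,
    cna: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> list[CisCnaResult]:
    """Per-gene Spearman test of expression against own copy number.

    One-sided (positive association: copy gain should raise expression),
    Benjamini-Hochberg corrected across genes; a gene is called cis when
    q < fdr_threshold and the correlation is positive.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie in (0, 1)")
    if list(expression.index) != list(cna.index) or list(expression.columns) != list(
        cna.columns
    ):
        raise ValueError("expression and cna must share gene and sample axes")
    if expression.shape[1] < 5:
        raise ValueError("need at least 5 samples for a rank test")

    genes = list(expression.index)
    rhos = np.empty(len(genes))
    pvals = np.empty(len(genes))
    e = expression.to_numpy(dtype=float)
    c = cna.to_numpy(dtype=float)
    for i in range(len(genes)):
        if np.ptp(e[i]) == 0 or np.ptp(c[i]) == 0:
            rhos[i], pvals[i] = 0.0, 1.0
            continue
        res = stats.spearmanr(e[i], c[i], alternative="greater")
        rhos[i], pvals[i] = res.statistic, res.pvalue
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        CisCnaResult(
            gene=g,
            correlation=float(rhos[i]),
            p=float(pvals[i]),
            q=float(qvals[i]),
            is_cis=bool(qvals[i] < fdr_threshold and rhos[i] > 0),
        )
        for i, g in enumerate(genes)
    ]
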