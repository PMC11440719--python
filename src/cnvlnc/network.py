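"""lncRNA-mRNA co-expression network and gene-set over-representation.

Edges are Pearson correlations between a candidate lncRNA and DE-prefiltered
mRNAs; the p-value uses the exact t transform t = r*sqrt((n-2)/(1-r^2)) with
n-2 degrees of freedom, BH-adjusted within each lncRNA's family of tests.
Retained edges satisfy |r| >= r_thr (r >= r_thr with ``positive_only``) and
adjusted p < alpha.

Over-representation of a query gene list against user-supplied GMT sets is an
upper-tail hypergeometric test P(X >= k) with BH across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

EDGE_COLUMNS = ["lnc_gene_id", "mrna_gene_id", "r", "p", "p_adj", "sign"]


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and the two-sided t-based p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 paired observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def build_network(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_thr: float = 0.7,
    alpha: float = 0.05,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Correlate each lncRNA (rows of ``lnc_expr``) against each mRNA.

    Both frames are genes x samples on log2 scale and must share their sample
    columns. Zero-variance genes are skipped and reported in the result's
    ``attrs['skipped_zero_variance']``. BH adjustment is applied per lncRNA.
    """
    shared = [c for c in lnc_expr.columns if c in set(mrna_expr.columns)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    L = lnc_expr[shared].to_numpy(dtype=float)
    M = mrna_expr[shared].to_numpy(dtype=float)
    n = len(shared)

    l_sd = L.std(axis=1)
    m_sd = M.std(axis=1)
    skipped = [str(g) for g, s in zip(lnc_expr.index, l_sd) if s == 0]
    skipped += [str(g) for g, s in zip(mrna_expr.index, m_sd) if s == 0]

    Lc = L - L.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Lc @ Mc.T) / (
            np.sqrt((Lc**2).sum(axis=1))[:, None] * np.sqrt((Mc**2).sum(axis=1))[None, :]
        )
    corr = np.clip(corr, -1.0, 1.0)

    rows = []
    m_ok = m_sd != 0
    for i, lnc_id in enumerate(lnc_expr.index):
        if l_sd[i] == 0:
            continue
        r = corr[i, m_ok]
        mrna_ids = mrna_expr.index[m_ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
        p_adj = bh_adjust(p)
        keep = (r >= r_thr) if positive_only else (np.abs(r) >= r_thr)
        keep &= p_adj < alpha
        for j in np.flatnonzero(keep):
            rows.append(
                {
                    "lnc_gene_id": lnc_id,
                    "mrna_gene_id": mrna_ids[j],
                    "r": float(r[j]),
                    "p": float(p[j]),
                    "p_adj": float(p_adj[j]),
                    "sign": "+" if r[j] >= 0 else "-",
                }
            )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    edges.attrs["skipped_zero_variance"] = skipped
    return edges


def hypergeom_ora(
    query,
    gene_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    With universe size N, set size K (after intersection with the universe),
    query size n and overlap k, p = P(X >= k) for X ~ Hypergeom(N, K, n);
    k = 0 gives p = 1 under the >= 0 convention. BH across tested sets.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not universe:
        raise ValueError("universe gene set is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n = len(query)
    N = len(universe)

    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    result = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result
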