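"""Probe-level differential expression.

Two engines cover the two comparisons the screen needs:

* :func:`paired_de` — tumor vs. matched normal on log2 expression, one paired
  t-test per probe with Benjamini-Hochberg adjustment across probes. A probe
  is called ``up`` when log2FC >= ``fc_thr`` and adjusted p <= ``alpha``
  (symmetric for ``down``); thresholds are inclusive.
* :func:`unpaired_de` — Welch two-sample t per gene for the treated-vs-control
  design, thresholded on raw p by default (the overexpression comparison uses
  |FC| >= 1.5 on the linear scale and raw P < 0.05).

Both return a tidy DataFrame with one row per probe/gene. Probes whose paired
differences have zero variance are flagged ``degenerate`` and get p = 0 when
the mean difference is non-zero, else p = 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
NS = "ns"

DE_COLUMNS = ["probe_id", "log2fc", "t", "p", "p_adj", "direction", "degenerate"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _assign_direction(log2fc: np.ndarray, p_ref: np.ndarray, fc_thr: float, alpha: float):
    direction = np.full(log2fc.shape, NS, dtype=object)
    direction[(log2fc >= fc_thr) & (p_ref <= alpha)] = UP
    direction[(log2fc <= -fc_thr) & (p_ref <= alpha)] = DOWN
    return direction


def paired_de(
    matrix: pd.DataFrame,
    pairing: pd.DataFrame,
    fc_thr: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired tumor-vs-normal DE on a probes x samples log2 matrix.

    ``pairing`` must have columns ``tumor_sample``, ``normal_sample`` (and
    typically ``patient_id``); every listed sample must be a matrix column.
    Per probe, log2FC is the mean of per-pair differences and p comes from a
    two-sided paired t-test on those differences; adjustment is BH across all
    tested probes.
    """
    required = {"tumor_sample", "normal_sample"}
    if not required.issubset(pairing.columns):
        raise ValueError(f"pairing table must have columns {sorted(required)}")
    tumor = list(pairing["tumor_sample"])
    normal = list(pairing["normal_sample"])
    missing = [s for s in tumor + normal if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples in pairing absent from expression matrix: {missing}")
    n_pairs = len(tumor)
    if n_pairs < 3:
        raise ValueError(f"paired DE requires >= 3 pairs, got {n_pairs}")

    diffs = matrix[tumor].to_numpy(dtype=float) - matrix[normal].to_numpy(dtype=float)
    log2fc = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (sd / math.sqrt(n_pairs))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_pairs - 1)
    # zero variance of differences: certain shift or exact equality
    p[degenerate & (log2fc != 0)] = 0.0
    p[degenerate & (log2fc == 0)] = 1.0
    t[degenerate] = np.nan

    p_adj = bh_adjust(p)
    direction = _assign_direction(log2fc, p_adj, fc_thr, alpha)
    return pd.DataFrame(
        {
            "probe_id": matrix.index,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)


def unpaired_de(
    matrix: pd.DataFrame,
    group_a,
    group_b,
    fc_thr: float = math.log2(1.5),
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Welch two-sample DE (group_a vs group_b, log2FC = mean_a - mean_b).

    ``fc_thr`` is in log2 units; the default log2(1.5) is the |FC| >= 1.5
    linear threshold. Direction uses raw p unless ``adjust`` is set.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    missing = [s for s in group_a + group_b if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples absent from expression matrix: {missing}")

    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)

    p_adj = bh_adjust(p)
    p_ref = p_adj if adjust else p
    direction = _assign_direction(log2fc, p_ref, fc_thr, alpha)
    return pd.DataFrame(
        {
            "probe_id": matrix.index,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)
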