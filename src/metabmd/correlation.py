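"""Spearman correlation of xenobiotic feature levels with gene expression.

For each gene in a xenobiotic-metabolism / oxidative-stress panel, computes
the Spearman rank correlation against every representative xenobiotic
feature, counts features with two-sided p < 0.05, takes the median absolute
correlation across features, and flags genes whose median |rho| reaches the
"strong" cutoff of 0.6.  Genes with no defined or significant correlation
anywhere are still reported (flagged, not dropped).

With small sample counts (n <= 9) the p-value comes from the exact
permutation distribution of the rank correlation; beyond that the standard
t approximation is used (the emulated study has n = 17 shared samples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

STRONG_CUTOFF = 0.6
P_CUTOFF = 0.05
_EXACT_N_MAX = 9


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=16)
def _perm_rank_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)


def _exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for the Spearman statistic."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = _perm_rank_matrix(n)
    # permute the ranks of y over all n! orderings; ties in the observed
    # ranks are preserved by indexing the tied rank vector
    ry_sorted = np.sort(ry)
    perm_ry = ry_sorted[perms.astype(int) - 1]
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c @ rx_c))
    ry_c = perm_ry - perm_ry.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((ry_c * ry_c).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (ry_c @ rx_c) / (denom * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p; exact permutation null for n <= 9."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = _spearman_rho(x, y)
    if not np.isfinite(rho):
        return np.nan, np.nan
    n = x.size
    if n <= _EXACT_N_MAX:
        return rho, _exact_p(x, y, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


@dataclass
class CorrelationSummary:
    """Per-gene summary plus the full rho / p matrices (radar-plot-ready)."""

    summary: pd.DataFrame   # gene, n_significant_features, median_abs_rho, strong, no_correlation
    rho: pd.DataFrame       # genes x features
    p: pd.DataFrame         # genes x features


def correlate(features: pd.DataFrame, genes: pd.DataFrame,
              p_cutoff: float = P_CUTOFF,
              strong_cutoff: float = STRONG_CUTOFF) -> CorrelationSummary:
    """Correlate every gene with every xenobiotic representative feature.

    Both inputs are (rows x samples) tables; they are aligned on their
    shared sample columns (>= 5 required).  Constant vectors give undefined
    rho for that pair, which is recorded as NaN and excluded from the
    per-gene median.
    """
    shared = [s for s in features.columns if s in genes.columns]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")
    F = features[shared]
    G = genes[shared]
    rho = pd.DataFrame(np.nan, index=G.index, columns=F.index)
    pmat = pd.DataFrame(np.nan, index=G.index, columns=F.index)
    for g in G.index:
        gv = G.loc[g].to_numpy(float)
        for f in F.index:
            r, p = spearman_with_p(F.loc[f].to_numpy(float), gv)
            rho.loc[g, f] = r
            pmat.loc[g, f] = p
    n_sig = ((pmat < p_cutoff) & rho.notna()).sum(axis=1)
    med = rho.abs().median(axis=1, skipna=True)
    strong = med >= strong_cutoff
    no_corr = (n_sig == 0) & (med.isna() | (rho.abs().max(axis=1) < 1e-12))
    summary = pd.DataFrame({
        "gene": G.index,
        "n_significant_features": n_sig.to_numpy(),
        "median_abs_rho": med.to_numpy(),
        "strong": strong.to_numpy(),
        "no_correlation": no_corr.to_numpy(),
    }).set_index("gene")
    return CorrelationSummary(summary=summary, rho=rho, p=pmat)
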