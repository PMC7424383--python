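"""Shared statistical primitives.

The hypergeometric upper tail here is the single code path used both for the
shared-miRNA test of ceRNA pairs and for gene-set over-representation, so the
two modules cannot drift apart.
"""
from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: population size (e.g. miRNA universe), K: marked items (miRNAs of the
    lncRNA), n: draws (miRNAs of the mRNA), k: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N} K={K} n={n}")
    if k < 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p via t = r*sqrt((n-2)/(1-r^2)).

    Requires >= 3 paired observations and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson expects two equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError(f"need >=3 samples for correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
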