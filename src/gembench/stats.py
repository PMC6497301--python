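"""Shared statistics: BH adjustment, hypergeometric tails, rank correlation."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom, spearmanr

__all__ = ["bh_adjust", "hypergeom_enrichment", "correlate", "jaccard"]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( n * p_(j) / j ), clipped to 1.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def hypergeom_enrichment(
    hits_in_selection: int,
    selection_size: int,
    hits_in_universe: int,
    universe_size: int,
    tail: str = "right",
) -> float:
    """Exact hypergeometric tail probability.

    Drawing ``selection_size`` items without replacement from a universe
    of ``universe_size`` containing ``hits_in_universe`` marked items,
    the right tail is P[X >= hits_in_selection] (over-representation)
    and the left tail is P[X <= hits_in_selection].
    """
    k, n, K, N = hits_in_selection, selection_size, hits_in_universe, universe_size
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    dist = hypergeom(N, K, n)
    if tail == "right":
        return float(dist.sf(k - 1))
    if tail == "left":
        return float(dist.cdf(k))
    raise ValueError(f"tail must be 'right' or 'left', got {tail!r}")


def correlate(pred: Sequence[float], meas: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (midrank ties) and its p-value."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(meas)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired finite values")
    rho, p = spearmanr(pred[ok], meas[ok])
    return float(rho), float(p)


def jaccard(a, b) -> float:
    """Jaccard index |A&B| / |A|B|; both-empty defined as 1 (with warning)."""
    a, b = set(a), set(b)
    if not a and not b:
        import warnings

        warnings.warn("Jaccard of two empty sets defined as 1")
        return 1.0
    return len(a & b) / len(a | b)
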