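"""Weighted summary statistics shared across the package.

All moments are *population* (not n-1) moments: the concentration-index
machinery is built on cumulative-distribution ranks, which assume
population normalization of the weights.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def _as_weights(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return w


def wmean(x, weights=None) -> float:
    x = np.asarray(x, dtype=float)
    w = _as_weights(weights, len(x))
    return float(np.sum(w * x) / np.sum(w))


def wvar(x, weights=None) -> float:
    """Weighted population variance."""
    x = np.asarray(x, dtype=float)
    w = _as_weights(weights, len(x))
    m = np.sum(w * x) / np.sum(w)
    return float(np.sum(w * (x - m) ** 2) / np.sum(w))


def wcov(x, y, weights=None) -> float:
    """Weighted population covariance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    w = _as_weights(weights, len(x))
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    return float(np.sum(w * (x - mx) * (y - my)) / sw)


def fractional_rank(values, weights=None) -> np.ndarray:
    """Weighted fractional (mid-point CDF) rank in (0, 1).

    Sorting ascending, individual i receives
    ``F_i = (cumulative weight before i + w_i / 2) / total weight``;
    tied values all receive the mid-point rank of their tie group, which
    keeps the weighted mean of the ranks at exactly 0.5.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-d array")
    if np.any(~np.isfinite(v)):
        raise ValueError("values must be finite")
    w = _as_weights(weights, len(v))

    order = np.argsort(v, kind="stable")
    vs, ws = v[order], w[order]
    uniq, inv = np.unique(vs, return_inverse=True)
    gw = np.bincount(inv, weights=ws)
    gcum = np.cumsum(gw)
    gmid = (gcum - gw / 2.0) / gcum[-1]
    out = np.empty(len(v), dtype=float)
    out[order] = gmid[inv]
    return out


def rank_quintile(frank) -> np.ndarray:
    """Quintile label 1-5 from fractional ranks.

    Boundaries sit at cumulative-weight fractions 0.2/0.4/0.6/0.8; a tie
    group lands in the quintile containing its mid-point rank.
    """
    f = np.asarray(frank, dtype=float)
    return np.minimum(np.floor(f * 5.0).astype(int) + 1, 5)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.575 -> 0.58), for report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
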