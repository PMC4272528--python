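"""Circular binary segmentation with permutation-based split acceptance.

Recursively finds the circular arc (i, j] of the current stretch maximizing
|T|, the pooled two-sample t-statistic comparing values inside the arc to
those outside, and accepts the split when its permutation p-value is at most
``alpha``.  Both circular pieces (arc and complement) must contain at least
``min_width`` points.  The permutation stream for the stretch spanning
absolute indices [lo, lo+n) is ``default_rng(SeedSequence(seed,
spawn_key=(lo, n)))`` — a documented convention, so independent
implementations can share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Segment:
    """Half-open index interval with the arithmetic mean of its member values."""

    start: int
    end: int
    mean: float


def _arcs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All arcs (i, j] with min_width <= j-i <= n-min_width, lexicographic order."""
    I, J = [], []
    for i in range(0, n):
        for j in range(i + min_width, n + 1):
            if n - (j - i) >= min_width:
                I.append(i)
                J.append(j)
    return np.asarray(I, dtype=np.int64), np.asarray(J, dtype=np.int64)


def _t_matrix(X: np.ndarray, I: np.ndarray, J: np.ndarray) -> np.ndarray:
    """|T| for every row of X (shape (P, n)) at every arc; returns (P, A)."""
    P, n = X.shape
    S = np.concatenate([np.zeros((P, 1)), np.cumsum(X, axis=1)], axis=1)
    S2 = np.concatenate([np.zeros((P, 1)), np.cumsum(X * X, axis=1)], axis=1)
    tot = S[:, -1:]
    tot2 = S2[:, -1:]
    k = (J - I).astype(float)
    m = n - k
    sum_in = S[:, J] - S[:, I]
    ss_in = S2[:, J] - S2[:, I]
    mean_in = sum_in / k
    mean_out = (tot - sum_in) / m
    d = mean_in - mean_out
    ss_within = (ss_in - sum_in**2 / k) + ((tot2 - ss_in) - (tot - sum_in) ** 2 / m)
    denom = max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss_within / denom) * (1.0 / k + 1.0 / m)
        T = np.abs(d) / np.sqrt(var)
    degenerate = var <= 0
    if degenerate.any():
        T = np.where(degenerate & (np.abs(d) > 0), np.inf, T)
        T = np.where(degenerate & (np.abs(d) == 0), 0.0, T)
    return T


def _best_arc(x: np.ndarray, I: np.ndarray, J: np.ndarray) -> tuple[float, int, int]:
    T = _t_matrix(x[None, :], I, J)[0]
    b = int(np.argmax(T))  # first max: smallest (i, j) lexicographically
    return float(T[b]), int(I[b]), int(J[b])


def _perm_reject(
    x: np.ndarray,
    I: np.ndarray,
    J: np.ndarray,
    tobs: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """True when the permutation p-value of ``tobs`` exceeds ``alpha``.

    The p-value is #{permutation max |T| >= tobs} / n_perm.  The k-th
    permutation rearranges the values by the ranks of ``n`` fresh uniform
    draws (so the stream is a flat sequence of ``n_perm * n`` uniforms and is
    insensitive to chunking).  Exceedances are counted in chunks and counting
    stops as soon as the threshold count floor(alpha * n_perm) is exceeded —
    the accept/reject decision is then identical to evaluating all ``n_perm``
    permutations.
    """
    threshold = int(np.floor(alpha * n_perm + 1e-9))
    n = x.size
    # permutations preserving the arc/complement partition reproduce tobs
    # exactly in exact arithmetic; a small tolerance keeps that tie a tie
    tie_tol = 0.0 if not np.isfinite(tobs) else 1e-9 * max(1.0, abs(tobs))
    max_block = max(1, int(2_000_000 // max(len(I), 1)))
    exceed = 0
    done = 0
    block = min(64, max_block)
    while done < n_perm:
        b = min(block, n_perm - done)
        Xp = x[np.argsort(rng.random((b, n)), axis=1)]
        exceed += int(np.count_nonzero(_t_matrix(Xp, I, J).max(axis=1) >= tobs - tie_tol))
        done += b
        if exceed > threshold:
            return True
        block = min(block * 4, max_block)
    return False


def cbs_segment(
    values,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[Segment]:
    """Segment a position-ordered sequence of (log) ratios.

    Returns segments partitioning ``range(len(values))``; each segment's mean
    is the arithmetic mean of its member values.  Deterministic for a fixed
    seed regardless of recursion order.
    """
    x_all = np.asarray(values, dtype=float)
    if x_all.ndim != 1 or x_all.size == 0:
        raise ValueError("values must be a non-empty 1-d sequence")
    if not np.isfinite(x_all).all():
        raise ValueError("values must be finite")

    change_points: list[int] = []
    stack = [(0, x_all.size)]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * min_width:
            continue
        x = x_all[lo:hi]
        I, J = _arcs(n, min_width)
        tobs, bi, bj = _best_arc(x, I, J)
        if tobs == 0.0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(lo, n)))
        if _perm_reject(x, I, J, tobs, alpha, n_perm, rng):
            continue
        cuts = sorted({c for c in (bi, bj) if 0 < c < n})
        if not cuts:
            continue
        bounds = [0, *cuts, n]
        for a, b in zip(bounds, bounds[1:]):
            stack.append((lo + a, lo + b))
        change_points.extend(lo + c for c in cuts)

    bounds = [0, *sorted(change_points), x_all.size]
    return [Segment(a, b, float(x_all[a:b].mean())) for a, b in zip(bounds, bounds[1:])]


def segment_values(values, **kwargs) -> np.ndarray:
    """Per-position segmented means (each value replaced by its segment mean)."""
    x = np.asarray(values, dtype=float)
    out = np.empty_like(x)
    for seg in cbs_segment(x, **kwargs):
        out[seg.start : seg.end] = seg.mean
    return out
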