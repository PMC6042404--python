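"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately simple and slow: direct numerical
integration, explicit tail summation, exhaustive enumeration — none of it
shares code with the implementation paths it checks.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import special, stats


def beta_diff_cdf(d: float, a1: float, b1: float, a2: float, b2: float,
                  step: float = 1e-3) -> float:
    """P(p2 - p1 <= d) for independent Beta posteriors, by 1-D grid
    integration of f1(p) * F2(p + d) over p (midpoint rule)."""
    p = np.arange(step / 2, 1.0, step)
    f1 = stats.beta.pdf(p, a1, b1) * step
    F2 = stats.beta.cdf(np.clip(p + d, 0.0, 1.0), a2, b2)
    return float(np.sum(f1 * F2))


def beta_diff_quantile(q: float, a1: float, b1: float, a2: float, b2: float,
                       step: float = 1e-3, iters: int = 40) -> float:
    """q-quantile of p2 - p1 by bisection on the grid-integrated CDF."""
    lo, hi = -1.0, 1.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if beta_diff_cdf(mid, a1, b1, a2, b2, step) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cdif_oracle(m1: int, t1: int, m2: int, t2: int, level: float = 0.95,
                prior: Tuple[float, float] = (1.0, 1.0),
                step: float = 1e-3) -> float:
    """Conservative credible-interval bound of p2 - p1 (grid integration)."""
    a1, b1 = m1 + prior[0], t1 - m1 + prior[1]
    a2, b2 = m2 + prior[0], t2 - m2 + prior[1]
    alpha = (1.0 - level) / 2.0
    lo = beta_diff_quantile(alpha, a1, b1, a2, b2, step)
    hi = beta_diff_quantile(1.0 - alpha, a1, b1, a2, b2, step)
    if lo > 0:
        return lo
    if hi < 0:
        return hi
    return 0.0


def poisson_tail(k: int, lam: float, upper: int = 400) -> float:
    """P(X >= k) by explicit pmf summation (iterative term recurrence)."""
    term = math.exp(-lam)  # pmf at 0
    total = term if k == 0 else 0.0
    for x in range(1, upper):
        term *= lam / x
        if x >= k:
            total += term
    return total


def poisson_max_dup(lam: float, cutoff: float) -> int:
    """Smallest k with P(X >= k+1) < cutoff, by tail summation."""
    k = 1
    while poisson_tail(k + 1, lam) >= cutoff:
        k += 1
    return k


def enumerate_dmr_runs(positions: Sequence[int], directions: Sequence[str],
                       merge_window: int, min_run: int) -> List[Tuple[int, int, str, int]]:
    """All maximal qualifying runs of same-direction calls, by checking
    every candidate (i, j) window directly.

    Returns (start_pos, end_pos, direction, n) per run. A window qualifies
    when all members share a direction, every adjacent pair is within
    merge_window, no opposite-direction call lies between its ends, and it
    cannot be extended in either direction.
    """
    n = len(positions)
    out = []
    for i in range(n):
        for j in range(i, n):
            members = list(range(i, j + 1))
            dirs = {directions[k] for k in members}
            if len(dirs) != 1:
                continue
            ok = all(positions[k + 1] - positions[k] <= merge_window
                     for k in members[:-1])
            if not ok:
                continue
            # maximality
            if i > 0 and directions[i - 1] == directions[i] \
                    and positions[i] - positions[i - 1] <= merge_window:
                continue
            if j < n - 1 and directions[j + 1] == directions[j] \
                    and positions[j + 1] - positions[j] <= merge_window:
                continue
            if len(members) >= min_run:
                out.append((positions[i], positions[j], directions[i],
                            len(members)))
    return out


def threshold_scan_segments(pos: np.ndarray, meth: np.ndarray,
                            total: np.ndarray, low_cut: float = 0.3,
                            max_meth: float = 0.10, min_len: int = 1000,
                            max_gap: int = 2000) -> List[Tuple[int, int]]:
    """Simple per-CpG threshold scan: runs of CpGs with ratio <= low_cut
    (gaps <= max_gap), kept if the count-weighted mean is <= max_meth and
    the span is >= min_len."""
    with np.errstate(invalid="ignore"):
        ratio = np.where(total > 0, meth / np.maximum(total, 1), 1.0)
    low = ratio <= low_cut
    out = []
    i = 0
    n = len(pos)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1] and pos[j + 1] - pos[j] <= max_gap:
            j += 1
        span = (int(pos[i]), int(pos[j]) + 2)
        tsum = total[i:j + 1].sum()
        if tsum > 0 and meth[i:j + 1].sum() / tsum <= max_meth \
                and span[1] - span[0] >= min_len:
            out.append(span)
        i = j + 1
    return out


def count_cpgs_in_window(cpg_positions: np.ndarray, lo: int, hi: int) -> int:
    """Position-wise brute-force CpG counter."""
    return int(sum(1 for p in cpg_positions if lo <= p < hi))


def jaccard(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union
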