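"""Independent reference implementations used only for cross-checking.

These deliberately take the slow, literal route — per-shift two-pass NCC,
full 2D exhaustive search over partitions, brute force over every candidate
base tile size — and share no code with the package internals they verify.
"""

from __future__ import annotations

import numpy as np


def ncc_two_pass(A: np.ndarray, B: np.ndarray, radii: tuple[int, int]):
    """Per-shift two-pass NCC map: pass one computes the two means over the
    intersection, pass two the normalized correlation.  Returns (values,
    valid) arrays shaped like the fast map."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    Rv, Ru = radii
    H, W = A.shape
    values = np.zeros((2 * Rv + 1, 2 * Ru + 1))
    valid = np.zeros_like(values, dtype=bool)
    for v in range(-Rv, Rv + 1):
        for u in range(-Ru, Ru + 1):
            a0, a1 = max(0, v), H + min(0, v)
            c0, c1 = max(0, u), W + min(0, u)
            a = A[a0:a1, c0:c1]
            b = B[a0 - v : a1 - v, c0 - u : c1 - u]
            # pass 1: averages
            ma = a.mean()
            mb = b.mean()
            # pass 2: centered products and variances
            da, db = a - ma, b - mb
            va = np.sum(da * da)
            vb = np.sum(db * db)
            if va <= 0 or vb <= 0:
                continue
            values[v + Rv, u + Ru] = np.sum(da * db) / np.sqrt(va * vb)
            valid[v + Rv, u + Ru] = True
    return values, valid


def exhaustive_partition(m: int, n: int, B: int) -> tuple[int, int, int]:
    """Full 2D search over all (p_m, p_n); returns (p_m, p_n, cost) of the
    minimum-cost feasible pair (ties: smaller p_m, then p_n)."""
    best = None
    for p_m in range(1, m // 2 + 1):
        for p_n in range(1, n // 2 + 1):
            if p_m * p_n < B:
                continue
            cost = (p_m - 1) * n + (p_n - 1) * m
            key = (cost, p_m, p_n)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[1], best[2], best[0]


def brute_force_tiling(D: int, w: int, n_levels: int) -> tuple[int, int, int]:
    """Reference (base, k, last) by scanning every b in [ceil(w/2), w]:
    prefer exact divisors (largest b), else maximize the remainder
    (largest b on ties)."""
    scale = 2 ** n_levels
    lo = -(-w // 2)
    exact = [b for b in range(lo, w + 1) if D % (scale * b) == 0]
    if exact:
        b = max(exact)
        return b, D // (scale * b), 0
    b = max(range(lo, w + 1), key=lambda b: (D % (scale * b), b))
    return b, D // (scale * b) + 1, D % (scale * b)
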