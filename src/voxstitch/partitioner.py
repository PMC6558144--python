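"""Dataset-partition optimization for embarrassingly parallel stitching.

Two independent problems are solved here.

**Alignment-step tile-matrix partition.**  Splitting the m x n tile grid
into ``p_m`` row-groups and ``p_n`` column-groups forces border tiles to be
loaded by more than one worker; the I/O overhead is
``(p_m - 1) * n + (p_n - 1) * m`` extra tile loads.  Given a minimum block
count B, we minimize this cost subject to ``p_m * p_n >= B``,
``1 <= p_m <= floor(m/2)``, ``1 <= p_n <= floor(n/2)`` — both by the fast
closed-form candidate points (integer neighbours of the relaxed optimum on
the hyperbola ``p_m * p_n = B``, ``p_m / p_n = m / n``) and by an exact
bounded enumeration.  Each block is extended with one row at the bottom and
one column at the right (where they exist) and carries flags disabling the
alignment computations among tiles of that extension row/column, so every
adjacent-pair alignment in the grid is computed exactly once.

**Fusion-step per-dimension tiling.**  For an output dimension of D voxels,
ideal tile size w and lowest resolution level n, choose a base tile size
``b`` with ``ceil(w/2) <= b <= w``: if some b makes ``2^n * b`` divide D
exactly, take the largest such b; otherwise take the b maximizing
``D mod (2^n * b)``, giving k full sub-intervals of width ``2^n * b`` plus
one final sub-interval of maximal size l'.  Sub-interval boundaries are
then aligned at every resolution 0..n, so independent workers can fuse and
downsample their regions with no information exchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .volume_model import pair_ids


@dataclass(frozen=True)
class GridPartition:
    """A (p_m, p_n) split of an m x n tile matrix."""

    p_m: int
    p_n: int
    m: int
    n: int

    @property
    def cost(self) -> int:
        return alignment_overhead(self.m, self.n, self.p_m, self.p_n)

    def feasible(self, B: int) -> bool:
        return (
            1 <= self.p_m <= max(self.m // 2, 1)
            and 1 <= self.p_n <= max(self.n // 2, 1)
            and self.p_m * self.p_n >= B
        )


@dataclass(frozen=True)
class BlockSpec:
    """A rectangular sub-block of the tile grid assigned to one worker.

    The core is rows [r0, r1) x cols [c0, c1); ``extend_bottom`` /
    ``extend_right`` add row r1 / column c1 to the load set so the block can
    compute its boundary alignments.  The disable flags suppress alignments
    among tiles of the block's last loaded row / column (computed by the
    neighbouring block instead).  When both extensions are present the
    corner tile participates in no enabled pair and is skipped entirely.
    """

    r0: int
    r1: int
    c0: int
    c1: int
    extend_bottom: bool = False
    extend_right: bool = False
    disable_last_row_pairs: bool = False
    disable_last_col_pairs: bool = False

    @property
    def skip_corner(self) -> bool:
        return self.extend_bottom and self.extend_right

    def loaded_rows(self) -> range:
        return range(self.r0, self.r1 + (1 if self.extend_bottom else 0))

    def loaded_cols(self) -> range:
        return range(self.c0, self.c1 + (1 if self.extend_right else 0))

    def load_set(self) -> set[tuple[int, int]]:
        """Grid positions of tiles this block must read."""
        tiles = {(r, c) for r in self.loaded_rows() for c in self.loaded_cols()}
        if self.skip_corner:
            tiles.discard((self.r1, self.c1))
        return tiles

    def computed_pairs(self) -> list[str]:
        """Pair ids this block is responsible for, in canonical order."""
        tiles = self.load_set()
        rows, cols = self.loaded_rows(), self.loaded_cols()
        last_row = rows[-1] if len(rows) else None
        last_col = cols[-1] if len(cols) else None
        ew = [
            f"EW:{r},{c}"
            for r in rows
            for c in cols[:-1]
            if (r, c) in tiles
            and (r, c + 1) in tiles
            and not (self.disable_last_row_pairs and r == last_row)
        ]
        ns = [
            f"NS:{r},{c}"
            for r in rows[:-1]
            for c in cols
            if (r, c) in tiles
            and (r + 1, c) in tiles
            and not (self.disable_last_col_pairs and c == last_col)
        ]
        return ew + ns

    def block_id(self) -> str:
        return f"r{self.r0}-{self.r1}_c{self.c0}-{self.c1}"


class FusionTiling(NamedTuple):
    """Per-dimension fusion decomposition: k sub-intervals of width
    ``2^n_levels * base`` plus (if ``last > 0``) one final sub-interval of
    width ``last``."""

    D: int
    w: int
    n_levels: int
    base: int  # chosen base tile size b
    k: int  # number of sub-intervals (including the last partial one)
    last: int  # size of the final sub-interval, 0 if the split is exact

    @property
    def stride(self) -> int:
        return (1 << self.n_levels) * self.base

    @property
    def degenerate(self) -> bool:
        return self.D < (1 << self.n_levels) * ((self.w + 1) // 2)

    def boundaries(self) -> list[int]:
        """Half-open sub-interval boundaries [0, ..., D]."""
        full = self.k - (1 if self.last > 0 else 0)
        bounds = [i * self.stride for i in range(full + 1)]
        if self.last > 0:
            bounds.append(self.D)
        return bounds


# ---------------------------------------------------------------------------
# Alignment-step partition
# ---------------------------------------------------------------------------


def alignment_overhead(m: int, n: int, p_m: int, p_n: int) -> int:
    """Extra tile loads caused by splitting an m x n grid into p_m x p_n
    blocks: ``(p_m - 1) * n + (p_n - 1) * m``."""
    if m < 1 or n < 1 or p_m < 1 or p_n < 1:
        raise ValueError("all arguments must be >= 1")
    return (p_m - 1) * n + (p_n - 1) * m


def _validate_B(m: int, n: int, B: int) -> None:
    if m < 2 or n < 2:
        raise ValueError("grid partition requires m, n >= 2")
    bmax = (m // 2) * (n // 2)
    if not 1 <= B <= bmax:
        raise ValueError(f"B={B} outside valid range [1, {bmax}] for {m}x{n}")


def _floor_sqrt_frac(num: int, den: int) -> int:
    """floor(sqrt(num/den)) computed exactly."""
    t = math.isqrt(num // den) if num >= den else 0
    while (t + 1) * (t + 1) * den <= num:
        t += 1
    while t * t * den > num:
        t -= 1
    return t


def _ceil_sqrt_frac(num: int, den: int) -> int:
    f = _floor_sqrt_frac(num, den)
    return f if f * f * den == num else f + 1


class CandidateResult(NamedTuple):
    candidates: tuple[GridPartition, ...]  # p, p', p'' (raw, unclamped)
    best: GridPartition


def candidate_points(m: int, n: int, B: int) -> CandidateResult:
    """Closed-form near-optimal partition via the three integer points
    nearest the relaxed optimum.

    ``p = (ceil(sqrt(Bm/n)), floor(sqrt(Bn/m)))``, ``p'`` with floor/ceil
    swapped, and ``p'' = (ceil, ceil)``.  Candidates violating the block
    constraint ``p_m * p_n >= B`` or the range bounds are discarded; of the
    rest, the one with minimal overhead is returned.  If no candidate is
    feasible (possible on strongly elongated grids where ``p''`` exceeds a
    range bound), the result falls back to clamping ``p''`` into range and
    raising the unconstrained coordinate to the minimum restoring
    ``p_m * p_n >= B`` — always feasible since ``B <= floor(m/2) *
    floor(n/2)``.
    """
    _validate_B(m, n, B)
    pm_c = _ceil_sqrt_frac(B * m, n)
    pm_f = _floor_sqrt_frac(B * m, n)
    pn_c = _ceil_sqrt_frac(B * n, m)
    pn_f = _floor_sqrt_frac(B * n, m)
    cands = (
        GridPartition(pm_c, pn_f, m, n),
        GridPartition(pm_f, pn_c, m, n),
        GridPartition(pm_c, pn_c, m, n),
    )
    feasible = [g for g in cands if g.feasible(B)]
    if feasible:
        best = min(feasible, key=lambda g: (g.cost, g.p_m, g.p_n))
    else:
        pm = min(max(pm_c, 1), m // 2)
        pn = min(max(pn_c, 1), n // 2)
        if pm * pn < B:
            pn = -(-B // pm)
            if pn > n // 2:
                pn = n // 2
                pm = -(-B // pn)
        best = GridPartition(pm, pn, m, n)
        assert best.feasible(B)
    return CandidateResult(cands, best)


def optimal_grid_partition(m: int, n: int, B: int) -> GridPartition:
    """Exact minimum-overhead partition by bounded enumeration.

    For each ``p_m`` the cheapest feasible ``p_n`` is ``ceil(B / p_m)``
    (cost is increasing in ``p_n``), so scanning ``p_m`` in
    ``[1, floor(m/2)]`` is exhaustive.  Ties break toward smaller ``p_m``,
    then smaller ``p_n``.
    """
    _validate_B(m, n, B)
    best: GridPartition | None = None
    for p_m in range(1, m // 2 + 1):
        p_n = -(-B // p_m)
        if p_n > n // 2:
            continue
        g = GridPartition(p_m, p_n, m, n)
        if best is None or g.cost < best.cost:
            best = g
    assert best is not None  # B <= (m//2)*(n//2) guarantees feasibility
    return best


def _group_bounds(total: int, groups: int) -> list[int]:
    """Split [0, total) into `groups` contiguous chunks, sizes differing by
    <= 1, the first (total mod groups) chunks one larger."""
    base, extra = divmod(total, groups)
    bounds = [0]
    for i in range(groups):
        bounds.append(bounds[-1] + base + (1 if i < extra else 0))
    return bounds


def make_blocks(m: int, n: int, p_m: int, p_n: int) -> list[BlockSpec]:
    """Row-major list of extended blocks realizing a (p_m, p_n) partition.

    Row-group (and column-group) sizes differ by at most one.  The union of
    the blocks' computed pair sets is exactly the grid adjacency set, with
    no pair claimed twice.
    """
    if not (1 <= p_m <= max(m // 2, 1) and 1 <= p_n <= max(n // 2, 1)):
        raise ValueError(f"infeasible partition ({p_m}, {p_n}) for {m}x{n} grid")
    rb = _group_bounds(m, p_m)
    cb = _group_bounds(n, p_n)
    blocks = []
    for i in range(p_m):
        for j in range(p_n):
            eb = rb[i + 1] < m
            er = cb[j + 1] < n
            blocks.append(
                BlockSpec(
                    r0=rb[i],
                    r1=rb[i + 1],
                    c0=cb[j],
                    c1=cb[j + 1],
                    extend_bottom=eb,
                    extend_right=er,
                    disable_last_row_pairs=eb,
                    disable_last_col_pairs=er,
                )
            )
    return blocks


class AlignmentTask(NamedTuple):
    block: BlockSpec
    substack_range: tuple[int, int]  # half-open substack indices


def plan_alignment_tasks(m: int, n: int, S: int, N: int) -> list[AlignmentTask]:
    """Partition the alignment workload into at least N independent tasks.

    If ``S >= N`` the grid is left whole and only Z is split: the S
    sub-stacks are divided into N contiguous near-equal index ranges.
    Otherwise the grid is split into at least ``B = ceil(N / S)`` blocks by
    :func:`optimal_grid_partition` and every block is crossed with each of
    the S single-sub-stack ranges.
    """
    if S < 1 or N < 1:
        raise ValueError("S and N must be >= 1")
    whole = BlockSpec(0, m, 0, n)
    if S >= N:
        bounds = _group_bounds(S, N)
        return [
            AlignmentTask(whole, (bounds[i], bounds[i + 1]))
            for i in range(N)
            if bounds[i + 1] > bounds[i]
        ]
    B = -(-N // S)
    bmax = (max(m, 2) // 2) * (max(n, 2) // 2)
    if m < 2 or n < 2 or bmax < 2:
        # Degenerate grid: never partition a single-row/column axis.
        blocks = [whole]
    else:
        part = optimal_grid_partition(m, n, min(B, bmax))
        blocks = make_blocks(m, n, part.p_m, part.p_n)
    return [AlignmentTask(b, (s, s + 1)) for b in blocks for s in range(S)]


# ---------------------------------------------------------------------------
# Fusion-step tiling
# ---------------------------------------------------------------------------


def fusion_tiling(D: int, w: int, n_levels: int) -> FusionTiling:
    """Choose the per-dimension base tile size and sub-interval layout.

    Prefers an exact split (``D mod 2^n * b == 0``, largest such b);
    otherwise maximizes the final sub-interval ``D mod 2^n * b`` (ties to
    the largest b).  When ``D < 2^n * ceil(w/2)`` the general rule
    degenerates gracefully to a single sub-interval of size D with
    ``b = w``.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if w < 2:
        raise ValueError("w must be >= 2")
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    scale = 1 << n_levels
    lo = (w + 1) // 2
    best_b, best_rem = None, -1
    for b in range(lo, w + 1):
        rem = D % (scale * b)
        if rem == 0:
            best_b, best_rem = b, 0  # exact; later (larger) b wins
        elif best_rem != 0 and rem >= best_rem:
            best_b, best_rem = b, rem
    b = best_b
    if best_rem == 0:
        return FusionTiling(D, w, n_levels, b, D // (scale * b), 0)
    return FusionTiling(D, w, n_levels, b, D // (scale * b) + 1, best_rem)


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # ((z0,z1),(y0,y1),(x0,x1))


def fusion_partition(
    dims: tuple[int, int, int],
    tile_sizes: tuple[int, int, int],
    n_levels: int,
    N: int,
    z_only: bool = False,
) -> list[Box]:
    """Partition the fused volume into >= N independent contiguous regions.

    Regions are groups of whole per-dimension sub-intervals (so every task
    is aligned for multiresolution generation) and split along Z first;
    Y and X splitting engages only when Z alone cannot yield N regions.
    With ``z_only`` (slice-series output, where concurrent writers must own
    whole slices) splitting never leaves the Z axis, so fewer than N
    regions may result.  Regions tile the volume exactly.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    tz, ty, tx = (fusion_tiling(d, w, n_levels) for d, w in zip(dims, tile_sizes))
    zb, yb, xb = tz.boundaries(), ty.boundaries(), tx.boundaries()
    kz, ky, kx = len(zb) - 1, len(yb) - 1, len(xb) - 1

    def grouped(bounds: list[int], groups: int) -> list[tuple[int, int]]:
        k = len(bounds) - 1
        groups = min(groups, k)
        idx = _group_bounds(k, groups)
        return [(bounds[idx[i]], bounds[idx[i + 1]]) for i in range(groups)]

    if kz >= N or z_only:
        z_parts = grouped(zb, N)
        return [(zp, (0, dims[1]), (0, dims[2])) for zp in z_parts]

    per_z = -(-N // kz)
    if ky >= per_z:
        y_parts = grouped(yb, per_z)
        return [
            ((zb[i], zb[i + 1]), yp, (0, dims[2]))
            for i in range(kz)
            for yp in y_parts
        ]
    per_y = -(-per_z // ky)
    x_parts = grouped(xb, per_y)
    return [
        ((zb[i], zb[i + 1]), (yb[j], yb[j + 1]), xp)
        for i in range(kz)
        for j in range(ky)
        for xp in x_parts
    ]


def coverage_check(m: int, n: int, blocks: list[BlockSpec]) -> None:
    """Assert the blocks' computed pairs exactly tile the adjacency set."""
    claimed: list[str] = []
    for b in blocks:
        claimed.extend(b.computed_pairs())
    expected = pair_ids(m, n)
    if sorted(claimed) != sorted(expected):
        dup = {p for p in claimed if claimed.count(p) > 1}
        missing = set(expected) - set(claimed)
        raise AssertionError(f"pair coverage broken: duplicates={dup}, missing={missing}")
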