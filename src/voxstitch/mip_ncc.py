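"""Pairwise tile alignment by maximum-intensity-projection NCC.

For each adjacent tile pair, the nominal overlap region of both tiles is
extracted (per Z sub-stack), projected along each of the three axes, and
every homologous MIP pair is compared by normalized cross-correlation over
a grid of integer shifts (the search area).  The NCC peak of each map gives
two displacement components; each axis appears in exactly two maps and
takes its value from the map with the higher peak, the peak score serving
as the per-axis reliability.

NCC of two equally shaped images A and B at shift (v, u) is computed over
the intersection of A and B-translated-by-(v, u), with means and standard
deviations recomputed over that intersection; values lie in [-1, 1] and are
invariant to linear intensity rescaling of either image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partitioner import BlockSpec
from .volume_model import (
    Displacement,
    ProjectDescriptor,
    VoxelBlock,
    pair_ids,
    pair_tiles,
    parse_pair_id,
    read_tile_region,
)

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


class AllInvalidMapError(RuntimeError):
    """Every entry of an NCC map was degenerate (zero variance)."""


@dataclass
class NCCMap:
    """NCC scores over the shift grid [-Rv, Rv] x [-Ru, Ru].

    ``values[v + Rv, u + Ru]`` is the NCC at shift (v, u); the center entry
    is the zero-shift correlation.  ``valid_mask`` is False where either
    image had zero variance on the intersection (score forced to 0).
    """

    values: np.ndarray
    radii: tuple[int, int]
    valid_mask: np.ndarray


def compute_mip(block: VoxelBlock | np.ndarray, axis: str | int) -> np.ndarray:
    """Maximum intensity projection along z, y or x, as float64."""
    data = block.data if isinstance(block, VoxelBlock) else np.asarray(block)
    if data.size == 0:
        raise ValueError("cannot project an empty block")
    ax = _AXIS_INDEX[axis] if isinstance(axis, str) else int(axis)
    return data.max(axis=ax).astype(np.float64)


def ncc_map(A: np.ndarray, B: np.ndarray, radii: tuple[int, int]) -> NCCMap:
    """NCC of A against B over all integer shifts within ``radii``.

    Shift (v, u) compares ``A[i, j]`` with ``B[i - v, j - u]`` on their
    index intersection, so if B was cut from the same parent as A but
    displaced by (v0, u0), the map peaks at (v0, u0).
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError(f"images must be 2D and equally shaped, got {A.shape} vs {B.shape}")
    Rv, Ru = (int(r) for r in radii)
    if Rv < 0 or Ru < 0:
        raise ValueError("radii must be non-negative")
    if A.shape[0] <= Rv or A.shape[1] <= Ru:
        raise ValueError(f"radii {radii} too large for image shape {A.shape}")

    H, W = A.shape
    values = np.zeros((2 * Rv + 1, 2 * Ru + 1))
    valid = np.zeros_like(values, dtype=bool)
    for v in range(-Rv, Rv + 1):
        a0, a1 = max(0, v), H + min(0, v)
        b0, b1 = a0 - v, a1 - v
        for u in range(-Ru, Ru + 1):
            ca0, ca1 = max(0, u), W + min(0, u)
            a = A[a0:a1, ca0:ca1]
            b = B[b0:b1, ca0 - u : ca1 - u]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            af, bf = a.ravel(), b.ravel()
            nvox = af.size
            sa, sb = af.sum(), bf.sum()
            va = af @ af - sa * sa / nvox
            vb = bf @ bf - sb * sb / nvox
            cov = af @ bf - sa * sb / nvox
            denom = np.sqrt(va * vb)
            if denom <= 0:
                continue
            values[v + Rv, u + Ru] = min(1.0, max(-1.0, cov / denom))
            valid[v + Rv, u + Ru] = True
    return NCCMap(values=values, radii=(Rv, Ru), valid_mask=valid)


def peak(nmap: NCCMap) -> tuple[tuple[int, int], float]:
    """Argmax over valid entries; ties break toward the smallest shift
    magnitude, then lexicographically on (v, u)."""
    if not nmap.valid_mask.any():
        raise AllInvalidMapError("no valid NCC entries")
    Rv, Ru = nmap.radii
    best = None
    it = np.argwhere(nmap.valid_mask)
    for iv, iu in it:
        v, u = int(iv) - Rv, int(iu) - Ru
        score = nmap.values[iv, iu]
        key = (-score, v * v + u * u, v, u)
        if best is None or key < best[0]:
            best = (key, (v, u), score)
    return best[1], best[2]


def substack_intervals(sz: int, S: int) -> list[tuple[int, int]]:
    """S contiguous near-equal Z ranges; the first (sz mod S) are one deeper."""
    if not 1 <= S <= sz:
        raise ValueError(f"substack count {S} invalid for depth {sz}")
    base, extra = divmod(sz, S)
    bounds = [0]
    for i in range(S):
        bounds.append(bounds[-1] + base + (1 if i < extra else 0))
    return [(bounds[i], bounds[i + 1]) for i in range(S)]


def _overlap_ranges(project: ProjectDescriptor, pair_id: str):
    """Per-tile (y, x) ranges of the nominal overlap region of a pair."""
    grid = project.grid
    sz, sy, sx = grid.tile_shape
    oy, ox = grid.nominal_overlap
    kind, r, c = parse_pair_id(pair_id)
    if kind == "EW":
        a = ((0, sy), (sx - ox, sx))
        b = ((0, sy), (0, ox))
        tiles = (grid.tile(r, c), grid.tile(r, c + 1))
    else:
        a = ((sy - oy, sy), (0, sx))
        b = ((0, oy), (0, sx))
        tiles = (grid.tile(r, c), grid.tile(r + 1, c))
    return tiles, a, b


def _round6(x: float) -> float:
    return round(max(0.0, min(1.0, x)), 6)


def align_pair(
    project: ProjectDescriptor,
    pair_id: str,
    substack_range: tuple[int, int] | None = None,
    radii: tuple[int, int, int] = (4, 4, 4),
) -> list[Displacement]:
    """Displacements (one per sub-stack in range) for one adjacent pair.

    Three MIP pairs are correlated per sub-stack: along z (a (y, x) map),
    along y ((z, x)) and along x ((z, y)).  Each displacement axis appears
    in two maps and is taken, together with its reliability, from the map
    with the higher peak score (ties prefer the z-, then y-, then x-
    projection).  If every map fails (zero variance throughout), the
    nominal alignment is kept: zero offset, reliability 0.
    """
    grid = project.grid
    sz = grid.tile_shape[0]
    Rz, Ry, Rx = (int(r) for r in radii)
    S = project.substack_count
    intervals = substack_intervals(sz, S)
    s0, s1 = substack_range if substack_range is not None else (0, S)
    if not 0 <= s0 < s1 <= S:
        raise ValueError(f"substack range {substack_range} invalid for S={S}")

    (tile_a, tile_b), rng_a, rng_b = _overlap_ranges(project, pair_id)
    ov_y = rng_a[0][1] - rng_a[0][0]
    ov_x = rng_a[1][1] - rng_a[1][0]
    for extent, R, name in ((ov_y, Ry, "y"), (ov_x, Rx, "x")):
        if extent <= 2 * R:
            raise ValueError(
                f"degenerate overlap: {name} extent {extent} <= 2*radius {2 * R}"
            )

    out: list[Displacement] = []
    for s in range(s0, s1):
        z0, z1 = intervals[s]
        if z1 - z0 <= 2 * Rz:
            raise ValueError(
                f"degenerate sub-stack: depth {z1 - z0} <= 2*radius {2 * Rz}"
            )
        a = read_tile_region(tile_a, (z0, z1), rng_a[0], rng_a[1]).data
        b = read_tile_region(tile_b, (z0, z1), rng_b[0], rng_b[1]).data

        maps = {}
        for proj_axis, map_radii in (("z", (Ry, Rx)), ("y", (Rz, Rx)), ("x", (Rz, Ry))):
            nmap = ncc_map(compute_mip(a, proj_axis), compute_mip(b, proj_axis), map_radii)
            try:
                shift, score = peak(nmap)
            except AllInvalidMapError:
                continue
            maps[proj_axis] = (shift, score)

        # map axes: z-projection -> (dy, dx); y -> (dz, dx); x -> (dz, dy)
        axis_sources = {
            "z": (("y", 0), ("x", 0)),
            "y": (("z", 0), ("x", 1)),
            "x": (("z", 1), ("y", 1)),
        }
        offset, reliab = [0, 0, 0], [0.0, 0.0, 0.0]
        for i, axis in enumerate(("z", "y", "x")):
            best = None
            for proj_axis, comp in axis_sources[axis]:
                if proj_axis not in maps:
                    continue
                shift, score = maps[proj_axis]
                if best is None or score > best[1]:
                    best = (shift[comp], score)
            if best is not None:
                offset[i], reliab[i] = int(best[0]), _round6(best[1])
        out.append(
            Displacement(
                pair_id=pair_id,
                substack=s,
                offset=tuple(offset),
                reliability=tuple(reliab),
            )
        )
    return out


def align_block(
    project: ProjectDescriptor,
    block: BlockSpec,
    substack_range: tuple[int, int] | None = None,
    radii: tuple[int, int, int] = (4, 4, 4),
) -> dict[str, list[Displacement]]:
    """Alignment fragment for one partition block: exactly the pairs its
    flags mandate, reading no tile outside the block's load set."""
    grid = project.grid
    load = block.load_set()
    fragment: dict[str, list[Displacement]] = {}
    all_ids = set(pair_ids(grid.m, grid.n))
    for pid in block.computed_pairs():
        if pid not in all_ids:
            raise ValueError(f"block claims pair {pid} outside the grid")
        a, b = pair_tiles(pid)
        assert a in load and b in load, f"pair {pid} touches a tile outside the load set"
        fragment[pid] = align_pair(project, pid, substack_range, radii)
    return fragment
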