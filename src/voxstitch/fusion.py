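"""Seamless fusion of placed tiles into a multiresolution stitched image.

Each output voxel blends the placed tiles covering it, either by a
linear-ramp feather (per-tile weight rising linearly across the overlap
width on the y and x axes, weights normalized to sum 1) or by
nearest-center selection.  Lower resolutions are derived by repeated
2 x 2 x 2 mean halving.  The volume is cut into regions aligned to the
per-dimension fusion tiling so that independent tasks can each fuse their
region, derive every resolution level locally, and write disjoint files —
producing output byte-identical to a sequential run.

Two on-disk layouts are supported: ``slice_series`` (one 2D TIFF per z
plane per level; parallelizable along Z only) and ``tiled3d`` (a directory
grid of small multipage TIFF blocks, parallelizable along any axis).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import tifffile

from .partitioner import Box, FusionTiling, fusion_partition, fusion_tiling
from .volume_model import ProjectDescriptor, VoxelBlock, read_tile_region

FORMATS = ("slice_series", "tiled3d")
BLENDINGS = ("nearest", "linear_ramp")


@dataclass(frozen=True)
class FusedVolumeSpec:
    """Geometry and output parameters of one fusion run."""

    extents: tuple[int, int, int]  # (Dz, Dy, Dx), bounding box of placed tiles
    origin: tuple[int, int, int]  # placed-frame coordinate of fused voxel (0,0,0)
    n_levels: int
    tilings: tuple[FusionTiling, FusionTiling, FusionTiling]
    out_format: str = "slice_series"
    blending: str = "linear_ramp"
    dtype: str = "uint8"

    def level_dims(self, r: int) -> tuple[int, int, int]:
        return tuple(d >> r for d in self.extents)


def make_fusion_spec(
    project: ProjectDescriptor,
    tile_size: tuple[int, int, int] = (64, 64, 64),
    n_levels: int = 0,
    out_format: str = "slice_series",
    blending: str = "linear_ramp",
) -> FusedVolumeSpec:
    """Derive the fused-volume geometry from a placed project."""
    if project.stage != "placed":
        raise ValueError("fusion requires a placed project")
    if out_format not in FORMATS:
        raise ValueError(f"unknown output format {out_format!r}")
    if blending not in BLENDINGS:
        raise ValueError(f"unknown blending {blending!r}")
    pos = project.absolute_positions
    lo = pos.reshape(-1, 3).min(axis=0)
    hi = pos.reshape(-1, 3).max(axis=0) + np.asarray(project.grid.tile_shape)
    extents = tuple(int(v) for v in (hi - lo))
    tilings = tuple(
        fusion_tiling(d, w, n_levels) for d, w in zip(extents, tile_size)
    )
    t00 = project.grid.tile(0, 0)
    probe = read_tile_region(t00, (0, 1), (0, 1), (0, 1))
    return FusedVolumeSpec(
        extents=extents,
        origin=tuple(int(v) for v in lo),
        n_levels=n_levels,
        tilings=tilings,
        out_format=out_format,
        blending=blending,
        dtype=str(probe.dtype),
    )


def _ramp_weights_1d(s: int, o: int, low: bool, high: bool) -> np.ndarray:
    """Feather profile along one tile axis: 0 at the first voxel of a
    neighboured low edge, rising by 1/o per voxel; symmetric profile
    ``(s - l) / o`` on a neighboured high edge (so the two tiles' weights
    sum to one across a nominally placed overlap)."""
    l = np.arange(s, dtype=np.float64)
    w = np.ones(s)
    if low:
        w = np.minimum(w, l / o)
    if high:
        w = np.minimum(w, (s - l) / o)
    return w


def _round_to(data: np.ndarray, dtype: np.dtype) -> np.ndarray:
    info = np.iinfo(dtype)
    return np.clip(np.floor(data + 0.5), info.min, info.max).astype(dtype)


def fuse_region(
    project: ProjectDescriptor,
    region: Box,
    blending: str = "linear_ramp",
    origin: tuple[int, int, int] | None = None,
    stats: dict | None = None,
) -> VoxelBlock:
    """Fuse one level-0 region of the stitched volume.

    ``region`` is given in the fused frame (origin at the placed bounding
    box minimum, which is recomputed unless passed explicitly).  Voxels
    covered by no tile (gaps opened by extreme corrections) are zero and
    counted in ``stats['gap_voxels']``.  Each contributing tile region is
    read exactly once.
    """
    if project.stage != "placed":
        raise ValueError("fusion requires a placed project")
    if blending not in BLENDINGS:
        raise ValueError(f"unknown blending {blending!r}")
    grid = project.grid
    sz, sy, sx = grid.tile_shape
    oy, ox = grid.nominal_overlap
    pos = project.absolute_positions
    if origin is None:
        origin = tuple(int(v) for v in pos.reshape(-1, 3).min(axis=0))
    (z0, z1), (y0, y1), (x0, x1) = region
    shape = (z1 - z0, y1 - y0, x1 - x0)
    if any(s <= 0 for s in shape):
        raise ValueError(f"empty region {region}")

    probe = read_tile_region(grid.tile(0, 0), (0, 1), (0, 1), (0, 1))
    dtype = probe.dtype

    num = np.zeros(shape)
    den = np.zeros(shape)
    cnt = np.zeros(shape, dtype=np.int32)
    valsum = np.zeros(shape)
    if blending == "nearest":
        best_dist = np.full(shape, np.inf)
        nearest_val = np.zeros(shape)

    for r in range(grid.m):
        for c in range(grid.n):
            q = pos[r, c] - np.asarray(origin)  # tile origin in fused frame
            iz0, iz1 = max(z0, q[0]), min(z1, q[0] + sz)
            iy0, iy1 = max(y0, q[1]), min(y1, q[1] + sy)
            ix0, ix1 = max(x0, q[2]), min(x1, q[2] + sx)
            if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
                continue
            block = read_tile_region(
                grid.tile(r, c),
                (iz0 - q[0], iz1 - q[0]),
                (iy0 - q[1], iy1 - q[1]),
                (ix0 - q[2], ix1 - q[2]),
            ).data.astype(np.float64)
            sel = (
                slice(iz0 - z0, iz1 - z0),
                slice(iy0 - y0, iy1 - y0),
                slice(ix0 - x0, ix1 - x0),
            )
            cnt[sel] += 1
            valsum[sel] += block
            if blending == "linear_ramp":
                wy = _ramp_weights_1d(sy, oy, low=r > 0, high=r < grid.m - 1)
                wx = _ramp_weights_1d(sx, ox, low=c > 0, high=c < grid.n - 1)
                w = (
                    wy[iy0 - q[1] : iy1 - q[1], None]
                    * wx[None, ix0 - q[2] : ix1 - q[2]]
                )[None, :, :]
                num[sel] += w * block
                den[sel] += w
            else:
                center = q + (np.asarray(grid.tile_shape) - 1) / 2.0
                dz = (np.arange(iz0, iz1) - center[0]) ** 2
                dy = (np.arange(iy0, iy1) - center[1]) ** 2
                dx = (np.arange(ix0, ix1) - center[2]) ** 2
                dist = dz[:, None, None] + dy[None, :, None] + dx[None, None, :]
                closer = dist < best_dist[sel]
                best_dist[sel] = np.where(closer, dist, best_dist[sel])
                nearest_val[sel] = np.where(closer, block, nearest_val[sel])

    if blending == "linear_ramp":
        out = np.zeros(shape)
        weighted = den > 0
        out[weighted] = num[weighted] / den[weighted]
        # Zero total feather weight but covered: plain mean of the covers.
        fallback = (~weighted) & (cnt > 0)
        out[fallback] = valsum[fallback] / cnt[fallback]
    else:
        out = nearest_val

    gaps = int((cnt == 0).sum())
    if stats is not None:
        stats["gap_voxels"] = stats.get("gap_voxels", 0) + gaps
    return VoxelBlock(_round_to(out, dtype), origin=(z0, y0, x0))


def downsample_halve(block: VoxelBlock) -> VoxelBlock:
    """Halve each axis by 2 x 2 x 2 block averaging (round half-up).

    Odd trailing voxels are truncated; an axis of size 1 passes through
    unchanged so degenerate thin volumes keep their extent.
    """
    data = block.data
    if data.size == 0:
        raise ValueError("cannot downsample an empty block")
    acc = data.astype(np.float64)
    for ax in range(3):
        s = acc.shape[ax]
        if s < 2:
            continue
        idx = [slice(None)] * 3
        idx[ax] = slice(0, (s // 2) * 2)
        acc = acc[tuple(idx)]
        shape = list(acc.shape)
        shape[ax : ax + 1] = [s // 2, 2]
        acc = acc.reshape(shape).mean(axis=ax + 1)
    return VoxelBlock(
        _round_to(acc, data.dtype),
        origin=tuple(o // 2 if sh >= 2 else o for o, sh in zip(block.origin, block.shape)),
    )


# ---------------------------------------------------------------------------
# Task-level output writing
# ---------------------------------------------------------------------------


def _check_alignment(region: Box, spec: FusedVolumeSpec) -> None:
    for (lo, hi), tiling, D in zip(region, spec.tilings, spec.extents):
        bounds = set(tiling.boundaries())
        if lo not in bounds or hi not in bounds:
            raise ValueError(
                f"region bound [{lo}, {hi}) not aligned to fusion sub-intervals "
                f"{sorted(bounds)}"
            )


def _chunk_starts(lo: int, hi: int, size: int) -> list[int]:
    """Chunk starts anchored at global multiples of `size` within [lo, hi)."""
    first = (lo // size) * size
    if first < lo:
        first += size
    assert first == lo, "task bound not chunk-aligned"
    return list(range(lo, hi, size))


def fuse_task(
    project: ProjectDescriptor,
    region: Box,
    spec: FusedVolumeSpec,
    out_dir: str,
    stats: dict | None = None,
) -> int:
    """Fuse one aligned region and write its share of every level 0..n.

    Contributing tiles are read once (for the level-0 fusion); each lower
    level is derived locally by halving.  Because region bounds are
    multiples of ``2^n_levels * base`` per dimension, no output file is
    ever written by two tasks.  Returns the gap-voxel count of the region.
    """
    _check_alignment(region, spec)
    local_stats: dict = {}
    block = fuse_region(project, region, spec.blending, origin=spec.origin, stats=local_stats)
    for r in range(spec.n_levels + 1):
        _write_level_share(block, r, spec, out_dir)
        if r < spec.n_levels:
            block = downsample_halve(block)
    if stats is not None:
        stats["gap_voxels"] = stats.get("gap_voxels", 0) + local_stats.get("gap_voxels", 0)
    return local_stats.get("gap_voxels", 0)


def _write_level_share(block: VoxelBlock, r: int, spec: FusedVolumeSpec, out_dir: str) -> None:
    dims_r = spec.level_dims(r)
    zl, yl, xl = block.origin
    data = block.data
    level_dir = os.path.join(out_dir, f"level_{r}")
    if spec.out_format == "slice_series":
        if data.shape[1] != dims_r[1] or data.shape[2] != dims_r[2]:
            raise ValueError(
                "slice_series output requires tasks owning whole planes "
                "(Z-only partitioning)"
            )
        os.makedirs(level_dir, exist_ok=True)
        for i in range(data.shape[0]):
            tifffile.imwrite(
                os.path.join(level_dir, f"{zl + i:06d}.tif"),
                data[i],
                photometric="minisblack",
            )
        return

    # tiled3d: one multipage TIFF per (y, x) block of `base` voxels per Z
    # sub-interval, origins named in level-r voxels.
    tz, ty, tx = spec.tilings
    z_bounds = [b >> r for b in tz.boundaries()]
    by, bx = ty.base, tx.base
    for zi in range(len(z_bounds) - 1):
        za, zb = z_bounds[zi], z_bounds[zi + 1]
        if za < zl or zb > zl + data.shape[0]:
            continue
        for ya in _chunk_starts(yl, yl + data.shape[1], by):
            yb = min(ya + by, dims_r[1])
            for xa in _chunk_starts(xl, xl + data.shape[2], bx):
                xb = min(xa + bx, dims_r[2])
                sub = data[za - zl : zb - zl, ya - yl : yb - yl, xa - xl : xb - xl]
                d = os.path.join(level_dir, f"{ya:06d}", f"{ya:06d}_{xa:06d}")
                os.makedirs(d, exist_ok=True)
                tifffile.imwrite(
                    os.path.join(d, f"{ya:06d}_{xa:06d}_{za:06d}.tif"),
                    sub,
                    photometric="minisblack",
                )


def plan_fusion_tasks(spec: FusedVolumeSpec, N: int) -> list[Box]:
    """Region list for N-way parallel fusion (Z-only for slice series)."""
    tile_sizes = tuple(t.w for t in spec.tilings)
    return fusion_partition(
        spec.extents,
        tile_sizes,
        spec.n_levels,
        N,
        z_only=spec.out_format == "slice_series",
    )


def fuse_dataset(
    project: ProjectDescriptor,
    spec: FusedVolumeSpec,
    out_dir: str,
    n_tasks: int = 1,
    workers: int = 1,
) -> dict:
    """Fuse the whole volume: plan regions, dispatch, write the manifest.

    The result is independent of the worker count and of task scheduling
    order; with ``workers=1`` the tasks run serially in plan order.
    """
    from .driver import TaskPlan, run_parallel

    regions = plan_fusion_tasks(spec, n_tasks)
    os.makedirs(out_dir, exist_ok=True)
    plan = TaskPlan(
        tasks=[
            {"kind": "fusion", "task_id": f"fuse_{i:03d}", "region": region}
            for i, region in enumerate(regions)
        ],
        P=workers,
    )
    results = run_parallel(plan, _fusion_worker, context={"project": project, "spec": spec, "out_dir": out_dir})
    manifest = {
        "extents": list(spec.extents),
        "origin": list(spec.origin),
        "n_levels": spec.n_levels,
        "tilings": [
            {"D": t.D, "w": t.w, "base": t.base, "k": t.k, "last": t.last}
            for t in spec.tilings
        ],
        "format": spec.out_format,
        "blending": spec.blending,
        "dtype": spec.dtype,
        "n_tasks": len(regions),
        "gap_voxels": int(sum(results)),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _fusion_worker(task: dict, context: dict) -> int:
    return fuse_task(
        context["project"], task["region"], context["spec"], context["out_dir"]
    )
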