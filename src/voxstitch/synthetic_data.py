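"""Synthetic tiled datasets with known ground truth.

A textured phantom volume (Gaussian blobs over a smooth random background)
is cut into an overlapping grid of tiles.  Each tile is displaced from its
nominal grid position by a known integer jitter, emulating stage positioning
error, and optionally corrupted with additive Gaussian noise.  The recorded
jitters make alignment recovery an exact pass/fail check: the true pairwise
displacement of two adjacent tiles is simply the difference of their jitters.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_model import (
    ProjectDescriptor,
    TileGrid,
    TileRef,
    VoxelBlock,
    save_project,
    write_tile,
)

# Default texture parameters, chosen to emulate sparsely labelled tissue on
# a speckled autofluorescence background.  The fine-grained background field
# keeps the intensity non-constant in every window (NCC is well defined
# everywhere) and, together with small blob widths, gives the sharp
# correlation autocorrelation that makes integer peak localization robust;
# the background level leaves ~3 sigma of headroom above zero at the
# reference noise level (amplitude / 5) so additive noise is not censored
# by the unsigned dtype.
BACKGROUND = 100.0
BLOB_AMPLITUDE = 150.0
BLOB_WIDTH_RANGE = (1.0, 3.5)  # per-axis Gaussian sigma, voxels
TEXTURE_AMPLITUDE = 20.0
TEXTURE_SCALE = 1.0  # smoothing sigma (voxels) of the background field


@dataclass
class GroundTruth:
    """Known per-tile jitter and generator parameters of a synthetic dataset."""

    true_offsets: np.ndarray  # (m, n, 3) int, (dz, dy, dx) per tile
    phantom_shape: tuple[int, int, int]
    params: dict = field(default_factory=dict)

    def pair_delta(self, pair_id: str) -> tuple[int, int, int]:
        """True displacement correction for an adjacent pair: jitter(B) - jitter(A)."""
        from .volume_model import pair_tiles

        (ra, ca), (rb, cb) = pair_tiles(pair_id)
        d = self.true_offsets[rb, cb] - self.true_offsets[ra, ca]
        return tuple(int(v) for v in d)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "offsets": self.true_offsets.tolist(),
                    "phantom_shape": list(self.phantom_shape),
                    "params": self.params,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path: str) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            true_offsets=np.asarray(obj["offsets"], dtype=np.int64),
            phantom_shape=tuple(obj["phantom_shape"]),
            params=obj.get("params", {}),
        )


def generate_phantom(
    shape: tuple[int, int, int],
    n_blobs: int,
    seed: int,
    dtype=np.uint16,
    amplitude: float = BLOB_AMPLITUDE,
) -> VoxelBlock:
    """Deterministic textured phantom: anisotropic Gaussian blobs on a
    fine-grained random background.

    The background field keeps the intensity non-constant in every window
    (so NCC never degenerates), while blobs of constant peak ``amplitude``
    — the signal level in signal-to-noise terms — and random position and
    width provide the localized structure for sharp correlation peaks.
    """
    if any(s <= 0 for s in shape):
        raise ValueError(f"shape must be positive, got {shape}")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    Z, Y, X = shape

    field_ = rng.standard_normal(shape)
    field_ = gaussian_filter(field_, TEXTURE_SCALE)
    field_ *= TEXTURE_AMPLITUDE / max(field_.std(), 1e-12)
    vol = BACKGROUND + np.abs(field_)

    zz = np.arange(Z, dtype=np.float64)
    yy = np.arange(Y, dtype=np.float64)
    xx = np.arange(X, dtype=np.float64)
    for _ in range(n_blobs):
        cz, cy, cx = rng.uniform(0, Z), rng.uniform(0, Y), rng.uniform(0, X)
        sz_, sy_, sx_ = rng.uniform(*BLOB_WIDTH_RANGE, size=3)
        amp = amplitude
        gz = np.exp(-0.5 * ((zz - cz) / sz_) ** 2)
        gy = np.exp(-0.5 * ((yy - cy) / sy_) ** 2)
        gx = np.exp(-0.5 * ((xx - cx) / sx_) ** 2)
        vol += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    info = np.iinfo(dtype)
    data = np.clip(np.floor(vol + 0.5), info.min, info.max).astype(dtype)
    return VoxelBlock(data)


def required_phantom_shape(m, n, tile_shape, overlap, jitter_bound):
    """Minimum phantom shape containing every jittered tile window."""
    sz, sy, sx = tile_shape
    oy, ox = overlap
    J = jitter_bound
    return (
        sz + 2 * J,
        (m - 1) * (sy - oy) + sy + 2 * J,
        (n - 1) * (sx - ox) + sx + 2 * J,
    )


def _draw_jitter(rng: np.random.Generator, m: int, n: int, J: int) -> np.ndarray:
    """Per-tile integer jitter, uniform on [-J, J] per axis, conditioned so
    adjacent tiles differ by at most J per axis.

    Stage positioning error accrues per move, so the *relative* error of two
    adjacent tiles — the quantity alignment has to recover — is what the
    bound must control; an alignment search radius > J then always contains
    the true pairwise displacement.  Tiles are drawn row-major, each
    component uniform on the (never empty) intersection of [-J, J] with the
    +/-J bands around the west and north neighbours.  The anchor tile (0, 0)
    is fixed at zero.
    """
    jitter = np.zeros((m, n, 3), dtype=np.int64)
    for r in range(m):
        for c in range(n):
            if r == 0 and c == 0:
                continue
            for ax in range(3):
                lo, hi = -J, J
                if c > 0:
                    w = jitter[r, c - 1, ax]
                    lo, hi = max(lo, w - J), min(hi, w + J)
                if r > 0:
                    nb = jitter[r - 1, c, ax]
                    lo, hi = max(lo, nb - J), min(hi, nb + J)
                jitter[r, c, ax] = rng.integers(lo, hi + 1)
    return jitter


def cut_tiles(
    phantom: VoxelBlock,
    m: int,
    n: int,
    tile_shape: tuple[int, int, int],
    overlap: tuple[int, int],
    jitter_bound: int,
    noise_sigma: float,
    seed: int,
    out_dir: str,
    substack_count: int = 1,
    intensity_jitter: float = 0.0,
) -> tuple[ProjectDescriptor, GroundTruth]:
    """Cut a phantom into an m x n overlapping tile grid with known jitter.

    Tile (r, c) is the phantom window at ``margin + nominal_origin +
    jitter[r, c]`` plus i.i.d. Gaussian noise clipped to the dtype; the
    anchor tile (0, 0) has zero jitter.  ``intensity_jitter`` optionally
    applies a per-tile multiplicative factor drawn in ``1 +/- value`` to
    exercise NCC's invariance to linear intensity scaling.

    Writes the tile directory hierarchy (``row_RR/col_CC/``), the XML
    descriptor at stage ``imported`` and a ground-truth JSON sidecar.
    """
    J = int(jitter_bound)
    if J < 0:
        raise ValueError("jitter_bound must be >= 0")
    need = required_phantom_shape(m, n, tile_shape, overlap, J)
    if any(p < r for p, r in zip(phantom.shape, need)):
        raise ValueError(
            f"phantom shape {phantom.shape} too small; need at least {need} "
            f"for an {m}x{n} grid with tile {tile_shape}, overlap {overlap}, "
            f"jitter bound {J}"
        )

    rng = np.random.default_rng(seed)
    jitter = _draw_jitter(rng, m, n, J)

    sz, sy, sx = tile_shape
    oy, ox = overlap
    info = np.iinfo(phantom.dtype)
    os.makedirs(out_dir, exist_ok=True)

    tiles: list[list[TileRef]] = []
    for r in range(m):
        row_refs = []
        for c in range(n):
            nominal = np.array([0, r * (sy - oy), c * (sx - ox)], dtype=np.int64)
            start = J + nominal + jitter[r, c]
            z0, y0, x0 = (int(v) for v in start)
            window = phantom.data[z0 : z0 + sz, y0 : y0 + sy, x0 : x0 + sx]
            window = window.astype(np.float64)
            if intensity_jitter > 0:
                window = window * (1.0 + rng.uniform(-intensity_jitter, intensity_jitter))
            if noise_sigma > 0:
                window = window + rng.normal(0.0, noise_sigma, size=window.shape)
            data = np.clip(np.floor(window + 0.5), info.min, info.max).astype(phantom.dtype)
            tile_dir = os.path.join(out_dir, f"row_{r:02d}", f"col_{c:02d}")
            write_tile(tile_dir, data)
            row_refs.append(TileRef(r, c, tile_dir))
        tiles.append(row_refs)

    grid = TileGrid(m=m, n=n, tile_shape=tile_shape, nominal_overlap=overlap, tiles=tiles)
    project = ProjectDescriptor(grid=grid, substack_count=substack_count, stage="imported")
    save_project(project, os.path.join(out_dir, "project.xml"))

    truth = GroundTruth(
        true_offsets=jitter,
        phantom_shape=phantom.shape,
        params={
            "seed": int(seed),
            "jitter_bound": J,
            "noise_sigma": float(noise_sigma),
            "tile_shape": list(tile_shape),
            "overlap": list(overlap),
            "intensity_jitter": float(intensity_jitter),
        },
    )
    truth.save(os.path.join(out_dir, "ground_truth.json"))
    return project, truth


def make_dataset(
    out_dir: str,
    m: int = 3,
    n: int = 3,
    tile_shape: tuple[int, int, int] = (32, 64, 64),
    overlap: tuple[int, int] = (16, 16),
    jitter_bound: int = 4,
    noise_sigma: float = 0.0,
    seed: int = 0,
    substack_count: int = 1,
    blob_density: float = 2.0e-3,
    intensity_jitter: float = 0.0,
) -> tuple[ProjectDescriptor, GroundTruth]:
    """One-call generator: phantom sized to the grid, then :func:`cut_tiles`.

    Blob count scales with phantom volume (``blob_density`` blobs per voxel)
    so texture density is comparable across grid sizes; the default puts
    roughly a dozen blobs in every 16-voxel-wide overlap strip.
    """
    shape = required_phantom_shape(m, n, tile_shape, overlap, jitter_bound)
    n_blobs = max(1, int(round(blob_density * shape[0] * shape[1] * shape[2])))
    phantom = generate_phantom(shape, n_blobs=n_blobs, seed=seed)
    return cut_tiles(
        phantom,
        m,
        n,
        tile_shape,
        overlap,
        jitter_bound,
        noise_sigma,
        seed + 1,
        out_dir,
        substack_count=substack_count,
        intensity_jitter=intensity_jitter,
    )
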