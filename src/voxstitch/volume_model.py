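"""Data model for tiled 3D volumes and the XML project descriptor.

A dataset is an ``m x n`` grid of 3D tiles (Z-series of 2D grayscale TIFF
planes) with a fixed nominal overlap between adjacent rows and columns.
The :class:`ProjectDescriptor` carries the pipeline state — grid metadata,
per-pair displacements and absolute tile positions — through the stages
``imported -> aligned -> projected -> thresholded -> placed``.

Conventions used throughout the package: 0-based indices, half-open
intervals, axis order ``(z, y, x)``; grid rows advance along y, columns
along x.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence
from xml.etree import ElementTree as ET

import numpy as np
import tifffile

STAGES = ("imported", "aligned", "projected", "thresholded", "placed")

PLANE_PATTERN = re.compile(r"^(\d+)\.tiff?$")


class ValidationError(ValueError):
    """A descriptor or dataset violates a structural invariant."""


class ProjectParseError(ValueError):
    """The XML project file is malformed."""


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TileRef:
    """Reference to one tile's Z-series on disk."""

    row: int
    col: int
    path: str

    def nominal_origin(self, tile_shape, overlap) -> tuple[int, int, int]:
        sz, sy, sx = tile_shape
        oy, ox = overlap
        return (0, self.row * (sy - oy), self.col * (sx - ox))


@dataclass
class TileGrid:
    """The m x n arrangement of 3D tiles with nominal overlaps."""

    m: int
    n: int
    tile_shape: tuple[int, int, int]  # (sz, sy, sx)
    nominal_overlap: tuple[int, int]  # (oy, ox)
    tiles: list[list[TileRef]]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValidationError("grid must have at least one row and column")
        sz, sy, sx = self.tile_shape
        oy, ox = self.nominal_overlap
        if not (0 < oy < sy and 0 < ox < sx):
            raise ValidationError(
                f"overlap {self.nominal_overlap} must be strictly inside "
                f"tile extents {(sy, sx)}"
            )
        if len(self.tiles) != self.m or any(len(r) != self.n for r in self.tiles):
            raise ValidationError("tile table does not match declared grid shape")
        for r, row in enumerate(self.tiles):
            for c, t in enumerate(row):
                if (t.row, t.col) != (r, c):
                    raise ValidationError(f"tile at ({r},{c}) declares ({t.row},{t.col})")

    def tile(self, row: int, col: int) -> TileRef:
        return self.tiles[row][col]

    def nominal_origin(self, row: int, col: int) -> tuple[int, int, int]:
        return self.tiles[row][col].nominal_origin(self.tile_shape, self.nominal_overlap)


@dataclass(frozen=True)
class Displacement:
    """Correction to the nominal relative position of one adjacent tile pair,
    for one sub-stack, with a per-axis reliability in [0, 1]."""

    pair_id: str
    substack: int
    offset: tuple[int, int, int]  # (dz, dy, dx)
    reliability: tuple[float, float, float]  # (rz, ry, rx)

    def min_reliability(self) -> float:
        return min(self.reliability)


@dataclass
class VoxelBlock:
    """A 3D intensity block positioned in some reference frame."""

    data: np.ndarray
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("VoxelBlock data must be 3-dimensional")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype


@dataclass
class ProjectDescriptor:
    """Serializable pipeline state: grid + displacements + positions."""

    grid: TileGrid
    substack_count: int = 1
    stage: str = "imported"
    pair_displacements: dict[str, list[Displacement]] = field(default_factory=dict)
    absolute_positions: np.ndarray | None = None  # (m, n, 3) int, (z, y, x)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.substack_count < 1:
            raise ValidationError("substack_count must be >= 1")
        ids = pair_ids(self.grid.m, self.grid.n)
        if not self.pair_displacements:
            self.pair_displacements = {p: [] for p in ids}
        elif set(self.pair_displacements) != set(ids):
            raise ValidationError("pair_displacements domain must equal the adjacency set")
        if (self.absolute_positions is not None) != (self.stage == "placed"):
            raise ValidationError("absolute_positions present iff stage == 'placed'")


# ---------------------------------------------------------------------------
# Adjacency enumeration
# ---------------------------------------------------------------------------


def pair_ids(m: int, n: int) -> list[str]:
    """All adjacent-pair ids in canonical order: EW row-major, then NS.

    ``EW:r,c`` pairs tile (r,c) with (r,c+1); ``NS:r,c`` pairs (r,c) with
    (r+1,c).  There are exactly ``m*(n-1) + (m-1)*n`` ids.
    """
    ew = [f"EW:{r},{c}" for r in range(m) for c in range(n - 1)]
    ns = [f"NS:{r},{c}" for r in range(m - 1) for c in range(n)]
    return ew + ns


def parse_pair_id(pair_id: str) -> tuple[str, int, int]:
    kind, _, rc = pair_id.partition(":")
    if kind not in ("EW", "NS") or "," not in rc:
        raise ValidationError(f"malformed pair id {pair_id!r}")
    r, c = rc.split(",")
    return kind, int(r), int(c)


def pair_tiles(pair_id: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two (row, col) grid positions joined by a pair id."""
    kind, r, c = parse_pair_id(pair_id)
    if kind == "EW":
        return (r, c), (r, c + 1)
    return (r, c), (r + 1, c)


def nominal_relative_offset(pair_id: str, grid: TileGrid) -> tuple[int, int, int]:
    """Nominal (z, y, x) offset of the second tile relative to the first."""
    kind, _, _ = parse_pair_id(pair_id)
    sz, sy, sx = grid.tile_shape
    oy, ox = grid.nominal_overlap
    if kind == "EW":
        return (0, 0, sx - ox)
    return (0, sy - oy, 0)


# ---------------------------------------------------------------------------
# Tile voxel I/O
# ---------------------------------------------------------------------------


def _plane_files(tile_dir: str) -> list[str]:
    names = sorted(f for f in os.listdir(tile_dir) if PLANE_PATTERN.match(f))
    if not names:
        raise IOError(f"no TIFF planes found in {tile_dir}")
    return [os.path.join(tile_dir, f) for f in names]


def read_tile_region(
    tile: TileRef,
    z_range: tuple[int, int],
    y_range: tuple[int, int],
    x_range: tuple[int, int],
) -> VoxelBlock:
    """Read a sub-block of a tile, touching only the planes in ``z_range``.

    The tile path may be a directory of single-page TIFFs (named by
    zero-padded z index) or a single multipage TIFF file.
    """
    z0, z1 = z_range
    y0, y1 = y_range
    x0, x1 = x_range
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        raise ValueError("requested ranges must be non-empty")
    if z0 < 0 or y0 < 0 or x0 < 0:
        raise IndexError("requested ranges must be non-negative")

    if os.path.isdir(tile.path):
        files = _plane_files(tile.path)
        if z1 > len(files):
            raise IndexError(
                f"z_range {z_range} exceeds tile depth {len(files)} at {tile.path}"
            )
        planes = []
        for z in range(z0, z1):
            try:
                planes.append(tifffile.imread(files[z]))
            except Exception as exc:  # pragma: no cover - disk corruption path
                raise IOError(f"cannot read plane {files[z]}: {exc}") from exc
        data = np.stack(planes, axis=0)
    else:
        try:
            data = tifffile.imread(tile.path, key=range(z0, z1))
        except (IndexError, FileNotFoundError) as exc:
            raise IOError(f"cannot read planes [{z0},{z1}) from {tile.path}: {exc}") from exc
        if data.ndim == 2:
            data = data[None]

    if y1 > data.shape[1] or x1 > data.shape[2]:
        raise IndexError(
            f"ranges y={y_range}, x={x_range} exceed plane shape {data.shape[1:]}"
        )
    return VoxelBlock(np.ascontiguousarray(data[:, y0:y1, x0:x1]), origin=(z0, y0, x0))


def write_tile(tile_dir: str, volume: np.ndarray) -> None:
    """Write a (sz, sy, sx) volume as one single-page TIFF per z plane."""
    os.makedirs(tile_dir, exist_ok=True)
    for z in range(volume.shape[0]):
        tifffile.imwrite(
            os.path.join(tile_dir, f"{z:06d}.tif"), volume[z], photometric="minisblack"
        )


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------


def _fmt_float(v: float) -> str:
    return f"{v:.6f}"


def _displacement_element(parent: ET.Element, d: Displacement) -> None:
    ET.SubElement(
        parent,
        "d",
        substack=str(d.substack),
        dz=str(d.offset[0]),
        dy=str(d.offset[1]),
        dx=str(d.offset[2]),
        rz=_fmt_float(d.reliability[0]),
        ry=_fmt_float(d.reliability[1]),
        rx=_fmt_float(d.reliability[2]),
    )


def save_project(project: ProjectDescriptor, path: str) -> None:
    """Write the descriptor as deterministic UTF-8 XML.

    Element order is fixed (row-major tiles, canonical pair order) so the
    same descriptor always produces byte-identical output.
    """
    g = project.grid
    root = ET.Element("stitch_project", stage=project.stage)
    ET.SubElement(
        root,
        "grid",
        rows=str(g.m),
        cols=str(g.n),
        tile_z=str(g.tile_shape[0]),
        tile_y=str(g.tile_shape[1]),
        tile_x=str(g.tile_shape[2]),
        overlap_y=str(g.nominal_overlap[0]),
        overlap_x=str(g.nominal_overlap[1]),
        substacks=str(project.substack_count),
        voxel_z=_fmt_float(g.voxel_size[0]),
        voxel_y=_fmt_float(g.voxel_size[1]),
        voxel_x=_fmt_float(g.voxel_size[2]),
    )
    base = os.path.dirname(os.path.abspath(path))
    tiles_el = ET.SubElement(root, "tiles")
    for row in g.tiles:
        for t in row:
            rel = os.path.relpath(os.path.abspath(t.path), base)
            ET.SubElement(tiles_el, "tile", row=str(t.row), col=str(t.col), path=rel)
    if any(project.pair_displacements.values()):
        disp_el = ET.SubElement(root, "displacements")
        for pid in pair_ids(g.m, g.n):
            ds = project.pair_displacements[pid]
            if not ds:
                continue
            pair_el = ET.SubElement(disp_el, "pair", id=pid)
            for d in sorted(ds, key=lambda d: d.substack):
                _displacement_element(pair_el, d)
    if project.stage == "placed":
        pos_el = ET.SubElement(root, "positions")
        for r in range(g.m):
            for c in range(g.n):
                z, y, x = (int(v) for v in project.absolute_positions[r, c])
                ET.SubElement(pos_el, "tile", row=str(r), col=str(c), z=str(z), y=str(y), x=str(x))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _parse_displacement(el: ET.Element, pair_id: str) -> Displacement:
    return Displacement(
        pair_id=pair_id,
        substack=int(el.get("substack")),
        offset=(int(el.get("dz")), int(el.get("dy")), int(el.get("dx"))),
        reliability=(float(el.get("rz")), float(el.get("ry")), float(el.get("rx"))),
    )


def load_project(path: str) -> ProjectDescriptor:
    """Parse and validate an XML project descriptor."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ProjectParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "stitch_project":
        raise ProjectParseError(f"unexpected root element <{root.tag}>")
    stage = root.get("stage")
    grid_el = root.find("grid")
    if grid_el is None:
        raise ProjectParseError("missing <grid> element")
    m, n = int(grid_el.get("rows")), int(grid_el.get("cols"))
    tile_shape = tuple(int(grid_el.get(k)) for k in ("tile_z", "tile_y", "tile_x"))
    overlap = (int(grid_el.get("overlap_y")), int(grid_el.get("overlap_x")))
    voxel = tuple(float(grid_el.get(k, "1")) for k in ("voxel_z", "voxel_y", "voxel_x"))
    substacks = int(grid_el.get("substacks", "1"))

    base = os.path.dirname(os.path.abspath(path))
    tile_els = root.findall("tiles/tile")
    if len(tile_els) != m * n:
        raise ValidationError(
            f"declared {m}x{n} grid but found {len(tile_els)} tile entries"
        )
    table: dict[tuple[int, int], TileRef] = {}
    for el in tile_els:
        r, c = int(el.get("row")), int(el.get("col"))
        p = el.get("path")
        if not os.path.isabs(p):
            p = os.path.normpath(os.path.join(base, p))
        table[(r, c)] = TileRef(r, c, p)
    missing = [(r, c) for r in range(m) for c in range(n) if (r, c) not in table]
    if missing:
        raise ValidationError(f"grid is incomplete; missing tiles {missing}")
    grid = TileGrid(
        m=m,
        n=n,
        tile_shape=tile_shape,
        nominal_overlap=overlap,
        tiles=[[table[(r, c)] for c in range(n)] for r in range(m)],
        voxel_size=voxel,
    )

    valid_ids = set(pair_ids(m, n))
    disp: dict[str, list[Displacement]] = {p: [] for p in valid_ids}
    for pair_el in root.findall("displacements/pair"):
        pid = pair_el.get("id")
        if pid not in valid_ids:
            raise ValidationError(f"displacement for unknown pair {pid!r}")
        disp[pid] = [_parse_displacement(d, pid) for d in pair_el.findall("d")]

    positions = None
    pos_els = root.findall("positions/tile")
    if pos_els:
        if len(pos_els) != m * n:
            raise ValidationError("positions present but incomplete")
        positions = np.zeros((m, n, 3), dtype=np.int64)
        for el in pos_els:
            r, c = int(el.get("row")), int(el.get("col"))
            positions[r, c] = (int(el.get("z")), int(el.get("y")), int(el.get("x")))

    return ProjectDescriptor(
        grid=grid,
        substack_count=substacks,
        stage=stage,
        pair_displacements=disp,
        absolute_positions=positions,
    )


# ---------------------------------------------------------------------------
# Alignment fragments (partial results produced by one block task)
# ---------------------------------------------------------------------------


def save_fragment(fragment: dict[str, list[Displacement]], path: str) -> None:
    """Serialize a partial alignment result (pair -> displacements)."""
    root = ET.Element("alignment_fragment")
    for pid in sorted(fragment, key=_pair_sort_key):
        pair_el = ET.SubElement(root, "pair", id=pid)
        for d in sorted(fragment[pid], key=lambda d: d.substack):
            _displacement_element(pair_el, d)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def load_fragment(path: str) -> dict[str, list[Displacement]]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ProjectParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "alignment_fragment":
        raise ProjectParseError(f"unexpected root element <{root.tag}>")
    out: dict[str, list[Displacement]] = {}
    for pair_el in root.findall("pair"):
        pid = pair_el.get("id")
        out[pid] = [_parse_displacement(d, pid) for d in pair_el.findall("d")]
    return out


def _pair_sort_key(pid: str) -> tuple[str, int, int]:
    kind, r, c = parse_pair_id(pid)
    return (kind, r, c)
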