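import os

import numpy as np
import pytest
import tifffile

from voxstitch import fusion, placement, synthetic_data, volume_model as vm
from voxstitch.mip_ncc import align_pair


def _place(project, truth):
    """Stage=placed descriptor with positions taken from ground truth."""
    grid = project.grid
    pos = np.zeros((grid.m, grid.n, 3), dtype=np.int64)
    for r in range(grid.m):
        for c in range(grid.n):
            pos[r, c] = np.asarray(grid.nominal_origin(r, c)) + truth.true_offsets[r, c]
    disp = {p: [vm.Displacement(p, 0, truth.pair_delta(p), (1.0, 1.0, 1.0))]
            for p in vm.pair_ids(grid.m, grid.n)}
    return vm.ProjectDescriptor(
        grid=grid, substack_count=project.substack_count, stage="placed",
        pair_displacements=disp, absolute_positions=pos,
    )


def _read_level(out_dir, r):
    level = os.path.join(out_dir, f"level_{r}")
    planes = sorted(os.listdir(level))
    return np.stack([tifffile.imread(os.path.join(level, p)) for p in planes])


class TestFuseRegion:
    def test_single_tile_grid_is_identity(self, tmp_path):
        project, truth = synthetic_data.make_dataset(
            str(tmp_path / "one"), m=1, n=2, tile_shape=(8, 24, 24), overlap=(8, 8),
            jitter_bound=0, noise_sigma=0.0, seed=1)
        placed = _place(project, truth)
        region = ((0, 8), (0, 24), (0, 24))  # exactly tile (0, 0)
        fused = fusion.fuse_region(placed, region, "linear_ramp")
        tile = vm.read_tile_region(project.grid.tile(0, 0), (0, 8), (0, 24), (0, 24))
        # the non-overlap part of tile (0,0) is covered by it alone
        assert np.array_equal(fused.data[:, :, :16], tile.data[:, :, :16])

    @pytest.mark.parametrize("blending", ["nearest", "linear_ramp"])
    def test_zero_jitter_fusion_reproduces_phantom_window(self, clean_dataset, blending):
        """Overlap strips are voxel-identical, so any convex blend must
        return exactly the underlying phantom values."""
        project, truth = clean_dataset
        placed = _place(project, truth)
        dims = fusion.make_fusion_spec(placed).extents
        fused = fusion.fuse_region(placed, tuple((0, d) for d in dims), blending)
        # reconstruct expectation by pasting tiles (all identical in overlaps)
        expect = np.zeros(dims, dtype=fused.dtype)
        for r in range(project.grid.m):
            for c in range(project.grid.n):
                z, y, x = project.grid.nominal_origin(r, c)
                t = vm.read_tile_region(project.grid.tile(r, c), (0, 16), (0, 48), (0, 48))
                expect[z : z + 16, y : y + 48, x : x + 48] = t.data
        assert np.array_equal(fused.data, expect)

    def test_linear_ramp_midpoint_of_constant_tiles(self, tmp_path):
        """1x2 grid, tiles constant 10 and 20: the overlap column weights
        follow the ramp i/o vs (o-i)/o, so the midpoint voxel is 15."""
        sz, sy, sx, o = 4, 8, 16, 4
        a = np.full((sz, sy, sx), 10, dtype=np.uint8)
        b = np.full((sz, sy, sx), 20, dtype=np.uint8)
        vm.write_tile(str(tmp_path / "a"), a)
        vm.write_tile(str(tmp_path / "b"), b)
        tiles = [[vm.TileRef(0, 0, str(tmp_path / "a")), vm.TileRef(0, 1, str(tmp_path / "b"))]]
        grid = vm.TileGrid(m=1, n=2, tile_shape=(sz, sy, sx), nominal_overlap=(4, o), tiles=tiles)
        disp = {"EW:0,0": [vm.Displacement("EW:0,0", 0, (0, 0, 0), (1.0, 1.0, 1.0))]}
        placed = vm.ProjectDescriptor(
            grid=grid, stage="placed", pair_displacements=disp,
            absolute_positions=np.array([[[0, 0, 0], [0, 0, sx - o]]]),
        )
        fused = fusion.fuse_region(placed, ((0, sz), (0, sy), (0, 2 * sx - o)), "linear_ramp")
        row = fused.data[0, 0]
        # overlap columns are sx-o .. sx-1, weights for B: i/o with i = 0..o-1
        assert row[sx - o + o // 2] == 15  # midpoint voxel, weight 1/2 each
        expect_overlap = [int(np.floor(10 + 10 * i / o + 0.5)) for i in range(o)]
        assert row[sx - o : sx].tolist() == expect_overlap
        assert (fused.data[:, :, : sx - o] == 10).all()
        assert (fused.data[:, :, sx:] == 20).all()

    def test_gap_voxels_are_zero_filled_and_counted(self, tmp_path):
        project, truth = synthetic_data.make_dataset(
            str(tmp_path / "g"), m=1, n=2, tile_shape=(8, 24, 24), overlap=(8, 8),
            jitter_bound=2, noise_sigma=0.0, seed=5)
        placed = _place(project, truth)
        stats = {}
        dims = fusion.make_fusion_spec(placed).extents
        fused = fusion.fuse_region(placed, tuple((0, d) for d in dims), "nearest", stats=stats)
        assert fused.shape == dims
        if truth.true_offsets.any():
            # jittered tiles leave uncovered slivers inside the bounding box
            assert stats["gap_voxels"] > 0


class TestDownsample:
    def test_constant_block(self):
        block = vm.VoxelBlock(np.full((4, 6, 8), 9, dtype=np.uint8))
        out = fusion.downsample_halve(block)
        assert out.shape == (2, 3, 4)
        assert (out.data == 9).all()

    def test_round_half_up_on_2x2x2(self):
        block = vm.VoxelBlock(np.arange(8, dtype=np.uint8).reshape(2, 2, 2))
        out = fusion.downsample_halve(block)
        assert out.shape == (1, 1, 1)
        assert out.data[0, 0, 0] == 4  # mean 3.5 rounds half-up

    def test_repeated_halving_equals_direct_block_mean(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 255, size=(8, 8, 8)).astype(np.uint8)
        block = vm.VoxelBlock(data)
        for _ in range(3):
            block = fusion.downsample_halve(block)
        # three halvings of integer-rounded intermediates stay within 1 of
        # the exact 8^3 mean (rounding accumulates at most half per level)
        direct = data.astype(np.float64).mean()
        assert abs(float(block.data[0, 0, 0]) - direct) <= 2

    def test_unit_axis_passes_through(self):
        block = vm.VoxelBlock(np.arange(12, dtype=np.uint16).reshape(1, 3, 4))
        out = fusion.downsample_halve(block)
        assert out.shape == (1, 1, 2)

    def test_odd_trailing_truncated(self):
        block = vm.VoxelBlock(np.zeros((5, 7, 9), dtype=np.uint8))
        assert fusion.downsample_halve(block).shape == (2, 3, 4)


@pytest.fixture(scope="module")
def placed_small(tmp_path_factory):
    out = tmp_path_factory.mktemp("fds")
    project, truth = synthetic_data.make_dataset(
        str(out), m=2, n=2, tile_shape=(16, 32, 32), overlap=(8, 8),
        jitter_bound=2, noise_sigma=0.0, seed=9)
    return _place(project, truth)


class TestFuseTask:
    def test_whole_volume_single_task_matches_fuse_region(self, placed_small, tmp_path):
        spec = fusion.make_fusion_spec(placed_small, tile_size=(16, 16, 16), n_levels=0)
        region = tuple((0, d) for d in spec.extents)
        fusion.fuse_task(placed_small, region, spec, str(tmp_path))
        got = _read_level(str(tmp_path), 0)
        want = fusion.fuse_region(placed_small, region, spec.blending, origin=spec.origin)
        assert np.array_equal(got, want.data)

    def test_task_concatenation_equals_sequential_fusion(self, placed_small, tmp_path):
        """Fusing region by region then halving per task reproduces, voxel
        for voxel, fusing the whole volume and halving it."""
        spec = fusion.make_fusion_spec(
            placed_small, tile_size=(8, 16, 16), n_levels=1, out_format="tiled3d")
        regions = fusion.plan_fusion_tasks(spec, 4)
        assert len(regions) >= 4
        for region in regions:
            fusion.fuse_task(placed_small, region, spec, str(tmp_path))
        whole = fusion.fuse_region(
            placed_small, tuple((0, d) for d in spec.extents), spec.blending,
            origin=spec.origin)
        for r in range(2):
            got = _read_tiled3d(str(tmp_path), r, spec)
            assert np.array_equal(got, whole.data)
            whole = fusion.downsample_halve(whole)

    def test_unaligned_region_rejected(self, placed_small, tmp_path):
        spec = fusion.make_fusion_spec(placed_small, tile_size=(16, 16, 16), n_levels=1)
        bad = ((1, spec.extents[0]), (0, spec.extents[1]), (0, spec.extents[2]))
        with pytest.raises(ValueError, match="aligned"):
            fusion.fuse_task(placed_small, bad, spec, str(tmp_path))


def _read_tiled3d(out_dir, r, spec):
    dims = spec.level_dims(r)
    out = np.zeros(dims, dtype=np.dtype(spec.dtype))
    level = os.path.join(out_dir, f"level_{r}")
    for ydir in sorted(os.listdir(level)):
        for yxdir in sorted(os.listdir(os.path.join(level, ydir))):
            y0, x0 = (int(v) for v in yxdir.split("_"))
            for f in sorted(os.listdir(os.path.join(level, ydir, yxdir))):
                z0 = int(f.split("_")[2].split(".")[0])
                blk = tifffile.imread(os.path.join(level, ydir, yxdir, f))
                if blk.ndim == 2:
                    blk = blk[None]
                out[z0 : z0 + blk.shape[0], y0 : y0 + blk.shape[1], x0 : x0 + blk.shape[2]] = blk
    return out


class TestFuseDataset:
    def test_worker_counts_give_byte_identical_trees(self, tmp_path):
        project, truth = synthetic_data.make_dataset(
            str(tmp_path / "ds"), m=2, n=2, tile_shape=(16, 32, 32), overlap=(8, 8),
            jitter_bound=2, noise_sigma=4.0, seed=2)
        placed = _place(project, truth)
        spec = fusion.make_fusion_spec(placed, tile_size=(8, 16, 16), n_levels=1,
                                       out_format="tiled3d")
        trees = {}
        for P in (1, 2):
            out = tmp_path / f"out{P}"
            fusion.fuse_dataset(placed, spec, str(out), n_tasks=4, workers=P)
            trees[P] = _hash_tree(str(out))
        assert trees[1] == trees[2]

    def test_slice_series_layout(self, tmp_path):
        project, truth = synthetic_data.make_dataset(
            str(tmp_path / "ds"), m=1, n=2, tile_shape=(8, 24, 24), overlap=(8, 8),
            jitter_bound=0, noise_sigma=0.0, seed=3)
        placed = _place(project, truth)
        spec = fusion.make_fusion_spec(placed, tile_size=(4, 16, 16), n_levels=1)
        manifest = fusion.fuse_dataset(placed, spec, str(tmp_path / "out"), n_tasks=2)
        for r in range(2):
            planes = os.listdir(str(tmp_path / "out" / f"level_{r}"))
            assert len(planes) == spec.level_dims(r)[0]  # one 2D TIFF per z
        assert manifest["format"] == "slice_series"
        level0 = _read_level(str(tmp_path / "out"), 0)
        assert level0.shape == spec.extents


def _hash_tree(root):
    import hashlib

    h = hashlib.md5()
    for dirpath, dirs, files in os.walk(root):
        dirs.sort()
        for f in sorted(files):
            p = os.path.join(dirpath, f)
            h.update(os.path.relpath(p, root).encode())
            h.update(open(p, "rb").read())
    return h.hexdigest()
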