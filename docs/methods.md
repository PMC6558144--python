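# Methods

This note records the models, conventions and design choices behind
`voxstitch`, including the points where the underlying problem leaves the
design genuinely open.

## Conventions

0-based indices, half-open intervals, axis order (z, y, x) everywhere.
Grid rows advance along y, columns along x. A tile is stored as a directory
of single-page grayscale TIFFs named by zero-padded z index (multipage TIFF
is also accepted on read); nominal overlaps are specified in voxels. The
XML project descriptor carries the pipeline state through the stages
`imported → aligned → projected → thresholded → placed`; element order is
fixed (row-major tiles, canonical pair order `EW:r,c` / `NS:r,c`) so
serialization is byte-deterministic, and reliabilities are rounded to six
decimals *when computed* so that save/load is lossless.

## Pairwise alignment

For a pair of adjacent tiles the nominal overlap sub-blocks are read (only
the planes of the requested sub-stack), projected by maximum intensity
along z, y and x, and each homologous projection pair is scored by NCC over
all integer shifts within per-axis radii (R_z, R_y, R_x). The CLI follows
the field's convention of specifying the *search area* as odd map side
lengths (e.g. `65x65`); radius = (side − 1)/2.

Numerical choices:

- NCC is computed in double precision whatever the input dtype, per shift,
  over the exact image intersection, with means and variances recomputed on
  that intersection. Shifts where either side has zero variance are flagged
  invalid and scored 0; a map with no valid entry yields the nominal
  alignment with reliability 0.
- Peak ties break toward the smallest Euclidean shift magnitude, then
  lexicographically on (v, u) — so a featureless-but-valid map returns the
  nominal alignment.
- Each axis appears in two of the three maps; it takes offset and
  reliability from the map with the strictly higher peak (precedence
  z-, y-, x-projection on ties). Reliability is the peak NCC clamped to
  [0, 1]. This is a deliberate simple estimator: monotone in match quality,
  free of extra parameters.
- Sub-stacks are S near-equal contiguous Z ranges, the first (s_z mod S)
  one plane deeper. Alignment requires the overlap extent and sub-stack
  depth to exceed twice the corresponding radius; thinner configurations
  are rejected rather than silently truncated.

## Partition optimization

`optimal_grid_partition` enumerates p_m ∈ [1, ⌊m/2⌋] with the cheapest
feasible p_n = ⌈B/p_m⌉ (cost is increasing in p_n), which is exhaustive,
hence exactly optimal; ties break toward smaller p_m, then p_n.
`candidate_points` evaluates the three integer neighbours of the relaxed
optimum; square roots are taken exactly in integer arithmetic so perfect
squares never suffer float rounding. When no candidate is feasible (very
elongated grids can push p″ past a range bound) the fallback clamps p″ into
range and raises the free coordinate to ⌈B/p⌉, which is always feasible
because B ≤ ⌊m/2⌋·⌊n/2⌋.

Blocks are extended with one row at the bottom and one column at the right
where those exist; the disable flags suppress alignments among tiles of the
extension row/column (the neighbouring block owns them), and a corner
extension tile — which then participates in no enabled pair — is skipped
from the load set. With this accounting, the count of multiply-loaded tiles
equals the cost function exactly, and there are (p_m−1)(p_n−1) skipped
corners.

Degenerate grids (m < 2 or n < 2) are never partitioned along the thin
axis; block demands are then satisfied along Z (or the plan simply yields
fewer tasks).

## Synthetic data

The generator emulates an acquisition: a textured phantom is cut into an
m×n grid of overlapping tiles, each displaced from its nominal origin by a
known integer jitter and corrupted with additive Gaussian noise (clipped
and rounded to the unsigned dtype, 16-bit by default). An optional per-tile
multiplicative intensity factor exercises NCC's invariance to linear
rescaling.

- **Texture.** A fine-grained background field (unit-sigma smoothed white
  noise, amplitude 20) plus Gaussian blobs of fixed peak amplitude 150 and
  per-axis widths drawn in [1.0, 3.5] voxels, about 2·10⁻³ blobs per voxel,
  over a background level of 100. The background field guarantees positive
  variance in every window (NCC is defined everywhere); the small blob
  widths give the sharp correlation peaks that make integer localization
  robust; the background level leaves ≈3σ of headroom at the reference
  noise level so clipping at zero does not skew the noise. Signal-to-noise
  is quoted as blob amplitude / noise sigma.
- **Jitter.** Drawn uniformly on integers [−J, J] per axis, *conditioned on
  differing by at most J from the west and north neighbours* (row-major
  sequential draw; the conditioning interval is never empty). Stage error
  physically accrues per move, so the bound belongs on the relative error
  of adjacent tiles — the quantity alignment must recover — and any search
  radius > J is then guaranteed to contain the true pairwise displacement.
  Tile (0,0) is the zero-jitter anchor, and the true displacement of any
  pair is the difference of its tiles' jitters, making recovery an exact
  pass/fail check.
- **Not modelled:** optics (PSF, vignetting, light-sheet stripes),
  intensity falloff with depth, non-integer stage error, tile-shape
  variation. Passing recovery tests therefore demonstrates the alignment
  machinery and its parallel decomposition, not robustness to real-world
  aberrations.

## Placement

Displacement projection keeps, per pair, the sub-stack displacement with
the best worst-axis reliability (ties: lowest sub-stack index) — one bad
sub-stack cannot drag down an average. Thresholding compares that worst
axis against the user threshold and falls back to the nominal alignment
(zero offset, reliability 0) below it. Positions propagate from the anchor
along a maximum-total-reliability spanning tree (Kruskal with ties broken
by canonical pair order, then BFS in deterministic neighbour order). On
globally consistent corrections — the synthetic case — the result is exact
and independent of which tree was chosen; with inconsistent corrections the
tree discards the least reliable contradictory edges rather than
distributing the error, a deliberate simplification versus global
least-squares adjustment.

## Fusion

The fused extent is the exact bounding box of the placed tiles; voxels
covered by no tile are zero-filled and tallied (`gap_voxels` in the
manifest). Blending weights for `linear_ramp` rise by 1/o per voxel across
an overlap of width o — w = l/o from a neighboured low edge, (s − l)/o
into a neighboured high edge, multiplied across y and x, then normalized to
sum 1. At nominal placement the two profiles are complementary (they sum
to one), so the blend is exactly convex; a voxel whose total feather weight
is zero but which is covered falls back to the plain mean. `nearest`
assigns each voxel to the tile with the closest center (ties: lower row,
then column). Z is never feathered: tiles form a 2D grid.

Downsampling is a 2×2×2 mean rounded half-up to the dtype; odd trailing
voxels are truncated and axes of size 1 pass through, so level r has
dimensions ⌊D/2^r⌋.

Per-dimension tiling: the largest b̄ in [⌈w/2⌉, w] with D mod 2ⁿb̄ = 0 if
one exists (fewest, largest tiles), else the b̄ maximizing the remainder
(ties to the largest b̄), the remainder forming one final shorter
sub-interval. When D < 2ⁿ·⌈w/2⌉ the same rule degenerates gracefully to a
single sub-interval of size D. Because task regions are unions of whole
sub-intervals, every region boundary is divisible by 2^r for all generated
levels, so per-task halving reproduces whole-volume halving bit for bit.

Task planning splits along Z first and engages Y, then X, only when Z
sub-intervals alone cannot reach the requested task count. The slice-series
format requires a writer to own whole planes, so it is partitioned along Z
only — with fewer Z sub-intervals than requested tasks, fewer tasks result.
The externally tiled format (one multipage TIFF per (y, x) block of b̄
voxels per Z sub-interval, origins in level-r voxels zero-padded to six
digits) supports arbitrary 3D partitions.

## Dispatcher

A local process pool replaces cluster middleware while preserving the
dispatch contract: N ≥ P independent tasks (default N = 2P for load
balancing), P started immediately, the rest assigned FIFO as workers
complete, outputs merged at the end. Workers are spawned processes running
the same single-task entry points used serially; tasks share no mutable
state and each writes only its own files, which is what makes the merged
result identical to a sequential run regardless of schedule. A failing task
does not interrupt the others: the run drains, then reports every failure
with its task identity (exit status 2 from the CLI).

## Problem sizes used in the test suite

The suite validates the optimizers exhaustively (all grids to 20×20 for
optimality, 8×8 for pair coverage, all D ≤ 5000 for the fusion tiling) and
the imaging pipeline on small synthetic grids — 3×3 grids of 32×64×64
tiles for recovery, a 2×3 grid for the parallel/sequential byte-equality
contract with 1, 2 and 4 workers — sizes at which every property under
test (coverage, determinism, exact recovery) is already fully exercised
while the suite stays fast enough to run routinely.

## Known limitations

- Global placement is a spanning tree, not a least-squares adjustment over
  all pairs; contradictory corrections are resolved by discarding, not
  averaging.
- NCC is evaluated by direct per-shift summation; no FFT path, no subpixel
  peak interpolation, no GPU backend (the NCC contract would be identical).
- The reliability estimate is simply the peak NCC; it does not model peak
  sharpness or multi-modality.
- No compressed or chunked container output; no on-the-fly stitching.
- XML descriptor and output layouts are this package's own; no file-level
  compatibility with other stitching tools is claimed.
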