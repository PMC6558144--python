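"""Global tile placement from pairwise displacements.

The per-block alignment fragments are merged into one descriptor, the
per-sub-stack displacements of each pair are projected to a single best
displacement, unreliable pairs are thresholded back to their nominal
alignment, and absolute tile positions are assigned by propagating
corrections along a maximum-reliability spanning tree of the grid
adjacency graph, anchored at tile (0, 0).

On globally consistent data (e.g. noiseless synthetic grids, where every
pairwise correction equals a difference of per-tile jitters) the result is
exact and independent of the tree actually chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume_model import (
    Displacement,
    ProjectDescriptor,
    nominal_relative_offset,
    pair_ids,
    pair_tiles,
)


class MergeError(ValueError):
    """Fragments overlap or do not cover the full adjacency set."""


@dataclass
class PlacementResult:
    absolute_positions: np.ndarray  # (m, n, 3) int, (z, y, x)
    used_pairs: set[str]  # spanning-tree edges


def merge_alignments(
    project: ProjectDescriptor, fragments: list[dict[str, list[Displacement]]]
) -> ProjectDescriptor:
    """Merge per-task alignment fragments into a stage=aligned descriptor.

    Every (pair, substack) must appear exactly once across all fragments
    and every pair must end up with one displacement per sub-stack — the
    merged result is then identical to a single whole-grid run.
    """
    grid = project.grid
    S = project.substack_count
    merged: dict[str, dict[int, Displacement]] = {p: {} for p in pair_ids(grid.m, grid.n)}
    for frag in fragments:
        for pid, ds in frag.items():
            if pid not in merged:
                raise MergeError(f"fragment contains unknown pair {pid}")
            for d in ds:
                if d.substack in merged[pid]:
                    raise MergeError(f"duplicate result for ({pid}, substack {d.substack})")
                merged[pid][d.substack] = d
    for pid, by_sub in merged.items():
        missing = [s for s in range(S) if s not in by_sub]
        if missing:
            raise MergeError(f"pair {pid} missing sub-stacks {missing}")
    return ProjectDescriptor(
        grid=grid,
        substack_count=S,
        stage="aligned",
        pair_displacements={
            pid: [by_sub[s] for s in range(S)] for pid, by_sub in merged.items()
        },
    )


def project_displacements(project: ProjectDescriptor) -> ProjectDescriptor:
    """Keep, per pair, the single sub-stack displacement with the best
    worst-axis reliability (ties: lowest sub-stack index)."""
    if project.stage != "aligned":
        raise ValueError(f"expected stage 'aligned', got {project.stage!r}")
    projected = {}
    for pid, ds in project.pair_displacements.items():
        if not ds:
            raise MergeError(f"pair {pid} has no displacements")
        best = max(ds, key=lambda d: (d.min_reliability(), -d.substack))
        projected[pid] = [best]
    return ProjectDescriptor(
        grid=project.grid,
        substack_count=project.substack_count,
        stage="projected",
        pair_displacements=projected,
    )


def threshold_displacements(project: ProjectDescriptor, threshold: float) -> ProjectDescriptor:
    """Zero out displacements whose worst-axis reliability is below the
    threshold, falling back to the nominal alignment for those pairs."""
    if project.stage != "projected":
        raise ValueError(f"expected stage 'projected', got {project.stage!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    out = {}
    for pid, (d,) in project.pair_displacements.items():
        if d.min_reliability() < threshold:
            d = replace(d, offset=(0, 0, 0), reliability=(0.0, 0.0, 0.0))
        out[pid] = [d]
    return ProjectDescriptor(
        grid=project.grid,
        substack_count=project.substack_count,
        stage="thresholded",
        pair_displacements=out,
    )


def _max_spanning_tree(m: int, n: int, weights: dict[str, float]) -> set[str]:
    """Deterministic maximum-weight spanning tree over the grid adjacency
    graph (Kruskal; ties broken by canonical pair order)."""
    order = {pid: i for i, pid in enumerate(pair_ids(m, n))}
    edges = sorted(weights, key=lambda pid: (-weights[pid], order[pid]))
    parent = {(r, c): (r, c) for r in range(m) for c in range(n)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: set[str] = set()
    for pid in edges:
        a, b = pair_tiles(pid)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add(pid)
            if len(tree) == m * n - 1:
                break
    return tree


def place_tiles(project: ProjectDescriptor) -> tuple[ProjectDescriptor, PlacementResult]:
    """Assign absolute (z, y, x) positions to all tiles.

    Edges are weighted by worst-axis reliability; positions propagate from
    the anchor tile (0, 0) at the origin along the maximum-reliability
    spanning tree as nominal offset + computed correction.
    """
    if project.stage != "thresholded":
        raise ValueError(f"expected stage 'thresholded', got {project.stage!r}")
    grid = project.grid
    m, n = grid.m, grid.n
    disp = {pid: ds[0] for pid, ds in project.pair_displacements.items()}
    weights = {pid: d.min_reliability() for pid, d in disp.items()}
    tree = _max_spanning_tree(m, n, weights)

    adj: dict[tuple[int, int], list[tuple[tuple[int, int], str, int]]] = {
        (r, c): [] for r in range(m) for c in range(n)
    }
    for pid in tree:
        a, b = pair_tiles(pid)
        adj[a].append((b, pid, +1))
        adj[b].append((a, pid, -1))

    positions = np.zeros((m, n, 3), dtype=np.int64)
    seen = {(0, 0)}
    queue = [(0, 0)]
    while queue:
        node = queue.pop(0)
        for other, pid, sign in sorted(adj[node], key=lambda e: e[0]):
            if other in seen:
                continue
            rel = np.asarray(nominal_relative_offset(pid, grid)) + np.asarray(disp[pid].offset)
            positions[other] = positions[node] + sign * rel
            seen.add(other)
            queue.append(other)
    assert len(seen) == m * n  # grid graph is connected

    placed = ProjectDescriptor(
        grid=grid,
        substack_count=project.substack_count,
        stage="placed",
        pair_displacements=project.pair_displacements,
        absolute_positions=positions,
    )
    return placed, PlacementResult(absolute_positions=positions, used_pairs=tree)
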