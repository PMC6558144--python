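"""Parallel task dispatcher and pipeline orchestration.

The dataset is divided into N independent tasks with N >= P (default
N = 2P); P worker processes are started, each task writes only its own
output files, and remaining tasks are dispatched FIFO as workers free up.
When all tasks have run, the per-task outputs are merged into the same
result a single sequential run would produce.  A failed task never aborts
running work: the run drains, then reports every failure with its task
identity.

Workers are plain processes executing the same single-task entry points
used serially, so there is no shared mutable state and no threading inside
tasks.
"""

from __future__ import annotations

import os
import sys
import time
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import dataclass, field

from . import mip_ncc, placement
from .partitioner import AlignmentTask, plan_alignment_tasks
from .volume_model import (
    ProjectDescriptor,
    load_fragment,
    save_fragment,
)


class TaskFailureError(RuntimeError):
    """One or more tasks failed; carries (task_id, exception) pairs."""

    def __init__(self, failures: list[tuple[str, BaseException]]):
        self.failures = failures
        ids = ", ".join(tid for tid, _ in failures)
        super().__init__(f"{len(failures)} task(s) failed: {ids}")


@dataclass
class TaskPlan:
    """An ordered list of independent task specs plus the worker count."""

    tasks: list[dict]
    P: int

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("worker count P must be >= 1")
        ids = [t["task_id"] for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ValueError("task ids must be unique")

    @property
    def N(self) -> int:
        return len(self.tasks)


def _log(stream, task_id: str, event: str) -> None:
    if stream is not None:
        stream.write(f"{time.time():.6f}\t{task_id}\t{event}\n")
        stream.flush()


def run_parallel(plan: TaskPlan, worker, context: dict | None = None, log_stream=None):
    """Execute every task exactly once on P workers, FIFO backfill.

    ``worker(task, context)`` must be a picklable top-level callable whose
    only side effects are its own output files.  Results are returned in
    plan order.  With P = 1 the tasks run serially in-process, which is
    bitwise equivalent to any parallel schedule by the independence
    contract.
    """
    context = context or {}
    P = min(plan.P, max(plan.N, 1))
    if P <= 1:
        serial: list[object] = []
        failures: list[tuple[str, BaseException]] = []
        for task in plan.tasks:
            _log(log_stream, task["task_id"], "start")
            try:
                serial.append(worker(task, context))
            except Exception as exc:
                _log(log_stream, task["task_id"], f"failed: {exc}")
                failures.append((task["task_id"], exc))
            else:
                _log(log_stream, task["task_id"], "done")
        if failures:
            raise TaskFailureError(failures)
        return serial

    results: dict[int, object] = {}
    failures: list[tuple[str, BaseException]] = []
    with ProcessPoolExecutor(max_workers=P) as pool:
        # Submitting in plan order gives FIFO dispatch: the first P tasks
        # start immediately, the rest are picked up as workers complete.
        futures = {}
        for i, task in enumerate(plan.tasks):
            _log(log_stream, task["task_id"], "submit")
            futures[pool.submit(worker, task, context)] = i
        pending = set(futures)
        while pending:
            done, pending = wait(pending, return_when=FIRST_COMPLETED)
            for fut in done:
                i = futures[fut]
                tid = plan.tasks[i]["task_id"]
                exc = fut.exception()
                if exc is not None:
                    _log(log_stream, tid, f"failed: {exc}")
                    failures.append((tid, exc))
                else:
                    _log(log_stream, tid, "done")
                    results[i] = fut.result()
    if failures:
        failures.sort(key=lambda f: f[0])
        raise TaskFailureError(failures)
    return [results[i] for i in range(plan.N)]


# ---------------------------------------------------------------------------
# Alignment orchestration
# ---------------------------------------------------------------------------


def _fragment_path(workdir: str, task: AlignmentTask) -> str:
    s0, s1 = task.substack_range
    return os.path.join(workdir, f"frag_{task.block.block_id()}_s{s0}-{s1}.xml")


def _alignment_worker(task: dict, context: dict) -> str:
    project = context["project"]
    at: AlignmentTask = task["alignment_task"]
    fragment = mip_ncc.align_block(
        project, at.block, substack_range=at.substack_range, radii=context["radii"]
    )
    path = _fragment_path(context["workdir"], at)
    save_fragment(fragment, path)
    return path


def run_alignment(
    project: ProjectDescriptor,
    radii: tuple[int, int, int],
    n_tasks: int | None = None,
    workers: int = 1,
    workdir: str = ".voxstitch_fragments",
    log_stream=None,
) -> ProjectDescriptor:
    """Plan, dispatch and merge the full pairwise-alignment step.

    Returns a stage=aligned descriptor identical to a single whole-grid
    run, for any task plan and worker count.
    """
    grid = project.grid
    S = project.substack_count
    if n_tasks is None:
        n_tasks = 2 * workers
    atasks = plan_alignment_tasks(grid.m, grid.n, S, n_tasks)
    os.makedirs(workdir, exist_ok=True)
    plan = TaskPlan(
        tasks=[
            {
                "kind": "alignment",
                "task_id": f"align_{at.block.block_id()}_s{at.substack_range[0]}-{at.substack_range[1]}",
                "alignment_task": at,
            }
            for at in atasks
        ],
        P=workers,
    )
    paths = run_parallel(
        plan,
        _alignment_worker,
        context={"project": project, "radii": radii, "workdir": workdir},
        log_stream=log_stream,
    )
    fragments = [load_fragment(p) for p in paths]
    return placement.merge_alignments(project, fragments)


def run_pipeline(
    project: ProjectDescriptor,
    radii: tuple[int, int, int] = (4, 4, 4),
    threshold: float = 0.0,
    tile_size: tuple[int, int, int] = (64, 64, 64),
    n_levels: int = 0,
    out_format: str = "slice_series",
    blending: str = "linear_ramp",
    out_dir: str = "fused",
    n_tasks: int | None = None,
    workers: int = 1,
    workdir: str = ".voxstitch_fragments",
    log_stream=None,
) -> tuple[ProjectDescriptor, dict]:
    """Full pipeline: align -> project -> threshold -> place -> fuse."""
    from . import fusion

    aligned = run_alignment(
        project, radii, n_tasks=n_tasks, workers=workers, workdir=workdir,
        log_stream=log_stream,
    )
    projected = placement.project_displacements(aligned)
    thresholded = placement.threshold_displacements(projected, threshold)
    placed, _ = placement.place_tiles(thresholded)
    spec = fusion.make_fusion_spec(
        placed, tile_size=tile_size, n_levels=n_levels,
        out_format=out_format, blending=blending,
    )
    manifest = fusion.fuse_dataset(
        placed,
        spec,
        out_dir,
        n_tasks=n_tasks if n_tasks is not None else 2 * workers,
        workers=workers,
    )
    return placed, manifest
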