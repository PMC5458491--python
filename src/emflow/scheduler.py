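"""On-the-fly processing: scheduling jobs and running them in cycles.

During data acquisition, new movies keep arriving in the project while
processing is already under way.  The mechanism here is deliberately
simple: jobs are created with status *scheduled* (their expected output
nodes are registered — and browsable — before any file exists), then a
:class:`Schedule` cycles through an ordered job list a fixed number of
times with a minimum start-to-start interval between cycles.  On the
first cycle each job is run; on later cycles it is *continued*, so
per-item stages act only on items that have not been processed before.
Within a cycle, jobs run strictly in list order and each job's output
files are awaited before the next job starts, so downstream stages see
the same cycle's upstream results.

Time is injected: a :class:`WallClock` for real runs, a
:class:`SimulatedClock` for deterministic tests of an inherently
temporal feature.  Independent schedules (e.g. a fast pre-processing
loop and a slow 2D-classification loop) may run concurrently over one
project; pipeline writes are serialised by the project lock and the
persisted file is always a consistent snapshot.
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .errors import PipelineError, ValidationError
from .execution import (RUN_JOB, ExecutorSpec, _executor_for, continue_job,
                        pending_items, run_job, write_run_job)
from .execution import poll as poll_status
from .pipeline import STATUS_FINISHED, STATUS_SCHEDULED, Process
from .project import Project
from .registry import JobType
from .star import StarBlock, StarDocument


class WallClock:
    """Real time."""

    def now(self) -> float:
        import time

        return time.monotonic()

    def sleep(self, seconds: float) -> None:
        import time

        if seconds > 0:
            time.sleep(seconds)


class SimulatedClock:
    """Deterministic clock for single-threaded tests: sleeping advances time."""

    def __init__(self, start: float = 0.0):
        self._now = float(start)

    def now(self) -> float:
        return self._now

    def sleep(self, seconds: float) -> None:
        if seconds > 0:
            self._now += seconds


@dataclass
class Schedule:
    """An ordered list of scheduled jobs plus loop count and minimum interval.

    ``min_wait`` is measured start-to-start between consecutive cycles: a
    cycle that completes early sleeps out the remainder before the next
    one begins.
    """

    name: str
    job_ids: list[int]
    n_cycles: int = 1
    min_wait: float = 0.0

    def __post_init__(self) -> None:
        if not self.job_ids:
            raise ValidationError("schedule needs at least one job")
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if self.min_wait < 0:
            raise ValidationError("min_wait must be >= 0")


@dataclass
class TraceEntry:
    cycle: int
    process_id: int
    items_processed: int  # -1 for non-per-item jobs
    t_start: float
    t_end: float


def schedule_job(
    project: Project,
    jt: JobType,
    params: dict[str, str] | None = None,
    inputs: list[str] | None = None,
    outputs: list[tuple[str, int]] | None = None,
) -> Process:
    """Create a job with status *scheduled* for later (possibly looped) execution.

    Inputs may reference the not-yet-existing outputs of other scheduled
    jobs; the new job's own expected outputs are registered in the
    pipeline and in the ``.Nodes/`` browse directory immediately.
    """
    with project.lock:
        proc = project.pipeline.add_job(
            jt, params=params, inputs=inputs, outputs=outputs,
            status=STATUS_SCHEDULED,
        )
        project.save()
        project.pipeline.rebuild_nodes_directory(project.root)
    return proc


def edit_scheduled_job(project: Project, id: int, new_params: dict[str, str]) -> None:
    """Replace the parameters of a scheduled job (or of a looped job between
    cycles).  Finished jobs are immutable; a written ``run.job`` is updated
    so the next cycle sees the new values."""
    proc = project.pipeline.process(id)
    if proc.status == STATUS_FINISHED:
        raise PipelineError(f"job {id} is finished; its parameters are frozen")
    for k, v in new_params.items():
        if k in ("classes", "iterations", "n_frames") and int(v) <= 0:
            raise ValidationError(f"parameter {k} must be positive, got {v}")
    with project.lock:
        proc.params = dict(new_params)
        project.save()
        run_job_path = project.job_dir(id) / RUN_JOB
        if run_job_path.parent.is_dir():
            write_run_job(run_job_path, proc.job_type.name, proc.params)


def _wait_for_files(project: Project, paths: list[Path], clock,
                    poll_interval: float, timeout: Optional[float]) -> None:
    start = clock.now()
    while not all(p.exists() for p in paths):
        if timeout is not None and clock.now() - start > timeout:
            raise PipelineError(
                f"timed out waiting for {[str(p) for p in paths if not p.exists()]}")
        clock.sleep(poll_interval)


def run_schedule(
    project: Project,
    schedule: Schedule,
    clock=None,
    executors: dict[str, ExecutorSpec] | None = None,
    poll_interval: float = 0.05,
    timeout: Optional[float] = None,
    before_cycle: Optional[Callable[[int, float], None]] = None,
) -> list[TraceEntry]:
    """Cycle through the schedule's jobs, returning an execution trace.

    ``before_cycle(cycle, now)`` is an optional hook invoked at each cycle
    start (the acquisition simulator uses it to deliver movies that are
    due).  ``timeout`` bounds each wait for a job's output files; by
    default the schedule blocks indefinitely, since the engine has no
    other sensor than the file system.
    """
    clock = clock or WallClock()
    for jid in schedule.job_ids:
        project.pipeline.process(jid)  # existence check
    trace: list[TraceEntry] = []
    for cycle in range(1, schedule.n_cycles + 1):
        cycle_start = clock.now()
        if before_cycle is not None:
            before_cycle(cycle, cycle_start)
        for jid in schedule.job_ids:
            proc = project.pipeline.process(jid)
            spec = executors.get(proc.job_type.name) if executors else None
            # inputs may come from another (slower) schedule: block and poll
            in_paths = [project.abspath(n.path)
                        for n in project.pipeline.inputs_of(jid)]
            _wait_for_files(project, in_paths, clock, poll_interval, timeout)
            t0 = clock.now()
            real = _executor_for(project, proc, spec)
            if cycle == 1 and proc.status == STATUS_SCHEDULED:
                n_items = (len(pending_items(project, proc, real))
                           if real.per_item else -1)
                run_job(project, proc, real)
            else:
                n_items = continue_job(project, proc, real)
            out_paths = [project.abspath(n.path)
                         for n in project.pipeline.outputs_of(jid)]
            _wait_for_files(project, out_paths, clock, poll_interval, timeout)
            poll_status(project)
            trace.append(TraceEntry(cycle, jid, n_items, t0, clock.now()))
        if cycle < schedule.n_cycles:
            elapsed = clock.now() - cycle_start
            if elapsed < schedule.min_wait:
                clock.sleep(schedule.min_wait - elapsed)
    return trace


def run_schedules_concurrently(
    project: Project,
    schedules: list[Schedule],
    clock=None,
    executors: dict[str, ExecutorSpec] | None = None,
    poll_interval: float = 0.05,
    timeout: Optional[float] = None,
    before_cycles: dict[str, Callable[[int, float], None]] | None = None,
) -> dict[str, list[TraceEntry]]:
    """Run several schedules over one project in parallel threads.

    Job lists must be disjoint.  All pipeline mutations go through the
    project lock, so the persisted pipeline is always one consistent
    interleaving of the loops' updates.  ``before_cycles`` optionally
    maps schedule names to per-cycle hooks (e.g. acquisition delivery).
    """
    seen: set[int] = set()
    for s in schedules:
        overlap = seen & set(s.job_ids)
        if overlap:
            raise ValidationError(f"schedules overlap on job ids {sorted(overlap)}")
        seen |= set(s.job_ids)
    clock = clock or WallClock()
    traces: dict[str, list[TraceEntry]] = {}
    errors: dict[str, BaseException] = {}

    def _worker(s: Schedule) -> None:
        try:
            hook = (before_cycles or {}).get(s.name)
            traces[s.name] = run_schedule(
                project, s, clock, executors, poll_interval, timeout,
                before_cycle=hook)
        except BaseException as exc:  # surfaced after join
            errors[s.name] = exc

    threads = [threading.Thread(target=_worker, args=(s,), daemon=True)
               for s in schedules]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if errors:
        name, exc = next(iter(errors.items()))
        raise PipelineError(f"schedule {name!r} failed: {exc!r}") from exc
    return traces


def trace_to_star(traces: dict[str, list[TraceEntry]]) -> StarDocument:
    """Serialise execution traces, one loop block per schedule."""
    doc = StarDocument()
    for name, entries in traces.items():
        doc.add(f"schedule_trace_{name}", StarBlock.from_table(
            ["emflowCycle", "emflowProcessId", "emflowItemsProcessed",
             "emflowStart", "emflowEnd"],
            [[str(e.cycle), str(e.process_id), str(e.items_processed),
              f"{e.t_start:.6f}", f"{e.t_end:.6f}"] for e in entries],
        ))
    return doc
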