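"""Job lifecycle: directory creation, bookkeeping files, executor dispatch,
and status transitions driven purely by output-file detection.

The engine deliberately does not retain control over running work: it
launches an executor, then its only sensor is the file system.  A job is
*finished* exactly when every registered output node file exists on
disk (:func:`poll`); there is no kill operation and no process-id
tracking.  An executor that raises leaves the job in *running* — the
error is logged to ``note.txt`` and the job can be continued or marked
as finished by hand, just as when an external program dies on a
cluster.

Continuation semantics depend on the job type's continuation mode:

* ``per-item-skip`` (motion correction, CTF estimation, picking,
  extraction, movie refinement) — the executor is re-invoked with only
  the input items whose expected per-item output files are absent, so
  already-processed micrographs are skipped;
* ``optimiser-restart`` (2D/3D classification, auto-refinement) — the
  executor is handed the newest ``run_it###_optimiser.star`` checkpoint
  in the job directory and resumes from it;
* ``none`` — the executor is simply re-invoked in full.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .errors import PipelineError, ValidationError
from .pipeline import STATUS_FINISHED, STATUS_RUNNING, STATUS_SCHEDULED, Process
from .project import Project

RUN_JOB = "run.job"
NOTE_TXT = "note.txt"

_CKPT_RE = re.compile(r"^run_it(\d{3,})_optimiser\.star$")
_ITER_FILE_RE = re.compile(r"^(run_it)(\d{3,})(_.+)$")


@dataclass
class ExecContext:
    """Everything an executor callable gets to see."""

    project: Project
    process: Process
    job_dir: Path  # absolute
    params: dict[str, str]
    inputs: list[Path]  # absolute resolved input node paths
    items: Optional[list[str]] = None  # pending items for per-item executors
    checkpoint: Optional[Path] = None  # optimiser restart point

    def input_rel(self) -> list[str]:
        return [str(p.relative_to(self.project.root)) for p in self.inputs]


@dataclass
class ExecutorSpec:
    """Contract between the engine and a stage implementation.

    ``run`` must create the registered output node files; it never
    writes outside the job directory except to paths that are its own
    registered output nodes.  Per-item executors additionally declare
    how to enumerate input items and which files each item yields, which
    is what makes skip-on-continue possible.
    """

    job_type: str
    run: Callable[[ExecContext], None]
    per_item: bool = False
    list_items: Optional[Callable[[ExecContext], list[str]]] = None
    item_outputs: Optional[Callable[[ExecContext, str], list[Path]]] = None
    extra: dict = field(default_factory=dict)


# -- run.job ---------------------------------------------------------------


def write_run_job(path: Path, job_type_name: str, params: dict[str, str]) -> None:
    lines = [f"job_type == {job_type_name}"]
    for k, v in params.items():
        if "\n" in k or "\n" in v:
            raise ValidationError("run.job labels/values must be single-line")
        lines.append(f"{k} == {v}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_run_job(path: Path) -> tuple[str, dict[str, str]]:
    """Reload a job's type name and parameter mapping from its run.job."""
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or " == " not in lines[0]:
        raise PipelineError(f"malformed run.job at {path}")
    _, jt_name = lines[0].split(" == ", 1)
    params: dict[str, str] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        if " == " not in ln:
            raise PipelineError(f"malformed run.job line {ln!r} at {path}")
        k, v = ln.split(" == ", 1)
        params[k] = v
    return jt_name, params


def _note(job_dir: Path, text: str) -> None:
    with open(job_dir / NOTE_TXT, "a", encoding="utf-8") as fh:
        fh.write(text)


# -- executor plumbing -----------------------------------------------------


def _executor_for(project: Project, process: Process,
                  executor: ExecutorSpec | None) -> ExecutorSpec:
    if executor is not None:
        return executor
    name = process.job_type.name
    try:
        return project.executors[name]  # type: ignore[return-value]
    except KeyError:
        raise PipelineError(f"no executor registered for job type {name!r}") from None


def _make_context(project: Project, process: Process) -> ExecContext:
    job_dir = project.job_dir(process.id)
    inputs = [project.abspath(n.path) for n in project.pipeline.inputs_of(process.id)]
    return ExecContext(project=project, process=process, job_dir=job_dir,
                       params=process.params, inputs=inputs)


def pending_items(project: Project, process: Process,
                  executor: ExecutorSpec | None = None) -> list[str]:
    """Input items whose expected per-item output files are not all on disk."""
    spec = _executor_for(project, process, executor)
    if not spec.per_item:
        raise ValidationError(f"{spec.job_type!r} is not a per-item job type")
    ctx = _make_context(project, process)
    out = []
    for item in spec.list_items(ctx):
        files = spec.item_outputs(ctx, item)
        if not all(f.exists() for f in files):
            out.append(item)
    return out


def _invoke(spec: ExecutorSpec, ctx: ExecContext) -> None:
    try:
        spec.run(ctx)
    except Exception as exc:  # engine keeps watching files; job stays running
        _note(ctx.job_dir, f"ERROR: executor raised: {exc!r}\n")


def run_job(project: Project, process: Process,
            executor: ExecutorSpec | None = None) -> None:
    """Execute a scheduled (or newly created) job.

    Creates the numbered output directory, writes ``run.job`` (the exact
    parameter mapping) and ``note.txt`` (ISO-8601 timestamp plus the
    command line), flips the status to *running*, persists the pipeline,
    and invokes the executor.  Control is not retained afterwards:
    completion is observed by :func:`poll`.
    """
    if process.status == STATUS_FINISHED:
        raise PipelineError(f"job {process.id} already finished")
    spec = _executor_for(project, process, executor)
    job_dir = project.job_dir(process.id)
    job_dir.mkdir(parents=True, exist_ok=True)
    write_run_job(job_dir / RUN_JOB, process.job_type.name, process.params)
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    cmd = f"emflow job run {process.id}"
    _note(job_dir, f"{stamp}\n++++ with the following command(s):\n{cmd}\n")
    with project.lock:
        process.status = STATUS_RUNNING
        project.save()
    ctx = _make_context(project, process)
    if spec.per_item:
        ctx.items = pending_items(project, process, spec)
    _invoke(spec, ctx)


def poll(project: Project) -> list[tuple[int, str, str]]:
    """Flip every running job whose output node files all exist to finished.

    Returns the list of ``(process id, old status, new status)``
    transitions; repeated polling is idempotent.
    """
    transitions: list[tuple[int, str, str]] = []
    with project.lock:
        for proc in project.pipeline.processes:
            if proc.status != STATUS_RUNNING:
                continue
            outs = project.pipeline.outputs_of(proc.id)
            if outs and all(project.abspath(n.path).exists() for n in outs):
                proc.status = STATUS_FINISHED
                transitions.append((proc.id, STATUS_RUNNING, STATUS_FINISHED))
        if transitions:
            project.save()
    return transitions


def latest_checkpoint(job_dir: Path) -> Path | None:
    """Newest ``run_it###_optimiser.star`` in *job_dir* (highest iteration)."""
    best, best_it = None, -1
    if job_dir.is_dir():
        for f in job_dir.iterdir():
            m = _CKPT_RE.match(f.name)
            if m and int(m.group(1)) > best_it:
                best, best_it = f, int(m.group(1))
    return best


def continue_job(project: Project, process: Process,
                 executor: ExecutorSpec | None = None) -> int:
    """Continue a job according to its continuation mode.

    Returns the number of items handed to the executor for per-item
    types (0 means the executor was not invoked at all); -1 otherwise.
    """
    spec = _executor_for(project, process, executor)
    mode = process.job_type.continuation_mode
    job_dir = project.job_dir(process.id)
    ctx = _make_context(project, process)
    if mode == "per-item-skip" and spec.per_item:
        items = pending_items(project, process, spec)
        if not items:
            return 0
        ctx.items = items
        with project.lock:
            process.status = STATUS_RUNNING
            project.save()
        _note(job_dir, f"continued with {len(items)} new item(s)\n")
        _invoke(spec, ctx)
        return len(items)
    if mode == "optimiser-restart":
        ckpt = latest_checkpoint(job_dir)
        if ckpt is None:
            raise PipelineError(
                f"job {process.id} has no _optimiser.star checkpoint to continue from")
        ctx.checkpoint = ckpt
        with project.lock:
            process.status = STATUS_RUNNING
            project.save()
        _note(job_dir, f"continued from checkpoint {ckpt.name}\n")
        _invoke(spec, ctx)
        return -1
    # mode "none": plain re-invocation
    with project.lock:
        process.status = STATUS_RUNNING
        project.save()
    _invoke(spec, ctx)
    return -1


def mark_as_finished(project: Project, process: Process) -> None:
    """Force a running job to finished without waiting for its files.

    For optimiser-restart job types the registered expected output nodes
    are re-pointed at the files of the last finished iteration present
    on disk (a stalled 25-iteration classification stopped at iteration
    7 ends up with ``run_it007_*`` nodes); an error is raised if no
    iteration ever completed.
    """
    if process.status != STATUS_RUNNING:
        raise PipelineError(
            f"job {process.id} is {process.status}, not running")
    pl = project.pipeline
    if process.job_type.continuation_mode == "optimiser-restart":
        ckpt = latest_checkpoint(project.job_dir(process.id))
        if ckpt is None:
            raise PipelineError(
                f"job {process.id} has no finished iteration to fall back to")
        newest = _CKPT_RE.match(ckpt.name).group(1)
        with project.lock:
            for node in pl.outputs_of(process.id):
                name = Path(node.path).name
                m = _ITER_FILE_RE.match(name)
                if not m or m.group(2) == newest:
                    continue
                new_path = node.path[: -len(name)] + m.group(1) + newest + m.group(3)
                old_path = node.path
                node.path = new_path
                pl.output_edges.discard((process.id, old_path))
                pl.output_edges.add((process.id, new_path))
                for (npath, pid) in list(pl.input_edges):
                    if npath == old_path:
                        pl.input_edges.discard((npath, pid))
                        pl.input_edges.add((new_path, pid))
            process.status = STATUS_FINISHED
            project.save()
    else:
        with project.lock:
            process.status = STATUS_FINISHED
            project.save()
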