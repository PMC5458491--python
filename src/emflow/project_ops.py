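"""Disk management, procedure exchange and flowcharts.

Deleting a job moves its directory (and those of all its descendants —
dangling consumers would break the DAG) into ``Trash/``, mirroring the
original layout so that undelete is a plain move back.  Alongside each
trashed directory a ``.fragment.star`` sidecar records the removed
process, its parameters, alias, nodes and edges, letting undelete
re-insert everything with the original ids.  Cleaning keeps only the
files the pipeline needs — registered output nodes, ``run.job``,
``note.txt``, ``logfile.pdf`` and the newest optimiser-checkpoint
iteration — and trashes the rest.  ``Empty Trash`` frees the space for
good.

Scheduled jobs can be exported as a reusable *procedure*: a bundle
directory with one generically named subdirectory per job (``Extract_1``
instead of ``Extract/job005``) and an ``exported.star`` index holding
job types and intra-bundle wiring.  Bundles contain no original job
numbers and no absolute paths, so they can be imported into any
project, where the jobs are re-instantiated as scheduled processes with
fresh consecutive ids; inputs that were not produced inside the bundle
become placeholder Import jobs.

Flowcharts of a job's ancestry are emitted as deterministic DOT text —
a standard, vector-renderable graph-description format.
"""

from __future__ import annotations

import os
import re
import shutil
from dataclasses import dataclass
from pathlib import Path

from . import registry
from .errors import PipelineError, ValidationError
from .execution import _ITER_FILE_RE, latest_checkpoint, read_run_job, write_run_job
from .pipeline import STATUS_FINISHED, STATUS_RUNNING, STATUS_SCHEDULED, Node, Process
from .project import Project
from .star import StarBlock, StarDocument, read_star, write_star

TRASH_DIR = "Trash"
FRAGMENT_SUFFIX = ".fragment.star"
EXPORTED_STAR = "exported.star"

_KEEP_ALWAYS = {"run.job", "note.txt", "logfile.pdf"}


@dataclass
class TrashEntry:
    original_dir: str  # project-relative job directory, with trailing /
    trashed_dir: str  # path under Trash/
    process_id: int


# -- delete / undelete / clean / empty ------------------------------------


def _fragment_path(project: Project, job_dir: str) -> Path:
    # Trash/Class2D/job010.fragment.star, sibling of the trashed directory
    return project.root / TRASH_DIR / (job_dir.rstrip("/") + FRAGMENT_SUFFIX)


def _write_fragment(project: Project, proc: Process) -> None:
    pl = project.pipeline
    doc = StarDocument()
    doc.add("fragment_process", StarBlock.from_pairs({
        "emflowProcessId": str(proc.id),
        "emflowProcessTypeId": str(proc.type_id),
        "emflowProcessStatus": proc.status,
        "emflowProcessAlias": proc.alias or "None",
    }))
    doc.add("fragment_params", StarBlock.from_table(
        ["emflowParamLabel", "emflowParamValue"],
        [[k, v] for k, v in proc.params.items()]))
    doc.add("fragment_nodes", StarBlock.from_table(
        ["emflowNodePath", "emflowNodeTypeId"],
        [[n.path, str(n.type_id)] for n in pl.outputs_of(proc.id)]))
    doc.add("fragment_input_edges", StarBlock.from_table(
        ["emflowEdgeFromNode"],
        [[npath] for npath, pid in sorted(pl.input_edges) if pid == proc.id]))
    path = _fragment_path(project, pl.job_dir(proc.id))
    path.parent.mkdir(parents=True, exist_ok=True)
    write_star(doc, path)


def delete_job(project: Project, id: int, cascade: bool = True) -> list[TrashEntry]:
    """Remove a job — and, by default, all jobs downstream of it — from the
    pipeline, moving their directories into ``Trash/``.

    With ``cascade=False`` the call is refused whenever the job has
    descendants, instead of silently orphaning them.
    """
    pl = project.pipeline
    proc = pl.process(id)
    doomed = {id} | pl.descendants(id)
    if not cascade and len(doomed) > 1:
        raise ValidationError(
            f"job {id} has descendants {sorted(doomed - {id})}; "
            "delete them first or allow cascading")
    entries: list[TrashEntry] = []
    with project.lock:
        for pid in sorted(doomed):
            p = pl.process(pid)
            job_dir = pl.job_dir(pid)
            _write_fragment(project, p)
            src = project.root / job_dir
            dst = project.root / TRASH_DIR / job_dir
            if src.exists():
                dst.parent.mkdir(parents=True, exist_ok=True)
                if dst.exists():
                    shutil.rmtree(dst)
                shutil.move(str(src), str(dst))
            if p.alias:
                link = src.parent / p.alias
                if link.is_symlink():
                    link.unlink()
            entries.append(TrashEntry(job_dir, f"{TRASH_DIR}/{job_dir}", pid))
        # drop graph records
        out_paths = {n.path for pid in doomed for n in pl.outputs_of(pid)}
        pl.processes = [p for p in pl.processes if p.id not in doomed]
        pl.nodes = [n for n in pl.nodes if n.path not in out_paths]
        pl.input_edges = {(np, pid) for np, pid in pl.input_edges
                          if pid not in doomed and np not in out_paths}
        pl.output_edges = {(pid, np) for pid, np in pl.output_edges
                           if pid not in doomed}
        project.save()
        pl.rebuild_nodes_directory(project.root)
    return entries


def undelete_job(project: Project, id: int) -> None:
    """Restore a trashed job: directory moved back byte-identically and the
    process re-inserted with its original id, alias and edges."""
    trash_root = project.root / TRASH_DIR
    frag_path = None
    for p in sorted(trash_root.rglob(f"job{id:03d}{FRAGMENT_SUFFIX}")):
        frag_path = p
        break
    if frag_path is None:
        raise PipelineError(f"no trashed job {id} found under {TRASH_DIR}/")
    doc = read_star(frag_path)
    gen = doc["fragment_process"].pairs
    pid = int(gen["emflowProcessId"])
    proc = Process(
        id=pid,
        type_id=int(gen["emflowProcessTypeId"]),
        status=gen["emflowProcessStatus"],
        alias=None if gen["emflowProcessAlias"] == "None" else gen["emflowProcessAlias"],
        params={k: v for k, v in doc["fragment_params"].rows},
    )
    pl = project.pipeline
    if pl.has_process(pid):
        raise PipelineError(f"process id {pid} already live in the pipeline")
    job_dir = pl_job_dir = registry.job_type(proc.type_id).dir_prefix + f"job{pid:03d}/"
    src = trash_root / job_dir
    dst = project.root / job_dir
    if dst.exists():
        raise PipelineError(f"live directory {job_dir} already exists")
    with project.lock:
        if src.exists():
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(src), str(dst))
        pl.processes.append(proc)
        pl.processes.sort(key=lambda p: p.id)
        for npath, tid_s in doc["fragment_nodes"].rows:
            if not pl.has_node(npath):
                pl.nodes.append(Node(npath, int(tid_s)))
            pl.output_edges.add((pid, npath))
        for (npath,) in doc["fragment_input_edges"].rows:
            if pl.has_node(npath):
                pl.input_edges.add((npath, pid))
        if proc.alias:
            link = dst.parent / proc.alias
            if not link.is_symlink() and not link.exists():
                link.symlink_to(dst.name)
        frag_path.unlink()
        project.save()
        pl.rebuild_nodes_directory(project.root)


def clean_job(project: Project, id: int) -> list[str]:
    """Trash intermediate files of a finished job, keeping everything the
    pipeline needs: registered output node files, run.job, note.txt,
    logfile.pdf and the newest optimiser-checkpoint iteration set.
    Returns the project-relative paths of the removed files."""
    pl = project.pipeline
    proc = pl.process(id)
    if proc.status == STATUS_RUNNING:
        raise ValidationError(f"refusing to clean running job {id}")
    job_dir = pl.job_dir(id)
    abs_dir = project.root / job_dir
    keep: set[Path] = {abs_dir / name for name in _KEEP_ALWAYS}
    for node in pl.outputs_of(id):
        keep.add(project.abspath(node.path))
    ckpt = latest_checkpoint(abs_dir)
    newest_it = None
    if ckpt is not None:
        newest_it = re.match(r"run_it(\d{3,})_optimiser\.star", ckpt.name).group(1)
    removed: list[str] = []
    with project.lock:
        for f in sorted(abs_dir.rglob("*")):
            if not f.is_file() or f in keep:
                continue
            m = _ITER_FILE_RE.match(f.name)
            if m and newest_it is not None and m.group(2) == newest_it:
                continue  # newest checkpoint set survives
            rel = f.relative_to(project.root)
            dst = project.root / TRASH_DIR / rel
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(f), str(dst))
            removed.append(str(rel))
    return removed


def empty_trash(project: Project) -> int:
    """Permanently remove ``Trash/``, returning the number of bytes freed."""
    trash = project.root / TRASH_DIR
    freed = 0
    if trash.exists():
        for f in trash.rglob("*"):
            if f.is_file() and not f.is_symlink():
                freed += f.stat().st_size
        shutil.rmtree(trash)
    trash.mkdir()
    return freed


def trash_size(project: Project) -> int:
    trash = project.root / TRASH_DIR
    if not trash.exists():
        return 0
    return sum(f.stat().st_size for f in trash.rglob("*")
               if f.is_file() and not f.is_symlink())


# -- export / import -------------------------------------------------------


def _generic_names(pl, job_ids: list[int]) -> dict[int, str]:
    counts: dict[str, int] = {}
    names: dict[int, str] = {}
    for jid in job_ids:
        prefix = pl.process(jid).job_type.dir_prefix.rstrip("/")
        counts[prefix] = counts.get(prefix, 0) + 1
        names[jid] = f"{prefix}_{counts[prefix]}"
    return names


def export_scheduled(project: Project, job_ids: list[int]) -> Path:
    """Write the listed scheduled jobs to a generic ``export<N>/`` bundle.

    Edges between listed jobs are recorded by (producer generic name,
    output filename, consumer generic name); inputs coming from outside
    the list are recorded as named external placeholders.  The original
    pipeline is untouched.
    """
    pl = project.pipeline
    for jid in job_ids:
        if pl.process(jid).status != STATUS_SCHEDULED:
            raise ValidationError(f"job {jid} is not scheduled; only scheduled "
                                  "jobs can be exported")
    names = _generic_names(pl, job_ids)
    listed = set(job_ids)
    n = 1
    while (project.root / f"export{n}").exists():
        n += 1
    bundle = project.root / f"export{n}"
    bundle.mkdir()

    jobs_rows: list[list[str]] = []
    edge_rows: list[list[str]] = []
    ext_rows: list[list[str]] = []
    for jid in job_ids:
        proc = pl.process(jid)
        gname = names[jid]
        (bundle / gname).mkdir()
        write_run_job(bundle / gname / "run.job", proc.job_type.name, proc.params)
        jobs_rows.append([gname, str(proc.type_id)])
        job_dir = pl.job_dir(jid)
        for node in pl.inputs_of(jid):
            producer = pl.producer_of(node.path)
            if producer in listed:
                fname = node.path[len(pl.job_dir(producer)):]
                edge_rows.append([names[producer], fname, gname])
            else:
                ext_rows.append([gname, str(node.type_id),
                                 os.path.basename(node.path)])
    doc = StarDocument()
    doc.add("exported_general", StarBlock.from_pairs({
        "emflowJobCount": str(len(job_ids))}))
    doc.add("exported_jobs", StarBlock.from_table(
        ["emflowGenericName", "emflowJobTypeId"], jobs_rows))
    doc.add("exported_edges", StarBlock.from_table(
        ["emflowFromJob", "emflowOutputFile", "emflowToJob"], edge_rows))
    doc.add("exported_external", StarBlock.from_table(
        ["emflowToJob", "emflowNodeTypeId", "emflowInputName"], ext_rows))
    write_star(doc, bundle / EXPORTED_STAR)
    return bundle


_IMPORT_KIND_BY_TYPE = {0: "movies", 1: "micrographs", 2: "coords",
                        3: "particles", 4: "movie_particles",
                        5: "references_2d", 6: "reference_3d",
                        7: "mask", 10: "half_map"}


def import_jobs(project: Project, bundle: str | Path) -> list[Process]:
    """Re-instantiate a bundle's jobs as scheduled processes with fresh ids.

    Intra-bundle edges are reconnected; each distinct external input gets
    a placeholder Import job so the wiring stays type-correct.  Importing
    the same bundle twice yields two disjoint copies.
    """
    from .scheduler import schedule_job

    bundle = Path(bundle)
    index = bundle / EXPORTED_STAR
    if not index.exists():
        raise PipelineError(f"no {EXPORTED_STAR} in {bundle}")
    doc = read_star(index)
    try:
        jobs = doc["exported_jobs"].rows
        edges = doc["exported_edges"].rows
        externals = doc["exported_external"].rows
    except KeyError as exc:
        raise PipelineError(f"malformed {EXPORTED_STAR}: missing block {exc}") from exc

    # placeholder Import jobs, one per distinct external (type, name)
    placeholder_nodes: dict[tuple[str, str], str] = {}
    for gname, tid_s, input_name in externals:
        key = (tid_s, input_name)
        if key in placeholder_nodes:
            continue
        kind = _IMPORT_KIND_BY_TYPE.get(int(tid_s))
        if kind is None:
            raise PipelineError(f"external input of node type {tid_s} cannot "
                                "be satisfied by an Import placeholder")
        proc = schedule_job(project, registry.job_type("Import"),
                            params={"kind": kind, "placeholder_for": input_name})
        placeholder_nodes[key] = project.pipeline.outputs_of(proc.id)[0].path

    new_procs: list[Process] = []
    by_generic: dict[str, Process] = {}
    for gname, tid_s in jobs:
        jt = registry.job_type(int(tid_s))
        run_job_file = bundle / gname / "run.job"
        if not run_job_file.exists():
            raise PipelineError(f"bundle job {gname!r} has no run.job")
        _, params = read_run_job(run_job_file)
        inputs: list[str] = []
        for from_g, fname, to_g in edges:
            if to_g != gname:
                continue
            producer = by_generic.get(from_g)
            if producer is None:
                raise PipelineError(
                    f"bundle edge {from_g} -> {to_g} references a job listed "
                    "later; bundles must be topologically ordered")
            inputs.append(project.pipeline.job_dir(producer.id) + fname)
        for g2, tid2, input_name in externals:
            if g2 == gname:
                inputs.append(placeholder_nodes[(tid2, input_name)])
        proc = schedule_job(project, jt, params=params, inputs=inputs)
        by_generic[gname] = proc
        new_procs.append(proc)
    return new_procs


# -- flowcharts ------------------------------------------------------------


def flowchart_edges(pl, id: int) -> tuple[set[tuple[int, int]], set[tuple[int, str]]]:
    """Edge sets of the ancestry flowchart of job *id*.

    Returns (job->job edges via any connecting node, producer->terminal-node
    edges), where a terminal node is an output of the subgraph consumed by
    no job inside it.
    """
    subgraph = pl.ancestors(id) | {id}
    job_edges: set[tuple[int, int]] = set()
    for jid in subgraph:
        for parent in pl.parents(jid):
            if parent in subgraph:
                job_edges.add((parent, jid))
    terminal: set[tuple[int, str]] = set()
    for jid in subgraph:
        for node in pl.outputs_of(jid):
            consumers = {pid for npath, pid in pl.input_edges if npath == node.path}
            if not consumers & subgraph:
                terminal.add((jid, node.path))
    return job_edges, terminal


def flowchart(pl, id: int) -> str:
    """Deterministic DOT text for the ancestry of job *id*: one box per job
    (labelled by alias or directory name), one ellipse per terminal node."""
    job_edges, terminal = flowchart_edges(pl, id)
    subgraph = sorted(pl.ancestors(id) | {id})
    lines = ["digraph pipeline {", "  rankdir=TB;", "  node [shape=box];"]
    for jid in subgraph:
        proc = pl.process(jid)
        label = proc.alias or pl.job_dir(jid)
        lines.append(f'  j{jid} [label="{label}"];')
    for jid, npath in sorted(terminal):
        lines.append(f'  "n_{npath}" [shape=ellipse, label="{npath}"];')
    for a, b in sorted(job_edges):
        lines.append(f"  j{a} -> j{b};")
    for jid, npath in sorted(terminal):
        lines.append(f'  j{jid} -> "n_{npath}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
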