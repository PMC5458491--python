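"""The project DAG: processes, nodes, edges, persistence and history queries.

A pipeline is a bipartite directed acyclic graph.  Data nodes (typed
files, identified by their project-relative path) alternate with
processes (numbered job instances).  An *input edge* connects a node to
a process that consumes it; an *output edge* connects a process to a
node it produces.  A node is produced by at most one process but may be
consumed by many, which keeps provenance well defined.

The whole graph is persisted as a single STAR document
(``default_pipeline.star`` in the project root) with one key-value
block for bookkeeping (format version, monotone job counter) and loop
blocks for processes, parameters, nodes and the two edge tables.  Job
ids are never reused, even after deletion: directory names must stay
unique across delete/undelete cycles.

A hidden ``.Nodes/`` directory mirrors the node table partitioned by
node type; it backs type-filtered browsing of available inputs and
includes nodes of scheduled jobs whose files do not exist yet.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import registry
from .errors import PipelineError, ValidationError
from .registry import JobType, validate_io
from .star import StarBlock, StarDocument, read_star, write_star

PIPELINE_STAR = "default_pipeline.star"
NODES_DIR = ".Nodes"
FORMAT_VERSION = "1"

STATUS_SCHEDULED = "scheduled"
STATUS_RUNNING = "running"
STATUS_FINISHED = "finished"

_ALIAS_RE = re.compile(r"^[A-Za-z0-9._-]+$")


@dataclass
class Node:
    path: str  # project-relative, "/" separators
    type_id: int


@dataclass
class Process:
    id: int
    type_id: int
    status: str
    alias: str | None = None
    params: dict[str, str] = field(default_factory=dict)

    @property
    def job_type(self) -> JobType:
        return registry.job_type(self.type_id)


def output_directory(jt: JobType, index: int) -> str:
    """Directory for the *index*-th job of type *jt*, e.g. ``Class2D/job010/``.

    Numbers are zero-padded to at least three digits, widening naturally
    above 999.
    """
    if index < 1:
        raise ValidationError(f"job index must be >= 1, got {index}")
    return f"{jt.dir_prefix}job{index:03d}/"


class Pipeline:
    """In-memory pipeline graph with STAR persistence."""

    def __init__(self) -> None:
        self.processes: list[Process] = []
        self.nodes: list[Node] = []
        self.input_edges: set[tuple[str, int]] = set()  # (node path, process id)
        self.output_edges: set[tuple[int, str]] = set()  # (process id, node path)
        self.job_counter: int = 0  # highest id ever assigned; monotone

    # -- lookups ----------------------------------------------------------

    def process(self, id: int) -> Process:
        for p in self.processes:
            if p.id == id:
                return p
        raise PipelineError(f"unknown process id {id}")

    def has_process(self, id: int) -> bool:
        return any(p.id == id for p in self.processes)

    def node(self, path: str) -> Node:
        for n in self.nodes:
            if n.path == path:
                return n
        raise PipelineError(f"unknown node path {path!r}")

    def has_node(self, path: str) -> bool:
        return any(n.path == path for n in self.nodes)

    def producer_of(self, path: str) -> int | None:
        for pid, npath in self.output_edges:
            if npath == path:
                return pid
        return None

    def outputs_of(self, id: int) -> list[Node]:
        paths = [npath for pid, npath in self.output_edges if pid == id]
        return [self.node(p) for p in sorted(paths)]

    def inputs_of(self, id: int) -> list[Node]:
        paths = [npath for npath, pid in self.input_edges if pid == id]
        return [self.node(p) for p in sorted(paths)]

    def job_dir(self, id: int) -> str:
        p = self.process(id)
        return output_directory(p.job_type, p.id)

    # -- construction -----------------------------------------------------

    def add_job(
        self,
        jt: JobType,
        params: dict[str, str] | None = None,
        inputs: list[str] | None = None,
        outputs: list[tuple[str, int]] | None = None,
        status: str = STATUS_SCHEDULED,
    ) -> Process:
        """Append a new process consuming the given input node paths.

        Input paths must already be registered nodes (they may belong to
        scheduled jobs whose files do not exist yet) and must pass the job
        type's input validation.  The job's expected output nodes — from
        *outputs* (filename-within-job-dir, type id) or the per-type default
        template — are registered immediately along with their edges.
        """
        params = dict(params or {})
        inputs = list(inputs or [])
        in_types = []
        for path in inputs:
            if not self.has_node(path):
                raise PipelineError(f"input path {path!r} is not a pipeline node")
            in_types.append(self.node(path).type_id)
        result = validate_io(jt, in_types)
        if not result.ok:
            raise ValidationError("; ".join(result.violations))

        pid = self.job_counter + 1
        proc = Process(id=pid, type_id=jt.id, status=status, params=params)
        job_dir = output_directory(jt, pid)
        if outputs is None:
            outputs = registry.default_outputs(jt, params)
        self.processes.append(proc)
        self.job_counter = pid
        for path in inputs:
            self.input_edges.add((path, pid))
        for fname, tid in outputs:
            npath = job_dir + fname
            if self.has_node(npath):
                raise PipelineError(f"output node {npath!r} already registered")
            self.nodes.append(Node(npath, tid))
            self.output_edges.add((pid, npath))
        return proc

    def set_alias(self, id: int, alias: str, project_dir: str | os.PathLike | None = None) -> None:
        """Attach a unique human-readable alias; optionally create the symlink.

        The alias becomes a symbolic link next to the numbered directory
        (``Class2D/first-classes -> job010``) when *project_dir* is given.
        """
        if not _ALIAS_RE.match(alias):
            raise ValidationError(
                f"alias {alias!r} may only contain letters, digits, '.', '_', '-'"
            )
        for p in self.processes:
            if p.alias == alias:
                raise ValidationError(f"alias {alias!r} already in use (job {p.id})")
        proc = self.process(id)
        proc.alias = alias
        if project_dir is not None:
            jd = Path(project_dir) / self.job_dir(id)
            link = jd.parent / alias
            if link.is_symlink() or link.exists():
                raise ValidationError(f"path {link} already exists")
            link.symlink_to(jd.name)

    # -- history queries ---------------------------------------------------

    def parents(self, id: int) -> set[int]:
        """Processes whose output nodes feed directly into *id*."""
        self.process(id)
        in_paths = {npath for npath, pid in self.input_edges if pid == id}
        return {pid for pid, npath in self.output_edges if npath in in_paths}

    def children(self, id: int) -> set[int]:
        """Processes directly consuming any output node of *id*."""
        self.process(id)
        out_paths = {npath for pid, npath in self.output_edges if pid == id}
        return {pid for npath, pid in self.input_edges if npath in out_paths}

    def ancestors(self, id: int) -> set[int]:
        """Transitive closure of :meth:`parents`."""
        seen: set[int] = set()
        stack = [id]
        while stack:
            for q in self.parents(stack.pop()):
                if q not in seen:
                    seen.add(q)
                    stack.append(q)
        return seen

    def descendants(self, id: int) -> set[int]:
        """Transitive closure of :meth:`children`."""
        seen: set[int] = set()
        stack = [id]
        while stack:
            for q in self.children(stack.pop()):
                if q not in seen:
                    seen.add(q)
                    stack.append(q)
        return seen

    def to_digraph(self) -> "nx.DiGraph":
        """The bipartite graph with ``('p', id)`` and ``('n', path)`` vertices."""
        g = nx.DiGraph()
        for p in self.processes:
            g.add_node(("p", p.id))
        for n in self.nodes:
            g.add_node(("n", n.path))
        for npath, pid in self.input_edges:
            g.add_edge(("n", npath), ("p", pid))
        for pid, npath in self.output_edges:
            g.add_edge(("p", pid), ("n", npath))
        return g

    def assert_acyclic(self) -> list | None:
        """Return None if acyclic, else one witness cycle as a vertex list."""
        g = self.to_digraph()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None
        return [edge[0] for edge in cycle]

    def check_integrity(self) -> None:
        """Raise PipelineError on dangling edges, duplicates or cycles."""
        paths = [n.path for n in self.nodes]
        if len(set(paths)) != len(paths):
            raise PipelineError("duplicate node paths")
        ids = [p.id for p in self.processes]
        if len(set(ids)) != len(ids):
            raise PipelineError("duplicate process ids")
        known_p, known_n = set(ids), set(paths)
        for npath, pid in self.input_edges:
            if npath not in known_n or pid not in known_p:
                raise PipelineError(f"dangling input edge ({npath!r}, {pid})")
        producers: dict[str, int] = {}
        for pid, npath in self.output_edges:
            if npath not in known_n or pid not in known_p:
                raise PipelineError(f"dangling output edge ({pid}, {npath!r})")
            if npath in producers:
                raise PipelineError(f"node {npath!r} produced by two processes")
            producers[npath] = pid
        cycle = self.assert_acyclic()
        if cycle is not None:
            raise PipelineError(f"pipeline contains a cycle: {cycle}")

    # -- persistence -------------------------------------------------------

    def to_star(self) -> StarDocument:
        doc = StarDocument()
        doc.add("pipeline_general", StarBlock.from_pairs({
            "emflowVersion": FORMAT_VERSION,
            "emflowJobCounter": str(self.job_counter),
        }))
        doc.add("pipeline_processes", StarBlock.from_table(
            ["emflowProcessId", "emflowProcessTypeId",
             "emflowProcessStatus", "emflowProcessAlias"],
            [[str(p.id), str(p.type_id), p.status, p.alias or "None"]
             for p in self.processes],
        ))
        doc.add("pipeline_params", StarBlock.from_table(
            ["emflowParamProcessId", "emflowParamLabel", "emflowParamValue"],
            [[str(p.id), k, v] for p in self.processes for k, v in p.params.items()],
        ))
        doc.add("pipeline_nodes", StarBlock.from_table(
            ["emflowNodePath", "emflowNodeTypeId"],
            [[n.path, str(n.type_id)] for n in self.nodes],
        ))
        doc.add("pipeline_input_edges", StarBlock.from_table(
            ["emflowEdgeFromNode", "emflowEdgeProcessId"],
            [[npath, str(pid)] for npath, pid in sorted(self.input_edges)],
        ))
        doc.add("pipeline_output_edges", StarBlock.from_table(
            ["emflowEdgeProcessId", "emflowEdgeToNode"],
            [[str(pid), npath] for pid, npath in sorted(self.output_edges)],
        ))
        return doc

    @classmethod
    def from_star(cls, doc: StarDocument) -> "Pipeline":
        try:
            p = cls()
            p.job_counter = int(doc["pipeline_general"].pairs["emflowJobCounter"])
            params: dict[int, dict[str, str]] = {}
            for pid_s, k, v in doc["pipeline_params"].rows:
                params.setdefault(int(pid_s), {})[k] = v
            for pid_s, tid_s, status, alias in doc["pipeline_processes"].rows:
                pid = int(pid_s)
                p.processes.append(Process(
                    id=pid, type_id=int(tid_s), status=status,
                    alias=None if alias == "None" else alias,
                    params=params.get(pid, {}),
                ))
            for npath, tid_s in doc["pipeline_nodes"].rows:
                p.nodes.append(Node(npath, int(tid_s)))
            for npath, pid_s in doc["pipeline_input_edges"].rows:
                p.input_edges.add((npath, int(pid_s)))
            for pid_s, npath in doc["pipeline_output_edges"].rows:
                p.output_edges.add((int(pid_s), npath))
        except (KeyError, ValueError) as exc:
            raise PipelineError(f"corrupt pipeline document: {exc}") from exc
        p.check_integrity()
        return p

    def save(self, project_dir: str | os.PathLike) -> None:
        write_star(self.to_star(), Path(project_dir) / PIPELINE_STAR)

    @classmethod
    def load(cls, project_dir: str | os.PathLike) -> "Pipeline":
        path = Path(project_dir) / PIPELINE_STAR
        if not path.exists():
            raise PipelineError(f"no pipeline file at {path}")
        return cls.from_star(read_star(path))

    # -- .Nodes/ browse directory -----------------------------------------

    @staticmethod
    def node_marker_name(path: str) -> str:
        return path.replace("/", "__")

    def rebuild_nodes_directory(self, project_dir: str | os.PathLike) -> None:
        """Delete and re-create ``.Nodes/``: one marker file per node, grouped
        in one subdirectory per node type id.  Nodes of scheduled jobs are
        included even though their files do not exist yet."""
        import shutil

        root = Path(project_dir) / NODES_DIR
        if root.exists():
            shutil.rmtree(root)
        root.mkdir(parents=True)
        for n in self.nodes:
            d = root / str(n.type_id)
            d.mkdir(exist_ok=True)
            (d / self.node_marker_name(n.path)).touch()

    def structurally_equal(self, other: "Pipeline") -> bool:
        return (
            self.job_counter == other.job_counter
            and [(p.id, p.type_id, p.status, p.alias, p.params) for p in self.processes]
            == [(p.id, p.type_id, p.status, p.alias, p.params) for p in other.processes]
            and [(n.path, n.type_id) for n in self.nodes]
            == [(n.path, n.type_id) for n in other.nodes]
            and self.input_edges == other.input_edges
            and self.output_edges == other.output_edges
        )
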