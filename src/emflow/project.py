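"""Project container: a directory on disk plus its pipeline and executors.

All mutating operations funnel through :meth:`Project.save`, which holds
an advisory lock (a thread lock combined with an ``fcntl`` flock on a
lockfile) while atomically rewriting ``default_pipeline.star``.  Because
writes are atomic and serialised, concurrently running schedule loops
always observe a consistent pipeline document.
"""

from __future__ import annotations

import fcntl
import threading
from pathlib import Path

from .errors import PipelineError
from .pipeline import NODES_DIR, PIPELINE_STAR, Pipeline

LOCKFILE = ".emflow.lock"


class ProjectLock:
    """Re-entrant advisory lock covering both threads and processes."""

    def __init__(self, path: Path):
        self._path = path
        self._tlock = threading.RLock()
        self._depth = 0
        self._fh = None

    def __enter__(self):
        self._tlock.acquire()
        if self._depth == 0:
            self._fh = open(self._path, "a")
            fcntl.flock(self._fh.fileno(), fcntl.LOCK_EX)
        self._depth += 1
        return self

    def __exit__(self, *exc):
        self._depth -= 1
        if self._depth == 0 and self._fh is not None:
            fcntl.flock(self._fh.fileno(), fcntl.LOCK_UN)
            self._fh.close()
            self._fh = None
        self._tlock.release()
        return False


class Project:
    """A project directory with its pipeline graph and executor registry."""

    def __init__(self, root: str | Path, pipeline: Pipeline):
        self.root = Path(root)
        self.pipeline = pipeline
        self.lock = ProjectLock(self.root / LOCKFILE)
        # job-type name -> ExecutorSpec; populated by toy_executors or the user
        self.executors: dict[str, object] = {}

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def init(cls, root: str | Path) -> "Project":
        """Create a new empty project (fails if one already exists)."""
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        if (root / PIPELINE_STAR).exists():
            raise PipelineError(f"project already initialised at {root}")
        proj = cls(root, Pipeline())
        proj.save()
        proj.pipeline.rebuild_nodes_directory(root)
        return proj

    @classmethod
    def open(cls, root: str | Path) -> "Project":
        return cls(root, Pipeline.load(root))

    def save(self) -> None:
        with self.lock:
            self.pipeline.save(self.root)

    def reload(self) -> None:
        with self.lock:
            self.pipeline = Pipeline.load(self.root)

    # -- path helpers ------------------------------------------------------

    def abspath(self, rel: str) -> Path:
        return self.root / rel

    def job_dir(self, process_id: int) -> Path:
        return self.root / self.pipeline.job_dir(process_id)

    def nodes_dir(self) -> Path:
        return self.root / NODES_DIR

    def rebuild_nodes_directory(self) -> None:
        with self.lock:
            self.pipeline.rebuild_nodes_directory(self.root)
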