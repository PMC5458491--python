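"""Shared fixtures: random STAR documents, random valid pipelines, and a
small ready-made synthetic project."""

from __future__ import annotations

import string
from pathlib import Path

import numpy as np
import pytest

from emflow.pipeline import Pipeline
from emflow.project import Project
from emflow.registry import JOB_TYPES
from emflow.star import KEY_VALUE, LOOP, StarBlock, StarDocument
from emflow.toy_executors import register_toy_executors

_TOKEN_ALPHABET = string.ascii_letters + string.digits + "._-#'\"_ ()[]{}"


def random_token(rng: np.random.Generator) -> str:
    # tokens holding both quote characters are not representable in the
    # escape-free STAR grammar, so they never occur in machine-written files
    while True:
        n = int(rng.integers(0, 12))
        t = "".join(rng.choice(list(_TOKEN_ALPHABET)) for _ in range(n))
        if '"' not in t or "'" not in t:
            return t


def random_label(rng: np.random.Generator) -> str:
    n = int(rng.integers(1, 12))
    return "".join(rng.choice(list(string.ascii_letters)) for _ in range(n))


def random_star_document(rng: np.random.Generator) -> StarDocument:
    doc = StarDocument()
    for b in range(int(rng.integers(1, 5))):
        name = f"block{b}_{random_label(rng)}"
        if rng.random() < 0.5:
            pairs = {}
            for _ in range(int(rng.integers(0, 6))):
                pairs[random_label(rng)] = random_token(rng)
            doc.add(name, StarBlock.from_pairs(pairs))
        else:
            ncols = int(rng.integers(1, 5))
            cols, seen = [], set()
            while len(cols) < ncols:
                lab = random_label(rng)
                if lab not in seen:
                    seen.add(lab)
                    cols.append(lab)
            rows = [[random_token(rng) for _ in cols]
                    for _ in range(int(rng.integers(0, 8)))]
            doc.add(name, StarBlock.from_table(cols, rows))
    return doc


def random_valid_pipeline(rng: np.random.Generator, n_jobs: int = 8) -> Pipeline:
    """Grow a pipeline by repeatedly adding a type-valid job whose inputs are
    randomly chosen already-registered nodes (Imports bootstrap it)."""
    pl = Pipeline()
    for _ in range(n_jobs):
        candidates = []
        for jt in JOB_TYPES:
            if jt.name == "Import":
                candidates.append((jt, []))
                continue
            avail = [n for n in pl.nodes if n.type_id in jt.input_node_types]
            if avail:
                candidates.append((jt, avail))
        jt, avail = candidates[int(rng.integers(len(candidates)))]
        inputs = []
        if avail:
            k = int(rng.integers(1, min(len(avail), 2) + 1))
            idx = rng.choice(len(avail), size=k, replace=False)
            inputs = [avail[i].path for i in idx]
        pl.add_job(jt, params={"p": str(int(rng.integers(100)))}, inputs=inputs)
    return pl


@pytest.fixture
def project(tmp_path: Path) -> Project:
    proj = Project.init(tmp_path / "proj")
    register_toy_executors(proj)
    return proj


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
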