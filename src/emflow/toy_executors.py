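"""Executor implementations for every job type, at desk scale.

The pre-processing chain (Import, Motion correction, CtfFind,
Auto-picking, Particle extraction) and 2D classification are real
implementations over synthetic data: they read and write MRC images and
STAR metadata, are deterministic under fixed seeds, and honour the
per-item / checkpoint continuation contracts, so the engine's
incremental loops can be verified file-by-file against uninterrupted
batch runs.  Every remaining job type gets a stub executor that
validates its inputs and writes syntactically valid placeholder files
of the registered output types, so all 18 table rows are executable.

Per-item stages persist one set of files per input item (e.g.
``<stem>_ali.mrc`` per movie) and rebuild their aggregated STAR node
from whatever per-item files are on disk, in sorted order — that is
what makes "incremental equals batch" hold byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import registry, synthetic
from .errors import ValidationError
from .execution import ExecContext, ExecutorSpec, read_run_job
from .star import StarBlock, StarDocument, read_star, write_star
from .synthetic import (extract_particles, gaussian_pick, motion_correct,
                        pseudo_defocus, read_mrc, write_mrc)

# A minimal, valid, constant one-page PDF used wherever a job type registers
# a Logfile output; graphical content is out of scope for the toy stages.
_STUB_PDF = b"""%PDF-1.1
1 0 obj << /Type /Catalog /Pages 2 0 R >> endobj
2 0 obj << /Type /Pages /Kids [3 0 R] /Count 1 >> endobj
3 0 obj << /Type /Page /Parent 2 0 R /MediaBox [0 0 200 100] >> endobj
trailer << /Root 1 0 R >>
%%EOF
"""


def _write_stub_pdf(path: Path) -> None:
    path.write_bytes(_STUB_PDF)


def _rel(ctx: ExecContext, path: Path) -> str:
    return str(path.relative_to(ctx.project.root))


def _input_of_type(ctx: ExecContext, type_id: int) -> Path:
    for node in ctx.project.pipeline.inputs_of(ctx.process.id):
        if node.type_id == type_id:
            return ctx.project.abspath(node.path)
    raise ValidationError(
        f"job {ctx.process.id} has no input node of type {type_id}")


def _star_column(path: Path, block: str, column: str) -> list[str]:
    doc = read_star(path)
    b = doc[block]
    idx = b.columns.index(column)
    return [row[idx] for row in b.rows]


def _stem(rel_path: str) -> str:
    return Path(rel_path).stem


# -- Import ----------------------------------------------------------------


def _import_run(ctx: ExecContext) -> None:
    kind = ctx.params.get("kind", "movies")
    if kind == "movies":
        pattern = ctx.params.get("glob", "Movies/*.mrcs")
        files = sorted(ctx.project.root.glob(pattern))
        doc = StarDocument()
        doc.add("movies", StarBlock.from_table(
            ["emflowMovieName"],
            [[_rel(ctx, f)] for f in files]))
        write_star(doc, ctx.job_dir / "movies.star")
        return
    # other kinds: placeholder files of the registered types
    _stub_run(ctx)


IMPORT_SPEC = ExecutorSpec("Import", _import_run)


# -- Motion correction -----------------------------------------------------


def _movies_of(ctx: ExecContext) -> list[str]:
    return _star_column(_input_of_type(ctx, 0), "movies", "emflowMovieName")


def _moco_item_outputs(ctx: ExecContext, item: str) -> list[Path]:
    s = _stem(item)
    return [ctx.job_dir / f"{s}_ali.mrc", ctx.job_dir / f"{s}_shifts.star"]


def _moco_run(ctx: ExecContext) -> None:
    for item in ctx.items or []:
        movie = read_mrc(ctx.project.abspath(item))
        micrograph, shifts = motion_correct(movie)
        s = _stem(item)
        write_mrc(ctx.job_dir / f"{s}_ali.mrc", micrograph)
        doc = StarDocument()
        doc.add("shifts", StarBlock.from_table(
            ["emflowFrame", "emflowShiftX", "emflowShiftY"],
            [[str(k), str(int(dx)), str(int(dy))]
             for k, (dx, dy) in enumerate(shifts)]))
        write_star(doc, ctx.job_dir / f"{s}_shifts.star")
    # rebuild aggregates from the per-item files present, in sorted order
    done = [m for m in _movies_of(ctx)
            if all(f.exists() for f in _moco_item_outputs(ctx, m))]
    done.sort()
    mics = StarDocument()
    mics.add("micrographs", StarBlock.from_table(
        ["emflowMicrographName", "emflowSourceMovie"],
        [[_rel(ctx, ctx.job_dir / f"{_stem(m)}_ali.mrc"), m] for m in done]))
    write_star(mics, ctx.job_dir / "corrected_micrographs.star")
    movs = StarDocument()
    movs.add("movies", StarBlock.from_table(
        ["emflowMovieName"], [[m] for m in done]))
    write_star(movs, ctx.job_dir / "corrected_movies.star")
    _write_stub_pdf(ctx.job_dir / "logfile.pdf")


MOTIONCORR_SPEC = ExecutorSpec(
    "Motion correction", _moco_run, per_item=True,
    list_items=_movies_of, item_outputs=_moco_item_outputs)


# -- CtfFind ---------------------------------------------------------------


def _mics_of(ctx: ExecContext) -> list[str]:
    return _star_column(_input_of_type(ctx, 1), "micrographs",
                        "emflowMicrographName")


def _ctf_item_outputs(ctx: ExecContext, item: str) -> list[Path]:
    return [ctx.job_dir / f"{_stem(item)}.ctf"]


def _ctf_run(ctx: ExecContext) -> None:
    for item in ctx.items or []:
        defocus = pseudo_defocus(_stem(item))
        (ctx.job_dir / f"{_stem(item)}.ctf").write_text(
            f"micrograph {item}\ndefocus_angstrom {defocus:.1f}\n",
            encoding="utf-8")
    done = [m for m in _mics_of(ctx)
            if _ctf_item_outputs(ctx, m)[0].exists()]
    done.sort()
    doc = StarDocument()
    doc.add("micrographs", StarBlock.from_table(
        ["emflowMicrographName", "emflowDefocusAngstrom"],
        [[m, f"{pseudo_defocus(_stem(m)):.1f}"] for m in done]))
    write_star(doc, ctx.job_dir / "micrographs_ctf.star")


CTFFIND_SPEC = ExecutorSpec(
    "CtfFind", _ctf_run, per_item=True,
    list_items=_mics_of, item_outputs=_ctf_item_outputs)


# -- Auto-picking ----------------------------------------------------------


def _pick_item_outputs(ctx: ExecContext, item: str) -> list[Path]:
    return [ctx.job_dir / f"{_stem(item)}_autopick.star"]


def _pick_run(ctx: ExecContext) -> None:
    width = int(ctx.params.get("gaussian_width", "27"))
    height = float(ctx.params.get("gaussian_height", "0.3"))
    min_distance = int(ctx.params["min_distance"]) \
        if "min_distance" in ctx.params else None
    for item in ctx.items or []:
        img = read_mrc(ctx.project.abspath(item))
        if img.ndim == 3:
            img = img[0]
        picks = gaussian_pick(img, width, height, min_distance)
        doc = StarDocument()
        doc.add("coordinates", StarBlock.from_table(
            ["emflowCoordinateX", "emflowCoordinateY", "emflowPickScore"],
            [[str(x), str(y), f"{s:.6f}"] for x, y, s in picks]))
        write_star(doc, ctx.job_dir / f"{_stem(item)}_autopick.star")
    done = [m for m in _mics_of(ctx)
            if _pick_item_outputs(ctx, m)[0].exists()]
    done.sort()
    doc = StarDocument()
    doc.add("coordinate_files", StarBlock.from_table(
        ["emflowMicrographName", "emflowCoordinateFile"],
        [[m, _rel(ctx, ctx.job_dir / f"{_stem(m)}_autopick.star")]
         for m in done]))
    write_star(doc, ctx.job_dir / "coords_suffix_autopick.star")


AUTOPICK_SPEC = ExecutorSpec(
    "Auto-picking", _pick_run, per_item=True,
    list_items=_mics_of, item_outputs=_pick_item_outputs)


# -- Particle extraction ---------------------------------------------------


def _extract_pairs(ctx: ExecContext) -> list[tuple[str, str]]:
    path = _input_of_type(ctx, 2)
    doc = read_star(path)
    b = doc["coordinate_files"]
    im = b.columns.index("emflowMicrographName")
    ic = b.columns.index("emflowCoordinateFile")
    return [(row[im], row[ic]) for row in b.rows]


def _extract_items(ctx: ExecContext) -> list[str]:
    return [mic for mic, _ in _extract_pairs(ctx)]


def _extract_item_outputs(ctx: ExecContext, item: str) -> list[Path]:
    s = _stem(item)
    return [ctx.job_dir / f"{s}_extract.star", ctx.job_dir / f"{s}_extract.mrcs"]


def _extract_run(ctx: ExecContext) -> None:
    box = int(ctx.params.get("box_size", "48"))
    down = int(ctx.params.get("downscale", "1"))
    pairs = dict(_extract_pairs(ctx))
    for item in ctx.items or []:
        img = read_mrc(ctx.project.abspath(item))
        if img.ndim == 3:
            img = img[0]
        coords_doc = read_star(ctx.project.abspath(pairs[item]))
        b = coords_doc["coordinates"]
        coords = [(int(r[0]), int(r[1])) for r in b.rows]
        stack, kept_idx, skipped = extract_particles(img, coords, box, down)
        s = _stem(item)
        write_mrc(ctx.job_dir / f"{s}_extract.mrcs", stack)
        doc = StarDocument()
        doc.add("extract_info", StarBlock.from_pairs({
            "emflowBoxSize": str(box),
            "emflowDownscale": str(down),
            "emflowNSkipped": str(skipped)}))
        doc.add("particles", StarBlock.from_table(
            ["emflowMicrographName", "emflowCoordinateX", "emflowCoordinateY",
             "emflowStackFile", "emflowIndexInStack"],
            [[item, str(coords[i][0]), str(coords[i][1]),
              _rel(ctx, ctx.job_dir / f"{s}_extract.mrcs"), str(j)]
             for j, i in enumerate(kept_idx)]))
        write_star(doc, ctx.job_dir / f"{s}_extract.star")
    done = [m for m in _extract_items(ctx)
            if all(f.exists() for f in _extract_item_outputs(ctx, m))]
    done.sort()
    cols = ["emflowMicrographName", "emflowCoordinateX", "emflowCoordinateY",
            "emflowStackFile", "emflowIndexInStack"]
    rows: list[list[str]] = []
    for m in done:
        d = read_star(ctx.job_dir / f"{_stem(m)}_extract.star")
        rows.extend(d["particles"].rows)
    agg = StarDocument()
    agg.add("particles", StarBlock.from_table(cols, rows))
    write_star(agg, ctx.job_dir / "particles.star")


EXTRACT_SPEC = ExecutorSpec(
    "Particle extraction", _extract_run, per_item=True,
    list_items=_extract_items, item_outputs=_extract_item_outputs)


# -- 2D classification -----------------------------------------------------


def load_particle_stack(project_root: Path, particles_star: Path) -> np.ndarray:
    """Assemble the (N, h, w) particle array referenced by a particles STAR."""
    doc = read_star(particles_star)
    b = doc["particles"]
    i_file = b.columns.index("emflowStackFile")
    i_idx = b.columns.index("emflowIndexInStack")
    cache: dict[str, np.ndarray] = {}
    out = []
    for row in b.rows:
        f = row[i_file]
        if f not in cache:
            cache[f] = read_mrc(project_root / f)
        out.append(cache[f][int(row[i_idx])])
    if not out:
        raise ValidationError(f"{particles_star} references no particles")
    return np.stack(out)


def _class2d_run(ctx: ExecContext) -> None:
    k = int(ctx.params.get("classes", "4"))
    iters = int(ctx.params.get("iterations", "10"))
    seed = int(ctx.params.get("seed", "0"))
    particles = load_particle_stack(ctx.project.root, _input_of_type(ctx, 3))
    start_iter, init_means = 0, None
    if ctx.checkpoint is not None:
        opt = read_star(ctx.checkpoint).blocks["optimiser"].pairs
        ck_it = int(opt["emflowIteration"])
        ck_n = int(opt["emflowNParticles"])
        if ck_n == particles.shape[0] and ck_it >= iters:
            return  # nothing new since the checkpoint
        start_iter = ck_it
        init_means = read_mrc(ctx.checkpoint.parent / opt["emflowClassesFile"])
    synthetic.classify_2d(particles, k, seed, iters, ctx.job_dir,
                          start_iter=start_iter, init_means=init_means)


CLASS2D_SPEC = ExecutorSpec("2D classification", _class2d_run)


# -- stubs for everything else --------------------------------------------


def _stub_run(ctx: ExecContext) -> None:
    jt = ctx.process.job_type
    if jt.name == "Join STAR files":
        _joinstar_run(ctx)
        return
    for node in ctx.project.pipeline.outputs_of(ctx.process.id):
        path = ctx.project.abspath(node.path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix == ".pdf":
            _write_stub_pdf(path)
        elif path.suffix in (".mrc", ".mrcs"):
            write_mrc(path, np.zeros((2, 8, 8), dtype=np.float32))
        else:
            doc = StarDocument()
            doc.add("stub", StarBlock.from_pairs({
                "emflowJobType": jt.name.replace(" ", "_"),
                "emflowSourceJob": str(ctx.process.id)}))
            write_star(doc, path)


def _joinstar_run(ctx: ExecContext) -> None:
    """Concatenate the rows of the inputs' first loop blocks."""
    columns: list[str] | None = None
    rows: list[list[str]] = []
    block_name = "joined"
    for node in ctx.project.pipeline.inputs_of(ctx.process.id):
        doc = read_star(ctx.project.abspath(node.path))
        for name, b in doc.blocks.items():
            if b.kind == "loop":
                if columns is None:
                    columns, block_name = list(b.columns), name
                if b.columns == columns:
                    rows.extend(b.rows)
                break
    out = StarDocument()
    out.add(block_name, StarBlock.from_table(columns or ["emflowEmpty"], rows))
    write_star(out, ctx.job_dir / "joined.star")


def stub_executor(jt: "registry.JobType | int | str") -> ExecutorSpec:
    """A placeholder executor for *jt* that writes valid files of the
    registered output node types."""
    jt = registry.job_type(jt) if not isinstance(jt, registry.JobType) else jt
    return ExecutorSpec(jt.name, _stub_run)


def toy_executor_set() -> dict[str, ExecutorSpec]:
    """The full executor registry: real toy stages where implemented,
    stubs everywhere else, keyed by job-type name."""
    specs = {s.job_type: s for s in (
        IMPORT_SPEC, MOTIONCORR_SPEC, CTFFIND_SPEC, AUTOPICK_SPEC,
        EXTRACT_SPEC, CLASS2D_SPEC)}
    for jt in registry.JOB_TYPES:
        if jt.name not in specs:
            specs[jt.name] = stub_executor(jt)
    return specs


def register_toy_executors(project) -> None:
    project.executors.update(toy_executor_set())
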