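"""Disk management, procedure export/import, flowcharts."""

import re
from pathlib import Path

import numpy as np
import pytest

from emflow.errors import PipelineError, ValidationError
from emflow.execution import poll, run_job
from emflow.pipeline import Pipeline, STATUS_FINISHED
from emflow.project import Project
from emflow.project_ops import (clean_job, delete_job, empty_trash,
                                export_scheduled, flowchart, flowchart_edges,
                                import_jobs, trash_size, undelete_job)
from emflow.registry import job_type
from emflow.scheduler import Schedule, SimulatedClock, run_schedule, schedule_job
from emflow.demo import DemoConfig, build_preprocessing_jobs, stage_movies
from emflow.toy_executors import register_toy_executors

_SMALL = dict(image_size=96, particle_diameter=15, particles_per_movie=2,
              gaussian_width=15, box_size=24, downscale=2, n_frames=2)


def _run_small_chain(project, n_movies=2):
    cfg = DemoConfig(n_movies=n_movies, **_SMALL)
    ids = build_preprocessing_jobs(project, cfg)
    stage_movies(cfg, project.root / "Movies")
    run_schedule(project, Schedule("pre", ids), SimulatedClock())
    poll(project)
    return ids


def _snapshot(root: Path, rel: str) -> dict[str, bytes]:
    base = root / rel
    return {str(f.relative_to(base)): f.read_bytes()
            for f in sorted(base.rglob("*")) if f.is_file()}


def test_delete_leaf_job_moves_to_trash(project):
    ids = _run_small_chain(project)
    leaf = ids[-1]
    job_dir = project.pipeline.job_dir(leaf)
    entries = delete_job(project, leaf)
    assert [e.process_id for e in entries] == [leaf]
    assert not (project.root / job_dir).exists()
    assert (project.root / "Trash" / job_dir).is_dir()
    assert not project.pipeline.has_process(leaf)
    project.pipeline.check_integrity()


def test_delete_cascades_to_descendants(project):
    ids = _run_small_chain(project)
    moco = ids[1]
    entries = delete_job(project, moco)
    assert {e.process_id for e in entries} == set(ids[1:])
    assert project.pipeline.has_process(ids[0])
    project.pipeline.check_integrity()


def test_delete_no_cascade_refuses_when_descendants_exist(project):
    ids = _run_small_chain(project)
    with pytest.raises(ValidationError):
        delete_job(project, ids[1], cascade=False)
    assert project.pipeline.has_process(ids[1])


def test_delete_undelete_is_identity(project):
    ids = _run_small_chain(project)
    leaf = ids[-1]
    job_dir = project.pipeline.job_dir(leaf)
    project.pipeline.set_alias(leaf, "my-extract", project.root)
    project.save()
    before_files = _snapshot(project.root, job_dir)
    before_star = (project.root / "default_pipeline.star").read_bytes()
    delete_job(project, leaf)
    undelete_job(project, leaf)
    assert _snapshot(project.root, job_dir) == before_files
    assert (project.root / "default_pipeline.star").read_bytes() == before_star
    assert (project.root / "Extract" / "my-extract").is_symlink()
    project.pipeline.check_integrity()


def test_undelete_after_empty_trash_errors(project):
    ids = _run_small_chain(project)
    delete_job(project, ids[-1])
    empty_trash(project)
    with pytest.raises(PipelineError):
        undelete_job(project, ids[-1])


def test_empty_trash_frees_measured_bytes(project):
    assert empty_trash(project) == 0
    ids = _run_small_chain(project)
    delete_job(project, ids[-1])
    expected = trash_size(project)
    assert expected > 0
    assert empty_trash(project) == expected
    assert trash_size(project) == 0
    assert (project.root / "Trash").is_dir()


def test_clean_keeps_node_files_and_newest_checkpoint(project):
    """Iterations 1..4 of a classification: cleaning trashes the old
    iterations and keeps the newest set plus registered node files."""
    from emflow.synthetic import classify_2d

    proc = schedule_job(project, job_type("2D classification"),
                        params={"classes": "2", "iterations": "4"})
    jd = project.job_dir(proc.id)
    rng = np.random.default_rng(1)
    classify_2d(rng.normal(size=(6, 8, 8)), k=2, seed=1, iterations=4,
                job_dir=jd)
    (jd / "run.job").write_text("job_type == 2D classification\n")
    (jd / "scratch_notes.txt").write_text("intermediate\n")
    proc.status = STATUS_FINISHED
    removed = clean_job(project, proc.id)
    kept = {f.name for f in jd.iterdir()}
    # all registered node files still present
    for node in project.pipeline.outputs_of(proc.id):
        assert project.abspath(node.path).exists()
    assert "run.job" in kept
    assert "run_it004_classes.mrcs" in kept  # newest checkpoint set
    assert not any("it001" in n or "it002" in n or "it003" in n for n in kept)
    assert "scratch_notes.txt" not in kept
    assert any("scratch_notes" in r for r in removed)


def test_clean_running_job_refused(project):
    ids = _run_small_chain(project)
    proc = project.pipeline.process(ids[0])
    proc.status = "running"
    with pytest.raises(ValidationError):
        clean_job(project, ids[0])


def test_clean_then_poll_status_unchanged(project):
    ids = _run_small_chain(project)
    statuses = {p.id: p.status for p in project.pipeline.processes}
    for jid in ids:
        clean_job(project, jid)
    assert poll(project) == []
    assert {p.id: p.status for p in project.pipeline.processes} == statuses


def _schedule_procedure(project, cfg=None):
    cfg = cfg or DemoConfig(**_SMALL)
    return build_preprocessing_jobs(project, cfg)


def test_export_bundle_layout_and_no_job_numbers(project):
    ids = _schedule_procedure(project)
    bundle = export_scheduled(project, ids)
    assert bundle.name == "export1"
    assert (bundle / "exported.star").exists()
    subdirs = sorted(d.name for d in bundle.iterdir() if d.is_dir())
    assert subdirs == ["AutoPick_1", "CtfFind_1", "Extract_1",
                       "Import_1", "MotionCorr_1"]
    for f in bundle.rglob("*"):
        if f.is_file():
            assert not re.search(r"job\d{3,}", f.read_text()), f
    # 4 internal edges for the 5-stage chain... plus the extra mic edge
    from emflow.star import read_star

    doc = read_star(bundle / "exported.star")
    consumers = {row[2] for row in doc["exported_edges"].rows}
    assert consumers == {"MotionCorr_1", "CtfFind_1", "AutoPick_1", "Extract_1"}


def test_export_refuses_non_scheduled(project):
    ids = _run_small_chain(project)
    with pytest.raises(ValidationError):
        export_scheduled(project, ids)


def test_export_import_round_trip_isomorphism(project, tmp_path):
    ids = _schedule_procedure(project)
    bundle = export_scheduled(project, ids)
    fresh = Project.init(tmp_path / "fresh")
    register_toy_executors(fresh)
    procs = import_jobs(fresh, bundle)
    assert len(procs) == len(ids)
    # typed-DAG isomorphism under the order-preserving mapping
    old_pl, new_pl = project.pipeline, fresh.pipeline
    mapping = dict(zip(ids, [p.id for p in procs]))
    for old_id, new_id in mapping.items():
        old_p, new_p = old_pl.process(old_id), new_pl.process(new_id)
        assert old_p.type_id == new_p.type_id
        assert old_p.params == new_p.params
        old_parents = {mapping[q] for q in old_pl.parents(old_id) if q in mapping}
        new_parents = new_pl.parents(new_id) & set(mapping.values())
        assert old_parents == new_parents
    fresh.pipeline.check_integrity()


def test_import_twice_gives_disjoint_copies(project, tmp_path):
    ids = _schedule_procedure(project)
    bundle = export_scheduled(project, ids)
    fresh = Project.init(tmp_path / "fresh")
    first = import_jobs(fresh, bundle)
    second = import_jobs(fresh, bundle)
    assert {p.id for p in first}.isdisjoint({p.id for p in second})
    assert max(p.id for p in first) < min(p.id for p in second)
    fresh.pipeline.check_integrity()


def test_import_external_inputs_become_placeholders(project, tmp_path):
    """Exporting a suffix of the chain leaves its upstream input external;
    import materialises it as a placeholder Import job."""
    ids = _schedule_procedure(project)
    bundle = export_scheduled(project, ids[1:])  # MotionCorr.. without Import
    fresh = Project.init(tmp_path / "fresh")
    procs = import_jobs(fresh, bundle)
    placeholder = [p for p in fresh.pipeline.processes
                   if p.job_type.name == "Import" and "placeholder_for" in p.params]
    assert len(placeholder) == 1
    moco_new = procs[0]
    assert fresh.pipeline.parents(moco_new.id) == {placeholder[0].id}


def test_random_scheduled_subgraphs_export_import(rng, tmp_path):
    """50 random scheduled procedures survive export→import with type,
    parameter and topology equality."""
    from conftest import random_valid_pipeline

    for trial in range(50):
        proj = Project.init(tmp_path / f"p{trial}")
        n = int(rng.integers(2, 7))
        # grow a scheduled pipeline through the project API
        pl = random_valid_pipeline(rng, n_jobs=n)
        proj.pipeline = pl
        proj.save()
        ids = [p.id for p in pl.processes]
        bundle = export_scheduled(proj, ids)
        fresh = Project.init(tmp_path / f"q{trial}")
        procs = import_jobs(fresh, bundle)
        mapping = dict(zip(ids, [p.id for p in procs]))
        for old_id, new_id in mapping.items():
            assert pl.process(old_id).type_id == fresh.pipeline.process(new_id).type_id
            assert pl.process(old_id).params == fresh.pipeline.process(new_id).params
            assert {mapping[q] for q in pl.parents(old_id)} == \
                fresh.pipeline.parents(new_id) & set(mapping.values())
        for f in bundle.rglob("*"):
            if f.is_file():
                assert not re.search(r"job\d{3,}", f.read_text())


def test_flowchart_single_job(project):
    imp = schedule_job(project, job_type("Import"), params={"kind": "movies"})
    dot = flowchart(project.pipeline, imp.id)
    assert dot.count("label=") >= 2  # the job box + its terminal node
    assert f"j{imp.id} [" in dot


def test_flowchart_edges_match_pipeline_tables(project):
    ids = _schedule_procedure(project)
    job_edges, terminal = flowchart_edges(project.pipeline, ids[-1])
    pl = project.pipeline
    expected = set()
    for jid in ids:
        for parent in pl.parents(jid):
            expected.add((parent, jid))
    assert job_edges == expected
    # every terminal node is produced inside and consumed nowhere inside
    for jid, npath in terminal:
        assert pl.producer_of(npath) == jid
        assert not any(npath == e[0] for e in pl.input_edges)


def test_flowchart_deterministic(project):
    ids = _schedule_procedure(project)
    assert flowchart(project.pipeline, ids[-1]) == \
        flowchart(project.pipeline, ids[-1])
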