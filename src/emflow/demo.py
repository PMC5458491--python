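"""End-to-end walkthrough on synthetic data: on-the-fly pre-processing
plus an independent 2D-classification loop.

This reproduces, at desk scale, the canonical on-the-fly session: movies
are "acquired" by timed copies into a watch directory while a scheduled
Import → Motion correction → CtfFind → Auto-picking → Particle
extraction procedure cycles over them, each cycle touching only the
movies that arrived since the last one; a second, independent schedule
periodically re-runs 2D classification on all particles extracted so
far.  Auto-picking uses a single Gaussian blob as template (width
matched to the particle diameter, detection threshold 0.3) and
particles are extracted with threefold downscaling.

Used by ``emflow demo`` and by the acceptance/reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import registry
from .project import Project
from .scheduler import (Schedule, SimulatedClock, WallClock, run_schedule,
                        run_schedules_concurrently)
from .synthetic import AcquisitionSimulator, make_movie, random_scene, read_ledger
from .toy_executors import register_toy_executors


@dataclass
class DemoConfig:
    n_movies: int = 20
    seed: int = 1
    image_size: int = 256
    n_frames: int = 3
    particles_per_movie: int = 5
    particle_diameter: int = 27
    noise_sigma: float = 0.1
    drift: tuple[float, float] = (1.0, 0.0)
    gaussian_width: int = 27
    gaussian_height: float = 0.3
    box_size: int = 48
    downscale: int = 3
    classes: int = 3
    class2d_iterations: int = 5
    preprocess_cycles: int = 5
    min_wait: float = 0.0
    match_tolerance: float = 3.0  # px, pick-to-truth matching radius


def stage_movies(cfg: DemoConfig, staging: Path) -> list[Path]:
    """Generate the synthetic session's movies (plus truth ledgers) into a
    staging directory, one scene per movie, seeds derived from cfg.seed."""
    staging.mkdir(parents=True, exist_ok=True)
    staged = []
    for i in range(cfg.n_movies):
        scene = random_scene(
            seed=cfg.seed * 100003 + i, image_size=cfg.image_size,
            n_particles=cfg.particles_per_movie,
            particle_diameter=cfg.particle_diameter,
            drift=cfg.drift, noise_sigma=cfg.noise_sigma)
        mov = staging / f"movie{i:03d}.mrcs"
        make_movie(scene, cfg.n_frames, mov, staging / f"movie{i:03d}_truth.star")
        staged.append(mov)
    return staged


def build_preprocessing_jobs(project: Project, cfg: DemoConfig) -> list[int]:
    """Schedule the five-stage pre-processing procedure; returns job ids."""
    from .scheduler import schedule_job

    pl = project.pipeline
    imp = schedule_job(project, registry.job_type("Import"),
                       params={"kind": "movies", "glob": "Movies/*.mrcs"})
    movies = pl.job_dir(imp.id) + "movies.star"
    moco = schedule_job(project, registry.job_type("Motion correction"),
                        inputs=[movies])
    mics = pl.job_dir(moco.id) + "corrected_micrographs.star"
    ctf = schedule_job(project, registry.job_type("CtfFind"), inputs=[mics])
    mics_ctf = pl.job_dir(ctf.id) + "micrographs_ctf.star"
    pick = schedule_job(project, registry.job_type("Auto-picking"),
                        params={"gaussian_width": str(cfg.gaussian_width),
                                "gaussian_height": str(cfg.gaussian_height)},
                        inputs=[mics_ctf])
    coords = pl.job_dir(pick.id) + "coords_suffix_autopick.star"
    extract = schedule_job(project, registry.job_type("Particle extraction"),
                           params={"box_size": str(cfg.box_size),
                                   "downscale": str(cfg.downscale)},
                           inputs=[mics_ctf, coords])
    return [imp.id, moco.id, ctf.id, pick.id, extract.id]


def build_class2d_job(project: Project, extract_id: int, cfg: DemoConfig) -> int:
    from .scheduler import schedule_job

    particles = project.pipeline.job_dir(extract_id) + "particles.star"
    proc = schedule_job(project, registry.job_type("2D classification"),
                        params={"classes": str(cfg.classes),
                                "iterations": str(cfg.class2d_iterations),
                                "seed": str(cfg.seed)},
                        inputs=[particles])
    return proc.id


def score_picks(project: Project, pick_id: int, staging: Path,
                tolerance: float) -> tuple[float, float, int, int]:
    """Precision/recall of the auto-picking job against the truth ledgers.

    Each pick is matched greedily to the nearest unmatched true particle
    within *tolerance* pixels.  Returns (precision, recall, n_picks,
    n_truth).
    """
    from .star import read_star

    coords_star = project.abspath(
        project.pipeline.job_dir(pick_id)) / "coords_suffix_autopick.star"
    doc = read_star(coords_star)
    tp = n_picks = n_truth = 0
    for mic_name, coord_file in doc["coordinate_files"].rows:
        stem = Path(mic_name).stem.replace("_ali", "")
        truth = read_ledger(staging / f"{stem}_truth.star")
        n_truth += len(truth)
        cdoc = read_star(project.abspath(coord_file))
        picks = [(int(x), int(y)) for x, y, _ in cdoc["coordinates"].rows]
        n_picks += len(picks)
        unmatched = list(truth)
        for x, y in picks:
            best, best_d = None, tolerance
            for t in unmatched:
                d = float(np.hypot(x - t[0], y - t[1]))
                if d <= best_d:
                    best, best_d = t, d
            if best is not None:
                unmatched.remove(best)
                tp += 1
    precision = tp / n_picks if n_picks else 0.0
    recall = tp / n_truth if n_truth else 0.0
    return precision, recall, n_picks, n_truth


def run_demo(project_dir: str | Path, cfg: DemoConfig | None = None,
             concurrent: bool = True) -> dict:
    """Run the whole walkthrough in *project_dir*; returns a summary dict.

    With ``concurrent=True`` the pre-processing loop and the 2D
    classification loop run as independent threads over real time (small
    waits); otherwise both run sequentially on a simulated clock, which
    is fully deterministic.
    """
    cfg = cfg or DemoConfig()
    project_dir = Path(project_dir)
    project = Project.init(project_dir)
    register_toy_executors(project)

    staging = project_dir / "Staging"
    staged = stage_movies(cfg, staging)
    pre_ids = build_preprocessing_jobs(project, cfg)
    class2d_id = build_class2d_job(project, pre_ids[-1], cfg)

    if concurrent:
        clock = WallClock()
        sim = AcquisitionSimulator(staged, project_dir / "Movies",
                                   interval=0.05, clock=clock)
        pre = Schedule("preprocess", pre_ids,
                       n_cycles=cfg.preprocess_cycles, min_wait=cfg.min_wait)
        cls = Schedule("class2d", [class2d_id], n_cycles=2, min_wait=0.2)
        traces = run_schedules_concurrently(
            project, [pre, cls], clock, timeout=300.0,
            before_cycles={"preprocess": lambda c, now: sim.deliver_due(now)})
        # catch any stragglers delivered after the last cycle started
        if len(sim.delivered) < cfg.n_movies:
            sim.deliver_all()
            final = Schedule("preprocess_final", pre_ids, n_cycles=1)
            # ids overlap with `pre`, but that run has completed; run directly
            traces["preprocess_final"] = run_schedule(
                project, final, clock, timeout=300.0)
    else:
        clock = SimulatedClock()
        sim = AcquisitionSimulator(staged, project_dir / "Movies",
                                   interval=60.0, clock=clock)
        pre = Schedule("preprocess", pre_ids,
                       n_cycles=cfg.n_movies, min_wait=60.0)
        traces = {"preprocess": run_schedule(
            project, pre, clock,
            before_cycle=lambda c, now: sim.deliver_due(now))}
        sim.deliver_all()
        traces["preprocess_final"] = run_schedule(
            project, Schedule("preprocess_final", pre_ids, n_cycles=1), clock)
        traces["class2d"] = run_schedule(
            project, Schedule("class2d", [class2d_id], n_cycles=2), clock)

    from .execution import poll
    from .star import read_star

    poll(project)
    project.save()

    precision, recall, n_picks, n_truth = score_picks(
        project, pre_ids[3], staging, cfg.match_tolerance)
    particles_star = project.abspath(
        project.pipeline.job_dir(pre_ids[-1])) / "particles.star"
    n_particles = len(read_star(particles_star)["particles"].rows)
    cycle_counts = [e.items_processed for e in traces["preprocess"]
                    if e.process_id == pre_ids[1]]
    return {
        "config": cfg,
        "project": project,
        "traces": traces,
        "job_ids": {"preprocess": pre_ids, "class2d": class2d_id},
        "movies_delivered": len(sim.delivered),
        "movies_processed": sum(max(c, 0) for c in cycle_counts)
        + sum(max(e.items_processed, 0)
              for e in traces.get("preprocess_final", [])
              if e.process_id == pre_ids[1]),
        "picks": n_picks,
        "true_particles": n_truth,
        "precision": precision,
        "recall": recall,
        "particles_extracted": n_particles,
    }
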