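# emflow

A file-based workflow engine for single-particle cryo-EM projects, with a
desk-scale synthetic data generator so every part of it can be exercised
without a microscope, a GPU, or a download.

## The problem and the model

Cryo-EM structure determination is a long chain of processing stages —
import movies, motion-correct them into micrographs, estimate the contrast
transfer function (CTF), pick particles, extract boxed sub-images, classify
and refine — where each stage consumes the files of earlier stages and
produces new ones. `emflow` models a project as a **bipartite directed
acyclic graph**:

* **Nodes** are typed data products on disk (14 types: movies, micrographs,
  particle coordinates, particles, 2D/3D references, masks, model and
  optimiser metadata, half-maps, final maps, local-resolution maps,
  logfiles).
* **Processes (jobs)** are numbered instances of one of 18 stage types, each
  with a declared set of legal input and output node types and a fixed
  output directory prefix — the tenth job of type 2D classification always
  lives in `Class2D/job010/`.

The whole graph is persisted as a single STAR text document
(`default_pipeline.star`), readable by anything that parses STAR. Job
status is sensed purely through the file system: a job is *finished* exactly
when all of its registered output node files exist. The engine never
retains control over running work — there is deliberately no kill operation.

This design gives three capabilities for free:

* **On-the-fly processing.** Jobs can be *scheduled* before their input
  files exist and run in cycles with a minimum start-to-start interval.
  Per-item stages (motion correction, CTF estimation, picking, extraction)
  skip items whose outputs already exist, so each cycle touches only the
  movies that arrived since the last one. Independent loops — a fast
  pre-processing cycle and a slow classification cycle — can share one
  project; pipeline writes are atomic and lock-serialised.
* **Provenance and disk management.** Parents/children queries, ancestry
  flowcharts (DOT text), deletion into `Trash/` with cascade and exact
  undelete, cleaning of intermediate files that keeps everything the
  pipeline needs, and an `Empty Trash` that reports bytes freed.
* **Procedure exchange.** Scheduled job chains export to a generic bundle
  (`export1/…`, indexed by `exported.star`) containing no project-specific
  job numbers, and import into any other project as freshly numbered
  scheduled jobs.

The synthetic stages are real arithmetic at toy scale: integer-shift motion
correction by FFT cross-correlation, auto-picking by locally normalised
cross-correlation against a unit-peak Gaussian blob (width ≈ particle
diameter, detection threshold on the [-1, 1] correlation scale), windowed
extraction with block-mean downscaling (a 360 px box at threefold
downscaling yields a 120 × 120 output box), and nearest-mean 2D
classification that writes `run_it###_optimiser.star` checkpoints each
iteration so interrupted runs resume correctly.

## Worked example

```sh
$ emflow -p /tmp/walk demo --movies 8 --seed 1
movies delivered: 8
movies motion-corrected: 8
particles picked: 40 (truth 40)
picking precision: 1.000  recall: 1.000
particles extracted: 30
```

Eight synthetic movies (five planted Gaussian particles each, 1 px/frame
drift, white noise) were copied into the project while a five-stage
scheduled loop processed them and an independent loop computed 2D class
averages. All 40 planted particles were picked with no false positives;
30 survived extraction (a 48 px box around a pick too close to the image
edge is skipped and counted, hence fewer particles than picks). Afterwards:

```sh
$ emflow -p /tmp/walk status          # finished/running/scheduled lists
$ emflow -p /tmp/walk history 5       # parameters + upstream/downstream jobs
$ emflow -p /tmp/walk flowchart 6     # DOT flowchart of the ancestry of job 6
```

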