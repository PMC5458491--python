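# Methods

## The pipeline model

A project is a bipartite DAG. Data **nodes** are identified by their
project-relative path and carry one of 14 type ids; **processes** carry
consecutive integer ids, a job-type id (0–17), a status
(scheduled/running/finished), optional alias and a flat string→string
parameter map. Input edges run node→process, output edges process→node.
Two structural rules make provenance unambiguous: a node is produced by at
most one process, and the graph must stay acyclic (checked with networkx on
every load).

Everything is persisted as one STAR document with a key-value bookkeeping
block (format version, job counter) and five loop blocks (processes,
parameters, nodes, input edges, output edges). The job counter is
monotone: ids are never reused, even after deletion, because directory
names derived from ids (`Class2D/job010/`) must stay unique across
delete/undelete cycles. Directory numbers are zero-padded to three digits
and widen naturally above 999 rather than capping.

A job's expected output nodes are registered at creation time, before any
file exists, from a per-type template (e.g. motion correction registers
`corrected_movies.star`, `corrected_micrographs.star`, `logfile.pdf`).
The template may register a subset of the node types the registry allows
for that job type: the registry says what a stage *may* emit, a concrete
run registers what it *will* emit given its parameters. Iterative
classification/refinement jobs name their outputs after the planned final
iteration (`run_it010_…`), which is what lets mark-as-finished re-point
them to the newest iteration actually present on disk.

## STAR format subset

The parser covers named `data_` blocks of key-value items or a single
`loop_` table per block, `#` comments, and single/double-quoted tokens.
Loops are row-per-line; an arity mismatch is an error naming the line.
The writer quotes any token that would be misread bare (whitespace, empty,
leading `_`/`#`/quote, `data_`/`loop_` prefixes) and picks whichever quote
character does not occur in the token — the grammar has no escapes, so a
token containing both quote characters is not representable and is
rejected. Comments are not preserved (pipeline files are machine-written);
the round-trip contract is `serialise∘parse∘serialise == serialise` on
bytes and structural identity through `parse`. Writes go through a temp
file and `os.replace`, so a schedule loop polling the file never sees a
truncated document. Encoding is UTF-8 with LF endings. Save frames and
CIF dictionary features are out of scope.

## Execution and continuation

The engine's only sensor is the file system. `run_job` creates the
numbered directory, writes `run.job` (header line plus one
`label == value` line per parameter — the file named by the job-parameter
reload feature; the syntax is this package's own) and `note.txt` (ISO-8601
timestamp, command line, free-form notes), flips the status to running,
persists, and invokes the executor. An executor that raises leaves the
job running with the error appended to `note.txt`; there is no kill or
process-id tracking by design.

Continuation depends on the job type's mode:

* *per-item-skip* — the executor receives only the items whose expected
  per-item output files are absent. Item enumeration and per-item file
  mapping are declared by the executor spec, so the engine can compute the
  pending set without running anything. Continuing with nothing pending
  invokes nothing. Existence of the per-item files is trusted; no
  checksumming.
* *optimiser-restart* — the newest `run_it###_optimiser.star` (highest
  iteration number in the filename) is handed to the executor; no
  checkpoint is an error. Mark-as-finished on such a job rewrites its
  registered output node paths to the newest iteration present.
* *none* — plain re-invocation (Import re-scans its glob, which is how new
  movies enter the pipeline each cycle).

Per-item executors rebuild their aggregated STAR outputs from whatever
per-item files are on disk, in sorted order. That single convention is
what makes incremental processing reproduce a batch run file-for-file.

## Scheduling and time

A schedule is an ordered job list plus a cycle count and a minimum
interval, measured start-to-start (a fast cycle sleeps out the remainder;
the anchor had to be chosen and is documented here rather than guessed).
Within a cycle jobs run strictly in order and each job's output files are
awaited before the next starts, so downstream stages see the same cycle's
upstream results. If a job's inputs are missing when its turn comes the
schedule blocks and polls — an implementation choice; an optional timeout
bounds the wait in tests.

Clocks are injected. `SimulatedClock` advances only when slept on, making
single-threaded timing tests exact and instant; `WallClock` is used for
genuinely concurrent loops. Concurrency control is an advisory lock (a
thread lock plus `fcntl` flock on a lockfile) held around every pipeline
mutation+save, combined with atomic STAR writes; executors themselves are
single-threaded. Acquisition is emulated by timed file copies from a
staging area, with a delivery ledger for exactly-once accounting.

## Disk management and procedure exchange

Deletion cascades to descendant jobs (dangling consumers would break the
DAG; a no-cascade mode refuses instead) and moves directories to `Trash/`
mirroring their original paths. A `.fragment.star` sidecar per trashed
job records the removed process, parameters, alias, nodes and edges, so
undelete restores the directory bytes and the graph records with original
ids; restoring a cascade in parent-first order reconnects every edge.
Cleaning keeps registered node files, `run.job`, `note.txt`,
`logfile.pdf`, and the newest checkpoint-iteration file set, trashing the
rest.

Export writes each scheduled job to a generically named subdirectory
(`Extract_1`, ordinal per prefix) with its `run.job`, plus an
`exported.star` index: job list, intra-bundle edges as (producer, output
filename, consumer), and external inputs as typed placeholders. Import
re-instantiates the jobs with fresh ids, reconnects intra-bundle edges via
the producers' new directories, and materialises each distinct external
input as a placeholder Import job. Bundles contain no absolute paths and
no original job numbers.

Flowcharts are emitted as deterministic DOT text (sorted vertices and
edges): one box per job in the ancestry of the requested job, one ellipse
per terminal node, job→job edges wherever any node connects them. DOT is
renderable to PDF with standard tools when available; rendering fidelity
is a non-goal.

## Synthetic data and the toy stages

The generator plants unit-peak 2-D Gaussian blobs (σ = diameter/4, so the
±2σ support spans the stated diameter) at known coordinates, applies a
cumulative rigid drift of `k·(dx, dy)` px at frame k, and adds white
Gaussian noise. The synthetic pixel size is taken as 2 Å/px, mapping a
ribosome-like 270 Å particle to a 135 px blob at full scale; the default
fixtures use 27 px blobs in 512² images (and smaller variants where a test
only exercises bookkeeping). Default noise σ = 0.1 against a unit peak
(peak-SNR 10); scenes place particles at least two diameters apart and
half a diameter from every edge. Everything derives from a single integer
seed.

Toy stages, in the order of the pre-processing chain:

* **Motion correction** estimates per-frame integer shifts against frame 0
  by FFT cross-correlation, aligns by whole-pixel rolls, and averages.
  Exact for the linear drifts the generator produces; no sub-pixel or
  local motion.
* **CTF estimation** writes a deterministic placeholder defocus per
  micrograph (CRC-derived). It exists so node/edge types flow and per-item
  skipping can be tested; there is no Thon-ring physics.
* **Auto-picking** computes the locally normalised cross-correlation
  (range [-1, 1], via `skimage.feature.match_template`) between the
  micrograph and a unit-peak Gaussian of the given width, then takes
  non-maximum-suppressed local maxima above the height threshold. The
  [-1, 1] normalisation makes the threshold scale-free; the default
  minimum peak separation is half the template width. On the standard
  fixture the matched-filter peak is ≈ 0.97 and noise-only correlations
  stay far below 0.3, giving perfect precision/recall; this says nothing
  about crowded or low-contrast real micrographs.
* **Extraction** crops box² windows centred on 0-based pixel coordinates
  (window start = centre − box/2), skips and counts windows crossing an
  edge, and downscales by block mean (exactly invertible on block-constant
  images; box must be divisible by the factor).
* **2D classification** is nearest-mean clustering on pixel vectors with
  seeded initialisation from k random particles, a fixed iteration count,
  and full checkpoint sets (`classes.mrcs`, `model.star`, `data.star`,
  `optimiser.star`) each iteration. Continuation warm-starts from the
  checkpoint's class means and runs the configured number of further
  iterations; a continuation with no new particles and a completed
  iteration count is a no-op. An empty class keeps its previous mean.

All other job types (sorting, selection, 3D classification/refinement,
polishing, masking, subtraction, post-processing, local resolution, movie
refinement, manual picking) have stub executors that validate inputs and
write syntactically valid placeholder files of the registered output types
— files, not science — so every registry row is executable in tests.
JoinStar is the one stub with real behaviour: it concatenates the rows of
its inputs' loop blocks. Logfile outputs are a constant minimal PDF;
graphical report content is out of scope.

MRC I/O goes through gemmi (mode-2 float maps); its writes were verified
byte-deterministic, which the incremental-equals-batch comparisons rely
on. `note.txt` carries wall-clock timestamps and is excluded from byte
comparisons.

## Problem sizes and numerical choices

Tests and the acceptance script use 96–128 px scenes with 2–3 frames and
2–5 particles for bookkeeping-heavy checks, and the full 512 px / 27 px
fixture where picking quality itself is measured; the simulated session
uses 20 movies. Random-structure suites run 200 STAR documents, 100
pipelines, and 20–50 export/import subgraphs. These sizes were chosen so
the full suite completes in seconds while each check still has room to
fail; the engine itself contains no size-dependent logic.

Tie-breaks and degenerate inputs: picks are ordered by descending score,
then position; classification keeps the previous mean for an empty class
and errors on an empty particle set; `poll` never finishes a job with
zero registered outputs; an alias must match `[A-Za-z0-9._-]+` and be
unique; aliases become relative symlinks beside the numbered directory.

## Known limitations

No cluster submission, queueing, or GPU dispatch; no multi-project
federation; no plugin job types or registry versioning; no CIF
dictionary/save-frame support; the toy stages make no claim of physical
realism (no CTF model, no dose weighting, no Bayesian refinement). The
concurrency contract is advisory locking within and across processes on
POSIX systems; executors are assumed not to write outside their job
directory except to their registered output nodes.
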