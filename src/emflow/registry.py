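"""Static type system of the pipeline: node types and job types.

Single-particle cryo-EM processing is modelled as a bipartite directed
acyclic graph in which *nodes* are typed data products on disk (movies,
micrographs, coordinates, particles, maps, masks, model/optimiser
metadata, logfiles) and *jobs* are instances of one of 18 processing
stage types that consume and produce nodes of declared types.  This
module ships both registries as immutable data, mirroring the RELION-2.0
type tables, plus the I/O validation used when wiring jobs together.

Node type 5 ("2D references") may live on disk as a STAR file or an MRC
stack; the registry records STAR, the form the pipeline metadata itself
uses.  "CTF estimation" is accepted as an alias for the canonical job
name "CtfFind".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import RegistryLookupError
from .star import StarBlock, StarDocument

# continuation modes
CONT_NONE = "none"
CONT_PER_ITEM = "per-item-skip"
CONT_OPTIMISER = "optimiser-restart"


@dataclass(frozen=True)
class NodeType:
    id: int
    name: str
    storage_kind: str  # STAR | MRC | PDF | text
    description: str


@dataclass(frozen=True)
class JobType:
    id: int
    name: str
    dir_prefix: str
    input_node_types: frozenset[int]
    output_node_types: frozenset[int]
    continuation_mode: str = CONT_NONE
    aliases: tuple[str, ...] = field(default=())


NODE_TYPES: tuple[NodeType, ...] = (
    NodeType(0, "Movies", "STAR", "A STAR file with two-dimensional movies and their metadata"),
    NodeType(1, "Micrographs", "STAR", "A STAR file with two-dimensional micrographs and their metadata"),
    NodeType(2, "Particle coordinates", "text", "A text file with the coordinate-file suffix"),
    NodeType(3, "Particles", "STAR", "A STAR file with individual particles and their metadata"),
    NodeType(4, "Movie particles", "STAR", "A STAR file with particle movie frames and their metadata"),
    NodeType(5, "2D references", "STAR", "A STAR file or MRC stack with two-dimensional (reference) images"),
    NodeType(6, "3D reference", "MRC", "A three-dimensional reference map (in .MRC format)"),
    NodeType(7, "3D mask", "MRC", "A three-dimensional mask (in .MRC format)"),
    NodeType(8, "Model", "STAR", "A _model.star file for selecting classes"),
    NodeType(9, "Optimiser", "STAR", "An _optimiser.star file for continuing optimizations"),
    NodeType(10, "Half-map", "MRC", "One of two unfiltered half-maps from an auto-refinement"),
    NodeType(11, "Final map", "MRC", "A post-processed map"),
    NodeType(12, "ResMap", "MRC", "A map with local resolution estimates"),
    NodeType(13, "Logfile", "PDF", "A PDF file with additional output from a process"),
)


def _jt(id, name, dir_prefix, inputs, outputs, mode=CONT_NONE, aliases=()):
    return JobType(id, name, dir_prefix, frozenset(inputs), frozenset(outputs),
                   mode, tuple(aliases))


JOB_TYPES: tuple[JobType, ...] = (
    _jt(0, "Import", "Import/", (), (0, 1, 2, 3, 4, 5, 6, 7, 10)),
    _jt(1, "Motion correction", "MotionCorr/", (0,), (0, 1, 13), CONT_PER_ITEM,
        aliases=("MotionCorr",)),
    _jt(2, "CtfFind", "CtfFind/", (1,), (1,), CONT_PER_ITEM,
        aliases=("CTF estimation",)),
    _jt(3, "Manual picking", "ManualPick/", (1,), (1, 2), CONT_PER_ITEM,
        aliases=("ManualPick",)),
    _jt(4, "Auto-picking", "AutoPick/", (1, 5), (2,), CONT_PER_ITEM,
        aliases=("AutoPick",)),
    _jt(5, "Particle extraction", "Extract/", (1, 2, 3), (3,), CONT_PER_ITEM,
        aliases=("Extract",)),
    _jt(6, "Particle sorting", "Sort/", (3, 5, 8), (3,), aliases=("Sort",)),
    _jt(7, "Subset selection", "Select/", (1, 2, 3, 8), (1, 3, 5),
        aliases=("Select",)),
    _jt(8, "2D classification", "Class2D/", (3, 9), (3, 8, 9), CONT_OPTIMISER,
        aliases=("Class2D",)),
    _jt(9, "3D classification", "Class3D/", (3, 6, 7, 9), (3, 6, 8, 9),
        CONT_OPTIMISER, aliases=("Class3D",)),
    _jt(10, "3D auto-refine", "Refine3D/", (3, 6, 7, 9), (3, 6, 8, 9, 10),
        CONT_OPTIMISER, aliases=("Refine3D",)),
    _jt(11, "Particle polishing", "Polish/", (0, 7), (3, 11, 13),
        aliases=("Polish",)),
    _jt(12, "Mask creation", "MaskCreate/", (6,), (7,), aliases=("MaskCreate",)),
    _jt(13, "Join STAR files", "JoinStar/", (0, 1, 3), (0, 1, 3),
        aliases=("JoinStar",)),
    _jt(14, "Particle subtraction", "Subtract/", (3, 6, 7), (3,),
        aliases=("Subtract",)),
    _jt(15, "Post-processing", "PostProcess/", (10, 7), (11, 13),
        aliases=("PostProcess",)),
    _jt(16, "Local resolution", "ResMap/", (7, 10), (12,), aliases=("ResMap",)),
    _jt(17, "Movie refinement", "MovieRefine/", (4, 9), (4, 6, 8, 10, 13),
        CONT_PER_ITEM, aliases=("MovieRefine",)),
)

_JOB_BY_NAME: dict[str, JobType] = {}
for _j in JOB_TYPES:
    _JOB_BY_NAME[_j.name] = _j
    for _a in _j.aliases:
        _JOB_BY_NAME[_a] = _j


def node_type(id: int) -> NodeType:
    """Look up a node type by its integer id (0..13)."""
    if not isinstance(id, int) or isinstance(id, bool) or not 0 <= id < len(NODE_TYPES):
        raise RegistryLookupError(f"unknown node type id {id!r}")
    return NODE_TYPES[id]


def job_type(id_or_name: int | str) -> JobType:
    """Look up a job type by integer id (0..17) or registered name/alias."""
    if isinstance(id_or_name, bool):
        raise RegistryLookupError(f"unknown job type {id_or_name!r}")
    if isinstance(id_or_name, int):
        if not 0 <= id_or_name < len(JOB_TYPES):
            raise RegistryLookupError(f"unknown job type id {id_or_name!r}")
        return JOB_TYPES[id_or_name]
    try:
        return _JOB_BY_NAME[id_or_name]
    except KeyError:
        raise RegistryLookupError(f"unknown job type name {id_or_name!r}") from None


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    violations: tuple[str, ...] = ()


def validate_io(jt: JobType, input_types: list[int]) -> ValidationResult:
    """Check that every supplied input node type is accepted by *jt*."""
    bad = [t for t in input_types if t not in jt.input_node_types]
    if not bad:
        return ValidationResult(True)
    return ValidationResult(
        False,
        tuple(
            f"job type {jt.name!r} does not accept input node type {t} "
            f"({node_type(t).name if 0 <= t < len(NODE_TYPES) else 'unregistered'})"
            for t in bad
        ),
    )


def registry_to_star() -> StarDocument:
    """Export both registries as a two-block STAR document."""
    doc = StarDocument()
    doc.add("node_types", StarBlock.from_table(
        ["emflowNodeTypeId", "emflowNodeTypeName", "emflowNodeStorage"],
        [[str(n.id), n.name, n.storage_kind] for n in NODE_TYPES],
    ))
    doc.add("job_types", StarBlock.from_table(
        ["emflowJobTypeId", "emflowJobTypeName", "emflowJobDirPrefix",
         "emflowJobInputs", "emflowJobOutputs", "emflowJobContinuation"],
        [[str(j.id), j.name, j.dir_prefix,
          ",".join(map(str, sorted(j.input_node_types))) or "-",
          ",".join(map(str, sorted(j.output_node_types))),
          j.continuation_mode]
         for j in JOB_TYPES],
    ))
    return doc


# ---------------------------------------------------------------------------
# Default output-node templates.
#
# A job registers its expected output nodes at creation time, before any file
# exists; the engine later detects completion by the presence of these files.
# Each entry maps a job type to (filename-within-job-directory, node type id)
# pairs.  Iterative classification/refinement jobs name their outputs after
# the planned final iteration so that checkpoint-based continuation and
# mark-as-finished can re-point them.


def _iter_name(params: dict[str, str], stem: str) -> str:
    n = int(params.get("iterations", "10"))
    return f"run_it{n:03d}_{stem}"


_IMPORT_KINDS = {
    "movies": [("movies.star", 0)],
    "micrographs": [("micrographs.star", 1)],
    "coords": [("coords_suffix_import.star", 2)],
    "particles": [("particles.star", 3)],
    "movie_particles": [("movie_particles.star", 4)],
    "references_2d": [("references.star", 5)],
    "reference_3d": [("reference.mrc", 6)],
    "mask": [("mask.mrc", 7)],
    "half_map": [("half_map.mrc", 10)],
}


def default_outputs(jt: JobType, params: dict[str, str]) -> list[tuple[str, int]]:
    """Expected output node files (relative to the job directory) for *jt*.

    The set may be a subset of the job type's allowed output node types:
    the registry declares what a stage *may* emit, a concrete run registers
    what it *will* emit given its parameters.
    """
    name = jt.name
    if name == "Import":
        kind = params.get("kind", "movies")
        try:
            return list(_IMPORT_KINDS[kind])
        except KeyError:
            raise RegistryLookupError(f"unknown import kind {kind!r}") from None
    if name == "Motion correction":
        return [("corrected_movies.star", 0),
                ("corrected_micrographs.star", 1),
                ("logfile.pdf", 13)]
    if name == "CtfFind":
        return [("micrographs_ctf.star", 1)]
    if name == "Manual picking":
        return [("micrographs_selected.star", 1),
                ("coords_suffix_manualpick.star", 2)]
    if name == "Auto-picking":
        return [("coords_suffix_autopick.star", 2)]
    if name == "Particle extraction":
        return [("particles.star", 3)]
    if name == "Particle sorting":
        return [("particles_sorted.star", 3)]
    if name == "Subset selection":
        return [("particles_selected.star", 3)]
    if name == "2D classification":
        return [(_iter_name(params, "data.star"), 3),
                (_iter_name(params, "model.star"), 8),
                (_iter_name(params, "optimiser.star"), 9)]
    if name == "3D classification":
        return [(_iter_name(params, "data.star"), 3),
                (_iter_name(params, "class001.mrc"), 6),
                (_iter_name(params, "model.star"), 8),
                (_iter_name(params, "optimiser.star"), 9)]
    if name == "3D auto-refine":
        return [(_iter_name(params, "data.star"), 3),
                (_iter_name(params, "class001.mrc"), 6),
                (_iter_name(params, "model.star"), 8),
                (_iter_name(params, "optimiser.star"), 9),
                (_iter_name(params, "half1_class001_unfil.mrc"), 10)]
    if name == "Particle polishing":
        return [("shiny.star", 3), ("shiny_post.mrc", 11), ("logfile.pdf", 13)]
    if name == "Mask creation":
        return [("mask.mrc", 7)]
    if name == "Join STAR files":
        kind = params.get("kind", "particles")
        tid = {"movies": 0, "micrographs": 1, "particles": 3}[kind]
        return [("joined.star", tid)]
    if name == "Particle subtraction":
        return [("particles_subtracted.star", 3)]
    if name == "Post-processing":
        return [("postprocess.mrc", 11), ("logfile.pdf", 13)]
    if name == "Local resolution":
        return [("relion_locres.mrc", 12)]
    if name == "Movie refinement":
        return [("shiny.star", 4),
                ("run_class001.mrc", 6),
                ("run_model.star", 8),
                ("run_half1_class001_unfil.mrc", 10),
                ("logfile.pdf", 13)]
    raise RegistryLookupError(f"no output template for job type {name!r}")
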