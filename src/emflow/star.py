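"""Reader/writer for the STAR text format used for all pipeline metadata.

STAR (Self-defining Text Archive and Retrieval) files hold named data
blocks.  A block is either a sequence of ``_label value`` items or a
``loop_`` table: a list of ``_label`` column headers followed by
whitespace-separated token rows, one row per line.  This module covers
exactly the subset the pipeline writes — no save frames, no CIF
dictionary features — and guarantees that serialise∘parse∘serialise is
the identity on bytes, so machine-written files diff cleanly.

Tokens containing whitespace (or that would otherwise be misread, e.g.
an empty string or a token starting with ``_``/``#``) are double-quoted
on output; quoting is stripped on input.  Comments introduced by ``#``
are consumed by the parser and not preserved: pipeline files are
machine-written, so structural equality is the round-trip contract.
Files are UTF-8 with LF line endings, and writes are atomic (temp file
plus rename) so a reader polling the file never observes a truncated
document.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .errors import StarParseError

HEADER_COMMENT = "# written by emflow"

KEY_VALUE = "key-value"
LOOP = "loop"


@dataclass
class StarBlock:
    """One ``data_`` block: either key-value items or a single loop table."""

    kind: str = KEY_VALUE
    pairs: dict[str, str] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)
    rows: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in (KEY_VALUE, LOOP):
            raise ValueError(f"unknown block kind {self.kind!r}")

    @classmethod
    def from_pairs(cls, pairs: dict[str, str]) -> "StarBlock":
        return cls(kind=KEY_VALUE, pairs=dict(pairs))

    @classmethod
    def from_table(cls, columns: list[str], rows: list[list[str]]) -> "StarBlock":
        for i, r in enumerate(rows):
            if len(r) != len(columns):
                raise ValueError(
                    f"row {i} has {len(r)} tokens, expected {len(columns)}"
                )
        return cls(kind=LOOP, columns=list(columns), rows=[list(r) for r in rows])


@dataclass
class StarDocument:
    """An ordered mapping of unique block names to blocks."""

    blocks: dict[str, StarBlock] = field(default_factory=dict)

    def __getitem__(self, name: str) -> StarBlock:
        return self.blocks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.blocks

    def add(self, name: str, block: StarBlock) -> None:
        if name in self.blocks:
            raise ValueError(f"duplicate block name {name!r}")
        self.blocks[name] = block


def _needs_quoting(token: str) -> bool:
    if token == "":
        return True
    if any(c.isspace() for c in token):
        return True
    if token[0] in "_#\"'" or token.startswith(("data_", "loop_")):
        return True
    return False


def _format_token(token: str) -> str:
    if not _needs_quoting(token):
        return token
    # the grammar has no escape sequences: quote with whichever delimiter
    # does not occur in the token itself
    if '"' not in token:
        return f'"{token}"'
    if "'" not in token:
        return f"'{token}'"
    raise ValueError(
        f"token {token!r} contains both quote characters and cannot be "
        "represented in STAR")


def serialise_star(doc: StarDocument) -> str:
    """Render a document to STAR text (UTF-8, LF endings)."""
    out: list[str] = [HEADER_COMMENT, ""]
    for name, block in doc.blocks.items():
        out.append(f"data_{name}")
        out.append("")
        if block.kind == KEY_VALUE:
            for label, value in block.pairs.items():
                out.append(f"_{label} {_format_token(value)}")
        else:
            out.append("loop_")
            for col in block.columns:
                out.append(f"_{col}")
            for row in block.rows:
                out.append(" ".join(_format_token(t) for t in row))
        out.append("")
    return "\n".join(out) + "\n" if out else ""


def _tokenise(line: str, lineno: int) -> list[tuple[str, bool]]:
    """Split one line into (token, was_quoted) pairs, honouring # comments.

    Quoted-ness matters downstream: a bare ``_x`` is a label, a quoted
    ``"_x"`` is a data value.
    """
    tokens: list[tuple[str, bool]] = []
    i, n = 0, len(line)
    while i < n:
        c = line[i]
        if c.isspace():
            i += 1
            continue
        if c == "#":
            break
        if c in "\"'":
            j = line.find(c, i + 1)
            if j < 0:
                raise StarParseError("unterminated quoted token", lineno)
            tokens.append((line[i + 1 : j], True))
            i = j + 1
        else:
            j = i
            while j < n and not line[j].isspace():
                j += 1
            tokens.append((line[i:j], False))
            i = j
    return tokens


def parse_star(text: str) -> StarDocument:
    """Parse STAR text into a document, preserving block/column/row order.

    Raises :class:`StarParseError` (with the offending line number) on
    loop-row arity mismatches, duplicate block names, stray tokens
    outside any block, and similar grammar violations.
    """
    doc = StarDocument()
    block: StarBlock | None = None
    # loop parser state: None = not in loop; "header" = reading columns;
    # "rows" = reading data rows
    loop_state: str | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = _tokenise(raw, lineno)
        if not tokens:
            # blank lines separate blocks in RELION-style files; allowed anywhere
            continue
        first, first_quoted = tokens[0]
        if not first_quoted and first.startswith("data_"):
            name = first[len("data_") :]
            if name in doc.blocks:
                raise StarParseError(f"duplicate block name {name!r}", lineno)
            if len(tokens) > 1:
                raise StarParseError("trailing tokens after block header", lineno)
            block = StarBlock()
            doc.blocks[name] = block
            loop_state = None
            continue
        if block is None:
            raise StarParseError("token outside any data_ block", lineno)
        if not first_quoted and first == "loop_":
            if block.pairs or block.columns:
                raise StarParseError("loop_ in a non-empty block", lineno)
            block.kind = LOOP
            loop_state = "header"
            continue
        if loop_state == "header":
            if not first_quoted and first.startswith("_") and len(tokens) == 1:
                block.columns.append(first[1:])
                continue
            loop_state = "rows"  # fall through: this line is the first row
        if loop_state == "rows":
            if len(tokens) != len(block.columns):
                raise StarParseError(
                    f"loop row has {len(tokens)} tokens, "
                    f"expected {len(block.columns)}",
                    lineno,
                )
            block.rows.append([t for t, _ in tokens])
            continue
        # key-value item
        if first_quoted or not first.startswith("_"):
            raise StarParseError(f"expected _label, got {first!r}", lineno)
        if len(tokens) != 2:
            raise StarParseError("key-value item needs exactly one value", lineno)
        label = first[1:]
        if label in block.pairs:
            raise StarParseError(f"duplicate label {label!r}", lineno)
        block.pairs[label] = tokens[1][0]

    for name, b in doc.blocks.items():
        if b.kind == LOOP and not b.columns:
            raise StarParseError(f"loop block {name!r} has no columns")
    return doc


def write_star(doc: StarDocument, path: str | os.PathLike) -> None:
    """Atomically write a document to *path* (temp file + rename)."""
    path = Path(path)
    text = serialise_star(doc)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
            fh.flush()
            os.fsync(fh.fileno())
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def read_star(path: str | os.PathLike) -> StarDocument:
    """Parse the STAR file at *path*."""
    return parse_star(Path(path).read_text(encoding="utf-8"))
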