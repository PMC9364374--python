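"""Reading, writing and encoding RNA secondary structures.

The unit of the whole pipeline is the :class:`RnaRecord`: one sequence with a
family label and a reference set of base pairs.  Structures come and go as
connectivity-table (CT) files or dot-bracket strings; for the neural network
they are turned into one-hot matrices and binary "shadow" vectors (paired /
unpaired per nucleotide, partner identity discarded).

Coordinates are 1-based in pair sets and in all file formats, following the CT
convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Bracket alphabets for dot-bracket layers; layer 0 is the plain parentheses,
#: further layers encode crossing (pseudoknotted) pairs.
BRACKET_LAYERS = ["()", "[]", "{}", "<>"] + [
    (chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)
]

#: Row order of the one-hot encoding.
ONEHOT_ROWS = "ACGU"


class FormatError(ValueError):
    """Raised for malformed CT / dot-bracket input."""


@dataclass(frozen=True)
class RnaRecord:
    """One RNA sequence with its family label and reference base pairs.

    Pairs are 1-based ``(i, j)`` tuples with ``i < j``; each index belongs to
    at most one pair.  Crossing pairs (pseudoknots) are allowed — they occur in
    reference data even though nested-only folding engines cannot predict them.
    """

    id: str
    family: str
    sequence: str
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= n):
                raise ValueError(
                    f"{self.id}: pair ({i},{j}) out of range for length {n}"
                )
            if i in seen or j in seen:
                raise ValueError(f"{self.id}: index in more than one pair")
            seen.update((i, j))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def paired_indices(self) -> frozenset[int]:
        return frozenset(i for p in self.pairs for i in p)


@dataclass(frozen=True)
class EncodedSample:
    """One-hot sequence matrix and zero-padded shadow target.

    ``x`` has shape ``(4, pad_to)`` with rows in A,C,G,U order; ``y`` has shape
    ``(pad_to,)``.  Columns beyond ``true_length`` are all zero (3' padding);
    ambiguity letters also encode as all-zero columns.
    """

    x: np.ndarray
    y: np.ndarray
    true_length: int


# ---------------------------------------------------------------------------
# CT format
# ---------------------------------------------------------------------------

def read_ct(path: str | Path) -> RnaRecord:
    """Read a 6-column connectivity-table file into an :class:`RnaRecord`.

    The first whitespace token of the header is the sequence length; the rest
    of the header (titles, energy annotations) is kept as the record id.  If
    the file holds several structures only the first is read, with a warning.
    The family label is left empty; callers attach it from a manifest.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad CT header {lines[0]!r}") from exc
    title = " ".join(header[1:]) or path.stem
    if len(lines) - 1 > n:
        warnings.warn(f"{path}: multiple structures; using the first")
    body = lines[1 : 1 + n]
    if len(body) < n:
        raise FormatError(f"{path}: expected {n} rows, found {len(body)}")

    seq = []
    partner = np.zeros(n + 1, dtype=np.int64)
    for row in body:
        tok = row.split()
        try:
            idx, base, pj = int(tok[0]), tok[1], int(tok[4])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad CT row {row!r}") from exc
        if not 1 <= idx <= n:
            raise FormatError(f"{path}: row index {idx} out of range")
        seq.append(base.upper().replace("T", "U"))
        partner[idx] = pj

    pairs = set()
    for i in range(1, n + 1):
        j = partner[i]
        if j == 0:
            continue
        if not 1 <= j <= n or partner[j] != i:
            raise FormatError(
                f"{path}: inconsistent partners at {i}: {i}->{j}, {j}->{partner[j] if 1 <= j <= n else '?'}"
            )
        if i < j:
            pairs.add((i, int(j)))
    return RnaRecord(id=title, family="", sequence="".join(seq), pairs=frozenset(pairs))


def write_ct(record: RnaRecord, path: str | Path) -> None:
    """Write a standard 6-column CT file; partner column is 0 for unpaired."""
    partner = {i: 0 for i in range(1, len(record) + 1)}
    for i, j in record.pairs:
        partner[i], partner[j] = j, i
    with open(path, "w") as fh:
        fh.write(f"{len(record)} {record.id}\n")
        for i, base in enumerate(record.sequence, start=1):
            fh.write(f"{i} {base} {i - 1} {i + 1} {partner[i]} {i}\n")


# ---------------------------------------------------------------------------
# Dot-bracket
# ---------------------------------------------------------------------------

def parse_dotbracket(s: str) -> frozenset[tuple[int, int]]:
    """Parse a dot-bracket string into a 1-based pair set.

    Extra bracket alphabets ``[] {} <> Aa Bb ...`` encode crossing pairs; each
    alphabet is matched with its own stack.
    """
    openers = {op: layer for layer, (op, cl) in enumerate(BRACKET_LAYERS)}
    closers = {cl: layer for layer, (op, cl) in enumerate(BRACKET_LAYERS)}
    stacks: dict[int, list[int]] = {}
    pairs = set()
    for pos, ch in enumerate(s, start=1):
        if ch == ".":
            continue
        if ch in openers:
            stacks.setdefault(openers[ch], []).append(pos)
        elif ch in closers:
            stack = stacks.get(closers[ch], [])
            if not stack:
                raise FormatError(f"unbalanced {ch!r} at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise FormatError(f"unexpected character {ch!r} at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            raise FormatError(
                f"unclosed {BRACKET_LAYERS[layer][0]!r} at position {stack[-1]}"
            )
    return frozenset(pairs)


def to_dotbracket(record: RnaRecord) -> str:
    """Render a record's pairs as dot-bracket, layering crossing pairs.

    Each pair is assigned greedily (in 5'→3' order of the opening index) to the
    lowest bracket layer in which it crosses no already-assigned pair.
    """
    chars = ["."] * len(record)
    layers: list[list[tuple[int, int]]] = []
    for i, j in sorted(record.pairs):
        for layer, assigned in enumerate(layers):
            if not any(a < i < b < j or i < a < j < b for a, b in assigned):
                assigned.append((i, j))
                break
        else:
            layers.append([(i, j)])
            layer = len(layers) - 1
        if layer >= len(BRACKET_LAYERS):
            raise ValueError("more crossing layers than bracket alphabets")
        op, cl = BRACKET_LAYERS[layer]
        chars[i - 1], chars[j - 1] = op, cl
    return "".join(chars)


# ---------------------------------------------------------------------------
# Shadows and encodings
# ---------------------------------------------------------------------------

def shadow_of(record: RnaRecord) -> np.ndarray:
    """Binary paired/unpaired vector: 1 where the index occurs in some pair."""
    values = np.zeros(len(record), dtype=np.int8)
    for i, j in record.pairs:
        values[i - 1] = 1
        values[j - 1] = 1
    return values


def encode(record: RnaRecord, pad_to: int = 512) -> EncodedSample:
    """One-hot encode a record to ``(4, pad_to)`` plus its padded shadow.

    Rows follow A,C,G,U order; ambiguity letters (N, R, Y, ...) give all-zero
    columns, indistinguishable from the 3' zero padding.  T is read as U.
    """
    n = len(record)
    if n > pad_to:
        raise ValueError(f"{record.id}: length {n} exceeds pad_to={pad_to}")
    x = np.zeros((4, pad_to), dtype=np.float32)
    for col, base in enumerate(record.sequence.upper().replace("T", "U")):
        row = ONEHOT_ROWS.find(base)
        if row >= 0:
            x[row, col] = 1.0
    y = np.zeros(pad_to, dtype=np.float32)
    y[:n] = shadow_of(record)
    return EncodedSample(x=x, y=y, true_length=n)


def length_filter(
    records: Sequence[RnaRecord], max_len: int = 512
) -> list[RnaRecord]:
    """Drop records longer than ``max_len`` nucleotides, preserving order."""
    kept = [r for r in records if len(r) <= max_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("length_filter: removed %d of %d records > %d nt",
                    removed, len(records), max_len)
    return kept


# ---------------------------------------------------------------------------
# Misc plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RnaRecord]:
    """Read sequence-only FASTA records (empty pair sets, empty family)."""
    records = []
    name, chunks = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append(_fasta_record(name, chunks))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line)
    if name is not None:
        records.append(_fasta_record(name, chunks))
    return records


def _fasta_record(name: str, chunks: list[str]) -> RnaRecord:
    seq = "".join(chunks).upper().replace("T", "U")
    return RnaRecord(id=name, family="", sequence=seq)


def read_dotbracket_file(path: str | Path, id: str = "", family: str = "") -> RnaRecord:
    """Read a two-line file: sequence line then dot-bracket structure line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a sequence line and a structure line")
    seq, db = lines[0], lines[1]
    if len(seq) != len(db):
        raise FormatError(f"{path}: sequence/structure length mismatch")
    return RnaRecord(
        id=id or Path(path).stem,
        family=family,
        sequence=seq.upper().replace("T", "U"),
        pairs=parse_dotbracket(db),
    )


def load_ct_directory(
    directory: str | Path, manifest: dict[str, str] | None = None
) -> list[RnaRecord]:
    """Read every ``*.ct`` file in a directory; family labels from a manifest
    mapping record id → family (or the file's parent directory name)."""
    records = []
    for ct in sorted(Path(directory).glob("*.ct")):
        rec = read_ct(ct)
        fam = (manifest or {}).get(rec.id, Path(directory).name)
        records.append(RnaRecord(rec.id, fam, rec.sequence, rec.pairs))
    return records
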