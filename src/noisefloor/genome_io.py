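"""Case-preserving FASTA I/O, fixed-width tiling, and softmask interval extraction.

Softmasked genome assemblies mark repeat-derived sequence in lowercase. Everything
here treats character case as data: it is preserved through reading, writing and
tiling, and the repeat/non-repeat partition of a chromosome is recovered directly
from the case pattern as a set of disjoint intervals.

Coordinates are 0-based half-open throughout, matching BED/bedGraph conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "Window",
    "MaskIntervals",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "tile_sequence",
    "case_mask_intervals",
    "read_bed",
    "write_bed",
]

_VALID_RESIDUES = re.compile(r"[ACGTNacgtn]*\Z")

MaskClass = Literal["repeat", "non_repeat"]


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or contains illegal residues."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N} with case carrying the repeat mask.

    Lowercase residues are repeat (softmasked) positions; uppercase are non-repeat.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        if not _VALID_RESIDUES.match(self.residues):
            bad = next(c for c in self.residues if c not in "ACGTNacgtn")
            raise ValueError(
                f"illegal residue {bad!r} in sequence {self.name!r}: "
                "alphabet is {A,C,G,T,N} upper or lower case"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Window:
    """A tile of a source sequence: ``residues == source[offset:offset+len]``."""

    source_name: str
    offset: int
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def name(self) -> str:
        """Window id in the style ``chr1:0-100000`` (half-open)."""
        return f"{self.source_name}:{self.offset}-{self.offset + len(self.residues)}"


@dataclass
class MaskIntervals:
    """Disjoint, sorted (name, start, end, class) intervals tiling each sequence.

    ``class`` is ``"repeat"`` (lowercase run) or ``"non_repeat"`` (uppercase run);
    within one sequence the union of both classes covers [0, length) exactly.
    """

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def for_sequence(self, name: str) -> list[tuple[int, int, str]]:
        return [(s, e, c) for n, s, e, c in self.intervals if n == name]

    def class_length(self, cls: MaskClass, name: str | None = None) -> int:
        """Total bases of one class, over all sequences or one."""
        return sum(
            e - s
            for n, s, e, c in self.intervals
            if c == cls and (name is None or n == name)
        )

    def __len__(self) -> int:
        return len(self.intervals)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly multi-line) FASTA file, preserving case exactly.

    Raises
    ------
    FastaParseError
        On an empty/malformed file or a residue outside {A,C,G,T,N,a,c,g,t,n};
        the message names the offending line.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found (missing '>' header?)")
    seqs = []
    for rec in records:
        residues = str(rec.seq)
        if not _VALID_RESIDUES.match(residues):
            raise FastaParseError(_locate_bad_residue(path, rec.id))
        seqs.append(GenomeSequence(name=rec.id, residues=residues))
    return seqs


def _locate_bad_residue(path: Path, rec_id: str) -> str:
    # Error path only: rescan the file to report the first offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if not _VALID_RESIDUES.match(line.strip()):
                bad = next(c for c in line.strip() if c not in "ACGTNacgtn")
                return f"{path}:{lineno}: illegal residue {bad!r} in record {rec_id!r}"
    return f"{path}: illegal residue in record {rec_id!r}"


def write_fasta(
    seqs: Iterable[GenomeSequence], path: str | Path, line_width: int = 60
) -> None:
    """Write sequences in input order, wrapped at ``line_width``, case preserved."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.residues), line_width):
                fh.write(seq.residues[i : i + line_width] + "\n")


def tile_sequence(
    seq: GenomeSequence,
    window: int = 100_000,
    step: int = 100_000,
    keep_partial: bool = True,
) -> list[Window]:
    """Tile a sequence into windows at offsets 0, step, 2*step, ...

    Each window has length ``min(window, len(seq) - offset)``. With
    ``keep_partial=False`` a terminal window shorter than ``window`` is dropped.
    When ``step == window`` and partial windows are kept, concatenating the
    windows reproduces the input.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    out = []
    for offset in range(0, len(seq), step):
        residues = seq.residues[offset : offset + window]
        if not residues:
            break
        if len(residues) < window and not keep_partial:
            continue
        out.append(Window(source_name=seq.name, offset=offset, residues=residues))
    return out


_CASE_RUNS = re.compile(r"[a-z]+|[A-Z]+")


def case_mask_intervals(seq: GenomeSequence) -> MaskIntervals:
    """Extract repeat/non-repeat intervals from the case pattern.

    Maximal lowercase runs become ``repeat`` intervals, maximal uppercase runs
    ``non_repeat``; together they tile [0, len). 'N'/'n' follow their case.
    """
    intervals = []
    for m in _CASE_RUNS.finditer(seq.residues):
        cls = "repeat" if m.group(0)[0].islower() else "non_repeat"
        intervals.append((seq.name, m.start(), m.end(), cls))
    return MaskIntervals(intervals=intervals)


def write_bed(mask: MaskIntervals, path: str | Path) -> None:
    """Write mask intervals as BED4 (0-based half-open, class in column 4)."""
    with open(path, "w") as fh:
        for name, start, end, cls in mask.intervals:
            fh.write(f"{name}\t{start}\t{end}\t{cls}\n")


def read_bed(path: str | Path) -> MaskIntervals:
    """Read a BED4 mask file written by :func:`write_bed`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            name, start, end, cls = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if cls not in ("repeat", "non_repeat"):
                raise ValueError(f"{path}:{lineno}: unknown mask class {cls!r}")
            intervals.append((name, start, end, cls))
    return MaskIntervals(intervals=intervals)
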