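"""Per-base transcription-initiation signal: bedGraph I/O, pseudo-reads, TSS calls.

A predictor (or a capped-5'-end assay pipeline) emits per-base signal on the
log10(s+1) scale, where s is a read count. This module expands bedGraph records
to dense per-base tracks, inverts the log encoding into integer "pseudo-read"
counts, calls TSS positions above a count threshold, and stitches per-window
tracks back into chromosome coordinates.

Strands are processed fully independently end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import Window

__all__ = [
    "SignalTrack",
    "PseudoReadTrack",
    "TSSSet",
    "read_bedgraph",
    "write_bedgraph",
    "to_pseudo_reads",
    "call_tss",
    "stitch_windows",
    "aggregate_tracks",
    "write_tss_bed",
    "read_tss_bed",
]

Strand = Literal["+", "-"]


@dataclass
class SignalTrack:
    """Dense per-base signal values on the log10(s+1) scale for one sequence/strand."""

    name: str
    values: np.ndarray
    strand: Strand = "+"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError(f"negative signal value in track {self.name!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PseudoReadTrack:
    """Dense per-base non-negative integer counts for one sequence/strand."""

    name: str
    counts: np.ndarray
    strand: Strand = "+"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError(f"negative count in track {self.name!r}")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class TSSSet:
    """Called TSS positions (0-based, strictly increasing) with their counts."""

    name: str
    positions: np.ndarray
    counts: np.ndarray
    strand: Strand = "+"
    threshold: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.positions) != len(self.counts):
            raise ValueError("positions and counts must have equal length")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < self.threshold):
            raise ValueError("all counts must be >= the calling threshold")

    def __len__(self) -> int:
        return len(self.positions)


def read_bedgraph(
    path: str | Path,
    lengths: Mapping[str, int] | None = None,
    expected_names: Sequence[str] | None = None,
    strand: Strand = "+",
) -> list[SignalTrack]:
    """Expand a bedGraph file (0-based half-open, sorted per sequence) to dense tracks.

    Uncovered positions get 0. Track length is taken from ``lengths`` when given,
    else from the maximum end coordinate per sequence. Overlapping or unsorted
    records and negative values are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["name", "start", "end", "value"],
            dtype={"name": str, "start": np.int64, "end": np.int64, "value": float},
            skiprows=_count_header_lines(path),
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["name", "start", "end", "value"])

    if len(df) and (df["value"] < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise ValueError(f"{path}: negative value {bad['value']} at {bad['name']}:{bad['start']}")

    tracks = []
    names = list(dict.fromkeys(df["name"])) if len(df) else []
    if expected_names is not None:
        unknown = set(names) - set(expected_names)
        if unknown:
            raise ValueError(f"{path}: unexpected sequence names {sorted(unknown)}")
        names = list(expected_names)
    for name in names:
        sub = df[df["name"] == name]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError(f"{path}: empty or inverted interval on {name}")
        if len(sub) > 1 and np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValueError(
                f"{path}: overlapping/unsorted records on {name} near position {starts[i + 1]}"
            )
        length = (lengths or {}).get(name, int(ends.max()) if len(ends) else 0)
        values = np.zeros(length, dtype=float)
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            values[s:e] = v
        tracks.append(SignalTrack(name=name, values=values, strand=strand))
    return tracks


def _count_header_lines(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph(tracks: Iterable[SignalTrack | PseudoReadTrack], path: str | Path) -> None:
    """Write dense tracks as run-length-collapsed bedGraph, omitting zero runs."""
    with open(path, "w") as fh:
        for track in tracks:
            vals = track.values if isinstance(track, SignalTrack) else track.counts
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{track.name}\t{s}\t{e}\t{v:g}\n")


def to_pseudo_reads(track: SignalTrack) -> PseudoReadTrack:
    """Invert the log10(s+1) encoding into integer pseudo-read counts.

    Per base: x = 10**v - 1; values below 1 are set to zero and values of 1 or
    more are rounded half away from zero to the nearest integer. This exactly
    inverts the encoding: for any integer s >= 0, log10(s+1) maps back to s.
    """
    x = np.power(10.0, track.values) - 1.0
    counts = np.where(x < 1.0, 0, np.floor(x + 0.5)).astype(np.int64)
    return PseudoReadTrack(name=track.name, counts=counts, strand=track.strand)


def call_tss(track: PseudoReadTrack, threshold: int = 1) -> TSSSet:
    """Positions with at least ``threshold`` pseudo-reads, in genomic order."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    positions = np.flatnonzero(track.counts >= threshold)
    return TSSSet(
        name=track.name,
        positions=positions,
        counts=track.counts[positions],
        strand=track.strand,
        threshold=threshold,
    )


def stitch_windows(
    window_tracks: Sequence[tuple[Window, SignalTrack]],
    total_length: int | None = None,
    strand: Strand = "+",
) -> SignalTrack:
    """Place per-window tracks at their source offsets; gaps become 0.

    All windows must come from one source sequence and be non-overlapping.
    """
    if not window_tracks:
        raise ValueError("no window tracks to stitch")
    source = window_tracks[0][0].source_name
    spans = []
    for win, track in window_tracks:
        if win.source_name != source:
            raise ValueError(f"windows from multiple sources: {source!r} vs {win.source_name!r}")
        if len(track) != len(win):
            raise ValueError(f"track length {len(track)} != window length {len(win)}")
        spans.append((win.offset, win.offset + len(win)))
    spans.sort()
    for (_, e1), (s2, _) in zip(spans[:-1], spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping windows near offset {s2}")
    length = total_length if total_length is not None else max(e for _, e in spans)
    values = np.zeros(length, dtype=float)
    for win, track in window_tracks:
        values[win.offset : win.offset + len(win)] = track.values
    return SignalTrack(name=source, values=values, strand=strand)


def write_tss_bed(tss_sets: Iterable[TSSSet], path: str | Path) -> None:
    """Write called TSSs as BED3+score (score = pseudo-read count)."""
    with open(path, "w") as fh:
        for tss in tss_sets:
            for pos, count in zip(tss.positions, tss.counts):
                fh.write(f"{tss.name}\t{pos}\t{pos + 1}\t{count}\n")


def read_tss_bed(path: str | Path, strand: Strand = "+") -> list[TSSSet]:
    """Read a BED3+score TSS file back into per-sequence TSS sets."""
    records: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            name, start = fields[0], int(fields[1])
            count = int(fields[3]) if len(fields) > 3 else 1
            records.setdefault(name, []).append((start, count))
    out = []
    for name, rows in records.items():
        rows.sort()
        positions = np.array([p for p, _ in rows], dtype=np.int64)
        counts = np.array([c for _, c in rows], dtype=np.int64)
        out.append(TSSSet(name=name, positions=positions, counts=counts, strand=strand))
    return out


def aggregate_tracks(
    tracks: Sequence[SignalTrack], how: Literal["max", "sum"] = "max"
) -> SignalTrack:
    """Reduce several same-length signal tracks (e.g. multiple assay outputs)
    for one sequence/strand to a single track by per-base max or sum."""
    if not tracks:
        raise ValueError("no tracks to aggregate")
    stacked = np.stack([t.values for t in tracks])
    values = stacked.max(axis=0) if how == "max" else stacked.sum(axis=0)
    return SignalTrack(name=tracks[0].name, values=values, strand=tracks[0].strand)
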