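"""Genome randomization operators: reversal and exact k-let shuffles.

Four null models for a softmasked genome sequence:

* plain reversal (no complementation — the reversed genome is a composition- and
  k-let-reversed background, not the opposite strand);
* global k-let shuffling: a uniform permutation for k=1, and for k=2 an exact
  dinucleotide-preserving shuffle via the Euler-path construction on the de Bruijn
  multigraph (Altschul–Erickson style), which keeps the overlapping k-let multiset
  identical and fixes the first and last residues;
* windowed (local) k-let shuffling over sliding windows, preserving local
  composition at the window scale;
* mask-class-restricted randomization, which reverses or shuffles every maximal
  lowercase (repeat) or uppercase (non-repeat) run independently in place,
  leaving all other positions byte-identical.

Characters carry their case through whole-sequence shuffles: the softmask is
scrambled along with the sequence, and downstream repeat analyses use the
original mask coordinates, not the shuffled file's case. 'N' participates as a
fifth symbol.

All operators are deterministic for a fixed seed; per-run and per-window
substreams are derived from the top-level seed with ``numpy.random.SeedSequence``
spawning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .genome_io import GenomeSequence

__all__ = [
    "ShuffleSpec",
    "reverse_sequence",
    "shuffle_klet_global",
    "shuffle_klet_windowed",
    "randomize_mask_class",
]


@dataclass(frozen=True)
class ShuffleSpec:
    """Parameters of a k-let shuffle.

    k=1 permutes characters; k=2 preserves the exact overlapping-dinucleotide
    multiset. ``window``/``step`` apply to the windowed scope only (defaults
    100/50, the sliding-window sizes used for local shuffling).
    """

    k: int = 1
    scope: Literal["global", "windowed"] = "global"
    window: int = 100
    step: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.scope == "windowed":
            if self.window < self.k:
                raise ValueError("window must be >= k")
            if self.step < 1:
                raise ValueError("step must be >= 1")


def reverse_sequence(seq: GenomeSequence) -> GenomeSequence:
    """Reverse character order without complementation; case travels with its character."""
    return GenomeSequence(name=seq.name, residues=seq.residues[::-1])


def _permute(s: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")


def _arborescence_ok(last_edge: dict[str, str], root: str) -> bool:
    """Do the chosen last edges lead every vertex to ``root`` without a stray cycle?"""
    reaches = {root}
    for v in last_edge:
        path = []
        u = v
        while u not in reaches:
            if u in path:
                return False
            path.append(u)
            u = last_edge[u]
        reaches.update(path)
    return True


def _euler_klet_shuffle(s: str, k: int, rng: np.random.Generator) -> str:
    """Exact k-let shuffle via a random Eulerian path on the de Bruijn multigraph.

    Vertices are (k-1)-mers, edges the overlapping k-lets of ``s``. A uniformly
    random last-edge-per-vertex assignment is drawn and rejected until the last
    edges form an arborescence toward the terminal vertex; remaining out-edges
    are then randomly ordered and the path walked from the initial vertex. The
    first and last (k-1)-mers of the output equal the input's.
    """
    order = k - 1
    verts = [s[i : i + order] for i in range(len(s) - order + 1)]
    out: dict[str, list[str]] = {}
    for a, b in zip(verts[:-1], verts[1:]):
        out.setdefault(a, []).append(b)
    start, last = verts[0], verts[-1]
    needs_last = [v for v in out if v != last]

    for _ in range(100_000):
        last_edge = {v: out[v][rng.integers(len(out[v]))] for v in needs_last}
        if _arborescence_ok(last_edge, last):
            break
    else:  # pragma: no cover - an Eulerian path always exists, so this cannot trigger
        raise RuntimeError("failed to sample an Eulerian-path edge ordering")

    ordering: dict[str, list[str]] = {}
    for v, targets in out.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        idx = rng.permutation(len(rest))
        rest = [rest[i] for i in idx]
        if v in last_edge:
            rest.append(last_edge[v])
        ordering[v] = rest

    ptr = dict.fromkeys(out, 0)
    cur = start
    pieces = [start]
    for _ in range(len(verts) - 1):
        nxt = ordering[cur][ptr[cur]]
        ptr[cur] += 1
        pieces.append(nxt[-1])
        cur = nxt
    return "".join(pieces)


def _klet_shuffle(s: str, k: int, rng: np.random.Generator) -> str:
    if len(s) <= k:
        return s
    if k == 1:
        return _permute(s, rng)
    return _euler_klet_shuffle(s, k, rng)


def shuffle_klet_global(seq: GenomeSequence, spec: ShuffleSpec) -> GenomeSequence:
    """Shuffle the whole sequence preserving the exact k-let multiset.

    A sequence whose k-let graph admits no alternative Eulerian path (e.g.
    "AAC" at k=2) is necessarily returned unchanged — the input is the unique
    arrangement.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return GenomeSequence(seq.name, _klet_shuffle(seq.residues, spec.k, rng))


def shuffle_klet_windowed(seq: GenomeSequence, spec: ShuffleSpec) -> GenomeSequence:
    """Shuffle sliding windows in place, left to right.

    Windows start at offsets 0, step, 2*step, ... (the last is truncated); each
    shuffle acts on the current, possibly already-shuffled content, so with
    step < window the overlap is re-shuffled by later windows. Total character
    composition is exactly preserved.
    """
    chars = list(seq.residues)
    offsets = range(0, len(chars), spec.step)
    children = np.random.SeedSequence(spec.seed).spawn(len(offsets))
    for offset, child in zip(offsets, children):
        rng = np.random.default_rng(child)
        sub = "".join(chars[offset : offset + spec.window])
        chars[offset : offset + len(sub)] = _klet_shuffle(sub, spec.k, rng)
    return GenomeSequence(seq.name, "".join(chars))


_RUN_PATTERNS = {"repeat": re.compile(r"[a-z]+"), "non_repeat": re.compile(r"[A-Z]+")}


def randomize_mask_class(
    seq: GenomeSequence,
    target: Literal["repeat", "non_repeat"],
    method: Literal["reverse", "shuffle"],
    spec: ShuffleSpec | None = None,
) -> GenomeSequence:
    """Reverse or shuffle every maximal run of one case class, in place.

    Each contiguous run of the target case (lowercase for ``repeat``, uppercase
    for ``non_repeat``) is independently randomized and reinserted at its
    original coordinates; all other positions are byte-identical, so the case
    pattern — and hence the mask intervals — is unchanged. The default shuffle
    is global mononucleotide (k=1) within each run.
    """
    if target not in _RUN_PATTERNS:
        raise ValueError(f"target must be 'repeat' or 'non_repeat', got {target!r}")
    if method not in ("reverse", "shuffle"):
        raise ValueError(f"method must be 'reverse' or 'shuffle', got {method!r}")
    spec = spec or ShuffleSpec()
    chars = list(seq.residues)
    runs = list(_RUN_PATTERNS[target].finditer(seq.residues))
    children = np.random.SeedSequence(spec.seed).spawn(max(len(runs), 1))
    for run, child in zip(runs, children):
        sub = run.group(0)
        if method == "reverse":
            new = sub[::-1]
        else:
            new = _klet_shuffle(sub, spec.k, np.random.default_rng(child))
        chars[run.start() : run.end()] = new
    return GenomeSequence(seq.name, "".join(chars))
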