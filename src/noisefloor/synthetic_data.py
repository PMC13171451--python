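"""Synthetic softmasked genomes and TSS signal tracks with known ground truth.

The generator emulates the statistical structure the analysis pipeline assumes,
so every stage can be tested without a deep-learning predictor or genome
download:

* softmasked sequences with i.i.d. uniform bases and an alternating-run case
  process (geometric run lengths) whose stationary lowercase fraction is the
  configured repeat fraction (default 0.403, the repeat share of the human
  genome);
* signal tracks built cluster by cluster: inter-cluster gaps drawn from a
  three-component log-normal mixture (modes near 50 bp, 300 bp and 15,000 bp —
  the short/medium/long trimodal structure of observed inter-cluster
  distances), clusters populated with a shifted-Poisson number of TSSs
  (mean ~7.8) spaced so cluster spans stay under ~100 bp, and per-TSS
  pseudo-read magnitudes from a per-cluster heavy-tailed (Pareto) strength
  shared by cluster members with small log-normal scatter.

Emitted values are log10(count+1), so the signal chain must invert the
encoding exactly. The returned truth object records every cluster, member
position, count and gap-component label.

It does not emulate sequence dependence (no sequence -> signal model) or real
chromosome-scale heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster_metrics import ClusterSet
from .genome_io import GenomeSequence, write_fasta
from .signal_io import SignalTrack

__all__ = [
    "TrackModel",
    "SyntheticTruth",
    "gen_masked_sequence",
    "gen_tss_track",
    "gen_fixture_suite",
    "truth_cluster_recovery",
]

# (weight, log10 location, log10 scale) — medians 50 / 300 / 15,000 bp
_DEFAULT_MIXTURE = (
    (0.30, math.log10(50.0), 0.12),
    (0.40, math.log10(300.0), 0.12),
    (0.30, math.log10(15_000.0), 0.20),
)


@dataclass(frozen=True)
class TrackModel:
    """Parameters of the synthetic TSS track generator.

    ``gap_mixture`` components are (weight, log10-location, log10-scale) of
    log-normal inter-cluster gaps. ``tss_per_cluster_mean`` parameterizes a
    shifted Poisson (1 + Poisson(mean - 1)). Adjacent members within a cluster
    are 1..``intra_gap_max`` bp apart so clusters hold together under 25 bp
    max-gap clustering, with total span capped at ``width_cap``. Magnitudes
    are a per-cluster Pareto strength (exponent ``magnitude_alpha``) shared by
    members with log-normal scatter ``magnitude_scatter`` (natural-log sd).
    """

    length: int = 10_000_000
    gap_mixture: tuple[tuple[float, float, float], ...] = _DEFAULT_MIXTURE
    tss_per_cluster_mean: float = 7.8
    intra_gap_max: int = 7
    width_cap: int = 100
    magnitude_alpha: float = 1.3
    magnitude_scatter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        w = [c[0] for c in self.gap_mixture]
        if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ValueError("mixture weights must be non-negative and sum to 1")
        locs = [c[1] for c in self.gap_mixture]
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise ValueError("mixture locations must be strictly increasing")
        if any(c[2] <= 0 for c in self.gap_mixture):
            raise ValueError("mixture scales must be > 0")
        if self.tss_per_cluster_mean < 1:
            raise ValueError("tss_per_cluster_mean must be >= 1")

    def component_medians(self) -> np.ndarray:
        """Median gap (bp) of each mixture component."""
        return np.array([10.0 ** loc for _, loc, _ in self.gap_mixture])


@dataclass
class SyntheticTruth:
    """Everything the generator drew: clusters, members, counts, gap labels."""

    cluster_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cluster_ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    members: list[np.ndarray] = field(default_factory=list)
    counts: list[np.ndarray] = field(default_factory=list)
    gap_components: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    @property
    def n_tss(self) -> int:
        return sum(len(m) for m in self.members)

    def gaps(self) -> np.ndarray:
        """Realized inter-cluster gaps, start(next) - end(previous)."""
        return self.cluster_starts[1:] - self.cluster_ends[:-1]


def gen_masked_sequence(
    length: int,
    repeat_fraction: float = 0.403,
    mean_run_length: float = 300.0,
    seed: int = 0,
    name: str = "synth",
) -> GenomeSequence:
    """Random softmasked sequence with the given stationary repeat fraction.

    Bases are i.i.d. uniform over {A,C,G,T}; case alternates between lowercase
    (repeat) and uppercase runs with geometric lengths. The repeat runs have
    mean ``mean_run_length``; non-repeat run lengths are scaled so lowercase
    occupies ``repeat_fraction`` of the sequence in expectation.
    """
    if not 0.0 <= repeat_fraction <= 1.0:
        raise ValueError("repeat_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    if repeat_fraction == 0.0:
        return GenomeSequence(name, bases.tobytes().decode("ascii"))
    if repeat_fraction == 1.0:
        return GenomeSequence(name, bases.tobytes().decode("ascii").lower())

    mean_rep = mean_run_length
    mean_non = mean_run_length * (1.0 - repeat_fraction) / repeat_fraction
    lower = np.zeros(length, dtype=bool)
    pos = 0
    state_repeat = bool(rng.random() < repeat_fraction)
    while pos < length:
        mean = mean_rep if state_repeat else mean_non
        run = int(rng.geometric(1.0 / mean))
        if state_repeat:
            lower[pos : pos + run] = True
        pos += run
        state_repeat = not state_repeat
    bases[lower] += 32  # ASCII lowercase offset
    return GenomeSequence(name, bases.tobytes().decode("ascii"))


def _sample_cluster(model: TrackModel, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Member offsets (from the anchor) and integer counts for one cluster."""
    n = 1 + int(rng.poisson(model.tss_per_cluster_mean - 1.0))
    gaps = rng.integers(1, model.intra_gap_max + 1, size=n - 1)
    while gaps.sum() + 1 > model.width_cap:
        gaps[np.argmax(gaps)] -= 1  # shrink the widest spacing to respect the span cap
    offsets = np.concatenate(([0], np.cumsum(gaps))).astype(np.int64)
    strength = 1.0 + rng.pareto(model.magnitude_alpha)
    scatter = rng.lognormal(0.0, model.magnitude_scatter, size=n)
    counts = np.maximum(1, np.rint(strength * scatter)).astype(np.int64)
    return offsets, counts


def gen_tss_track(model: TrackModel, name: str = "synth") -> tuple[SignalTrack, SyntheticTruth]:
    """Generate a per-base log10(count+1) signal track plus its ground truth.

    Clusters are placed left to right; each inter-cluster gap (from the end of
    one cluster to the start of the next) is drawn from the log-normal mixture
    and its component label recorded. A sequence too short for a single
    cluster yields an empty track and empty truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    weights = np.array([c[0] for c in model.gap_mixture])

    def draw_gap() -> tuple[int, int]:
        comp = int(rng.choice(len(weights), p=weights))
        _, loc, scale = model.gap_mixture[comp]
        return max(1, int(round(10.0 ** rng.normal(loc, scale)))), comp

    starts: list[int] = []
    ends: list[int] = []
    members: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    comps: list[int] = []

    first_gap, _ = draw_gap()
    anchor = first_gap
    while True:
        offsets, cts = _sample_cluster(model, rng)
        if anchor + offsets[-1] >= model.length:
            break
        starts.append(anchor)
        ends.append(anchor + int(offsets[-1]))
        members.append(anchor + offsets)
        counts.append(cts)
        gap, comp = draw_gap()
        anchor = ends[-1] + gap
        comps.append(comp)

    values = np.zeros(model.length, dtype=float)
    for pos, cts in zip(members, counts):
        values[pos] = np.log10(cts + 1.0)
    truth = SyntheticTruth(
        cluster_starts=np.array(starts, dtype=np.int64),
        cluster_ends=np.array(ends, dtype=np.int64),
        members=members,
        counts=counts,
        gap_components=np.array(comps[: max(len(starts) - 1, 0)], dtype=np.int64),
    )
    return SignalTrack(name=name, values=values), truth


def truth_cluster_recovery(truth: SyntheticTruth, clusters: ClusterSet) -> float:
    """Fraction of truth clusters recovered exactly (same span and member count).

    Mis-merges happen only when a sampled inter-cluster gap is at or below the
    clustering max gap; both clusters of a merged pair count as unrecovered.
    """
    if truth.n_clusters == 0:
        return float("nan")
    recovered_spans = {
        (int(s), int(e), int(n))
        for s, e, n in zip(clusters.starts, clusters.ends, clusters.n_tss)
    }
    hits = sum(
        (int(s), int(e), len(m)) in recovered_spans
        for s, e, m in zip(truth.cluster_starts, truth.cluster_ends, truth.members)
    )
    return hits / truth.n_clusters


def gen_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the small worked-example fixtures in standard formats.

    Deterministic: running twice produces identical bytes. Returns a mapping
    of fixture key to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    # the {100,110,140,200} worked TSS example, BED3+score (score = count)
    tss_bed = out / "tss_example.bed"
    with open(tss_bed, "w") as fh:
        for pos in (100, 110, 140, 200):
            fh.write(f"chrS\t{pos}\t{pos + 1}\t1\n")
    paths["tss_bed"] = tss_bed

    # the same example as a log10(count+1) bedGraph (count 1 everywhere)
    bedgraph = out / "signal_example.bedgraph"
    v = math.log10(2.0)
    with open(bedgraph, "w") as fh:
        for pos in (100, 110, 140, 200):
            fh.write(f"chrS\t{pos}\t{pos + 1}\t{v:.6f}\n")
    paths["bedgraph"] = bedgraph

    # a toy softmasked genome with one repeat run
    fasta = out / "masked_example.fasta"
    write_fasta([GenomeSequence("chrS", "ACGtttGA")], fasta)
    paths["fasta"] = fasta
    return paths
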