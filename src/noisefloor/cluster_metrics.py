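"""Max-gap TSS clustering, initiation metrics, and inter-cluster distance analysis.

TSSs are merged into clusters by single linkage: consecutive TSSs at most
``max_gap`` bases apart (25 bp by default) belong to one cluster. From a TSS
set and its clusters the module computes the six standard initiation metrics —
number of TSSs, number of clusters, mean cluster width (inclusive span, bp),
mean TSSs per cluster, mean inter-TSS distance, and mean inter-cluster
distance (the gap between the end of a cluster and the start of the next) —
plus log-spaced distance histograms, smoothed-histogram mode counts for
modality assessment, and read-threshold sweeps.

Distances never cross sequence or strand boundaries; means are pooled across
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .signal_io import PseudoReadTrack, TSSSet, call_tss

__all__ = [
    "ClusterSet",
    "MetricsRow",
    "DistanceHistogram",
    "cluster_tss",
    "compute_metrics",
    "inter_cluster_distances",
    "inter_tss_distances",
    "distance_histogram",
    "histogram_peaks",
    "count_modes",
    "threshold_sweep",
    "metrics_table",
]


@dataclass
class ClusterSet:
    """Merged TSS clusters for one sequence/strand.

    ``starts``/``ends`` are inclusive member-position bounds; a cluster's width
    is ``end - start + 1`` bp, so a singleton has width 1.
    """

    name: str
    starts: np.ndarray
    ends: np.ndarray
    n_tss: np.ndarray
    strand: str = "+"
    max_gap: int = 25

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.n_tss = np.asarray(self.n_tss, dtype=np.int64)
        if not (len(self.starts) == len(self.ends) == len(self.n_tss)):
            raise ValueError("starts, ends and n_tss must have equal length")
        if np.any(self.ends < self.starts):
            raise ValueError("cluster end before start")
        if len(self.starts) > 1 and np.any(self.starts[1:] <= self.ends[:-1]):
            raise ValueError("clusters must be sorted and non-overlapping")

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts + 1

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class MetricsRow:
    """The six initiation statistics for one dataset at one calling threshold.

    Distance fields are NaN when fewer than two TSSs (or clusters) exist.
    Full precision is retained; rounding happens only in :func:`metrics_table`.
    """

    label: str
    threshold: int
    n_tss: int
    n_clusters: int
    mean_cluster_width: float
    mean_tss_per_cluster: float
    mean_inter_tss_distance: float
    mean_inter_cluster_distance: float


@dataclass
class DistanceHistogram:
    """Counts of distances over log10-spaced bins (left-closed, right-open)."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin midpoints (natural for log-spaced bins)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])


def cluster_tss(tss: TSSSet, max_gap: int = 25) -> ClusterSet:
    """Single-linkage merge: consecutive TSSs <= ``max_gap`` bp apart share a cluster.

    Cluster bounds are the min/max member positions; every TSS belongs to
    exactly one cluster and cluster TSS counts sum to the input size.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pos = tss.positions
    if len(pos) == 0:
        empty = np.empty(0, dtype=np.int64)
        return ClusterSet(tss.name, empty, empty, empty, strand=tss.strand, max_gap=max_gap)
    breaks = np.flatnonzero(np.diff(pos) > max_gap)
    starts_idx = np.concatenate(([0], breaks + 1))
    ends_idx = np.concatenate((breaks, [len(pos) - 1]))
    return ClusterSet(
        name=tss.name,
        starts=pos[starts_idx],
        ends=pos[ends_idx],
        n_tss=ends_idx - starts_idx + 1,
        strand=tss.strand,
        max_gap=max_gap,
    )


def _as_list(x):
    return list(x) if isinstance(x, (list, tuple)) else [x]


def inter_tss_distances(tss: TSSSet | Sequence[TSSSet]) -> np.ndarray:
    """Differences between consecutive TSS positions, pooled per sequence/strand."""
    parts = [np.diff(t.positions) for t in _as_list(tss) if len(t) >= 2]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def inter_cluster_distances(clusters: ClusterSet | Sequence[ClusterSet]) -> np.ndarray:
    """Gap from each cluster's end to the next cluster's start, per sequence/strand.

    Never crosses sequence or strand boundaries. With max-gap clustering the
    minimum possible value is ``max_gap + 1``.
    """
    parts = [c.starts[1:] - c.ends[:-1] for c in _as_list(clusters) if len(c) >= 2]
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


def compute_metrics(
    tss: TSSSet | Sequence[TSSSet],
    clusters: ClusterSet | Sequence[ClusterSet],
    label: str = "",
    threshold: int = 1,
) -> MetricsRow:
    """Compute the six initiation statistics, pooling across sequences/strands."""
    tss_list = _as_list(tss)
    cl_list = _as_list(clusters)
    n_tss = sum(len(t) for t in tss_list)
    n_clusters = sum(len(c) for c in cl_list)
    if sum(int(c.n_tss.sum()) for c in cl_list) != n_tss:
        raise ValueError("clusters were not built from this TSS set (member counts differ)")
    widths = np.concatenate([c.widths for c in cl_list]) if cl_list else np.empty(0)
    d_tss = inter_tss_distances(tss_list)
    d_cl = inter_cluster_distances(cl_list)
    return MetricsRow(
        label=label,
        threshold=threshold,
        n_tss=n_tss,
        n_clusters=n_clusters,
        mean_cluster_width=float(widths.mean()) if len(widths) else 0.0,
        mean_tss_per_cluster=n_tss / n_clusters if n_clusters else 0.0,
        mean_inter_tss_distance=float(d_tss.mean()) if len(d_tss) else float("nan"),
        mean_inter_cluster_distance=float(d_cl.mean()) if len(d_cl) else float("nan"),
    )


def distance_histogram(
    distances: np.ndarray | Sequence[float],
    n_bins: int = 100,
    range: tuple[float, float] = (1.0, 1e8),
    edges: np.ndarray | None = None,
) -> DistanceHistogram:
    """Bin distances into log10-spaced, left-closed right-open bins.

    Values falling outside the edge range are clipped into the end bins so the
    histogram always conserves the number of distances. Non-positive distances
    are rejected.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be >= 1")
    if edges is None:
        lo, hi = range
        if not (0 < lo < hi):
            raise ValueError("need 0 < range[0] < range[1]")
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges = np.asarray(edges, dtype=float)
    if len(d) == 0:
        return DistanceHistogram(edges=edges, counts=np.zeros(len(edges) - 1, dtype=np.int64))
    idx = np.digitize(d, edges) - 1  # edges[i] <= x < edges[i+1]
    idx = np.clip(idx, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    return DistanceHistogram(edges=edges, counts=counts)


def _smooth(counts: np.ndarray, bandwidth: int) -> np.ndarray:
    if bandwidth <= 1:
        return counts.astype(float)
    kernel = np.ones(bandwidth) / bandwidth
    return np.convolve(counts.astype(float), kernel, mode="same")


def histogram_peaks(
    hist: DistanceHistogram,
    smooth_bandwidth: int = 5,
    prominence_frac: float = 0.05,
) -> np.ndarray:
    """Locations (bin centers, bp) of local maxima of the smoothed histogram.

    The counts are smoothed with a moving average of ``smooth_bandwidth`` bins
    in log space; peaks must have prominence of at least ``prominence_frac``
    of the tallest smoothed bin. Deterministic.
    """
    if hist.total == 0:
        return np.empty(0)
    smoothed = _smooth(hist.counts, smooth_bandwidth)
    floor = prominence_frac * smoothed.max()
    peaks, _ = find_peaks(smoothed, prominence=floor)
    return hist.centers[peaks]


def count_modes(hist: DistanceHistogram, smooth_bandwidth: int = 5) -> int:
    """Number of modes of the smoothed log-spaced distance histogram."""
    return len(histogram_peaks(hist, smooth_bandwidth=smooth_bandwidth))


def threshold_sweep(
    track: PseudoReadTrack | Sequence[PseudoReadTrack],
    thresholds: Sequence[int],
    max_gap: int = 25,
    label: str = "",
) -> list[MetricsRow]:
    """Re-call TSSs at each threshold and recompute the six metrics.

    Thresholds must be ascending; the number of called TSSs is non-increasing
    along the sweep.
    """
    thresholds = list(thresholds)
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    tracks = _as_list(track)
    rows = []
    for thr in thresholds:
        tss = [call_tss(t, thr) for t in tracks]
        clusters = [cluster_tss(t, max_gap) for t in tss]
        rows.append(compute_metrics(tss, clusters, label=label, threshold=thr))
    return rows


_TABLE_COLUMNS = {
    "label": "Dataset",
    "threshold": "Threshold",
    "n_tss": "Number of TSSs",
    "n_clusters": "Number of TSS clusters",
    "mean_cluster_width": "Mean cluster width",
    "mean_tss_per_cluster": "Mean number of TSSs per cluster",
    "mean_inter_tss_distance": "Mean inter-TSS distance",
    "mean_inter_cluster_distance": "Mean inter-cluster distance",
}


def metrics_table(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Report table with conventional column names and report rounding.

    Widths to 1 dp, TSSs per cluster to 2 dp, distances to integer bp.
    """
    df = pd.DataFrame([vars(r) for r in rows]).rename(columns=_TABLE_COLUMNS)
    df["Mean cluster width"] = df["Mean cluster width"].round(1)
    df["Mean number of TSSs per cluster"] = df["Mean number of TSSs per cluster"].round(2)
    for col in ("Mean inter-TSS distance", "Mean inter-cluster distance"):
        df[col] = df[col].round(0)
    return df
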