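import math

import numpy as np
import pytest

from noisefloor import (
    PseudoReadTrack,
    TSSSet,
    TrackModel,
    cluster_tss,
    compute_metrics,
    count_modes,
    distance_histogram,
    gen_tss_track,
    histogram_peaks,
    inter_cluster_distances,
    metrics_table,
    threshold_sweep,
    to_pseudo_reads,
)


def brute_force_clusters(positions, max_gap):
    """O(n^2) transitive-closure merge: the clustering oracle."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted((min(g), max(g), len(g)) for g in groups.values())


def make_tss(positions):
    positions = np.asarray(sorted(positions), dtype=int)
    return TSSSet("s", positions, np.ones(len(positions), dtype=int))


class TestClustering:
    def test_worked_example(self, worked_tss):
        cl = cluster_tss(worked_tss, 25)
        assert list(zip(cl.starts, cl.ends, cl.n_tss)) == [(100, 110, 2), (140, 140, 1), (200, 200, 1)]
        assert cl.widths.tolist() == [11, 1, 1]

    def test_single_tss_is_singleton_cluster_of_width_one(self):
        cl = cluster_tss(make_tss([42]), 25)
        assert len(cl) == 1 and cl.widths.tolist() == [1]

    def test_chained_merges_at_exact_gap_bound(self):
        cl = cluster_tss(make_tss([0, 25, 50]), 25)
        assert len(cl) == 1
        assert cl.starts[0] == 0 and cl.ends[0] == 50
        assert cl.widths[0] == 51 and cl.n_tss[0] == 3

    @pytest.mark.parametrize("max_gap", [0, 1, 25, 100])
    def test_matches_transitive_closure_oracle(self, max_gap):
        rng = np.random.default_rng(max_gap)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            positions = np.unique(rng.integers(0, 10_000, size=n))
            cl = cluster_tss(make_tss(positions), max_gap)
            got = sorted(zip(cl.starts.tolist(), cl.ends.tolist(), cl.n_tss.tolist()))
            assert got == brute_force_clusters(positions, max_gap)

    def test_conservation_of_tss_count(self):
        rng = np.random.default_rng(9)
        positions = np.unique(rng.integers(0, 100_000, size=500))
        cl = cluster_tss(make_tss(positions), 25)
        assert cl.n_tss.sum() == len(positions)

    def test_cluster_count_non_increasing_in_max_gap(self):
        rng = np.random.default_rng(3)
        positions = np.unique(rng.integers(0, 50_000, size=400))
        counts = [len(cluster_tss(make_tss(positions), g)) for g in (0, 1, 5, 25, 100, 1000)]
        assert counts == sorted(counts, reverse=True)


class TestMetrics:
    def test_worked_example_row(self, worked_tss):
        cl = cluster_tss(worked_tss, 25)
        row = compute_metrics(worked_tss, cl, label="fix", threshold=1)
        assert row.n_tss == 4 and row.n_clusters == 3
        assert row.mean_cluster_width == pytest.approx(13 / 3)
        assert row.mean_tss_per_cluster == pytest.approx(4 / 3)
        assert row.mean_inter_tss_distance == pytest.approx(100 / 3)
        assert row.mean_inter_cluster_distance == pytest.approx(45.0)

    def test_identity_holds_exactly(self):
        rng = np.random.default_rng(5)
        positions = np.unique(rng.integers(0, 100_000, size=800))
        tss = make_tss(positions)
        cl = cluster_tss(tss, 25)
        row = compute_metrics(tss, cl)
        assert row.mean_tss_per_cluster * row.n_clusters == pytest.approx(row.n_tss)

    def test_empty_tss_set_gives_zero_row_with_missing_distances(self):
        tss = make_tss([])
        row = compute_metrics(tss, cluster_tss(tss, 25))
        assert row.n_tss == 0 and row.n_clusters == 0
        assert math.isnan(row.mean_inter_tss_distance)
        assert math.isnan(row.mean_inter_cluster_distance)

    def test_single_cluster_has_no_inter_cluster_distance(self):
        tss = make_tss([10, 20])
        row = compute_metrics(tss, cluster_tss(tss, 25))
        assert row.n_clusters == 1
        assert math.isnan(row.mean_inter_cluster_distance)

    def test_pooling_does_not_cross_sequences(self):
        a = make_tss([0, 10])
        b = TSSSet("t", np.array([5000]), np.array([1]))
        ca, cb = cluster_tss(a, 25), cluster_tss(b, 25)
        row = compute_metrics([a, b], [ca, cb])
        # no distance between chromosome a's cluster and chromosome b's
        assert math.isnan(row.mean_inter_cluster_distance)
        assert row.mean_inter_tss_distance == pytest.approx(10.0)

    def test_report_rounding_matches_conventions(self, worked_tss):
        cl = cluster_tss(worked_tss, 25)
        df = metrics_table([compute_metrics(worked_tss, cl, label="fix")])
        assert df["Mean cluster width"].iloc[0] == 4.3
        assert df["Mean number of TSSs per cluster"].iloc[0] == 1.33
        assert df["Mean inter-TSS distance"].iloc[0] == 33.0


class TestInterClusterDistances:
    def test_worked_example(self, worked_tss):
        cl = cluster_tss(worked_tss, 25)
        assert inter_cluster_distances(cl).tolist() == [30, 60]

    def test_one_cluster_per_chromosome_gives_no_distances(self):
        a = cluster_tss(make_tss([10]), 25)
        b = cluster_tss(TSSSet("t", np.array([20]), np.array([1])), 25)
        assert inter_cluster_distances([a, b]).tolist() == []

    def test_minimal_legal_separation_is_max_gap_plus_one(self):
        cl = cluster_tss(make_tss([0, 26]), 25)
        assert len(cl) == 2
        assert inter_cluster_distances(cl).tolist() == [26]


class TestHistogram:
    def test_decade_binning_left_closed_right_open(self):
        hist = distance_histogram([10, 10, 1000], edges=np.array([1, 10, 100, 1000, 10000]))
        assert hist.counts.tolist() == [0, 2, 0, 1]
        assert hist.total == 3

    def test_empty_distances_give_zero_counts(self):
        hist = distance_histogram([], n_bins=10, range=(1, 1e4))
        assert hist.total == 0 and len(hist.counts) == 10

    def test_identical_distances_fill_single_bin(self):
        hist = distance_histogram([500] * 7, n_bins=20, range=(1, 1e6))
        assert hist.counts.max() == 7 and (hist.counts > 0).sum() == 1

    def test_conservation_with_out_of_range_values(self):
        hist = distance_histogram([0.5 + 1, 1, 10**9], n_bins=10, range=(10, 1e4))
        assert hist.total == 3

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([0, 10])


class TestModes:
    def test_single_lognormal_gap_sample_is_unimodal(self):
        rng = np.random.default_rng(12)
        d = np.round(10 ** rng.normal(2.5, 0.2, size=5000)).clip(min=1)
        assert count_modes(distance_histogram(d)) == 1

    def test_well_separated_three_component_mixture_is_trimodal(self):
        rng = np.random.default_rng(13)
        parts = [10 ** rng.normal(loc, 0.12, size=2000) for loc in (1.7, 2.48, 4.18)]
        d = np.round(np.concatenate(parts)).clip(min=1)
        hist = distance_histogram(d)
        assert count_modes(hist) == 3
        peaks = histogram_peaks(hist)
        for peak, median in zip(sorted(peaks), (50, 300, 15000)):
            assert median / 2 <= peak <= median * 2

    def test_empty_histogram_has_zero_modes(self):
        assert count_modes(distance_histogram([], n_bins=10, range=(1, 100))) == 0


class TestThresholdSweep:
    def test_tss_counts_from_worked_counts(self):
        track = PseudoReadTrack("s", np.array([0, 2, 0, 1, 5]))
        rows = threshold_sweep(track, [1, 2, 5])
        assert [r.n_tss for r in rows] == [3, 2, 1]

    def test_single_threshold_reproduces_default_pipeline_row(self, worked_tss):
        counts = np.zeros(300, dtype=int)
        counts[worked_tss.positions] = worked_tss.counts
        (row,) = threshold_sweep(PseudoReadTrack("chrS", counts), [1])
        direct = compute_metrics(worked_tss, cluster_tss(worked_tss, 25), threshold=1)
        assert (row.n_tss, row.n_clusters, row.mean_cluster_width) == (
            direct.n_tss, direct.n_clusters, direct.mean_cluster_width)

    def test_thresholds_above_max_count_give_empty_rows(self):
        track = PseudoReadTrack("s", np.array([0, 2, 0, 1]))
        rows = threshold_sweep(track, [5, 10])
        assert [r.n_tss for r in rows] == [0, 0]

    def test_n_tss_non_increasing_in_threshold(self):
        track, _ = gen_tss_track(TrackModel(length=500_000, seed=3))
        pseudo = to_pseudo_reads(track)
        rows = threshold_sweep(pseudo, [1, 2, 3, 5, 8])
        n = [r.n_tss for r in rows]
        assert n == sorted(n, reverse=True)

    def test_descending_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(PseudoReadTrack("s", np.array([1])), [2, 1])
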