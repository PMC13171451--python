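# Methods

## Scope and model

`noisefloor` operates downstream of a transcription-initiation signal source.
It never models the sequence → signal relationship itself; it takes per-base
signal on the log10(s+1) scale (s a read count) for one sequence and strand,
together with a (possibly randomized) softmasked genome sequence, and computes
the spatial statistics of transcription start sites. Strands are independent
end to end. All coordinates are 0-based half-open, matching BED/bedGraph.

## Randomization operators

**Reversal** reverses character order without complementation. It preserves
mononucleotide composition exactly and maps the dinucleotide multiset XY → YX,
so it destroys directional sequence information while keeping local
composition statistics.

**Global k-let shuffling** preserves the exact multiset of overlapping
k-lets. For k=1 this is a uniform permutation. For k=2 it is the Euler-path
construction on the de Bruijn multigraph (the Altschul–Erickson approach):
vertices are (k−1)-mers, edges the k-lets of the input; a last-outgoing-edge
per vertex is drawn uniformly and rejected until those edges form an
arborescence toward the terminal vertex, the remaining out-edges are randomly
ordered, and the Eulerian path is walked from the initial vertex. Consequences
worth noting: the first and last residues are always fixed, and a sequence
whose k-let multiset admits only one arrangement (e.g. "AAC", "ATATAT" at
k=2) is returned unchanged — correctly, since the input is the unique valid
output. Rejection sampling terminates quickly in practice because the de
Bruijn graph of any realistic sequence is small (≤ 10 vertices over the
case-sensitive nucleotide alphabet); the loop is capped at 10^5 draws as a
safety net.

**Windowed (local) shuffling** applies the k-let shuffle to sliding windows
(default 100 bp window, 50 bp step) in place, left to right, each shuffle
acting on the current — possibly already-shuffled — content. With step <
window the overlap region is therefore re-shuffled by later windows. This
sequential in-place reading of sliding-window shuffling is a design choice:
window semantics differ between shuffling tools and are rarely documented;
total composition is exactly preserved under any such choice, which is what
the downstream analysis relies on.

**Mask-class randomization** extracts every maximal lowercase (repeat) or
uppercase (non-repeat) run by regular expression, independently reverses or
shuffles it (global mononucleotide by default), and reinserts it at its
original coordinates. Off-target positions are byte-identical and the case
pattern — hence the mask interval set — is invariant.

Case handling in whole-sequence shuffles: characters carry their case, so the
mask is scrambled along with the sequence. Downstream repeat analyses of
shuffled genomes must therefore use the original mask coordinates (BED), not
the shuffled file's case; mask-class randomization, by contrast, preserves the
in-file mask. 'N' participates in shuffles as an ordinary fifth symbol.

Determinism: every operator takes a single seed; per-run and per-window
substreams are spawned with `numpy.random.SeedSequence`, so outputs are
bitwise reproducible and independent of execution order.

## Signal chain

Pseudo-read conversion computes x = 10^v − 1 per base, sets x < 1 to zero and
rounds x ≥ 1 half away from zero. Two boundary choices are deliberate: x
exactly 1 maps to 1 (continuity with the round-trip property), and rounding
is half-away-from-zero rather than banker's so fixtures are stable. The
conversion exactly inverts the encoding: for any integer s ≥ 0,
log10(s+1) → s (property-tested up to 10^6; the float excursion of
10^log10(s+1) is far below the 0.5 rounding margin). TSS calling selects
positions with count ≥ threshold (default 1).

Per-window prediction tracks are stitched into chromosome coordinates by
offset placement with zero fill; distances downstream are computed on the
stitched coordinates, so they may span window boundaries. Multiple assay
tracks for one sequence/strand can be reduced by per-base max (default) or
sum before calling — which reduction is appropriate depends on the upstream
predictor and is configuration, not a fixed choice.

## Clustering and metrics

Clustering is single linkage with a max-gap parameter: consecutive TSSs at
most `max_gap` (default 25) bp apart share a cluster. Single linkage over
sorted positions is exactly the transitive closure of the pairwise
≤ max_gap relation, which is what interval-merge tooling (e.g. IRanges-style
gap merging) computes; the test suite checks this equivalence against a
brute-force O(n²) union-find oracle. Cluster width is the inclusive span
end − start + 1, so a singleton has width 1. Mean TSSs per cluster is
n_tss / n_clusters, an identity maintained at full precision and verified on
every pipeline run.

Inter-TSS distances are differences of consecutive TSS positions;
inter-cluster distance is start(next) − end(previous), i.e. the gap between
spans, not start-to-start — "distance to the next cluster" read as
separation. Neither distance crosses a sequence or strand boundary; means are
pooled across sequences. With fewer than two TSSs (or clusters) the
corresponding mean is reported as missing (NaN). Report tables round widths
to 1 dp, TSSs per cluster to 2 dp and distances to integer bp; internal
values are never rounded.

Distance histograms use 100 log10-spaced bins from 1 bp to 10^8 bp by
default, left-closed right-open, with out-of-range values clipped into the
end bins so counts are conserved. Modality is the number of local maxima of
the moving-average-smoothed histogram (bandwidth 5 bins in log space) with
prominence ≥ 5% of the tallest smoothed bin — deterministic and scale-free
enough to distinguish one from three modes at the sample sizes the generator
produces; it is a descriptive statistic, not a significance test.

Threshold sweeps re-call TSSs at each threshold of an ascending list and
recompute all six metrics; the TSS count is non-increasing by construction.

## Repeat partitioning

TSSs are assigned to the repeat or non-repeat interval containing their
position, half-open, consistent with BED (a TSS exactly at an interval end
belongs to the following interval). Class lengths for the density
denominators come from the same mask used for classification, so mask and
TSS set must share a coordinate system (enforced via sequence names).
Densities satisfy density_repeat·repeat_kb + density_nonrepeat·nonrepeat_kb
= total TSSs exactly, pre-rounding.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, with
every draw recorded as ground truth.

*Masked genomes.* Bases are i.i.d. uniform; case alternates between
lowercase and uppercase runs with geometric lengths. Repeat runs have mean
300 bp — a round figure in the range of common interspersed repeats (SINE
elements are ~100–300 bp, truncated LINE copies longer) — and non-repeat run
means are scaled by (1−f)/f so the stationary lowercase fraction equals the
configured repeat fraction f (default 0.403, the repeat share of the human
genome). At 1 Mb the realized fraction concentrates within ±0.02 of f.

*Tracks.* Clusters are laid down left to right. Inter-cluster gaps (end of
one cluster to start of the next, matching the analysis definition) are
drawn from a three-component log-normal mixture with weights 0.30/0.40/0.30,
log10 locations at 50, 300 and 15,000 bp and log10 scales 0.12/0.12/0.20:
medians at the three observed gap modes, scales narrow enough that the modes
are separable in a 10 Mb sample, and weights chosen so no mode is rare. The
number of TSSs per cluster is shifted Poisson, 1 + Poisson(mean−1), with
mean 7.8 (the per-cluster TSS count scale of dense native initiation
maps); adjacent members are spaced uniformly on 1..7 bp, which caps realized
spans near the ~100 bp upper range of typical initiation clusters (hard cap
100 bp, enforced by shrinking the widest spacings) and — because every
intra-cluster spacing is ≤ 25 bp — guarantees a truth cluster is never split
by 25 bp max-gap clustering. Mis-merges in the other direction occur exactly
when a sampled gap is ≤ 25 bp (probability ~0.2% per gap under the default
mixture), so pipeline recovery of truth clusters exceeds 99% and every
mis-merge is attributable to a recorded gap.

*Magnitudes.* Each cluster draws a heavy-tailed strength B = 1 + Pareto(1.3);
member counts are max(1, round(B·ε)) with ε log-normal (sd 0.05). Promoter
strength is modeled as a property of the initiation region, shared by its
TSSs: this makes clusters respond to read thresholds as units, so threshold
sweeps thin the number of TSSs steeply (the Pareto tail) while cluster-shape
statistics (mean width, mean TSSs per cluster) stay within ~10% — the
qualitative robustness signature of real initiation data. Independent
per-TSS magnitudes cannot produce this: random within-cluster thinning
shrinks mean TSSs per cluster roughly in proportion to survival. The member
scatter is kept small (5%) because integer thresholds make larger scatter
act like independent thinning again.

Emitted values are log10(count+1), so the signal chain must invert the
encoding exactly for truth recovery to succeed — the recovery tests exercise
the real pipeline path, not a shortcut.

*What passing synthetic tests does not show.* The generator has no
sequence→signal dependence, no chromosome-scale heterogeneity
(centromeres, gene deserts), no strand asymmetry and no correlated noise;
results on synthetic tracks validate the operators and the metric
definitions, not biological conclusions about any real genome.

## Problem sizes and numerical choices

Default test and acceptance runs use a 10 Mb track (~1,900 clusters, ~15,000
TSSs) for distribution-level checks and 1 Mb for partition checks — large
enough that the three gap modes are resolved and recovery rates are stable
across seeds, while a full run of the suite plus the acceptance script stays
in the tens of seconds. Degenerate inputs are defined, not errored, wherever
a sensible value exists: empty TSS sets yield zero-count rows with missing
distances, a sequence too short for one cluster yields an empty track, and a
k-let-shuffle input with a unique arrangement is returned unchanged.

## Known limitations

* The six metrics are spatial only; initiation magnitude beyond thresholding
  is deliberately out of scope.
* Mode counting on very sparse histograms (tens of distances) is noisy; the
  prominence floor suppresses spurious peaks but cannot create power that
  isn't there.
* bedGraph ingestion materializes dense per-base arrays (8 bytes/base), which
  is the right trade for chromosome-scale scans but not for sparse genome-wide
  storage.
* The windowed-shuffle overlap semantics are one defensible reading among
  several; composition invariants hold regardless, but exact outputs are not
  comparable across tools with different window conventions.
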