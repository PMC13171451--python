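"""End-to-end orchestration: signal -> pseudo-reads -> TSSs -> clusters -> reports.

A run is described by a single declarative :class:`RunConfig` (loadable from
YAML); :func:`run_pipeline` executes the stages and writes a metrics table,
distance histograms, an optional repeat/non-repeat partition table, and a
machine-readable manifest sufficient to re-derive every output. Re-running
with the same config and seed reproduces every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster_metrics import (
    cluster_tss,
    compute_metrics,
    distance_histogram,
    inter_cluster_distances,
    metrics_table,
    threshold_sweep,
)
from .genome_io import read_bed
from .repeat_partition import class_summary, classify_tss, summary_table
from .signal_io import call_tss, read_bedgraph, to_pseudo_reads, write_tss_bed
from .synthetic_data import TrackModel, gen_tss_track

log = logging.getLogger("noisefloor")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Exactly one of ``bedgraph`` (a real signal file) or ``synthetic`` (keyword
    arguments for :class:`TrackModel`) must be supplied. ``mask`` is an
    optional BED4 repeat/non-repeat file; when present the partition table is
    produced. ``thresholds`` must be ascending.
    """

    out_dir: str | Path = "noisefloor_out"
    label: str = "run"
    bedgraph: str | Path | None = None
    synthetic: dict | None = None
    mask: str | Path | None = None
    thresholds: list[int] = field(default_factory=lambda: [1])
    max_gap: int = 25
    seed: int = 0
    histogram_bins: int = 100
    histogram_range: tuple[float, float] = (1.0, 1e8)

    def __post_init__(self) -> None:
        if (self.bedgraph is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'bedgraph' or 'synthetic' must be set")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly ascending")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "histogram_range" in raw:
            raw["histogram_range"] = tuple(raw["histogram_range"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis described by ``config``.

    Writes under ``config.out_dir``: ``metrics.tsv`` (one row per threshold in
    the standard six-metric column order), ``tss_threshold<t>.bed`` for the
    lowest threshold, ``histogram_threshold<t>.tsv`` per threshold, optionally
    ``partition.tsv``, and ``manifest.json``. Returns the output paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    try:
        if config.bedgraph is not None:
            tracks = read_bedgraph(config.bedgraph)
            source = {"bedgraph": str(config.bedgraph), "sha256": _sha256(Path(config.bedgraph))}
        else:
            params = dict(config.synthetic or {})
            params.setdefault("seed", config.seed)
            model = TrackModel(**params)
            track, _ = gen_tss_track(model)
            tracks = [track]
            source = {"synthetic": params}
    except (OSError, ValueError, TypeError) as exc:
        raise PipelineError(f"stage signal-input: {exc}") from exc
    log.info("signal-input: %d track(s)", len(tracks))

    try:
        pseudo = [to_pseudo_reads(t) for t in tracks]
    except ValueError as exc:
        raise PipelineError(f"stage pseudo-reads: {exc}") from exc
    log.info("pseudo-reads: %s total reads", sum(int(p.counts.sum()) for p in pseudo))

    try:
        rows = threshold_sweep(pseudo, config.thresholds, max_gap=config.max_gap,
                               label=config.label)
    except ValueError as exc:
        raise PipelineError(f"stage metrics: {exc}") from exc
    for row in rows:
        log.info(
            "metrics[threshold=%d]: %d TSSs, %d clusters, %.2f TSSs/cluster",
            row.threshold, row.n_tss, row.n_clusters, row.mean_tss_per_cluster,
        )
    metrics_path = out / "metrics.tsv"
    metrics_table(rows).to_csv(metrics_path, sep="\t", index=False)
    outputs["metrics"] = metrics_path

    base_tss = [call_tss(p, config.thresholds[0]) for p in pseudo]
    tss_path = out / f"tss_threshold{config.thresholds[0]}.bed"
    write_tss_bed(base_tss, tss_path)
    outputs["tss_bed"] = tss_path

    for thr in config.thresholds:
        tss = [call_tss(p, thr) for p in pseudo]
        clusters = [cluster_tss(t, config.max_gap) for t in tss]
        hist = distance_histogram(
            inter_cluster_distances(clusters),
            n_bins=config.histogram_bins,
            range=config.histogram_range,
        )
        hist_path = out / f"histogram_threshold{thr}.tsv"
        with open(hist_path, "w") as fh:
            fh.write("bin_left\tcount\n")
            for left, count in zip(hist.edges[:-1], hist.counts):
                fh.write(f"{left:.6g}\t{count}\n")
        outputs[f"histogram_{thr}"] = hist_path

    if config.mask is not None:
        try:
            mask = read_bed(config.mask)
            counts = classify_tss(base_tss, mask)
            summary = class_summary(counts, mask, label=config.label)
        except (OSError, ValueError) as exc:
            raise PipelineError(f"stage partition: {exc}") from exc
        log.info(
            "partition: %d repeat / %d non-repeat TSSs",
            summary.n_repeat_tss, summary.n_nonrepeat_tss,
        )
        partition_path = out / "partition.tsv"
        summary_table([summary]).to_csv(partition_path, sep="\t", index=False)
        outputs["partition"] = partition_path

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "label": config.label,
        "source": source,
        "mask": str(config.mask) if config.mask else None,
        "thresholds": list(config.thresholds),
        "max_gap": config.max_gap,
        "histogram_bins": config.histogram_bins,
        "histogram_range": list(config.histogram_range),
        "outputs": {k: v.name for k, v in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = manifest_path

    # verify the six-metric identity before handing results back
    for row in rows:
        if row.n_clusters and abs(row.mean_tss_per_cluster * row.n_clusters - row.n_tss) > 1e-6:
            raise PipelineError(f"stage metrics: identity violated at threshold {row.threshold}")
    return outputs
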