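"""Partition TSSs into repeat and non-repeat classes and normalize by class length.

Repeat-derived sequence (mostly transposable elements) occupies a large
fraction of mammalian genomes, so raw per-class TSS counts are compared via
length-normalized densities (TSS per kb of class sequence). Classification is
by half-open interval containment against the softmask-derived intervals; the
mask and the TSS set must share a coordinate system, enforced by matching
sequence names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import MaskIntervals
from .signal_io import TSSSet

__all__ = ["ClassSummary", "classify_tss", "class_summary", "summary_table"]


@dataclass
class ClassSummary:
    """Per-class TSS counts, percentages and densities for one dataset.

    Percentages are full precision (round at report time); densities are TSS
    per kb of class sequence. Percentage fields are NaN when there are no TSSs.
    """

    label: str
    n_repeat_tss: int
    n_nonrepeat_tss: int
    pct_repeat: float
    pct_nonrepeat: float
    repeat_length: int
    nonrepeat_length: int
    density_repeat: float
    density_nonrepeat: float

    @property
    def total_tss(self) -> int:
        return self.n_repeat_tss + self.n_nonrepeat_tss

    def to_row(self) -> dict:
        """Report-shaped dict with percentages rounded to 1 dp."""
        return {
            "Dataset": self.label,
            "TSSs within repeats": self.n_repeat_tss,
            "TSSs within non-repeats": self.n_nonrepeat_tss,
            "Repeat (% total)": round(self.pct_repeat, 1),
            "Non-repeat (% total)": round(self.pct_nonrepeat, 1),
            "Total TSS count": self.total_tss,
            "TSS per repeat length": self.density_repeat,
            "TSS per non-repeat length": self.density_nonrepeat,
        }


def classify_tss(
    tss: TSSSet | Sequence[TSSSet], mask: MaskIntervals
) -> tuple[int, int]:
    """Count TSSs falling in repeat vs non-repeat intervals (half-open containment).

    Every TSS position must be covered by the mask; an uncovered position (or a
    sequence name absent from the mask) is an error, since it indicates the
    mask and TSS set are not from the same coordinate system.
    """
    tss_list = tss if isinstance(tss, (list, tuple)) else [tss]
    n_repeat = n_nonrepeat = 0
    for t in tss_list:
        ivals = mask.for_sequence(t.name)
        if not ivals and len(t):
            raise ValueError(f"no mask intervals for sequence {t.name!r}")
        if not len(t):
            continue
        starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
        is_repeat = np.array([c == "repeat" for _, _, c in ivals])
        # mask intervals tile [0, length), so searchsorted on starts locates
        # the containing interval; positions beyond the last end are uncovered
        idx = np.searchsorted(starts, t.positions, side="right") - 1
        if np.any(idx < 0) or np.any(t.positions >= ends[np.clip(idx, 0, None)]):
            bad = t.positions[(idx < 0) | (t.positions >= ends[np.clip(idx, 0, None)])][0]
            raise ValueError(f"TSS at {t.name}:{bad} outside mask coverage")
        rep = int(is_repeat[idx].sum())
        n_repeat += rep
        n_nonrepeat += len(t) - rep
    return n_repeat, n_nonrepeat


def class_summary(
    counts: tuple[int, int], mask: MaskIntervals, label: str = ""
) -> ClassSummary:
    """Build the per-class summary from (repeat, non-repeat) counts and a mask.

    Class lengths come from the same mask used for classification; densities
    divide counts by class length in kb. Density conservation holds exactly:
    density_repeat*repeat_kb + density_nonrepeat*nonrepeat_kb == total TSSs.
    """
    n_repeat, n_nonrepeat = counts
    total = n_repeat + n_nonrepeat
    rep_len = mask.class_length("repeat")
    nonrep_len = mask.class_length("non_repeat")
    for n, length, cls in ((n_repeat, rep_len, "repeat"), (n_nonrepeat, nonrep_len, "non_repeat")):
        if n > 0 and length == 0:
            raise ValueError(f"{cls} TSSs present but {cls} class length is zero")
    return ClassSummary(
        label=label,
        n_repeat_tss=n_repeat,
        n_nonrepeat_tss=n_nonrepeat,
        pct_repeat=100.0 * n_repeat / total if total else float("nan"),
        pct_nonrepeat=100.0 * n_nonrepeat / total if total else float("nan"),
        repeat_length=rep_len,
        nonrepeat_length=nonrep_len,
        density_repeat=n_repeat / (rep_len / 1000.0) if rep_len else 0.0,
        density_nonrepeat=n_nonrepeat / (nonrep_len / 1000.0) if nonrep_len else 0.0,
    )


def summary_table(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    """Stack class summaries into a report table."""
    return pd.DataFrame([s.to_row() for s in summaries])
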