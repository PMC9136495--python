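"""Consensus open-chromatin peak sets.

ATAC-seq peak callers emit variable-width peaks per sample. To compare
accessibility across samples the peaks are standardized to a fixed width
(summit +/- 250 bp, 501 bp total) and merged into a single non-overlapping
"common" peak set by iterative overlap removal: repeatedly keep the peak
with the strongest signal (-log10 FDR) and discard everything it overlaps.
"""

from __future__ import annotations

import logging
from bisect import bisect_right, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "summit", "score", "sample_id"]

HALF_WIDTH = 250
FIXED_WIDTH = 2 * HALF_WIDTH + 1  # summit +/- 250, summit included


@dataclass(frozen=True)
class Peak:
    """A scored genomic interval with a summit (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float
    sample_id: str = ""
    peak_id: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end}) for {self.peak_id!r}"
            )
        if self.score < 0:
            raise ValueError(f"negative score {self.score} for {self.peak_id!r}")


@dataclass
class PeakSet:
    """An ordered collection of peaks backed by a DataFrame.

    ``provenance`` tracks how the set was built (``raw``, ``fixed-width``,
    ``iterated`` or ``common``); iterated/common sets are guaranteed
    pairwise non-overlapping within each chromosome.
    """

    df: pd.DataFrame
    width_fixed: bool = False
    provenance: str = "raw"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"PeakSet missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_peaks(cls, peaks: list[Peak], **kwargs) -> "PeakSet":
        rows = [
            (p.peak_id, p.chrom, p.start, p.end, p.summit, p.score, p.sample_id)
            for p in peaks
        ]
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
        return cls(df, **kwargs)

    @classmethod
    def empty(cls, **kwargs) -> "PeakSet":
        return cls(pd.DataFrame(columns=PEAK_COLUMNS), **kwargs)

    def sorted_by_coordinate(self) -> "PeakSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return PeakSet(df, width_fixed=self.width_fixed, provenance=self.provenance,
                       extra=dict(self.extra))


def fixed_width(
    peaks: PeakSet,
    chrom_sizes: dict[str, int],
    half_width: int = HALF_WIDTH,
) -> PeakSet:
    """Extend each summit by ``half_width`` on both sides.

    Output intervals are ``[summit - half_width, summit + half_width + 1)``
    (width ``2*half_width + 1``; the summit base is included). Peaks whose
    window would cross a chromosome boundary — or whose chromosome is not in
    ``chrom_sizes`` — are dropped with a logged warning, preserving the
    fixed-width invariant.
    """
    df = peaks.df.copy()
    if len(df) == 0:
        return PeakSet(df, width_fixed=True, provenance="fixed-width")
    sizes = df["chrom"].map(chrom_sizes)
    unknown = sizes.isna()
    if unknown.any():
        logger.warning("dropping %d peaks on chromosomes without a known size", int(unknown.sum()))
    start = df["summit"] - half_width
    end = df["summit"] + half_width + 1
    inside = (~unknown) & (start >= 0) & (end <= sizes.fillna(-1))
    n_drop = int((~inside).sum()) - int(unknown.sum())
    if n_drop > 0:
        logger.warning("dropping %d peaks whose fixed-width window crosses a chromosome end", n_drop)
    out = df.loc[inside].copy()
    out["start"] = start[inside].astype(int)
    out["end"] = end[inside].astype(int)
    return PeakSet(out, width_fixed=True, provenance="fixed-width")


def _greedy_order(df: pd.DataFrame) -> pd.DataFrame:
    # descending score; ties broken by earlier coordinate, then summit/id for
    # full determinism
    return df.sort_values(
        ["score", "chrom", "start", "end", "summit", "peak_id", "sample_id"],
        ascending=[False, True, True, True, True, True, True],
        kind="mergesort",
    )


def iterative_overlap_filter(peaks: PeakSet, provenance: str = "iterated") -> PeakSet:
    """Greedy selection of non-overlapping peaks in descending score order.

    Repeatedly keep the highest-scoring remaining peak and remove every peak
    that shares >= 1 bp with it on the same chromosome, until all peaks are
    accounted for. Equal scores are broken by earlier coordinate. Output is
    sorted by coordinate and pairwise non-overlapping.
    """
    df = peaks.df
    if len(df) == 0:
        return PeakSet.empty(width_fixed=peaks.width_fixed, provenance=provenance)
    ordered = _greedy_order(df)
    # kept intervals per chromosome, as parallel sorted lists of starts/ends;
    # kept peaks are non-overlapping so a candidate can only hit the
    # predecessor or successor of its insertion point
    kept_starts: dict[str, list[int]] = {}
    kept_ends: dict[str, list[int]] = {}
    keep_idx: list[int] = []
    chroms = ordered["chrom"].to_numpy()
    starts = ordered["start"].to_numpy()
    ends = ordered["end"].to_numpy()
    for i in range(len(ordered)):
        chrom, s, e = chroms[i], int(starts[i]), int(ends[i])
        cs = kept_starts.setdefault(chrom, [])
        ce = kept_ends.setdefault(chrom, [])
        pos = bisect_right(cs, s)
        if pos > 0 and ce[pos - 1] > s:
            continue
        if pos < len(cs) and cs[pos] < e:
            continue
        cs.insert(pos, s)
        ce.insert(pos, e)
        keep_idx.append(i)
    out = ordered.iloc[keep_idx].sort_values(["chrom", "start"], kind="mergesort")
    return PeakSet(out, width_fixed=peaks.width_fixed, provenance=provenance)


def build_common_peak_set(per_sample: list[PeakSet]) -> PeakSet:
    """Pool fixed-width peaks from all samples and filter once.

    Returns the common (consensus) peak set: non-overlapping fixed-width
    peaks carrying the best score among contributors. Each kept peak gets a
    fresh ``peak_id`` (``ocr_N`` in coordinate order) and a ``samples``
    column listing the sample ids of all pooled peaks it overlaps.
    """
    if not per_sample:
        return PeakSet.empty(width_fixed=True, provenance="common")
    for ps in per_sample:
        if len(ps) and not ps.width_fixed:
            raise ValueError("build_common_peak_set expects fixed-width input peaks")
    pooled = pd.concat([ps.df for ps in per_sample], ignore_index=True)
    merged = iterative_overlap_filter(PeakSet(pooled, width_fixed=True), provenance="common")
    out = merged.df.reset_index(drop=True)
    out["samples"] = _contributing_samples(out, pooled)
    out["peak_id"] = [f"ocr_{i + 1}" for i in range(len(out))]
    return PeakSet(out, width_fixed=True, provenance="common")


def _contributing_samples(kept: pd.DataFrame, pooled: pd.DataFrame) -> list[str]:
    """For each kept peak, the sorted unique sample ids of pooled peaks overlapping it."""
    result = []
    by_chrom = {c: g.sort_values("start") for c, g in pooled.groupby("chrom")}
    for chrom, s, e in zip(kept["chrom"], kept["start"], kept["end"]):
        g = by_chrom[chrom]
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        hit = (gs < e) & (ge > s)
        result.append(",".join(sorted(set(g.loc[hit, "sample_id"]))))
    return result
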