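"""Variant / QTL geometry relative to open chromatin.

Distances from point variants (SNPs) to the nearest peak are measured to
the nearest peak base: 0 inside a peak, otherwise ``start - pos`` to the
left edge or ``pos - (end - 1)`` to the last covered base. Distances are
summarized into the six conventional bins 0, (0,0.5], (0.5,1.5], (1.5,3],
(3,10] and >10 kb. QTL intervals are scored for overlap (>= 1 shared base,
half-open coordinates) with any peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import PeakSet

BIN_LABELS = ("0", "0-0.5", "0.5-1.5", "1.5-3", "3-10", ">10")
#: right edges in bp of the first five bins; the sixth is unbounded
BIN_EDGES = (0, 500, 1500, 3000, 10_000)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos"]
QTL_COLUMNS = ["qtl_id", "chrom", "start", "end"]


def distance_bin(distance: float) -> str:
    """Bin label for a nonnegative distance in bp; left-open, right-closed."""
    if distance < 0:
        raise ValueError(f"negative distance {distance}")
    if distance == 0:
        return BIN_LABELS[0]
    for label, hi in zip(BIN_LABELS[1:], BIN_EDGES[1:]):
        if distance <= hi:
            return label
    return BIN_LABELS[-1]


class _ChromIndex:
    """Sorted starts plus running max of ends; exact for overlapping peaks too."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray) -> None:
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.cummax_end = np.maximum.accumulate(ends[order])

    def nearest_distance(self, pos: int) -> int:
        i = np.searchsorted(self.starts, pos, side="right")
        left = np.inf
        if i > 0:
            # farthest-reaching peak among those starting at or before pos
            left = max(0, pos - (int(self.cummax_end[i - 1]) - 1))
        right = int(self.starts[i]) - pos if i < len(self.starts) else np.inf
        return int(min(left, right))

    def overlaps(self, start: int, end: int) -> bool:
        i = np.searchsorted(self.starts, end, side="left")
        return i > 0 and int(self.cummax_end[i - 1]) > start


def _index_peaks(peaks: PeakSet) -> dict[str, _ChromIndex]:
    out = {}
    for chrom, grp in peaks.df.groupby("chrom"):
        out[chrom] = _ChromIndex(
            grp["start"].to_numpy(dtype=int), grp["end"].to_numpy(dtype=int)
        )
    return out


def nearest_peak_distance(variants: pd.DataFrame, peaks: PeakSet) -> pd.Series:
    """Distance in bp from each variant to its nearest peak.

    Returns a float Series aligned to ``variants`` (columns variant_id,
    chrom, pos); NaN where the variant's chromosome carries no peak
    (undefined, not an error).
    """
    index = _index_peaks(peaks)
    dists = []
    for chrom, pos in zip(variants["chrom"], variants["pos"]):
        idx = index.get(chrom)
        dists.append(np.nan if idx is None else idx.nearest_distance(int(pos)))
    return pd.Series(dists, index=variants.index, name="distance", dtype=float)


def bin_distances(distances: pd.Series | np.ndarray) -> pd.DataFrame:
    """Counts and fractions of defined distances in the six distance bins.

    Fractions are over variants with a defined (non-NaN) distance and sum
    to 1 when any are defined; the undefined count is carried in
    ``attrs["n_undefined"]``.
    """
    arr = np.asarray(distances, dtype=float)
    defined = arr[~np.isnan(arr)]
    if (defined < 0).any():
        raise ValueError("negative distances violate the nearest-distance contract")
    labels = [distance_bin(d) for d in defined]
    counts = pd.Series(labels).value_counts()
    total = len(defined)
    out = pd.DataFrame(
        {
            "bin": BIN_LABELS,
            "count": [int(counts.get(b, 0)) for b in BIN_LABELS],
        }
    )
    out["fraction"] = out["count"] / total if total else 0.0
    out.attrs["n_undefined"] = int(np.isnan(arr).sum())
    return out


def qtl_overlap_fraction(qtls: pd.DataFrame, peaks: PeakSet) -> tuple[float, pd.Series]:
    """Fraction of QTL intervals sharing >= 1 bp with at least one peak.

    Returns (fraction, per-QTL boolean Series). Abutting intervals under
    half-open coordinates do not count as overlapping.
    """
    if len(qtls) == 0:
        raise ValueError("empty QTL list")
    index = _index_peaks(peaks)
    flags = []
    for chrom, start, end in zip(qtls["chrom"], qtls["start"], qtls["end"]):
        if end <= start:
            raise ValueError(f"invalid QTL interval [{start}, {end})")
        idx = index.get(chrom)
        flags.append(bool(idx is not None and idx.overlaps(int(start), int(end))))
    flags = pd.Series(flags, index=qtls.index, name="overlaps_peak")
    return float(flags.mean()), flags


@dataclass
class ProximityReport:
    """Combined variant/QTL vs open-chromatin geometry summary."""

    bin_table: pd.DataFrame
    n_variants: int
    n_undefined: int
    fraction_in_peaks: float
    fraction_within_3kb: float
    qtl_fraction_overlapping: float | None
    n_qtls: int

    def as_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "n_undefined": self.n_undefined,
            "bins": {
                row["bin"]: {"count": int(row["count"]), "fraction": float(row["fraction"])}
                for _, row in self.bin_table.iterrows()
            },
            "fraction_in_peaks": self.fraction_in_peaks,
            "fraction_within_3kb": self.fraction_within_3kb,
            "qtl_fraction_overlapping": self.qtl_fraction_overlapping,
            "n_qtls": self.n_qtls,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def proximity_report(
    variants: pd.DataFrame, qtls: pd.DataFrame | None, peaks: PeakSet
) -> ProximityReport:
    """Assemble distance-bin fractions and QTL overlap into one report.

    Deterministic: identical inputs produce byte-identical JSON. An empty
    variant table yields zero counts; QTLs are optional.
    """
    if len(variants):
        dists = nearest_peak_distance(variants, peaks)
        table = bin_distances(dists)
        defined = int(table["count"].sum())
        frac_in = float(table.loc[table["bin"] == "0", "fraction"].iloc[0]) if defined else 0.0
        within = table[table["bin"].isin(["0", "0-0.5", "0.5-1.5", "1.5-3"])]["fraction"].sum()
        n_undef = table.attrs["n_undefined"]
    else:
        table = bin_distances(np.array([]))
        frac_in, within, n_undef = 0.0, 0.0, 0
    if qtls is not None and len(qtls):
        qtl_frac, _ = qtl_overlap_fraction(qtls, peaks)
        n_qtls = len(qtls)
    else:
        qtl_frac, n_qtls = None, 0
    return ProximityReport(
        bin_table=table,
        n_variants=len(variants),
        n_undefined=n_undef,
        fraction_in_peaks=frac_in,
        fraction_within_3kb=float(within),
        qtl_fraction_overlapping=qtl_frac,
        n_qtls=n_qtls,
    )
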