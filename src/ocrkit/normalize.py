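"""Count normalization and stage-level summaries.

Raw feature-by-sample counts (genes or peaks) are normalized to counts per
million (CPM) and per-feature Z scores, then collapsed to stage level
(mean over replicates per time point, Z across the stage means). A simple
fold-change filter stands in for differential testing, and k-means on stage
Z profiles groups features into co-regulated clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

STAGE_ORDER = ("P", "D0", "D2", "D4")


@dataclass
class CountMatrix:
    """Raw counts (features x samples) plus the stage/replicate design.

    ``design`` has one row per sample with columns sample, stage, replicate;
    every column of ``counts`` must appear exactly once in the design.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample", "stage", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design missing column {col!r}")
        samples = list(self.design["sample"])
        if len(samples) != len(set(samples)):
            raise ValueError("duplicate sample ids in design")
        if set(self.counts.columns) != set(samples):
            raise ValueError("count matrix columns and design samples differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.design["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_of(self, stage: str) -> list[str]:
        return list(self.design.loc[self.design["stage"] == stage, "sample"])


@dataclass
class StageMatrix:
    """Per-feature stage-level summaries: mean CPM and Z across stage means."""

    mean_cpm: pd.DataFrame  # features x stages
    z: pd.DataFrame  # features x stages
    stage_order: tuple[str, ...] = STAGE_ORDER
    flags: dict = field(default_factory=dict)

    @property
    def features(self) -> pd.Index:
        return self.mean_cpm.index


class ZeroLibraryError(ValueError):
    pass


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``raw * 1e6 / library size`` per sample (column)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ZeroLibraryError(f"zero library size for sample(s): {list(zero.index)}")
    return mat * 1e6 / totals


def zscore(values: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-feature (row-wise) Z scores with sample standard deviation (n-1).

    Constant features get Z = 0 everywhere (flagged via a log message) so
    downstream set operations remain total.
    """
    if values.shape[1] < 2:
        raise ValueError("zscore requires at least 2 columns")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.info("zscore: %d constant feature(s) set to 0", int(constant.sum()))
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def stage_summarize(
    cpm_values: pd.DataFrame,
    design: pd.DataFrame,
    stage_order: tuple[str, ...] | None = None,
) -> StageMatrix:
    """Collapse per-sample CPM to stage means, then Z across the stage means."""
    if stage_order is None:
        seen: list[str] = []
        for s in design["stage"]:
            if s not in seen:
                seen.append(s)
        stage_order = tuple(seen)
    means = {}
    for stage in stage_order:
        samples = list(design.loc[design["stage"] == stage, "sample"])
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        means[stage] = cpm_values[samples].mean(axis=1)
    mean_cpm = pd.DataFrame(means, index=cpm_values.index)[list(stage_order)]
    z = zscore(mean_cpm)
    return StageMatrix(mean_cpm=mean_cpm, z=z, stage_order=tuple(stage_order))


def naive_differential(
    stages: StageMatrix,
    min_max_cpm: float = 1.0,
    min_fold: float = 4.0,
    pseudocount: float = 0.1,
) -> list[str]:
    """Fold-change-based selection of variable features.

    A feature is selected iff its maximal stage mean is at least
    ``min_max_cpm`` and max/(min + pseudocount) is at least ``min_fold``.
    This is a deliberately simple filter, not a dispersion-based test.
    """
    mx = stages.mean_cpm.max(axis=1)
    mn = stages.mean_cpm.min(axis=1)
    selected = (mx >= min_max_cpm) & (mx / (mn + pseudocount) >= min_fold)
    return list(stages.mean_cpm.index[selected])


def kmeans_profiles(
    z_profiles: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> pd.Series:
    """K-means on per-feature stage-Z vectors.

    Cluster labels are relabelled deterministically so that cluster order
    follows the stage of peak mean activity (earliest-peaking cluster first;
    ties broken by centroid profile).
    """
    if len(z_profiles) < k:
        raise ValueError(f"need at least k={k} features, got {len(z_profiles)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z_profiles.to_numpy(dtype=float))
    centers = km.cluster_centers_
    order = sorted(range(k), key=lambda c: (int(np.argmax(centers[c])), *(-centers[c])))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    return pd.Series(labels, index=z_profiles.index, name="cluster")
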