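import numpy as np
import pandas as pd
import pytest

from ocrkit import PeakSet, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=60, n_peaks=200, n_chromosomes=2, chromosome_length=1_500_000,
        n_variants_per_bin=3, n_qtls=20, seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def make_peakset(rows, **kwargs) -> PeakSet:
    """rows: (chrom, start, end, score) or (chrom, start, end, score, summit)."""
    recs = []
    for i, row in enumerate(rows):
        chrom, start, end, score = row[:4]
        summit = row[4] if len(row) > 4 else (start + end) // 2
        recs.append((f"p{i}", chrom, start, end, summit, score, "s"))
    df = pd.DataFrame(
        recs, columns=["peak_id", "chrom", "start", "end", "summit", "score", "sample_id"]
    )
    return PeakSet(df, **kwargs)


def random_fixed_width_peaks(rng: np.random.Generator, n: int, span: int = 100_000) -> PeakSet:
    """Random 501-bp peaks; scores rounded to one decimal so ties occur."""
    chroms = rng.choice(["chr1", "chr2"], size=n)
    summits = rng.integers(250, span, size=n)
    scores = np.round(rng.exponential(5.0, size=n) + 0.5, 1)
    df = pd.DataFrame(
        {
            "peak_id": [f"p{i}" for i in range(n)],
            "chrom": chroms,
            "start": summits - 250,
            "end": summits + 251,
            "summit": summits,
            "score": scores,
            "sample_id": "s",
        }
    )
    return PeakSet(df, width_fixed=True)


def brute_force_greedy(peaks: PeakSet) -> pd.DataFrame:
    """Direct O(n^2) simulation of iterative overlap removal.

    At every step the strongest remaining peak (ties: earlier coordinate) is
    re-identified from scratch among the survivors, then every overlapping
    survivor on its chromosome is deleted.
    """
    df = peaks.df.copy().reset_index(drop=True)
    n = len(df)
    priority = df.sort_values(
        ["score", "chrom", "start", "end", "summit", "peak_id", "sample_id"],
        ascending=[False, True, True, True, True, True, True],
        kind="mergesort",
    ).index.to_numpy()
    rank = np.empty(n, dtype=int)
    rank[priority] = np.arange(n)
    chrom = df["chrom"].astype("category").cat.codes.to_numpy()
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    alive = np.ones(n, dtype=bool)
    kept = []
    while alive.any():
        survivors = np.flatnonzero(alive)
        best = survivors[np.argmin(rank[survivors])]
        kept.append(best)
        overlapping = alive & (chrom == chrom[best]) & (start < end[best]) & (end > start[best])
        alive[overlapping] = False
    out = df.loc[kept].sort_values(["chrom", "start"], kind="mergesort")
    return out.reset_index(drop=True)
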