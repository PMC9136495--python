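"""Truth-labelled synthetic data for the full analysis pipeline.

The generator emulates a 4-stage differentiation time course (proliferating
myoblasts P, then differentiation days D0/D2/D4) with replicated ATAC-seq
and RNA-seq libraries: gene models on a small artificial genome, per-sample
variable-width peak calls jittered across replicates, negative-binomial
count matrices with planted stage-specific and housekeeping features,
promoter accessibility coupled to expression at a target rank correlation,
and variants placed at controlled distances from open chromatin. Every
planted signal is recorded in truth labels so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModelSet
from .normalize import CountMatrix
from .peaks import HALF_WIDTH, PeakSet
from .variants import BIN_LABELS, distance_bin

DEFAULT_STAGES = ("P", "D0", "D2", "D4")

#: sampling ranges (bp) for planted variant distances, kept clear of bin
#: edges so replicate jitter cannot move a variant across a bin boundary
_BIN_DISTANCE_RANGES = {
    "0-0.5": (50, 450),
    "0.5-1.5": (550, 1450),
    "1.5-3": (1550, 2950),
    "3-10": (3100, 9900),
    ">10": (10_100, 30_000),
}


class PlacementError(RuntimeError):
    """Raised when the configured genome cannot host the requested features."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    The negative-binomial noise model has variance mu + dispersion * mu^2,
    so ``nb_dispersion = 0`` recovers Poisson counts. Base expression /
    accessibility levels are log-normal across features with log-sd
    ``feature_log_sd``; a shared per-gene latent couples promoter peak
    accessibility to gene expression at Spearman ``promoter_coupling_rho``
    (Gaussian-copula calibration).
    """

    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_genes: int = 1000
    n_peaks: int = 3000
    n_stages: int = 4
    n_replicates_per_stage: int = 2
    baseline_mean: float = 50.0
    nb_dispersion: float = 0.1
    stage_specific_fraction: float = 0.04
    stage_fold_change: float = 8.0
    housekeeping_fraction: float = 0.1
    housekeeping_factor: float = 8.0
    promoter_coupling_rho: float = 0.6
    feature_log_sd: float = 1.2
    summit_jitter_sd: float = 20.0
    #: peak-free bp reserved at the end of each chromosome, so variants can
    #: be planted at any distance (up to ~half the margin) from open chromatin
    peak_free_margin: int = 80_000
    n_variants_per_bin: int = 10
    n_qtls: int = 50
    qtl_overlap_target: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chromosome_length", "n_stages", "n_replicates_per_stage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_genes", "n_peaks", "n_variants_per_bin", "n_qtls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("stage_specific_fraction", "housekeeping_fraction",
                     "promoter_coupling_rho", "qtl_overlap_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0 or self.stage_fold_change <= 0:
            raise ValueError("baseline_mean and stage_fold_change must be positive")
        if not (0 <= self.peak_free_margin < self.chromosome_length):
            raise ValueError("peak_free_margin must be in [0, chromosome_length)")

    @property
    def stage_labels(self) -> tuple[str, ...]:
        if self.n_stages == len(DEFAULT_STAGES):
            return DEFAULT_STAGES
        return tuple(f"S{i + 1}" for i in range(self.n_stages))

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{stage}_r{rep + 1}"
            for stage in self.stage_labels
            for rep in range(self.n_replicates_per_stage)
        ]

    def design(self) -> pd.DataFrame:
        rows = [
            (f"{stage}_r{rep + 1}", stage, rep + 1)
            for stage in self.stage_labels
            for rep in range(self.n_replicates_per_stage)
        ]
        return pd.DataFrame(rows, columns=["sample", "stage", "replicate"])

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chromosome_length for c in self.chrom_names}


@dataclass
class TruthLabels:
    """Ground truth of planted structure.

    ``features``: feature_id, kind (gene|peak), label
    (``stage_specific:<stage>`` | ``housekeeping`` | ``background``), fold.
    ``gene_promoter``: gene_id -> planted promoter peak_id.
    ``variants``: variant_id -> planted distance bin.
    ``qtls``: qtl_id -> planted overlap status.
    """

    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_promoter: pd.DataFrame = field(default_factory=pd.DataFrame)
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    qtls: pd.DataFrame = field(default_factory=pd.DataFrame)

    def planted_stage(self, kind: str) -> pd.Series:
        """feature_id -> planted stage, for stage-specific features of a kind."""
        f = self.features
        mask = (f["kind"] == kind) & f["label"].str.startswith("stage_specific:")
        return pd.Series(
            f.loc[mask, "label"].str.split(":").str[1].to_numpy(),
            index=f.loc[mask, "feature_id"],
        )


def _rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def generate_gene_models(config: SimulationConfig) -> GeneModelSet:
    """Place non-overlapping multi-exon gene models on both strands.

    Genes are laid out left to right with random gaps; each has 2-4 exons,
    a 5'UTR inside the first exon (in transcription order) and a 3'UTR
    inside the last. Raises :class:`PlacementError` when a chromosome is too
    short to host its share of genes.
    """
    rng = _rngs(config, 5)[0]
    genes_rows, block_rows = [], []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    for chrom, n_here in zip(config.chrom_names, per_chrom):
        cursor = int(rng.integers(2000, 5000))
        for _ in range(n_here):
            gene_no += 1
            gene_id = f"gene_{gene_no:05d}"
            n_exons = int(rng.integers(2, 5))
            exon_lens = [int(rng.integers(200, 401))]
            exon_lens += [int(rng.integers(100, 301)) for _ in range(n_exons - 2)]
            exon_lens.append(int(rng.integers(200, 401)))
            intron_lens = [int(rng.integers(500, 5001)) for _ in range(n_exons - 1)]
            strand = "+" if rng.random() < 0.5 else "-"
            gap = int(rng.integers(500, 3000))
            start = cursor + gap
            length = sum(exon_lens) + sum(intron_lens)
            end = start + length
            if end > config.chromosome_length - config.peak_free_margin - 2000:
                raise PlacementError(
                    f"cannot place gene {gene_no} on {chrom}: "
                    f"chromosome_length={config.chromosome_length} too small for the request"
                )
            pos = start
            exons = []
            for j, elen in enumerate(exon_lens):
                exons.append((pos, pos + elen))
                pos += elen
                if j < n_exons - 1:
                    pos += intron_lens[j]
            utr5_len = int(rng.integers(50, 151))
            utr3_len = int(rng.integers(100, 251))
            if strand == "+":
                tss, tes = start, end - 1
                utr5 = (start, start + utr5_len)
                utr3 = (end - utr3_len, end)
            else:
                tss, tes = end - 1, start
                utr5 = (end - utr5_len, end)
                utr3 = (start, start + utr3_len)
            genes_rows.append((gene_id, chrom, strand, start, end, tss, tes))
            for s, e in exons:
                block_rows.append((gene_id, "exon", s, e))
            block_rows.append((gene_id, "five_prime_utr", *utr5))
            block_rows.append((gene_id, "three_prime_utr", *utr3))
            cursor = end
    genes = pd.DataFrame(
        genes_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss", "tes"]
    )
    blocks = pd.DataFrame(block_rows, columns=["gene_id", "feature", "start", "end"])
    return GeneModelSet(genes=genes, blocks=blocks)


def generate_peak_calls(
    config: SimulationConfig, gene_models: GeneModelSet
) -> tuple[dict[str, PeakSet], pd.DataFrame, pd.DataFrame]:
    """Per-sample raw peak calls around shared true peak locations.

    One true peak is planted in the promoter window (within +/- 1 kb of the
    TSS) of each gene while peaks remain; the rest are background peaks
    rejected out of promoter windows so region classes are unambiguous. Per
    sample, each true peak appears with a jittered summit, variable width
    (half-widths 100-400 bp) and an exponential -log10 FDR score.

    Returns (per-sample PeakSets, true-peak table, gene->promoter-peak map).
    """
    rng = _rngs(config, 5)[1]
    chrom_len = config.chromosome_length
    true_rows = []
    promoter_rows = []
    g = gene_models.genes
    n_promoter = min(config.n_genes, config.n_peaks)
    for k in range(n_promoter):
        row = g.iloc[k]
        summit = int(row["tss"]) + int(rng.integers(-1000, 1001))
        summit = int(np.clip(summit, HALF_WIDTH, chrom_len - HALF_WIDTH - 1))
        peak_id = f"peak_{k + 1:06d}"
        true_rows.append((peak_id, row["chrom"], summit, "promoter", row["gene_id"]))
        promoter_rows.append((row["gene_id"], peak_id))

    # background peaks: reject summits whose fixed-width window touches a
    # promoter window, so planted promoter coupling stays confined
    tss_by_chrom = {
        chrom: np.sort(grp["tss"].to_numpy()) for chrom, grp in g.groupby("chrom")
    }
    margin = 2500 + HALF_WIDTH + 100

    def in_promoter_window(chrom: str, summit: int) -> bool:
        tss = tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            return False
        i = np.searchsorted(tss, summit)
        for j in (i - 1, i):
            if 0 <= j < len(tss) and abs(int(tss[j]) - summit) <= margin:
                return True
        return False

    for k in range(n_promoter, config.n_peaks):
        peak_id = f"peak_{k + 1:06d}"
        for _ in range(1000):
            chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
            summit = int(rng.integers(1000, chrom_len - config.peak_free_margin))
            if not in_promoter_window(chrom, summit):
                break
        else:
            raise PlacementError("could not place background peak outside promoter windows")
        true_rows.append((peak_id, chrom, summit, "background", None))

    true_peaks = pd.DataFrame(
        true_rows, columns=["peak_id", "chrom", "summit", "kind", "gene_id"]
    )
    gene_promoter = pd.DataFrame(promoter_rows, columns=["gene_id", "peak_id"])

    samples: dict[str, PeakSet] = {}
    n_true = len(true_peaks)
    for sample in config.sample_ids:
        if n_true == 0:
            samples[sample] = PeakSet.empty(provenance="raw")
            continue
        jitter = np.rint(rng.normal(0.0, config.summit_jitter_sd, size=n_true)).astype(int)
        summit = np.clip(true_peaks["summit"].to_numpy() + jitter, 1, chrom_len - 2)
        left = rng.integers(100, 401, size=n_true)
        right = rng.integers(100, 401, size=n_true)
        start = np.maximum(0, summit - left)
        end = np.minimum(chrom_len, summit + right + 1)
        score = rng.exponential(3.0, size=n_true) + 2.0
        df = pd.DataFrame(
            {
                "peak_id": [f"{pid}:{sample}" for pid in true_peaks["peak_id"]],
                "chrom": true_peaks["chrom"].to_numpy(),
                "start": start,
                "end": end,
                "summit": summit,
                "score": score,
                "sample_id": sample,
            }
        )
        samples[sample] = PeakSet(df, provenance="raw")
    return samples, true_peaks, gene_promoter


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _assign_classes(
    rng: np.random.Generator,
    ids: list[str],
    stages: tuple[str, ...],
    specific_fraction: float,
    housekeeping_fraction: float,
    hk_ids: set[str] | None = None,
    eligible_specific: list[str] | None = None,
) -> pd.Series:
    """Randomly assign planted classes; stage-specific stages round-robin."""
    labels = pd.Series("background", index=pd.Index(ids), dtype=object)
    if hk_ids is not None:
        labels.loc[list(hk_ids)] = "housekeeping"
    elif housekeeping_fraction > 0:
        n_hk = round(housekeeping_fraction * len(ids))
        hk = rng.permutation(np.asarray(ids))[:n_hk]
        labels.loc[hk] = "housekeeping"
    preferred = [i for i in (eligible_specific if eligible_specific is not None else ids)
                 if labels.loc[i] == "background"]
    fallback = [i for i in ids if labels.loc[i] == "background" and i not in set(preferred)]
    n_ss = round(specific_fraction * len(ids))
    if n_ss > len(preferred) + len(fallback):
        raise ValueError("not enough background features to plant stage-specific ones")
    pool = list(rng.permutation(np.asarray(preferred))) if preferred else []
    if n_ss > len(pool):
        pool += list(rng.permutation(np.asarray(fallback)))
    chosen = pool[:n_ss]
    for j, fid in enumerate(chosen):
        labels.loc[fid] = f"stage_specific:{stages[j % len(stages)]}"
    return labels


def generate_counts(
    config: SimulationConfig,
    gene_models: GeneModelSet,
    true_peaks: pd.DataFrame,
    gene_promoter: pd.DataFrame,
) -> tuple[CountMatrix, CountMatrix, TruthLabels]:
    """Negative-binomial count matrices for genes and (true) peaks.

    Base levels are log-normal across features. Housekeeping genes get a
    high flat mean and a matching high-accessibility promoter peak;
    stage-specific features get their mean multiplied by the configured fold
    change in the target stage; for the remaining genes with a promoter
    peak, expression and promoter accessibility share a Gaussian-copula
    latent calibrated so their CPM rank correlation hits
    ``promoter_coupling_rho``. Stage-specific peaks are planted among
    background (non-promoter) peaks only.
    """
    rng = _rngs(config, 5)[2]
    design = config.design()
    stages = config.stage_labels
    gene_ids = list(gene_models.genes["gene_id"])
    peak_ids = list(true_peaks["peak_id"])
    prom_of_gene = dict(zip(gene_promoter["gene_id"], gene_promoter["peak_id"]))

    gene_labels = _assign_classes(
        rng, gene_ids, stages, config.stage_specific_fraction, config.housekeeping_fraction
    )
    hk_peaks = {
        prom_of_gene[g]
        for g in gene_labels.index[gene_labels == "housekeeping"]
        if g in prom_of_gene
    }
    background_peaks = list(true_peaks.loc[true_peaks["kind"] == "background", "peak_id"])
    peak_labels = _assign_classes(
        rng, peak_ids, stages, config.stage_specific_fraction, 0.0,
        hk_ids=hk_peaks, eligible_specific=background_peaks,
    )

    sd = config.feature_log_sd
    # Gaussian copula: Spearman rho of a bivariate normal with correlation c
    # is (6/pi) * arcsin(c/2); invert for the latent correlation
    c = 2.0 * math.sin(math.pi * config.promoter_coupling_rho / 6.0)
    u_gene = pd.Series(rng.normal(size=len(gene_ids)), index=pd.Index(gene_ids))

    gene_base = config.baseline_mean * np.exp(sd * u_gene - sd * sd / 2.0)
    gene_base[gene_labels == "housekeeping"] = config.baseline_mean * config.housekeeping_factor

    peak_base = pd.Series(index=pd.Index(peak_ids), dtype=float)
    eps = rng.normal(size=len(peak_ids))
    gene_of_prom = dict(zip(gene_promoter["peak_id"], gene_promoter["gene_id"]))
    for j, pid in enumerate(peak_ids):
        if pid in hk_peaks:
            peak_base[pid] = config.baseline_mean * config.housekeeping_factor
        elif pid in gene_of_prom:
            v = c * u_gene[gene_of_prom[pid]] + math.sqrt(1.0 - c * c) * eps[j]
            peak_base[pid] = config.baseline_mean * math.exp(sd * v - sd * sd / 2.0)
        else:
            peak_base[pid] = config.baseline_mean * math.exp(sd * eps[j] - sd * sd / 2.0)

    def stage_mean_matrix(base: pd.Series, labels: pd.Series) -> np.ndarray:
        mat = np.tile(base.to_numpy(dtype=float)[:, None], (1, len(stages)))
        for i, fid in enumerate(base.index):
            label = labels[fid]
            if label.startswith("stage_specific:"):
                mat[i, stages.index(label.split(":", 1)[1])] *= config.stage_fold_change
        return mat

    def draw_counts(base: pd.Series, labels: pd.Series) -> pd.DataFrame:
        mat = stage_mean_matrix(base, labels)
        cols = {}
        for _, row in design.iterrows():
            mu = mat[:, list(stages).index(row["stage"])]
            cols[row["sample"]] = _nb_draw(rng, mu, config.nb_dispersion)
        return pd.DataFrame(cols, index=base.index)

    gene_counts = CountMatrix(draw_counts(gene_base, gene_labels), design)
    peak_counts = CountMatrix(draw_counts(peak_base, peak_labels), design)

    def fold_of(label: str) -> float:
        return config.stage_fold_change if label.startswith("stage_specific:") else 1.0

    features = pd.DataFrame(
        [("gene", fid, gene_labels[fid], fold_of(gene_labels[fid])) for fid in gene_ids]
        + [("peak", fid, peak_labels[fid], fold_of(peak_labels[fid])) for fid in peak_ids],
        columns=["kind", "feature_id", "label", "fold"],
    )[["feature_id", "kind", "label", "fold"]]
    truth = TruthLabels(features=features, gene_promoter=gene_promoter)
    return gene_counts, peak_counts, truth


def true_fixed_width_peaks(config: SimulationConfig, true_peaks: pd.DataFrame) -> PeakSet:
    """The planted peak locations as a fixed-width reference PeakSet."""
    df = pd.DataFrame(
        {
            "peak_id": true_peaks["peak_id"],
            "chrom": true_peaks["chrom"],
            "start": true_peaks["summit"] - HALF_WIDTH,
            "end": true_peaks["summit"] + HALF_WIDTH + 1,
            "summit": true_peaks["summit"],
            "score": 1.0,
            "sample_id": "truth",
        }
    )
    return PeakSet(df, width_fixed=True, provenance="iterated")


def generate_variants(
    config: SimulationConfig, peaks: PeakSet
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """SNPs at controlled distances from peaks, and QTL intervals with known
    overlap status.

    ``n_variants_per_bin`` SNPs are planted per distance bin (0 means inside
    a peak); each placement is verified against a linear scan of all peaks
    on the chromosome and resampled if another peak spoils the intended bin.
    QTLs are intervals of 2-20 kb; a ``qtl_overlap_target`` fraction is
    built around a peak, the rest are rejected into peak-free space.
    """
    if len(peaks) == 0:
        raise ValueError("generate_variants requires a non-empty peak set")
    rng = _rngs(config, 5)[3]
    chrom_len = config.chromosome_length
    pdf = peaks.df
    by_chrom = {
        chrom: (grp["start"].to_numpy(int), grp["end"].to_numpy(int))
        for chrom, grp in pdf.groupby("chrom")
    }

    def scan_distance(chrom: str, pos: int) -> float:
        if chrom not in by_chrom:
            return np.inf
        s, e = by_chrom[chrom]
        return int((np.maximum(s - pos, 0) + np.maximum(pos - (e - 1), 0)).min())

    # gaps between merged peak intervals (plus chromosome-end gaps): a point
    # at distance d from the nearer flanking peak needs a gap wide enough
    # that the other flank is not closer
    gaps: list[tuple[str, int | None, int | None, int]] = []
    for chrom, (s, e) in by_chrom.items():
        order = np.argsort(s)
        s, e = s[order], np.maximum.accumulate(e[order])
        merged: list[tuple[int, int]] = []
        for si, ei in zip(s, e):
            if merged and si < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], int(ei)))
            else:
                merged.append((int(si), int(ei)))
        first_start, last_end = merged[0][0], merged[-1][1]
        gaps.append((chrom, None, first_start, first_start))
        gaps.append((chrom, last_end, None, chrom_len - last_end))
        for (s0, e0), (s1, e1) in zip(merged, merged[1:]):
            gaps.append((chrom, e0, s1, (s1 - e0 + 1) // 2))

    def place_at_distance(d: int) -> tuple[str, int] | None:
        feasible = [g for g in gaps if g[3] >= d]
        if not feasible:
            return None
        chrom, left_end, right_start, _cap = feasible[int(rng.integers(len(feasible)))]
        anchors = []
        if left_end is not None:
            anchors.append(left_end - 1 + d)
        if right_start is not None:
            anchors.append(right_start - d)
        return chrom, int(anchors[int(rng.integers(len(anchors)))])

    variant_rows, variant_truth = [], []
    n = 0
    for label in BIN_LABELS:
        for _ in range(config.n_variants_per_bin):
            for _attempt in range(500):
                if label == "0":
                    k = int(rng.integers(len(pdf)))
                    chrom = pdf["chrom"].iloc[k]
                    pos = int(rng.integers(int(pdf["start"].iloc[k]), int(pdf["end"].iloc[k])))
                else:
                    lo, hi = _BIN_DISTANCE_RANGES[label]
                    placed = place_at_distance(int(rng.integers(lo, hi + 1)))
                    if placed is None:
                        continue
                    chrom, pos = placed
                if not (0 <= pos < chrom_len):
                    continue
                actual = scan_distance(chrom, pos)
                if np.isfinite(actual) and distance_bin(actual) == label:
                    break
            else:
                raise PlacementError(f"could not place a variant in bin {label}")
            n += 1
            vid = f"snp_{n:04d}"
            variant_rows.append((vid, chrom, pos))
            variant_truth.append((vid, label))

    qtl_rows, qtl_truth = [], []
    n_overlap = round(config.qtl_overlap_target * config.n_qtls)
    for q in range(config.n_qtls):
        qid = f"qtl_{q + 1:04d}"
        want_overlap = q < n_overlap
        for _attempt in range(500):
            if want_overlap:
                k = int(rng.integers(len(pdf)))
                chrom = pdf["chrom"].iloc[k]
                start = max(0, int(pdf["start"].iloc[k]) - int(rng.integers(0, 5000)))
                end = min(chrom_len, int(pdf["end"].iloc[k]) + int(rng.integers(0, 5000)))
                break
            chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
            length = int(rng.integers(2000, 20_001))
            start = int(rng.integers(0, max(1, chrom_len - length)))
            end = start + length
            s, e = by_chrom.get(chrom, (np.array([], int), np.array([], int)))
            if not ((s < end) & (e > start)).any():
                break
        else:
            raise PlacementError("could not place a peak-free QTL interval")
        qtl_rows.append((qid, chrom, start, end))
        qtl_truth.append((qid, want_overlap))

    variants = pd.DataFrame(variant_rows, columns=["variant_id", "chrom", "pos"])
    qtls = pd.DataFrame(qtl_rows, columns=["qtl_id", "chrom", "start", "end"])
    truth = TruthLabels(
        variants=pd.DataFrame(variant_truth, columns=["variant_id", "true_bin"]),
        qtls=pd.DataFrame(qtl_truth, columns=["qtl_id", "overlaps"]),
    )
    return variants, qtls, truth


@dataclass
class SyntheticDataset:
    """A complete simulated study: inputs for every pipeline stage + truth."""

    config: SimulationConfig
    gene_models: GeneModelSet
    sample_peaks: dict[str, PeakSet]
    true_peaks: pd.DataFrame
    gene_counts: CountMatrix
    peak_counts: CountMatrix
    variants: pd.DataFrame
    qtls: pd.DataFrame
    truth: TruthLabels


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generators under one seed and bundle the results."""
    gene_models = generate_gene_models(config)
    sample_peaks, true_peaks, gene_promoter = generate_peak_calls(config, gene_models)
    gene_counts, peak_counts, truth = generate_counts(
        config, gene_models, true_peaks, gene_promoter
    )
    if len(true_peaks):
        ref = true_fixed_width_peaks(config, true_peaks)
        variants, qtls, vtruth = generate_variants(config, ref)
    else:
        variants = pd.DataFrame(columns=["variant_id", "chrom", "pos"])
        qtls = pd.DataFrame(columns=["qtl_id", "chrom", "start", "end"])
        vtruth = TruthLabels()
    truth.variants = vtruth.variants
    truth.qtls = vtruth.qtls
    return SyntheticDataset(
        config=config,
        gene_models=gene_models,
        sample_peaks=sample_peaks,
        true_peaks=true_peaks,
        gene_counts=gene_counts,
        peak_counts=peak_counts,
        variants=variants,
        qtls=qtls,
        truth=truth,
    )
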