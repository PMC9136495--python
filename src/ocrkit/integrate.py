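"""Accessibility-expression integration.

Three analyses relate open chromatin to transcription:

* per-region-category Spearman correlation between peak accessibility (CPM)
  and the linked gene's expression (CPM);
* classification of genes into joint accessibility/expression quadrants
  (HA-HE, MA-ME, HA-ME, MA-HE) by 70th/50th percentile cuts of per-gene
  maxima of promoter accessibility and expression;
* an empirical resampling test for over-representation of a property gene
  set (e.g. housekeeping genes) inside a target group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotate import GeneModelSet

logger = logging.getLogger(__name__)

QUADRANTS = ("HA-HE", "MA-ME", "HA-ME", "MA-HE")


def link_peaks_to_genes(
    annotated: pd.DataFrame, genes: GeneModelSet, peaks: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One peak-gene link per annotated peak.

    Non-intergenic peaks link to their assigned gene under their annotated
    category. Intergenic peaks link to the gene with the nearest TSS on the
    same chromosome (flagged ``distal``); equidistant ties go to the
    lexicographically smaller gene id and are flagged. ``peaks`` (a frame
    with peak_id/chrom/start/end) is required when intergenic peaks are
    present. Intergenic peaks on chromosomes without genes are dropped.
    """
    cols = ["peak_id", "gene_id", "category", "distal", "tie"]
    if len(annotated) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    proximal = annotated[annotated["category"] != "intergenic"]
    for peak_id, category, gene in zip(
        proximal["peak_id"], proximal["category"], proximal["assigned_gene"]
    ):
        rows.append((peak_id, gene, category, False, False))

    distal = annotated[annotated["category"] == "intergenic"]
    if len(distal):
        if peaks is None:
            raise ValueError("peak coordinates required to link intergenic peaks")
        coords = peaks.set_index("peak_id")
        g = genes.genes
        by_chrom = {
            chrom: grp.sort_values(["tss", "gene_id"]) for chrom, grp in g.groupby("chrom")
        }
        for peak_id in distal["peak_id"]:
            chrom = coords.at[peak_id, "chrom"]
            start = int(coords.at[peak_id, "start"])
            end = int(coords.at[peak_id, "end"])
            grp = by_chrom.get(chrom)
            if grp is None:
                logger.warning("intergenic peak %s on gene-free chromosome %r dropped", peak_id, chrom)
                continue
            tss = grp["tss"].to_numpy()
            dist = np.where(
                (tss >= start) & (tss < end), 0, np.minimum(np.abs(tss - start), np.abs(tss - (end - 1)))
            )
            best = dist.min()
            cand = sorted(grp["gene_id"].to_numpy()[dist == best])
            rows.append((peak_id, cand[0], "intergenic", True, len(cand) > 1))
    return pd.DataFrame(rows, columns=cols)


def region_correlation(
    links: pd.DataFrame,
    peak_cpm: pd.DataFrame,
    gene_cpm: pd.DataFrame,
    mode: str = "per_sample",
    min_links: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of accessibility vs expression per region category.

    For each category, pairs (peak CPM, linked gene CPM) are correlated —
    per sample (default), or pooled across samples with ``mode="pooled"``.
    Categories/samples with fewer than ``min_links`` pairs or a constant
    vector are omitted (logged). Returns a DataFrame with columns
    category, sample (``"pooled"`` in pooled mode), r, n.
    """
    if mode not in ("per_sample", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = [s for s in peak_cpm.columns if s in gene_cpm.columns]
    rows = []
    for category, grp in links.groupby("category"):
        usable = grp[grp["peak_id"].isin(peak_cpm.index) & grp["gene_id"].isin(gene_cpm.index)]
        if len(usable) < min_links:
            logger.info("category %s: only %d links, omitted", category, len(usable))
            continue
        acc = peak_cpm.loc[usable["peak_id"], samples].to_numpy(dtype=float)
        expr = gene_cpm.loc[usable["gene_id"], samples].to_numpy(dtype=float)
        if mode == "pooled":
            pairs = [("pooled", acc.ravel(), expr.ravel())]
        else:
            pairs = [(s, acc[:, j], expr[:, j]) for j, s in enumerate(samples)]
        for sample, x, y in pairs:
            if np.all(x == x[0]) or np.all(y == y[0]):
                logger.info("category %s sample %s: constant vector, omitted", category, sample)
                continue
            r = spearmanr(x, y).statistic
            rows.append((category, sample, float(r), len(x)))
    return pd.DataFrame(rows, columns=["category", "sample", "r", "n"])


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th order statistic."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty values")
    rank = max(1, math.ceil(pct / 100.0 * arr.size))
    return float(arr[rank - 1])


def promoter_accessibility(
    links: pd.DataFrame, peak_cpm: pd.DataFrame, agg: str = "max"
) -> pd.Series:
    """Per-gene promoter accessibility: max (or mean) over the gene's
    promoter peaks of each peak's maximal CPM across samples."""
    prom = links[(links["category"] == "promoter") & links["peak_id"].isin(peak_cpm.index)]
    per_peak = peak_cpm.loc[prom["peak_id"]].max(axis=1)
    frame = pd.DataFrame({"gene_id": prom["gene_id"].to_numpy(), "acc": per_peak.to_numpy()})
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown agg {agg!r}")
    return frame.groupby("gene_id")["acc"].agg(agg)


@dataclass
class QuadrantReport:
    assignments: pd.DataFrame  # gene_id, accessibility_max, expression_max, group
    n_excluded: int  # genes with no promoter peak
    high_cut_acc: float
    low_cut_acc: float
    high_cut_expr: float
    low_cut_expr: float

    def counts(self) -> dict[str, int]:
        c = self.assignments["group"].value_counts().to_dict()
        return {g: int(c.get(g, 0)) for g in (*QUADRANTS, "unassigned")}


def classify_quadrants(
    accessibility_max: pd.Series,
    expression_max: pd.Series,
    high_pct: float = 70.0,
    low_pct: float = 50.0,
    percentile: str = "nearest_rank",
) -> QuadrantReport:
    """Joint accessibility/expression quadrant classification.

    High (HA/HE) means strictly above the ``high_pct`` percentile of the
    respective per-gene maxima; medium-low (MA/ME) means strictly below the
    ``low_pct`` percentile. The four cross combinations define the groups;
    genes intermediate on either axis are "unassigned". Genes present in
    ``expression_max`` but lacking promoter accessibility are excluded and
    counted.
    """
    common = accessibility_max.index.intersection(expression_max.index)
    n_excluded = len(expression_max.index.difference(accessibility_max.index))
    if len(common) < 10:
        raise ValueError(f"need >= 10 genes with both axes, got {len(common)}")
    acc = accessibility_max.loc[common].to_numpy(dtype=float)
    expr = expression_max.loc[common].to_numpy(dtype=float)

    if percentile == "nearest_rank":
        pctl = nearest_rank_percentile
    elif percentile == "linear":
        def pctl(v, q):  # numpy's interpolating definition
            return float(np.percentile(v, q))
    else:
        raise ValueError(f"unknown percentile method {percentile!r}")

    acc_hi, acc_lo = pctl(acc, high_pct), pctl(acc, low_pct)
    expr_hi, expr_lo = pctl(expr, high_pct), pctl(expr, low_pct)
    ha, ma = acc > acc_hi, acc < acc_lo
    he, me = expr > expr_hi, expr < expr_lo
    group = np.full(len(common), "unassigned", dtype=object)
    group[ha & he] = "HA-HE"
    group[ma & me] = "MA-ME"
    group[ha & me] = "HA-ME"
    group[ma & he] = "MA-HE"
    assignments = pd.DataFrame(
        {
            "gene_id": common,
            "accessibility_max": acc,
            "expression_max": expr,
            "group": group,
        }
    )
    return QuadrantReport(assignments, n_excluded, acc_hi, acc_lo, expr_hi, expr_lo)


@dataclass(frozen=True)
class EnrichmentResult:
    observed_proportion: float
    n_samples: int
    n_exceeding: int
    empirical_p: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "observed_proportion": self.observed_proportion,
            "n_samples": self.n_samples,
            "n_exceeding": self.n_exceeding,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
        }


def empirical_enrichment(
    target_genes,
    universe_genes,
    property_genes,
    n_samples: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Resampling test for over-representation of ``property_genes`` in the target.

    The observed statistic is |target ∩ property| / |target|. For each of
    ``n_samples`` draws of |target| genes uniformly without replacement from
    the universe, the draw counts as exceeding iff its property proportion
    is strictly greater than the observed one. The empirical p-value is
    (1 + n_exceeding) / (n_samples + 1), so its smallest attainable value is
    1/(n_samples + 1).
    """
    target = list(dict.fromkeys(target_genes))
    universe = list(dict.fromkeys(universe_genes))
    prop = set(property_genes)
    if not target:
        raise ValueError("empty target gene set")
    if not set(target) <= set(universe):
        raise ValueError("target genes must be a subset of the universe")
    k = len(target)
    observed = sum(g in prop for g in target) / k
    is_prop = np.fromiter((g in prop for g in universe), dtype=bool, count=len(universe))
    rng = np.random.default_rng(seed)
    exceeding = 0
    for _ in range(n_samples):
        draw = rng.choice(len(universe), size=k, replace=False)
        if is_prop[draw].sum() / k > observed:
            exceeding += 1
    p = (1 + exceeding) / (n_samples + 1)
    return EnrichmentResult(observed, n_samples, exceeding, p, seed)
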