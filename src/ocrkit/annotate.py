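"""Genomic-region annotation of peaks against gene models.

Each consensus peak is assigned exactly one category — promoter
(TSS +/- 2.5 kb), 5'UTR, 3'UTR, exon, intron, downstream (3 kb past the
transcript end on the gene's strand) or intergenic — by testing interval
overlap against each feature class in a fixed precedence order. All
coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .peaks import PeakSet

logger = logging.getLogger(__name__)

PROMOTER_HALFWIDTH = 2500
DOWNSTREAM_LEN = 3000

#: precedence order in which feature classes are tested; first hit wins
CATEGORY_PRECEDENCE = (
    "promoter",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "downstream",
)
CATEGORIES = CATEGORY_PRECEDENCE + ("intergenic",)

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss", "tes"]
BLOCK_COLUMNS = ["gene_id", "feature", "start", "end"]


@dataclass
class GeneModelSet:
    """Gene models: one transcript per gene plus its sub-gene feature blocks.

    ``genes`` has one row per gene (id, chrom, strand, start, end, tss, tes);
    ``blocks`` holds exon / five_prime_utr / three_prime_utr intervals in long
    format. TSS is ``start`` for + strand genes and ``end - 1`` for - strand.
    """

    genes: pd.DataFrame
    blocks: pd.DataFrame

    def __post_init__(self) -> None:
        for col in GENE_COLUMNS:
            if col not in self.genes.columns:
                raise ValueError(f"GeneModelSet.genes missing column {col!r}")
        for col in BLOCK_COLUMNS:
            if col not in self.blocks.columns:
                raise ValueError(f"GeneModelSet.blocks missing column {col!r}")
        self.genes = self.genes.reset_index(drop=True)
        self.blocks = self.blocks.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class AnnotatedPeak:
    peak_id: str
    category: str
    assigned_gene: str | None


class PeakAnnotator:
    """Interval index over a :class:`GeneModelSet` for repeated annotation.

    Ties between genes providing the winning feature are broken by nearest
    TSS (distance from the peak interval), then lexicographic gene id.
    """

    def __init__(
        self,
        genes: GeneModelSet,
        promoter_halfwidth: int = PROMOTER_HALFWIDTH,
        downstream_len: int = DOWNSTREAM_LEN,
        precedence: tuple[str, ...] = CATEGORY_PRECEDENCE,
    ) -> None:
        self.genes = genes
        self.precedence = precedence
        g = genes.genes
        self._tss = dict(zip(g["gene_id"], g["tss"]))
        self._chrom = dict(zip(g["gene_id"], g["chrom"]))
        self._span = {
            gid: (int(s), int(e)) for gid, s, e in zip(g["gene_id"], g["start"], g["end"])
        }
        self._trees: dict[tuple[str, str], IntervalTree] = {}

        def add(category: str, chrom: str, start: int, end: int, gene_id: str) -> None:
            if end <= start:
                return
            self._trees.setdefault((chrom, category), IntervalTree()).addi(start, end, gene_id)

        for gene_id, chrom, strand, start, end, tss, tes in zip(
            g["gene_id"], g["chrom"], g["strand"], g["start"], g["end"], g["tss"], g["tes"]
        ):
            add("promoter", chrom, max(0, tss - promoter_halfwidth), tss + promoter_halfwidth + 1, gene_id)
            if strand == "+":
                add("downstream", chrom, end, end + downstream_len, gene_id)
            else:
                add("downstream", chrom, max(0, start - downstream_len), start, gene_id)
        for gene_id, feature, start, end in zip(
            genes.blocks["gene_id"], genes.blocks["feature"],
            genes.blocks["start"], genes.blocks["end"],
        ):
            add(feature, self._chrom[gene_id], int(start), int(end), gene_id)
        # introns: gene body minus exon blocks
        exons = genes.blocks[genes.blocks["feature"] == "exon"]
        for gene_id, grp in exons.groupby("gene_id"):
            chrom = self._chrom[gene_id]
            gene_start, gene_end = self._span[gene_id]
            cursor = gene_start
            for ex_start, ex_end in sorted(zip(grp["start"], grp["end"])):
                if ex_start > cursor:
                    add("intron", chrom, cursor, int(ex_start), gene_id)
                cursor = max(cursor, int(ex_end))
            if cursor < gene_end:
                add("intron", chrom, cursor, gene_end, gene_id)

    def annotate(self, chrom: str, start: int, end: int, peak_id: str = "") -> AnnotatedPeak:
        """Assign the single highest-precedence category overlapping [start, end)."""
        known = any(c == chrom for c, _ in self._trees)
        if not known:
            logger.warning("peak %s on chromosome %r without gene models: intergenic", peak_id, chrom)
            return AnnotatedPeak(peak_id, "intergenic", None)
        for category in self.precedence:
            tree = self._trees.get((chrom, category))
            if tree is None:
                continue
            hits = tree.overlap(start, end)
            if hits:
                gene = self._pick_gene({h.data for h in hits}, start, end)
                return AnnotatedPeak(peak_id, category, gene)
        return AnnotatedPeak(peak_id, "intergenic", None)

    def _pick_gene(self, gene_ids: set[str], start: int, end: int) -> str:
        def key(gid: str) -> tuple[int, str]:
            tss = self._tss[gid]
            if start <= tss < end:
                d = 0
            else:
                d = min(abs(tss - start), abs(tss - (end - 1)))
            return (d, gid)

        return min(gene_ids, key=key)


def annotate_peaks(
    peaks: PeakSet,
    genes: GeneModelSet,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    downstream_len: int = DOWNSTREAM_LEN,
) -> pd.DataFrame:
    """Annotate every peak; returns a DataFrame (peak_id, category, assigned_gene)."""
    annotator = PeakAnnotator(genes, promoter_halfwidth, downstream_len)
    rows = [
        annotator.annotate(chrom, start, end, peak_id)
        for peak_id, chrom, start, end in zip(
            peaks.df["peak_id"], peaks.df["chrom"], peaks.df["start"], peaks.df["end"]
        )
    ]
    return pd.DataFrame(
        [(a.peak_id, a.category, a.assigned_gene) for a in rows],
        columns=["peak_id", "category", "assigned_gene"],
    )
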