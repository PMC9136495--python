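"""Readers/writers for the plain-text formats the pipeline consumes.

Peaks travel as ENCODE narrowPeak (10 columns; the summit as an offset from
the interval start in column 10, the -log10 FDR in the qValue column).
Everything else is TSV: counts with a sample-id header row plus a design
sidecar (sample, stage, replicate), gene models in long GTF-like form,
variants/QTLs as position tables or BED, gene sets as one id per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import GeneModelSet
from .normalize import CountMatrix
from .peaks import PeakSet

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    df = peaks.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["peak_id"].where(df["peak_id"] != "", "."),
            "score": (df["score"] * 10).round().clip(0, 1000).astype(int),
            "strand": ".",
            "signalValue": df["score"].map(lambda v: f"{v:.6g}"),
            "pValue": -1,
            "qValue": df["score"].map(lambda v: f"{v:.6g}"),
            "peak": df["summit"] - df["start"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path, sample_id: str = "") -> PeakSet:
    """Read a narrowPeak file; the qValue column is taken as the -log10 FDR score."""
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                     dtype={"chrom": str, "name": str})
    if not sample_id:
        sample_id = Path(path).stem
    out = pd.DataFrame(
        {
            "peak_id": df["name"].where(df["name"] != ".", ""),
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "summit": (df["start"] + df["peak"]).astype(int),
            "score": df["qValue"].astype(float),
            "sample_id": sample_id,
        }
    )
    return PeakSet(out, provenance="raw")


def write_counts(counts: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    counts.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
    counts.design.to_csv(design_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
    design = pd.read_csv(design_path, sep="\t", dtype={"sample": str, "stage": str})
    return CountMatrix(counts, design)


def write_gene_models(genes: GeneModelSet, path: str | Path) -> None:
    """Long GTF-like TSV: gene rows carry strand/TSS/TES, block rows the sub-features."""
    g = genes.genes.copy()
    g["feature"] = "gene"
    blocks = genes.blocks.copy()
    for col in ("chrom", "strand", "tss", "tes"):
        blocks[col] = blocks["gene_id"].map(dict(zip(g["gene_id"], g[col])))
    cols = ["gene_id", "chrom", "strand", "feature", "start", "end", "tss", "tes"]
    pd.concat([g[cols], blocks[cols]], ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> GeneModelSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = df[df["feature"] == "gene"][
        ["gene_id", "chrom", "strand", "start", "end", "tss", "tes"]
    ]
    blocks = df[df["feature"] != "gene"][["gene_id", "feature", "start", "end"]]
    return GeneModelSet(genes=genes, blocks=blocks)


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})


def write_qtls_bed(qtls: pd.DataFrame, path: str | Path) -> None:
    qtls[["chrom", "start", "end", "qtl_id"]].to_csv(path, sep="\t", header=False, index=False)


def read_qtls_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "qtl_id"],
                     dtype={"chrom": str, "qtl_id": str})
    return df[["qtl_id", "chrom", "start", "end"]]


def read_gene_set(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_set(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            chrom, size = line.split("\t")[:2]
            out[chrom] = int(size)
    return out


def write_dataset(dataset, outdir: str | Path) -> None:
    """Serialize a :class:`~ocrkit.synthetic.SyntheticDataset` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_models(dataset.gene_models, outdir / "gene_models.tsv")
    write_chrom_sizes(dataset.config.chrom_sizes, outdir / "chrom.sizes")
    for sample, ps in dataset.sample_peaks.items():
        write_narrowpeak(ps, outdir / f"peaks_{sample}.narrowPeak")
    write_counts(dataset.gene_counts, outdir / "gene_counts.tsv", outdir / "design.tsv")
    write_counts(dataset.peak_counts, outdir / "peak_counts.tsv", outdir / "design.tsv")
    write_variants(dataset.variants, outdir / "snps.tsv")
    write_qtls_bed(dataset.qtls, outdir / "qtls.bed")
    truth = dataset.truth
    truth.features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)
    truth.gene_promoter.to_csv(outdir / "truth_gene_promoter.tsv", sep="\t", index=False)
    truth.variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    truth.qtls.to_csv(outdir / "truth_qtls.tsv", sep="\t", index=False)
    dataset.true_peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
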