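# ocrkit

Integration of time-course chromatin accessibility (ATAC-seq) and
transcriptome (RNA-seq) data, modelled on a four-stage myogenic
differentiation design: proliferating myoblasts (P) followed by
differentiation days D0, D2 and D4, each with replicated libraries. The
package is aimed at analysts who start from per-sample peak calls and raw
count matrices and want the downstream regulatory-genomics statistics as
tested, reusable code.

## What it computes

- **Consensus open-chromatin peak set.** Per-sample peak summits are
  extended ±250 bp to 501-bp fixed-width peaks; pooled peaks are reduced to
  a non-overlapping set by *iterative overlap removal*: repeatedly keep the
  peak with the strongest signal (−log₁₀ FDR) and discard every peak
  overlapping it. Each consensus peak is assigned one genomic category
  (promoter = TSS ± 2.5 kb, 5′UTR, 3′UTR, exon, intron, downstream,
  intergenic) by fixed precedence.
- **Normalization and stage summaries.** Counts per million
  (CPM = raw·10⁶/library size), per-feature Z scores, stage means over
  replicates; a fold-change filter for variable features and k-means
  clustering of stage-Z profiles.
- **Stage-specific genes and peaks.** For stage means x₁…x_S with
  pᵢ = xᵢ/Σx, the Shannon entropy H = −Σ pᵢ log₂ pᵢ (bits). A feature is
  stage-specific when H is below a threshold (1.6 genes, 1.8 peaks), its
  stage Z at the top stage exceeds 1, and at most two other stages have
  Z > 0.
- **Accessibility–expression integration.** Spearman correlation between
  peak CPM and linked-gene CPM per region category; HA–HE / MA–ME / HA–ME /
  MA–HE quadrant classes from 70th/50th nearest-rank percentile cuts of
  per-gene maxima; an empirical resampling enrichment test with
  p = (1 + #{draws exceeding observed}) / (n_draws + 1) over 10,000 draws.
- **Variant geometry.** Distance of each SNP to the nearest open-chromatin
  peak, binned as 0 (inside), 0–0.5, 0.5–1.5, 1.5–3, 3–10 and >10 kb, plus
  the fraction of QTL intervals overlapping at least one peak.
- **Synthetic data.** A seeded generator (`ocrkit.synthetic`) produces gene
  models, per-sample peak calls, negative-binomial count matrices with
  planted stage-specific/housekeeping features and promoter-expression
  coupling, and variants at controlled distances — all with truth labels,
  so every stage of the pipeline can be validated end to end.

## Worked example

```python
import ocrkit as ok

cfg = ok.SimulationConfig(seed=1)          # 4 stages x 2 replicates
ds = ok.simulate_dataset(cfg)

fixed = [ok.fixed_width(ps, cfg.chrom_sizes) for ps in ds.sample_peaks.values()]
common = ok.build_common_peak_set(fixed)
print(len(common))                          # 2657

stages = ok.stage_summarize(ok.cpm(ds.gene_counts), ds.gene_counts.design)
calls = ok.call_stage_specific(stages, ok.GENE_ENTROPY_THRESHOLD)
print(int(calls["specific"].sum()))         # 41
print(calls[calls["specific"]]["stage"].value_counts().to_dict())
# {'P': 11, 'D2': 11, 'D0': 10, 'D4': 9}
```

The first number is the size of the non-overlapping 501-bp consensus peak
set built from the 8 samples' jittered peak calls (3000 planted regions,
some merged where promoters are close). The second is how many genes pass
the entropy and activity filters at threshold 1.6; the per-stage split
is dominated by the planted stage-specific genes (40, ten per stage) with
a single additional noisy background call.

The same steps are exposed as a CLI (`ocrkit simulate`, `ocrkit peakset`,
`ocrkit normalize`, `ocrkit cluster`, `ocrkit stage-specific`,
`ocrkit correlate`, `ocrkit quadrants`, `ocrkit enrich`,
`ocrkit variants`); see `ocrkit --help`.

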