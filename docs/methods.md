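# Methods

This note documents the models and procedures ocrkit implements, the
assumptions behind them, and the choices made where more than one sensible
definition exists. All genomic coordinates are 0-based, half-open (BED
convention); "overlap" always means at least one shared base.

## Consensus peak set

Peak callers report variable-width peaks per sample, which makes signal
incomparable across samples. Each peak is therefore standardized to its
summit ± 250 bp. The resulting window `[summit − 250, summit + 251)` is
501 bp wide because the summit base itself is included; peaks whose window
would cross a chromosome boundary are dropped rather than clipped, so the
fixed-width invariant holds for every retained peak.

The pooled fixed-width peaks from all samples are reduced to a
non-overlapping consensus set by greedy iterative overlap removal: the
highest-scoring remaining peak (score = −log₁₀ FDR) is kept and every peak
overlapping it is discarded, until no peaks remain. Equal scores are broken
by earlier coordinate (chromosome, start), making the procedure fully
deterministic. The implementation keeps per-chromosome sorted interval
lists so each candidate is checked against at most two neighbours
(O(n log n) in practice); the test suite verifies it against a literal
O(n²) re-simulation of the procedure on random instances. Two guarantees
follow from the construction and are asserted as properties: output peaks
are pairwise non-overlapping per chromosome, and every removed peak
overlaps some kept peak of greater or equal score.

`build_common_peak_set` pools all samples and filters the pool once. The
alternative — filter each sample first, then pool and filter again — can
differ in rare cascades (a peak eliminated within its own sample might, in
the pooled pass, have been the one to displace a third sample's peak), so
the two are distinct procedures; pool-once is the default because the
common set is defined by one global greedy pass over all evidence, and
per-sample pre-filtering composes directly from
`iterative_overlap_filter` when wanted.

## Region annotation

Each consensus peak receives exactly one category by testing overlap
against feature classes in a fixed precedence order: promoter (TSS
± 2.5 kb) > 5′UTR > 3′UTR > exon > intron > downstream (3 kb past the
transcript end, on the gene's strand) > intergenic. The precedence and the
3-kb downstream window follow the conventions of standard annotators;
both are configurable. When several genes supply the winning feature the
gene with the nearest TSS wins, then the lexicographically smaller id —
ties are resolved, never dropped. Peaks on chromosomes without gene models
are intergenic (logged).

Note that with a ±2.5 kb promoter window the 5′UTR category is effectively
unreachable for typical UTR lengths — the promoter window covers it. This
mirrors the behaviour of precedence-based annotators and is why 5′UTR
fractions are near zero in the outputs.

## Normalization and stage summaries

CPM = raw count · 10⁶ / library size, per sample. Z scores are computed
per feature with the sample standard deviation (denominator n − 1);
constant features are set to Z = 0 and flagged in the log rather than
returned as NaN so downstream set operations stay total. Stage summaries
take the arithmetic mean of replicate CPM per stage, then Z across the
stage means. Z profiles of CPM are invariant to rescaling any sample's
library, which the tests assert.

Z scores are computed on CPM, not log-CPM, by default; `log1p` can be
applied upstream where the log scale is preferred. The fold-change filter
(`naive_differential`: max stage mean ≥ 1 CPM and max/(min + 0.1) ≥ 4) is a
deliberately simple stand-in for dispersion-based differential testing; the
0.1 pseudocount only guards the division. K-means on stage-Z profiles uses
10 restarts under a fixed seed, and cluster labels are renumbered by the
stage at which each centroid peaks so labels are reproducible.

## Stage specificity

Entropy is computed on stage-mean CPM (nonnegative by construction; Z
scores can be negative and are unsuitable as probabilities). For stage
means x with pᵢ = xᵢ/Σx, H = −Σ pᵢ log₂ pᵢ with 0·log 0 ≡ 0, so
H ∈ [0, log₂ S]; all-zero features have undefined entropy and are excluded
(logged), not failed. A feature is called specific to its argmax stage iff

1. H < threshold (defaults: 1.6 bits for genes, 1.8 for peaks),
2. stage Z at the argmax stage > 1, and
3. at most 2 other stages have stage Z > 0,

with strict inequalities throughout and the first failed criterion recorded
as the reject reason (entropy → max_activity → spread). The activity
filters are interpreted on the stage-level Z scale — the normalization
pipeline ends in Z scores, and a raw-CPM reading of "activity > 0" would be
vacuous for any expressed feature — but both cutoffs are parameters
(`z_high`, `z_active`), so a raw-CPM reading can be reproduced by passing
CPM-scale thresholds and a CPM matrix. With four stages criterion 3 can
only reject when all three other stages are above the activity cutoff,
which criterion 2 makes nearly impossible; it matters for designs with more
stages.

## Accessibility–expression integration

Peak–gene links carry the peak's annotated category; intergenic peaks link
to the gene with the nearest TSS and are flagged distal. Spearman
correlations between peak CPM and linked-gene CPM are computed per category
and per sample by default (pooling samples is available); categories with
fewer than 3 links or a constant vector are omitted with a log message
rather than reported as NaN.

Quadrants: per gene, accessibility = max over samples and promoter peaks of
peak CPM (max, not mean, to capture "high accessibility"; configurable) and
expression = max gene CPM over samples. High means strictly above the 70th
percentile, medium-low strictly below the 50th, with nearest-rank
percentiles (the ⌈q·n⌉-th order statistic; linear interpolation available).
The four cross combinations give HA–HE, MA–ME, HA–ME, MA–HE; genes
intermediate on either axis are unassigned, and genes with no promoter peak
are excluded and counted, so the five groups plus exclusions always
partition the input.

Enrichment: with observed proportion = |target ∩ property|/|target|, the
test draws |target| genes uniformly without replacement from the universe
10,000 times and counts draws whose proportion strictly exceeds the
observed one (ties do not count). p = (1 + count)/(n + 1), bounded below by
1/(n + 1). On small universes this Monte-Carlo tail is validated against
the exact hypergeometric survival function in the tests.

## Variant geometry

Distance from a position to a peak is 0 inside the peak, else the gap to
the nearest covered base (`start − pos` to the left edge, `pos − (end − 1)`
to the last base). Distances bin as {0} ∪ (0, 500] ∪ (500, 1500] ∪
(1500, 3000] ∪ (3000, 10000] ∪ (10000, ∞) bp — left-open, right-closed, so
every positive distance falls in exactly one bin. Fractions are over
variants with a defined distance; variants on peak-free chromosomes are
counted separately (undefined is a value, not an error). QTL intervals
overlap the peak set iff they share ≥ 1 bp with ≥ 1 peak; abutting
intervals do not overlap under half-open coordinates. The per-chromosome
index stores starts sorted with a running maximum of ends, which stays
exact when input peaks overlap each other.

## Synthetic data generator

The generator emulates the four-stage design (P, D0, D2, D4; 2 replicates
per stage by default — replicate count is a config field since designs
vary) on a small artificial genome (default 2 × 5 Mb).

*Gene models.* Genes are placed left to right with random 0.5–3 kb gaps;
each has 2–4 exons (first/last 200–400 bp, internal 100–300 bp), introns of
0.5–5 kb, a 5′UTR (50–150 bp) inside the first exon in transcription order
and a 3′UTR (100–250 bp) inside the last, on a random strand. TSS = start
on +, end − 1 on −. A configured genome that cannot host the requested
genes raises a placement error rather than silently truncating.

*Peaks.* One true peak is planted within ±1 kb of each gene's TSS (well
inside the ±2.5 kb promoter window even after width and jitter), and the
remaining peaks are placed outside promoter windows so the planted
promoter coupling stays confined to promoter-category links. Per sample,
every true peak reappears with a Gaussian summit jitter (sd 20 bp, making
cross-sample merging non-trivial), half-widths drawn from 100–400 bp and an
exponential −log₁₀ FDR score. The last 80 kb of each chromosome is kept
free of genes and peaks — a peak desert — because without one a
realistically dense peak landscape has no gap able to host the >10 kb
distance bin.

*Counts.* Counts are negative binomial with variance μ + φμ² (φ = 0
recovers Poisson; the relation is verified empirically in the tests).
Feature base levels are log-normal (log-sd 1.2) around a baseline mean of
50, mean-corrected so the expectation stays at the baseline. Housekeeping
genes (10% of genes) get a flat mean of 8× baseline and the same for their
promoter peak. Stage-specific features (4% of features, assigned
round-robin over stages) have their mean multiplied by the fold change
(default 8) in their target stage; stage-specific peaks are drawn from
non-promoter peaks first. For the remaining genes with a promoter peak,
expression and accessibility share a Gaussian-copula latent with
correlation c = 2·sin(π·ρ/6) chosen so the latent Spearman correlation is
ρ (default 0.6). The realized CPM-level correlation is attenuated slightly
by counting noise and inflated slightly by the housekeeping genes sitting
in the top corner of both axes; empirically the two effects roughly cancel
and the measured promoter-category R lands within ±0.05 of ρ across seeds.

*Variants.* SNPs are planted per distance bin by choosing an inter-peak gap
(or chromosome-end gap) wide enough to host the sampled distance, anchoring
the position at exactly that distance from the flanking peak, and verifying
the realized nearest-peak distance by a linear scan; mis-binned placements
are resampled. Distances are sampled ≥ 50 bp away from bin edges so summit
jitter in downstream peak sets cannot move a variant across a boundary.
QTLs are 2–20 kb intervals; a configured fraction (default 0.9) is built
around a peak (guaranteed overlap), the rest are rejection-sampled into
peak-free space.

*Determinism.* All randomness flows from one integer seed through spawned
NumPy SeedSequences per component; identical config + seed gives
byte-identical serialized outputs, which the tests check file by file.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the methods assume:
replicated NB counts, stage-concentrated activation, promoter-coupled
accessibility, controlled variant geometry. It does not model GC or
mappability bias, peak-width heterogeneity across biological classes,
correlated replicates, linkage between variants, TF motifs, or distal
(enhancer) regulation — intergenic peaks are independent of expression by
construction. Passing recovery tests therefore demonstrates correctness of
the implementations under the stated noise model, not performance on real
libraries.

Recovery figures quoted in the tests (sensitivity/precision ≥ 0.9 for
stage-specificity at fold 8, baseline 50, dispersion 0.1, 2 replicates,
50 planted per stage among 5,000 features) use a homogeneous baseline.
Under the default log-normal baseline spread, weakly covered features are
much noisier on the CPM ratio scale and precision degrades (to roughly
0.65–0.87 in the same design) — on real data the entropy caller should be
paired with a minimum-expression filter.

## Problem sizes and numerics

Simulated designs in the tests and the acceptance script range from 20 to
5,000 genes and 60 to 6,000 peaks on 0.6–45 Mb genomes — sizes chosen so
the full suite runs in seconds while keeping ≥ 50 planted features per
stage for stable recovery estimates. Entropy uses the 0·log 0 ≡ 0
convention; Z of constant rows is 0 by definition; Spearman ties get
average ranks (scipy); percentile cuts use strict inequalities, so values
exactly at a cut are never "high"/"low"; all greedy and k-means tie-breaks
are deterministic as described above.
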