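import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ocrkit import (
    classify_quadrants,
    empirical_enrichment,
    link_peaks_to_genes,
    nearest_rank_percentile,
    promoter_accessibility,
    region_correlation,
)
from ocrkit.annotate import GeneModelSet


def gene_models(rows):
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end", "tss", "tes"])
    blocks = pd.DataFrame(columns=["gene_id", "feature", "start", "end"])
    return GeneModelSet(genes=genes, blocks=blocks)


class TestLinks:
    def test_promoter_peak_links_to_its_gene(self):
        ann = pd.DataFrame(
            [("p1", "promoter", "G")], columns=["peak_id", "category", "assigned_gene"]
        )
        links = link_peaks_to_genes(ann, gene_models([("G", "chr1", "+", 0, 100, 0, 99)]))
        assert links.iloc[0].tolist() == ["p1", "G", "promoter", False, False]

    def test_intergenic_tie_goes_to_lexicographically_smaller_gene(self):
        gm = gene_models(
            [("A", "chr1", "+", 0, 100, 0, 99), ("B", "chr1", "+", 2000, 2100, 2000, 2099)]
        )
        ann = pd.DataFrame(
            [("p1", "intergenic", None)], columns=["peak_id", "category", "assigned_gene"]
        )
        peaks = pd.DataFrame(
            [("p1", "chr1", 950, 1051)], columns=["peak_id", "chrom", "start", "end"]
        )  # edges 950 and 1050: both TSSs 950 away
        links = link_peaks_to_genes(ann, gm, peaks)
        row = links.iloc[0]
        assert row["gene_id"] == "A" and row["distal"] and row["tie"]

    def test_empty_annotation_gives_empty_links(self):
        gm = gene_models([("G", "chr1", "+", 0, 100, 0, 99)])
        assert len(link_peaks_to_genes(pd.DataFrame(
            columns=["peak_id", "category", "assigned_gene"]), gm)) == 0


class TestRegionCorrelation:
    def _links(self, n, category="promoter"):
        return pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(n)],
             "gene_id": [f"g{i}" for i in range(n)],
             "category": category},
        )

    def test_perfect_monotone_gives_plus_one(self):
        links = self._links(3)
        peak_cpm = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["p0", "p1", "p2"])
        gene_cpm = pd.DataFrame({"s1": [2.0, 4.0, 6.0]}, index=["g0", "g1", "g2"])
        out = region_correlation(links, peak_cpm, gene_cpm)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_perfect_antitone_gives_minus_one(self):
        links = self._links(3)
        peak_cpm = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["p0", "p1", "p2"])
        gene_cpm = pd.DataFrame({"s1": [6.0, 4.0, 2.0]}, index=["g0", "g1", "g2"])
        assert region_correlation(links, peak_cpm, gene_cpm).iloc[0]["r"] == pytest.approx(-1.0)

    def test_constant_vector_omitted(self):
        links = self._links(3)
        peak_cpm = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["p0", "p1", "p2"])
        gene_cpm = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=["g0", "g1", "g2"])
        assert len(region_correlation(links, peak_cpm, gene_cpm)) == 0

    def test_too_few_links_omitted(self):
        links = self._links(2)
        peak_cpm = pd.DataFrame({"s1": [1.0, 2.0]}, index=["p0", "p1"])
        gene_cpm = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g0", "g1"])
        assert len(region_correlation(links, peak_cpm, gene_cpm)) == 0

    def test_pooled_mode_concatenates_samples(self):
        links = self._links(3)
        peak_cpm = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]}, index=["p0", "p1", "p2"]
        )
        gene_cpm = peak_cpm.rename(index={"p0": "g0", "p1": "g1", "p2": "g2"}) * 2
        out = region_correlation(links, peak_cpm, gene_cpm, mode="pooled")
        assert list(out["sample"]) == ["pooled"] and out.iloc[0]["n"] == 6


class TestQuadrants:
    def test_nearest_rank_percentile_oracle(self):
        values = np.arange(1, 11)
        assert nearest_rank_percentile(values, 70) == 7
        assert nearest_rank_percentile(values, 50) == 5

    def test_ten_gene_worked_example(self):
        vals = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(1, 11)])
        report = classify_quadrants(vals, vals)
        byg = report.assignments.set_index("gene_id")["group"]
        assert set(byg.index[byg == "HA-HE"]) == {"g8", "g9", "g10"}
        assert set(byg.index[byg == "MA-ME"]) == {"g1", "g2", "g3", "g4"}
        # value exactly at P70 is not high (strict >): g7, and g5/g6 intermediate
        assert set(byg.index[byg == "unassigned"]) == {"g5", "g6", "g7"}

    def test_cross_groups(self):
        rng = np.random.default_rng(0)
        n = 40
        acc = pd.Series(rng.permutation(np.arange(1.0, n + 1)),
                        index=[f"g{i}" for i in range(n)])
        expr = pd.Series(rng.permutation(np.arange(1.0, n + 1)),
                         index=[f"g{i}" for i in range(n)])
        report = classify_quadrants(acc, expr)
        a = report.assignments
        hame = a[a["group"] == "HA-ME"]
        assert (hame["accessibility_max"] > report.high_cut_acc).all()
        assert (hame["expression_max"] < report.low_cut_expr).all()

    def test_partition_counts_add_up(self):
        rng = np.random.default_rng(1)
        acc = pd.Series(rng.gamma(2, 10, 200), index=[f"g{i}" for i in range(200)])
        expr = pd.Series(rng.gamma(2, 10, 300), index=[f"g{i}" for i in range(300)])
        report = classify_quadrants(acc, expr)
        counts = report.counts()
        assert sum(counts.values()) == 200
        assert report.n_excluded == 100

    def test_genes_without_promoter_peak_excluded(self):
        acc = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        expr = pd.Series(np.arange(1.0, 16.0), index=[f"g{i}" for i in range(15)])
        assert classify_quadrants(acc, expr).n_excluded == 5


class TestEmpiricalEnrichment:
    def test_p_value_formula_and_lower_bound(self):
        universe = [f"g{i}" for i in range(40)]
        prop = universe[:10]
        # target entirely inside the property set: observed proportion 1,
        # no draw can strictly exceed it
        res = empirical_enrichment(prop, universe, prop, n_samples=10_000, seed=0)
        assert res.observed_proportion == 1.0
        assert res.n_exceeding == 0
        assert res.empirical_p == pytest.approx(1 / 10_001)

    def test_p_equals_formula_exactly(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(50)]
        target = list(rng.choice(universe, size=15, replace=False))
        prop = set(rng.choice(universe, size=20, replace=False))
        res = empirical_enrichment(target, universe, prop, n_samples=2000, seed=3)
        assert res.empirical_p == (1 + res.n_exceeding) / 2001

    def test_target_equals_universe_reproduces_base_rate(self):
        universe = [f"g{i}" for i in range(30)]
        prop = universe[:12]
        res = empirical_enrichment(universe, universe, prop, n_samples=500, seed=1)
        assert res.observed_proportion == pytest.approx(12 / 30)
        assert res.empirical_p == pytest.approx(1 / 501)

    def test_agrees_with_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(40)]
        prop = set(universe[:12])
        target = universe[5:20]  # 15 genes, 7 in the property set
        res = empirical_enrichment(target, universe, prop, n_samples=10_000, seed=4)
        k = int(res.observed_proportion * 15)
        analytic = hypergeom(40, 12, 15).sf(k)  # P(X > k)
        sd = np.sqrt(analytic * (1 - analytic) / 10_000)
        assert abs(res.n_exceeding / 10_000 - analytic) <= 3 * sd + 1e-4

    def test_reproducible_under_seed(self):
        universe = [f"g{i}" for i in range(50)]
        a = empirical_enrichment(universe[:10], universe, universe[:25], 500, seed=9)
        b = empirical_enrichment(universe[:10], universe, universe[:25], 500, seed=9)
        assert a == b

    def test_errors(self):
        with pytest.raises(ValueError, match="empty target"):
            empirical_enrichment([], ["g1"], [])
        with pytest.raises(ValueError, match="subset"):
            empirical_enrichment(["gX"], ["g1"], [])


def test_promoter_coupling_recovered_on_synthetic_data(small_dataset):
    """Planted promoter-accessibility/expression coupling shows up as a
    clearly positive promoter-category Spearman R."""
    from ocrkit import cpm

    ds = small_dataset
    gene_cpm = cpm(ds.gene_counts)
    peak_cpm = cpm(ds.peak_counts)
    links = ds.truth.gene_promoter.rename(columns={"peak_id": "peak_id"})
    links = pd.DataFrame(
        {"peak_id": links["peak_id"], "gene_id": links["gene_id"], "category": "promoter"}
    )
    out = region_correlation(links, peak_cpm, gene_cpm)
    assert out["r"].mean() > 0.3


def test_promoter_accessibility_takes_max_over_peaks_and_samples():
    links = pd.DataFrame(
        [("p1", "G", "promoter"), ("p2", "G", "promoter"), ("p3", "G", "intron")],
        columns=["peak_id", "gene_id", "category"],
    )
    peak_cpm = pd.DataFrame(
        {"s1": [5.0, 1.0, 99.0], "s2": [2.0, 7.0, 99.0]}, index=["p1", "p2", "p3"]
    )
    acc = promoter_accessibility(links, peak_cpm)
    assert acc["G"] == 7.0  # intron peak ignored, max over promoter peaks/samples
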