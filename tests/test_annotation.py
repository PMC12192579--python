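import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mlgscan.annotation import (
    AnnotationSet,
    binomial_enrichment_test,
    classify_low_confidence,
    enrichment_by_category,
    intersect_annotations,
    longest_transcripts,
    multinomial_uniformity_test,
    permutation_pvalue,
    rank_genes,
    read_bed,
    track_values,
)


def _df(rows, cols=("chrom", "start", "end", "name")):
    return pd.DataFrame(rows, columns=list(cols))


@pytest.fixture()
def annotations():
    transcripts = _df(
        [
            ("chr1", 100, 500, "GENE_A"),  # longest A
            ("chr1", 100, 300, "GENE_A"),
            ("chr1", 1000, 1400, "GENE_B"),
            ("chr2", 50, 250, "GENE_C"),
        ]
    )
    feats = _df(
        [
            ("chr1", 100, 150, "5'UTR"),
            ("chr1", 100, 200, "exon"),
            ("chr1", 200, 400, "intron"),
            ("chr1", 400, 500, "3'UTR"),
            ("chr1", 1000, 1400, "exon"),
        ]
    )
    return AnnotationSet(transcripts=transcripts, genic_features=feats)


class TestIntersect:
    def test_intron_containment(self, annotations):
        out = intersect_annotations(np.array(["chr1"]), np.array([250]), annotations)
        assert out.loc[0, "label"] == "genic"
        assert out.loc[0, "sublabel"] == "intron"
        assert out.loc[0, "genes"] == "GENE_A"

    def test_utr_precedence_over_exon(self, annotations):
        out = intersect_annotations(np.array(["chr1"]), np.array([120]), annotations)
        assert out.loc[0, "sublabel"] == "5'UTR"

    def test_half_open_interval_end_outside(self, annotations):
        out = intersect_annotations(
            np.array(["chr1", "chr1"]), np.array([499, 500]), annotations
        )
        assert list(out["label"]) == ["genic", "intergenic"]

    def test_empty_annotations_all_intergenic(self):
        out = intersect_annotations(
            np.array(["chr1"]), np.array([10]), AnnotationSet()
        )
        assert list(out["label"]) == ["intergenic"]

    def test_every_anchor_gets_exactly_one_label(self, annotations, rng):
        pos = rng.integers(0, 2000, size=50)
        out = intersect_annotations(np.full(50, "chr1"), pos, annotations)
        assert set(out["label"]) <= {"genic", "intergenic"}
        genic = out[out["label"] == "genic"]
        assert set(genic["sublabel"]) <= {"5'UTR", "3'UTR", "exon", "intron"}
        assert (out[out["label"] == "intergenic"]["sublabel"] == "").all()


def test_longest_transcript_selection():
    picked = longest_transcripts(
        _df(
            [
                ("chr1", 0, 100, "G1"),
                ("chr1", 0, 300, "G1"),
                ("chr1", 500, 600, "G2"),
                ("chr1", 700, 800, "G2"),  # tie span: first in file wins
            ]
        )
    )
    assert picked.loc[picked["name"] == "G1", "end"].item() == 300
    assert picked.loc[picked["name"] == "G2", "start"].item() == 500


class TestCrgTrack:
    @pytest.fixture()
    def crg(self):
        return _df(
            [("chr1", 0, 100, "crg", 0.9), ("chr1", 100, 200, "crg", 1.0),
             ("chr1", 200, 300, "crg", 0.89)],
            cols=("chrom", "start", "end", "name", "score"),
        )

    def test_threshold_inclusive(self, crg):
        flags = classify_low_confidence(
            np.array(["chr1"] * 3), np.array([50, 150, 250]), crg
        )
        np.testing.assert_array_equal(flags, [1.0, 0.0, 1.0])

    def test_uncovered_anchor_is_nan(self, crg):
        flags = classify_low_confidence(np.array(["chr1"]), np.array([999]), crg)
        assert np.isnan(flags[0])


class TestMultinomial:
    def test_proportional_observed_p_one(self):
        p, kind = multinomial_uniformity_test(
            np.array([600, 400]), np.array([0.6, 0.4]), exact_limit=10
        )
        assert kind == "chi2"
        assert p == pytest.approx(1.0)

    def test_exact_two_category_oracle(self):
        # (5,0) under (0.5,0.5): only (5,0) and (0,5) are as unlikely -> 2/32
        p, kind = multinomial_uniformity_test(np.array([5, 0]), np.array([0.5, 0.5]))
        assert kind == "exact"
        assert p == pytest.approx(0.0625)

    def test_exact_matches_binomial_two_sided(self):
        # with 2 categories the exact multinomial is the two-sided binomial
        p, _ = multinomial_uniformity_test(np.array([8, 2]), np.array([0.5, 0.5]))
        assert p == pytest.approx(stats.binomtest(8, 10, 0.5).pvalue)

    def test_relabeling_invariance(self):
        p1, _ = multinomial_uniformity_test(np.array([7, 2, 1]), np.array([0.5, 0.3, 0.2]))
        p2, _ = multinomial_uniformity_test(np.array([1, 7, 2]), np.array([0.2, 0.5, 0.3]))
        assert p1 == pytest.approx(p2)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            multinomial_uniformity_test(np.array([0, 0]), np.array([0.5, 0.5]))


class TestBinomial:
    def test_symmetric_oracle(self):
        # two-sided at p=0.5: 2 * P(X >= 8), X ~ Bin(10, 0.5) = 112/1024
        assert binomial_enrichment_test(8, 10, 0.5) == pytest.approx(0.109375)

    def test_degenerate_success(self):
        assert binomial_enrichment_test(10, 10, 1.0) == 1.0

    def test_observed_at_mode_gives_one(self):
        assert binomial_enrichment_test(5, 10, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", range(2, 13, 2))
    def test_doubling_equivalence_at_half(self, n):
        # at p=0.5 the pmf is symmetric: min-likelihood = doubled one tail
        for x in range(n // 2 + 1, n + 1):
            doubled = min(1.0, 2 * stats.binom.sf(x - 1, n, 0.5))
            assert binomial_enrichment_test(x, n, 0.5) == pytest.approx(doubled)


class TestPermutation:
    def test_constant_labels_fraction_zero(self):
        labels = np.zeros(20, dtype=int)

        def fn(lab):
            return 0.5

        assert permutation_pvalue(fn, labels, n_perm=100, seed=0) == 0.0

    def test_observed_p_one_fraction_zero(self, rng):
        labels = rng.integers(0, 2, size=30)

        def fn(lab):
            return 1.0  # nothing can be strictly smaller

        assert permutation_pvalue(fn, labels, n_perm=200, seed=0) == 0.0

    def test_planted_extreme_enrichment(self):
        # all 40 outliers in one of two balanced categories
        rng = np.random.default_rng(5)
        labels = np.array(["a"] * 500 + ["b"] * 500)
        outliers = np.zeros(1000, dtype=bool)
        outliers[:40] = True  # all in category a

        def fn(lab):
            x = int((lab[outliers] == "a").sum())
            return binomial_enrichment_test(x, 40, 0.5)

        frac = permutation_pvalue(fn, labels, n_perm=10_000, seed=1)
        assert frac <= 0.001

    def test_reproducible_under_fixed_seed(self):
        labels = np.array(["x"] * 10 + ["y"] * 10)

        def fn(lab):
            return float((lab[:5] == "x").mean())

        a = permutation_pvalue(fn, labels, n_perm=500, seed=7)
        b = permutation_pvalue(fn, labels, n_perm=500, seed=7)
        assert a == b
        # a different seed may differ, but only within Monte Carlo noise
        c = permutation_pvalue(fn, labels, n_perm=500, seed=8)
        assert abs(a - c) < 0.15


class TestRankGenes:
    def test_gene_without_outliers_absent(self):
        genes = _df([("chr1", 0, 100, "G1"), ("chr1", 200, 300, "G2")])
        ranked = rank_genes(
            np.array(["chr1"]), np.array([50]), np.array([1e-10]), genes
        )
        assert list(ranked["gene"]) == ["G1"]

    def test_min_p_ordering(self):
        genes = _df([("chr1", 0, 100, "G1"), ("chr1", 200, 300, "G2")])
        ranked = rank_genes(
            np.array(["chr1", "chr1"]),
            np.array([50, 250]),
            np.array([1e-9, 1e-12]),
            genes,
        )
        assert list(ranked["gene"]) == ["G2", "G1"]

    def test_matches_brute_force_scan(self, rng):
        genes = _df(
            [("chr1", i * 100, i * 100 + 80, f"G{i}") for i in range(5)]
        )
        anchors = rng.integers(0, 500, size=20)
        pvals = rng.uniform(1e-12, 1e-6, size=20)
        ranked = rank_genes(np.full(20, "chr1"), anchors, pvals, genes)
        for _, row in ranked.iterrows():
            g = genes[genes["name"] == row["gene"]].iloc[0]
            mask = (anchors >= g["start"]) & (anchors < g["end"])
            assert row["min_p"] == pytest.approx(pvals[mask].min())
        assert list(ranked["min_p"]) == sorted(ranked["min_p"])


def test_enrichment_by_category_pipeline(rng):
    # 200 anchors in two categories; outliers concentrated in 'rep'
    categories = np.array(["rep"] * 60 + ["non"] * 140)
    outliers = np.zeros(200, dtype=bool)
    outliers[rng.choice(60, size=15, replace=False)] = True  # all in rep
    multi_p, kind, multi_perm, results = enrichment_by_category(
        categories, outliers, alpha=0.025, n_perm=300, seed=3
    )
    assert 0 <= multi_p <= 1
    by_label = {r.label: r for r in results}
    assert by_label["rep"].observed == 15
    assert by_label["rep"].total == 15
    assert by_label["rep"].pvalue < 1e-6
    assert by_label["rep"].perm_pvalue <= 0.05


def test_read_bed_rejects_bad_intervals(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t100\t100\tX\n")
    with pytest.raises(ValueError, match="start < end"):
        read_bed(path)
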