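"""Voting system, forwarding rules, duplicate-probe resolution, final
assembly against a top-k sort oracle, annotation, and density summaries."""

import numpy as np
import pandas as pd
import pytest

from maizearray import design
from maizearray.containers import AA, AB, BB, HET, HOM_ALT, HOM_REF, MISSING, OO
from maizearray.errors import ValidationError


def cat_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "category_nocorr", "category_corr"])


class TestForwardPhrStable:
    def test_only_doubly_phr_forwarded(self):
        cats = cat_frame([
            ("a", "PolyHighResolution", "PolyHighResolution"),
            ("b", "PolyHighResolution", "NoMinorHom"),
            ("c", "NoMinorHom", "PolyHighResolution"),
        ])
        assert design.forward_phr_stable(cats) == ["a"]

    def test_empty_input(self):
        assert design.forward_phr_stable(cat_frame([])) == []

    def test_missing_column_raises(self):
        with pytest.raises(ValidationError):
            design.forward_phr_stable(pd.DataFrame({"variant_id": []}))


def metric_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["variant_id", "final_call_rate", "fld", "het_so", "hom_ro",
                 "hom_fld", "n_geno_clusters"],
    )


class TestSelectOtvStable:
    def test_passing_variant_selected(self):
        cats = cat_frame([("a", "OTV", "OTV")])
        m = metric_frame([("a", 92.0, 4.0, -1.0, 1.5, 8.0, 3)])
        assert design.select_otv_stable(cats, m) == ["a"]

    def test_monomorphic_rejected(self):
        cats = cat_frame([("a", "OTV", "OTV")])
        m = metric_frame([("a", 95.0, np.nan, np.nan, 1.5, 8.0, 1)])
        assert design.select_otv_stable(cats, m) == []

    def test_unstable_otv_rejected(self):
        cats = cat_frame([("a", "OTV", "PolyHighResolution")])
        m = metric_frame([("a", 95.0, 4.0, -1.0, 1.5, 8.0, 3)])
        assert design.select_otv_stable(cats, m) == []

    def test_excess_missingness_rejected(self):
        cats = cat_frame([("a", "OTV", "OTV")])
        m = metric_frame([("a", 88.0, 4.0, -1.0, 1.5, 8.0, 3)])
        assert design.select_otv_stable(cats, m) == []

    def test_homfld_rule_for_two_cluster_case(self):
        cats = cat_frame([("a", "OTV", "OTV"), ("b", "OTV", "OTV")])
        m = metric_frame([
            ("a", 95.0, np.nan, np.nan, 1.5, 6.0, 2),   # homFLD > 5 passes
            ("b", 95.0, np.nan, np.nan, 1.5, 4.0, 2),   # homFLD <= 5 fails
        ])
        assert design.select_otv_stable(cats, m) == ["a"]

    def test_metric_thresholds(self):
        cats = cat_frame([(v, "OTV", "OTV") for v in "abc"])
        m = metric_frame([
            ("a", 95.0, 3.4, -1.0, 1.5, 8.0, 3),   # FLD too low
            ("b", 95.0, 4.0, -3.6, 1.5, 8.0, 3),   # HetSO too low
            ("c", 95.0, 4.0, -1.0, 0.9, 8.0, 3),   # HomRO too low
        ])
        assert design.select_otv_stable(cats, m) == []


class TestSequenceConcordance:
    def test_full_agreement(self):
        arr = np.array([[AA], [AB], [BB]])
        seq = np.array([[HOM_REF], [HET], [HOM_ALT]])
        c, flag = design.sequence_concordance(arr, seq, ["a", "b", "c"],
                                              ["a", "b", "c"])
        assert c[0] == 1.0 and not flag[0]

    def test_partial_agreement_ratio(self):
        n = 30
        arr = np.full((n, 1), AA)
        seq = np.full((n, 1), HOM_REF)
        seq[:3, 0] = MISSING          # 27 comparable
        seq[3:12, 0] = HOM_ALT        # 9 mismatches -> 18 of 27 match
        c, _ = design.sequence_concordance(arr, seq, list("abcdefghijklmnopqrstuvwxyz1234")[:n],
                                           list("abcdefghijklmnopqrstuvwxyz1234")[:n])
        assert c[0] == pytest.approx(18 / 27)

    def test_oo_calls_not_compared(self):
        arr = np.array([[OO], [AA]])
        seq = np.array([[HOM_ALT], [HOM_REF]])
        c, flag = design.sequence_concordance(arr, seq, ["a", "b"], ["a", "b"])
        assert c[0] == 1.0  # only the AA/hom-ref pair counts

    def test_no_comparable_pairs_flagged(self):
        arr = np.array([[MISSING]])
        seq = np.array([[HOM_REF]])
        c, flag = design.sequence_concordance(arr, seq, ["a"], ["a"])
        assert c[0] == 0.0 and flag[0]

    def test_disjoint_samples_raise(self):
        with pytest.raises(ValidationError):
            design.sequence_concordance(np.zeros((1, 1)), np.zeros((1, 1)),
                                        ["a"], ["b"])


class TestBinRepresentationScore:
    def test_balanced_bin_scores_zero(self):
        counts = np.full(11, 20)
        assert design.bin_representation_score(counts, 5) == 0.0

    def test_empty_bin_scores_plus_one(self):
        counts = np.array([10, 10, 0, 10, 10])
        assert design.bin_representation_score(counts, 2) == 1.0

    def test_overrepresented_bin(self):
        counts = np.array([10] * 5 + [30] + [10] * 5)
        assert design.bin_representation_score(counts, 5) == pytest.approx(-0.5)

    def test_window_truncated_at_chromosome_edge(self):
        counts = np.array([0, 10, 10])
        assert design.bin_representation_score(counts, 0) == 1.0


class TestRankVariant:
    @pytest.mark.parametrize(
        "w,c,s,expected", [(10, 1.0, 1.0, 450.0), (0, 0.0, -1.0, -10.0),
                           (5, 0.5, 0.0, 220.0)],
    )
    def test_formula(self, w, c, s, expected):
        assert design.rank_variant(w, c, s) == expected

    @pytest.mark.parametrize("w,c,s", [(3, 0.5, 0.0), (10, 1.5, 0.0), (10, 0.5, 2.0)])
    def test_out_of_range_raises(self, w, c, s):
        with pytest.raises(ValidationError):
            design.rank_variant(w, c, s)

    def test_monotone_in_each_argument(self):
        base = design.rank_variant(5, 0.5, 0.0)
        assert design.rank_variant(10, 0.5, 0.0) > base
        assert design.rank_variant(5, 0.6, 0.0) > base
        assert design.rank_variant(5, 0.5, 0.1) > base


class TestResolveDuplicateProbes:
    def test_higher_rank_wins(self):
        ranked = pd.DataFrame({"variant_id": ["v", "v"], "probe_id": ["f", "r"],
                               "rank": [440.0, 430.0]})
        out = design.resolve_duplicate_probes(ranked, seed=0)
        assert out["probe_id"].tolist() == ["f"]

    def test_tie_broken_reproducibly(self):
        ranked = pd.DataFrame({"variant_id": ["v", "v"], "probe_id": ["f", "r"],
                               "rank": [440.0, 440.0]})
        a = design.resolve_duplicate_probes(ranked, seed=3)["probe_id"].iloc[0]
        b = design.resolve_duplicate_probes(ranked, seed=3)["probe_id"].iloc[0]
        assert a == b

    def test_single_probe_kept(self):
        ranked = pd.DataFrame({"variant_id": ["v"], "probe_id": ["f"], "rank": [1.0]})
        assert len(design.resolve_duplicate_probes(ranked, seed=0)) == 1


class TestAssembleFinal:
    def test_target_equal_to_forwarded(self):
        ranked = pd.DataFrame({"variant_id": ["x"], "rank": [100.0]})
        d = design.assemble_final(["a", "b"], ["c"], ranked, target_size=3)
        assert set(d.variants["variant_id"]) == {"a", "b", "c"}
        assert d.composition["n_ranked"] == 0

    def test_matches_top_k_sort_oracle(self):
        rng = np.random.default_rng(0)
        ranked = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(200)],
            "rank": rng.choice(np.arange(0, 450, 5).astype(float), 200),
        })
        d = design.assemble_final([], [], ranked, target_size=50, seed=1)
        chosen = set(d.variants["variant_id"])
        cutoff = np.sort(ranked["rank"].to_numpy())[::-1][49]
        must_have = set(ranked.loc[ranked["rank"] > cutoff, "variant_id"])
        assert must_have <= chosen
        assert (d.variants.dropna(subset=["rank"])["rank"] >= cutoff).all()
        assert len(chosen) == 50

    def test_forwarded_never_dropped_and_pool_exhaustion_warns(self):
        ranked = pd.DataFrame({"variant_id": ["x", "y"], "rank": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            d = design.assemble_final(["a"], [], ranked, target_size=10)
        assert "a" in set(d.variants["variant_id"])
        assert len(d.variants) == 3

    def test_target_zero_with_empty_forwarded(self):
        ranked = pd.DataFrame({"variant_id": ["x"], "rank": [1.0]})
        d = design.assemble_final([], [], ranked, target_size=0)
        assert len(d.variants) == 0


class TestAnnotateVariants:
    def _genes(self):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "chrom": "chr1",
            "start": np.arange(10) * 100_000 + 50_000,
            "end": np.arange(10) * 100_000 + 52_000,
            "strand": ["+", "-"] * 5,
        })

    def test_gene_body_hit_is_genic_without_features(self):
        var = pd.DataFrame({"variant_id": ["v0"], "chrom": ["chr1"], "pos": [50_500]})
        table, summary = design.annotate_variants(var, self._genes())
        assert table["labels"].iloc[0] == "genic"
        assert summary["feature_resolution"] == "genic-only"

    def test_upstream_boundary_at_4999bp(self):
        var = pd.DataFrame({"variant_id": ["v0"], "chrom": ["chr1"],
                            "pos": [50_000 - 4_999]})
        table, _ = design.annotate_variants(var, self._genes())
        assert "upstream-5kb" in table["labels"].iloc[0]

    def test_strand_aware_flanks(self):
        # gene g1 on '-' strand: positions after its end are upstream
        var = pd.DataFrame({"variant_id": ["v0"], "chrom": ["chr1"],
                            "pos": [152_000 + 100]})
        table, _ = design.annotate_variants(var, self._genes())
        assert "upstream-5kb" in table["labels"].iloc[0]

    def test_seventy_percent_tagged_toy(self):
        genes = self._genes()
        var = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(7)],
            "chrom": "chr1",
            "pos": [i * 100_000 + 51_000 for i in range(7)],
        })
        _, summary = design.annotate_variants(var, genes)
        assert summary["pct_tagged_genic"] == pytest.approx(70.0)
        assert summary["pct_tagged_with_flanks"] >= summary["pct_tagged_genic"]

    def test_every_variant_gets_a_label(self):
        var = pd.DataFrame({"variant_id": ["far"], "chrom": ["chr1"],
                            "pos": [999_999_999]})
        table, _ = design.annotate_variants(var, self._genes())
        assert table["labels"].iloc[0] == "intergenic"

    def test_feature_level_labels(self):
        genes = pd.DataFrame({
            "gene_id": ["g0", "g0", "g0"],
            "feature": ["gene", "CDS", "five_prime_UTR"],
            "chrom": "chr1",
            "start": [1000, 1200, 1000],
            "end": [3000, 2000, 1199],
            "strand": "+",
        })
        var = pd.DataFrame({
            "variant_id": ["in_cds", "in_utr", "in_intron"],
            "chrom": "chr1",
            "pos": [1500, 1100, 2500],
        })
        table, summary = design.annotate_variants(var, genes)
        assert table["labels"].tolist() == ["coding", "UTR", "intron"]
        assert summary["feature_resolution"] == "coding/intron/UTR"


class TestDensityStats:
    def test_two_variants_one_kb_apart(self):
        var = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1000, 2000]})
        out = design.density_stats(var, {"chr1": 10_000})
        assert out["mean_gap_kb"] == pytest.approx(1.0)

    def test_uniform_grid_mean_equals_median(self):
        var = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 101) * 500})
        out = design.density_stats(var, {"chr1": 60_000})
        assert out["mean_gap_kb"] == pytest.approx(out["median_gap_kb"])

    def test_genome_average_density(self):
        var = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 1001) * 100})
        out = design.density_stats(var, {"chr1": 2_000_000})
        assert out["mean_density_kb"] == pytest.approx(2.0)

    def test_genetic_map_interpolation(self):
        var = pd.DataFrame({"chrom": "chr1", "pos": [1000, 2000, 3000]})
        gmap = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [0, 4000],
                             "cm": [0.0, 4.0]})
        out = design.density_stats(var, {"chr1": 10_000}, genetic_map=gmap)
        assert out["mean_gap_cm"] == pytest.approx(1.0)

    def test_empty_design_raises(self):
        with pytest.raises(ValidationError):
            design.density_stats(pd.DataFrame({"chrom": [], "pos": []}), {})
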