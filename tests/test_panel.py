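"""Panel validation analyses: concordance, Mendelian checks, polymorphism
partition, MAF spectra, Rogers distances and PCoA, LD statistics, pruning
and imputation."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from maizearray import panel
from maizearray.containers import HET, HOM_ALT, HOM_REF, MISSING
from maizearray.errors import ValidationError


class TestReplicateConcordance:
    def test_identical_rows_give_100(self):
        m = np.tile([HOM_REF, HET, HOM_ALT], (2, 10))
        out = panel.replicate_concordance(m, [(0, 1)])
        assert out["pct_identical"].iloc[0] == 100.0

    def test_direct_count(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 1000).astype(np.int8)
        b = a.copy()
        b[:5] = (b[:5] + 1) % 3
        out = panel.replicate_concordance(np.vstack([a, b]), [(0, 1)])
        assert out["pct_identical"].iloc[0] == pytest.approx(99.5)

    def test_disjoint_missingness_undefined(self):
        a = np.array([HOM_REF, MISSING])
        b = np.array([MISSING, HOM_REF])
        out = panel.replicate_concordance(np.vstack([a, b]), [(0, 1)])
        assert out["undefined"].iloc[0] and np.isnan(out["pct_identical"].iloc[0])


class TestTrioMendelian:
    def test_compatible_and_incompatible_cases(self):
        #            offspring, p1, p2
        m = np.array([
            [HET, HET],        # offspring
            [HOM_REF, HOM_REF],  # parent 1
            [HOM_ALT, HOM_REF],  # parent 2
        ])
        overall, per = panel.trio_mendelian(m, [(0, 1, 2)])
        # variant 0: AA x BB -> AB consistent; variant 1: AA x AA -> AB not
        assert per["pct_consistent"].iloc[0] == 50.0
        assert overall == 50.0

    def test_missing_calls_skip_variant(self):
        m = np.array([[HET], [MISSING], [HOM_ALT]])
        overall, per = panel.trio_mendelian(m, [(0, 1, 2)])
        assert np.isnan(overall)

    def test_simulated_trios_fully_consistent(self, truth, panel_config):
        idx = {s.id: i for i, s in enumerate(panel_config.samples)}
        trios = [(idx[s.id], idx[s.parents[0]], idx[s.parents[1]])
                 for s in panel_config.samples if s.pool == "hybrid"]
        overall, _ = panel.trio_mendelian(truth.genotypes, trios)
        assert overall == 100.0

    def test_bad_index_raises(self):
        with pytest.raises(ValidationError):
            panel.trio_mendelian(np.zeros((2, 3), np.int8), [(0, 1, 5)])


class TestPolymorphismPartition:
    def test_constant_column_monomorphic_everywhere(self):
        m = np.full((6, 4), HOM_REF, np.int8)
        summary, venn = panel.polymorphism_partition(m, {"g1": [0, 1, 2], "g2": [3, 4, 5]})
        assert summary["g1"]["n_polymorphic"] == 0
        assert all(v == 0 for v in venn.values())

    def test_single_sample_group_always_monomorphic(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 3, (4, 50)).astype(np.int8)
        summary, _ = panel.polymorphism_partition(m, {"solo": [0]})
        assert summary["solo"]["n_polymorphic"] == 0

    def test_venn_matches_brute_force_set_algebra(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 3, (9, 200)).astype(np.int8)
        groups = {"a": [0, 1, 2], "b": [3, 4, 5], "c": [6, 7, 8]}
        summary, venn = panel.polymorphism_partition(m, groups)
        poly = {
            g: {j for j in range(200) if len(set(m[rows, j])) >= 2}
            for g, rows in groups.items()
        }
        for cell, count in venn.items():
            expected = set(range(200))
            for g in groups:
                expected &= poly[g] if g in cell else (set(range(200)) - poly[g])
            assert count == len(expected)
        assert sum(venn.values()) == len(poly["a"] | poly["b"] | poly["c"])


class TestMafSpectrum:
    def test_fixed_column_has_zero_maf(self):
        m = np.full((10, 1), HOM_ALT, np.int8)
        assert panel.maf_spectrum(m).maf[0] == 0.0

    def test_balanced_column_has_maf_half(self):
        m = np.array([[HOM_REF]] * 5 + [[HOM_ALT]] * 5, np.int8)
        assert panel.maf_spectrum(m).maf[0] == 0.5

    def test_het_contributes_half(self):
        m = np.array([[HET]] * 4, np.int8)
        assert panel.maf_spectrum(m).maf[0] == 0.5

    def test_ascertained_set_loses_rare_alleles(self, truth):
        gt = truth.genotypes
        spec_all = panel.maf_spectrum(gt)
        intermediate = (spec_all.maf > 0.2) & (spec_all.maf < 0.5)
        spec_asc = panel.maf_spectrum(gt, subset=intermediate)
        assert spec_asc.frac_below_005 < spec_all.frac_below_005


class TestRogersDistance:
    def test_identical_samples_zero(self):
        m = np.tile([HOM_REF, HET, HOM_ALT], (2, 5))
        d = panel.rogers_distance(m)
        assert d[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        m = np.vstack([np.full(10, HOM_REF), np.full(10, HOM_ALT)]).astype(np.int8)
        assert panel.rogers_distance(m)[0, 1] == 1.0

    def test_single_locus_hom_vs_het(self):
        m = np.array([[HOM_REF], [HET]], np.int8)
        # sqrt(0.5 * ((1-0.5)^2 + (0-0.5)^2)) = 0.5
        assert panel.rogers_distance(m)[0, 1] == pytest.approx(0.5)

    def test_reduction_to_mean_absolute_frequency_difference(self):
        # the locus term sqrt(((dp)^2 + (dq)^2)/2) equals |dp| for bi-allelic
        # loci; check the full formula against the implementation
        rng = np.random.default_rng(3)
        m = rng.integers(0, 3, (4, 60)).astype(np.int8)
        d = panel.rogers_distance(m)
        p = m / 2.0
        for i in range(4):
            for j in range(i + 1, 4):
                loci = np.sqrt(((p[i] - p[j]) ** 2 + ((1 - p[i]) - (1 - p[j])) ** 2) / 2)
                assert d[i, j] == pytest.approx(loci.mean())

    @given(m=arrays(np.int8, (5, 30), elements=st.integers(0, 2)))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_metric_properties_on_complete_data(self, m):
        # with pairwise-complete deletion the triangle inequality can fail
        # (pairs average over different locus sets), so the metric property
        # is asserted on complete matrices
        d = panel.rogers_distance(m)
        npt.assert_allclose(d, d.T)
        npt.assert_allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1.0 + 1e-12).all()
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    @given(m=arrays(np.int8, (4, 20), elements=st.integers(-1, 2)))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_bounds_with_missingness(self, m):
        d = panel.rogers_distance(m)
        npt.assert_allclose(d, d.T)
        finite = ~np.isnan(d)
        assert (d[finite] >= -1e-12).all() and (d[finite] <= 1.0 + 1e-12).all()


class TestPcoa:
    def test_recovers_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 2.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = panel.pcoa(d, n_axes=2)
        axis1 = res.coordinates[:, 0]
        recovered = np.abs(axis1[:, None] - axis1[None, :])
        npt.assert_allclose(recovered, d, atol=1e-8)

    def test_two_pool_panel_separates_on_axis_one(self, truth, panel_config):
        from sklearn.metrics import silhouette_score

        pools = np.array([s.pool for s in panel_config.samples])
        keep = np.isin(pools, ["Dent", "Flint"])
        d = panel.rogers_distance(truth.genotypes[keep])
        res = panel.pcoa(d, n_axes=2)
        assert silhouette_score(res.coordinates[:, :1], pools[keep]) > 0

    def test_zero_distances_give_zero_coordinates(self):
        res = panel.pcoa(np.zeros((4, 4)), n_axes=2)
        npt.assert_allclose(res.coordinates, 0.0, atol=1e-9)

    def test_asymmetric_matrix_raises(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            panel.pcoa(d)


class TestLdR2:
    def test_duplicated_column_r2_one(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, 50).astype(np.int8)
        m = np.stack([col, col], axis=1)
        out = panel.ld_r2(m, positions=np.array([100, 200]))
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_column_excluded(self):
        m = np.stack([np.full(20, HOM_REF), np.arange(20) % 3], axis=1).astype(np.int8)
        out = panel.ld_r2(m, positions=np.array([100, 200]))
        assert len(out) == 0

    def test_independent_loci_mean_r2_near_null(self):
        rng = np.random.default_rng(5)
        n = 200
        m = rng.integers(0, 3, (n, 60)).astype(np.int8)
        out = panel.ld_r2(m, positions=np.arange(60) * 10 + 1)
        assert abs(out["r2"].mean() - 1.0 / n) < 3.0 / n

    def test_window_limits_pairs(self):
        m = np.random.default_rng(6).integers(0, 3, (30, 3)).astype(np.int8)
        out = panel.ld_r2(m, positions=np.array([1, 2, 2_000_000]), window_bp=1_000_000)
        assert set(zip(out["i"], out["j"])) <= {(0, 1)}


class TestLdDecay:
    def test_recovers_analytic_crossing_of_exponential(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(1e3, 1e6, 4000)
        r2 = 0.4 * np.exp(-d / 100_000) + rng.normal(0, 0.02, d.size)
        est = panel.ld_decay_distance(d, r2, threshold=0.2)
        assert est == pytest.approx(100.0 * np.log(2.0), rel=0.15)

    def test_curve_below_threshold_returns_zero(self):
        d = np.linspace(1e3, 1e5, 100)
        r2 = np.full(100, 0.05)
        assert panel.ld_decay_distance(d, r2, threshold=0.2) == 0.0

    def test_curve_above_threshold_is_undefined(self):
        d = np.linspace(1e3, 1e5, 100)
        r2 = np.full(100, 0.9)
        assert panel.ld_decay_distance(d, r2, threshold=0.2) is None

    def test_too_few_pairs_undefined(self):
        assert panel.ld_decay_distance(np.arange(5.0) + 1, np.ones(5)) is None


class TestLdPrune:
    def test_duplicated_adjacent_column_dropped(self):
        rng = np.random.default_rng(8)
        col = rng.integers(0, 3, 40).astype(np.int8)
        m = np.stack([col, col], axis=1)
        kept = panel.ld_prune(m, positions=np.array([100, 150]))
        assert kept.tolist() == [0]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(9)
        m = rng.integers(0, 3, (200, 10)).astype(np.int8)
        kept = panel.ld_prune(m, positions=np.arange(10) * 100 + 1)
        assert kept.tolist() == list(range(10))

    def test_matches_greedy_oracle_on_planted_blocks(self):
        rng = np.random.default_rng(10)
        base = rng.integers(0, 3, (100, 6)).astype(np.int8)
        # plant LD blocks by duplicating columns with light noise
        cols = [base[:, 0], base[:, 0], base[:, 1], base[:, 1], base[:, 2],
                base[:, 3]]
        m = np.stack(cols, axis=1)
        flip = rng.random(m.shape) < 0.02
        m[flip] = (m[flip] + 1) % 3
        pos = np.arange(6) * 50 + 1
        kept = panel.ld_prune(m, positions=pos, r2_max=0.8)

        def oracle():
            retained = []
            dose = m.astype(float)
            for v in range(6):
                ok = True
                for u in retained:
                    r = np.corrcoef(dose[:, v], dose[:, u])[0, 1]
                    if r * r > 0.8:
                        ok = False
                        break
                if ok:
                    retained.append(v)
            return retained

        assert kept.tolist() == oracle()


class TestImputeMissing:
    def test_high_missingness_variant_dropped(self):
        m = np.zeros((25, 2), np.int8)
        m[:3, 0] = MISSING  # 12 % missing
        out, kept = panel.impute_missing(m, max_missing_fraction=0.10)
        assert kept.tolist() == [1]

    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(11)
        m = rng.integers(0, 3, (10, 5)).astype(np.int8)
        out, kept = panel.impute_missing(m)
        npt.assert_array_equal(out, m)

    def test_mode_fill(self):
        col = np.array([HOM_REF] * 9 + [MISSING], np.int8)
        out, _ = panel.impute_missing(col[:, None])
        assert (out == HOM_REF).all()
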