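import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milletmap import association as assoc
from milletmap import population_structure as ps
from milletmap.errors import AnalysisError
from milletmap.panel_io import MISSING

from conftest import make_panel


class TestThreshold:
    def test_one_over_n_and_neglog(self):
        thr, neglog = assoc.bonferroni_threshold(267)
        assert thr == 1.0 / 267
        assert f"{thr:.2e}" == "3.75e-03"
        assert neglog == 2.43

    def test_single_marker(self):
        assert assoc.bonferroni_threshold(1) == (1.0, 0.0)


class TestLD:
    def test_pair_count(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([100, 104], size=(20, 12, 2)).astype(np.int32)
        df = assoc.ld_matrix(make_panel(calls))
        assert len(df) == 12 * 11 // 2

    def test_complete_association_r2_one(self):
        # two biallelic loci, allele states perfectly matched line by line
        calls = [[(100, 100), (200, 200)]] * 6 + [[(104, 104), (204, 204)]] * 6
        df = assoc.ld_matrix(make_panel(calls), n_perm=50, seed=1)
        assert df.loc[0, "r2"] == pytest.approx(1.0, abs=1e-12)
        assert df.loc[0, "p"] == pytest.approx(1 / 51)

    def test_monomorphic_pair_flagged_zero(self):
        calls = [[(100, 100), (200, 200)], [(100, 100), (204, 204)], [(100, 100), (200, 204)]]
        df = assoc.ld_matrix(make_panel(calls))
        assert bool(df.loc[0, "monomorphic"]) and df.loc[0, "r2"] == 0.0

    def test_missing_path_agrees_with_complete_path(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([100, 104, 108], size=(25, 8, 2)).astype(np.int32)
        panel = make_panel(calls)
        fast = assoc.ld_matrix(panel, n_perm=0)
        slow = assoc._ld_matrix_missing(panel, n_perm=0, seed=0)
        assert np.allclose(fast["r2"], slow["r2"], atol=1e-12)

    def test_independent_loci_low_r2_uniform_p(self, small_sim):
        panel, _, _ = small_sim
        df = assoc.ld_matrix(panel, n_perm=99, seed=5)
        ok = ~df["monomorphic"]
        assert df.loc[ok, "r2"].mean() < 0.05
        assert stats.kstest(df.loc[ok, "p"], "uniform").statistic < 0.1


def _series(panel, values):
    return pd.Series(np.asarray(values, float), index=panel.line_ids)


class TestGLM:
    def test_perfect_separation(self):
        calls = [[(100, 100)]] * 6 + [[(108, 108)]] * 6
        panel = make_panel(calls)
        y = _series(panel, [40.0 + i * 0.01 for i in range(6)] + [60.0 + i * 0.01 for i in range(6)])
        (rec,) = assoc.glm_scan(y, panel, None, trait="Fe", dataset_name="t")
        assert rec.p < 1e-6 and rec.marker_R2 > 0.99

    def test_marker_orthogonal_to_structure_driven_trait(self):
        rng = np.random.default_rng(0)
        n = 40
        q = np.column_stack([np.r_[np.full(20, 0.9), np.full(20, 0.1)]])
        q = np.column_stack([q, 1 - q])
        # marker alternates within subpopulations: orthogonal to structure
        calls = np.array([[(100, 100)] if i % 2 else [(108, 108)] for i in range(n)], dtype=np.int32)
        panel = make_panel(calls)
        y = _series(panel, 50 + 10 * q[:, 0] + rng.normal(0, 0.1, n))
        (rec,) = assoc.glm_scan(y, panel, ps.QMatrix(panel.line_ids, q), trait="Fe", dataset_name="t")
        assert rec.p > 0.05

    def test_type_one_error_near_nominal(self, default_sim):
        panel, pheno, _ = default_sim
        from milletmap import phenotype_stats as phs

        y = phs.build_datasets(pheno, "Fe")["GM"]
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(3):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            recs = assoc.glm_scan(yp, panel, None, trait="Fe", dataset_name="null")
            hits += sum(r.p < 0.05 for r in recs)
            total += len(recs)
        lo, hi = stats.binom.interval(0.999, total, 0.05)
        assert lo <= hits <= hi

    def test_partial_f_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        alleles = np.array([100, 104, 108])
        calls = alleles[rng.integers(0, 3, size=(40, 1, 2))].astype(np.int32)
        panel = make_panel(np.sort(calls, axis=2))
        y = _series(panel, rng.normal(50, 5, 40))
        (rec,) = assoc.glm_scan(y, panel, None, trait="Fe", dataset_name="t")
        X, _ = assoc._marker_design(panel, 0, np.arange(40), 3)
        full = sm.OLS(y.to_numpy(), sm.add_constant(X)).fit()
        null = sm.OLS(y.to_numpy(), np.ones((40, 1))).fit()
        _, p_sm, _ = full.compare_f_test(null)
        assert rec.p == pytest.approx(p_sm, abs=1e-10)
        assert rec.marker_R2 == pytest.approx(full.rsquared, abs=1e-10)

    def test_rare_alleles_merged_into_other_class(self):
        calls = [[(100, 100)]] * 8 + [[(104, 104)]] * 4 + [[(108, 108)], [(112, 112)]]
        panel = make_panel(calls)
        y = _series(panel, np.arange(14, dtype=float) + 40)
        (rec,) = assoc.glm_scan(y, panel, None, trait="Fe", dataset_name="t", min_class_size=3)
        labels = [e.split("=")[0] for e in rec.allele_effects]
        assert "other" in labels or len(labels) == 1  # 108/112 carriers pooled


class TestMLM:
    def test_equals_glm_when_polygenic_variance_zero(self, small_sim):
        panel, pheno, _ = small_sim
        from milletmap import phenotype_stats as phs

        y = phs.build_datasets(pheno, "Fe")["GM"]
        kin = ps.kinship(panel)
        glm = assoc.glm_scan(y, panel, None, trait="Fe", dataset_name="GM")
        mlm = assoc.mlm_scan(y, panel, None, kin, trait="Fe", dataset_name="GM", variance_ratio=0.0)
        assert len(glm) == len(mlm) > 0
        for a, b in zip(glm, mlm):
            assert a.p == pytest.approx(b.p, abs=1e-8)
            assert a.marker_R2 == pytest.approx(b.marker_R2, abs=1e-8)

    def test_mlm_less_inflated_than_glm_under_confounding(self):
        # phenotype = polygenic signal along structure, no true marker effect
        from milletmap.synthetic_panel import SimConfig, simulate_panel
        from milletmap import phenotype_stats as phs

        better = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SimConfig(n_lines=80, n_markers=120, drift_F=0.3, seed=seed + 60, planted_qtls=[])
            panel, pheno, truth = simulate_panel(cfg)
            y = phs.build_datasets(pheno, "Fe")["GM"]
            kin = ps.kinship(panel)
            glm = assoc.glm_scan(y, panel, None, trait="Fe", dataset_name="GM")
            mlm = assoc.mlm_scan(y, panel, None, kin, trait="Fe", dataset_name="GM")
            lam_g = assoc.genomic_inflation([r.p for r in glm])
            lam_m = assoc.genomic_inflation([r.p for r in mlm])
            better += abs(lam_m - 1) <= abs(lam_g - 1)
        assert better >= n_seeds - 1


class TestDiagnostics:
    def test_qq_single_value(self):
        expected, observed = assoc.qq_data([0.5])
        assert expected[0] == 0.5 and observed[0] == 0.5

    def test_qq_reorder_invariance_and_uniform_diagonal(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        e1, o1 = assoc.qq_data(p)
        e2, o2 = assoc.qq_data(p[::-1])
        assert np.array_equal(o1, o2) and np.array_equal(e1, e2)
        ks_band = 1.36 / np.sqrt(len(p))  # 95% Kolmogorov band
        assert np.max(np.abs(o1 - e1)) < ks_band * 1.5

    def test_empty_pvalues_rejected(self):
        with pytest.raises(AnalysisError):
            assoc.qq_data([])

    def test_mta_frequency_counts_and_order_invariance(self):
        recs = [
            assoc.MTARecord("m1", "Fe", d, "MLM", 0.001, 0.1)
            for d in ["Del-14", "Jod-14", "GM"]
        ] + [
            assoc.MTARecord("m1", "Fe", "DW-14", "MLM", 0.5, 0.0),
            assoc.MTARecord("m2", "Zn", "GM", "MLM", 0.002, 0.1),
        ]
        thr = 1 / 267
        tab1 = assoc.mta_frequency(recs, thr)
        tab2 = assoc.mta_frequency(recs[::-1], thr)
        assert tab1.equals(tab2)
        row = tab1[(tab1.marker_id == "m1") & (tab1.trait == "Fe")].iloc[0]
        assert row.n_significant == 3
        assert row.datasets == "Del-14;GM;Jod-14"
        assert assoc.mta_frequency([recs[3]], thr).empty


class TestSubpopAnova:
    def _assignment(self, panel, label="A"):
        return ps.SubpopAssignment({l: label for l in panel.line_ids})

    def test_two_classes_match_t_test_squared(self):
        rng = np.random.default_rng(2)
        calls = [[(100, 100)]] * 7 + [[(108, 108)]] * 7
        panel = make_panel(calls)
        y = _series(panel, rng.normal(50, 5, 14))
        res = assoc.subpop_allele_anova(panel, y, self._assignment(panel), "M1")
        f, p = res["A"]
        g1, g2 = y.iloc[:7], y.iloc[7:]
        t, pt = stats.ttest_ind(g1, g2)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(pt, abs=1e-10)

    def test_equal_class_means_give_tiny_f(self):
        calls = [[(100, 100)]] * 4 + [[(108, 108)]] * 4
        panel = make_panel(calls)
        y = _series(panel, [49.0, 51.0, 50.0, 50.0, 49.0, 51.0, 50.0, 50.0])
        f, p = assoc.subpop_allele_anova(panel, y, self._assignment(panel), "M1")["A"]
        assert f == pytest.approx(0.0, abs=1e-12) and p > 0.99

    def test_separated_classes_significant(self):
        rng = np.random.default_rng(4)
        calls = [[(100, 100)]] * 6 + [[(108, 108)]] * 6
        panel = make_panel(calls)
        y = _series(panel, np.r_[rng.normal(50, 1, 6), rng.normal(55, 1, 6)])  # 5 SD apart
        _, p = assoc.subpop_allele_anova(panel, y, self._assignment(panel), "M1")["A"]
        assert p < 0.01

    def test_monomorphic_subpop_skipped(self):
        calls = [[(100, 100)]] * 5
        panel = make_panel(calls)
        y = _series(panel, np.arange(5, dtype=float) + 40)
        res = assoc.subpop_allele_anova(panel, y, self._assignment(panel), "M1")
        assert res["A"] is None
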