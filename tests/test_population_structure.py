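import numpy as np
import pandas as pd
import pytest
from scipy import stats

from milletmap import population_structure as ps
from milletmap.errors import AnalysisError, ConfigError
from milletmap.synthetic_panel import SimConfig, simulate_panel

from conftest import make_panel


class TestAdmixtureEM:
    def test_k1_is_pooled_frequency_model(self, small_sim):
        panel, _, _ = small_sim
        (run,) = ps.fit_admixture(panel, K=1)
        assert np.all(run.Q.q == 1.0)
        # independent multinomial log-likelihood from pooled copy counts
        D, slices, _ = panel.dosage()
        ll = 0.0
        for sl in slices:
            counts = D[:, sl].sum(axis=0).astype(float)
            p = counts / counts.sum()
            ll += float((counts * np.log(p)).sum())
        assert run.loglik == pytest.approx(ll, abs=1e-6)

    def test_em_loglik_is_nondecreasing(self, small_sim):
        panel, _, _ = small_sim
        runs = ps.fit_admixture(panel, K=3, restarts=2, max_iter=60, seed=3, track_loglik=True)
        for run in runs:
            trace = np.array(run.loglik_trace)
            assert np.all(np.diff(trace) > -1e-6)

    def test_two_population_recovery_without_admixture(self):
        cfg = SimConfig(
            n_lines=60, n_markers=80, K_true=2, drift_F=0.3,
            admixture_alpha=0.0, seed=9, planted_qtls=[],
        )
        panel, _, truth = simulate_panel(cfg)
        best = ps.fit_admixture(panel, K=2, restarts=3, max_iter=300, seed=1)[0]
        assert best.Q.q.max(axis=1).mean() > 0.9
        qa, _ = ps.align_q(best.Q.q, truth.q_true.q)
        agree = (qa.argmax(axis=1) == truth.q_true.q.argmax(axis=1)).mean()
        assert agree > 0.95

    def test_k_out_of_range_rejected(self, small_sim):
        panel, _, _ = small_sim
        with pytest.raises(ConfigError):
            ps.fit_admixture(panel, K=panel.n_lines + 1)


class TestEvanno:
    @staticmethod
    def _runs(ll_values, K):
        return [
            ps.AdmixtureRun(K, i, ll, ps.QMatrix(["x"], np.ones((1, 1))), np.zeros((1, 1, 1)), 1, True)
            for i, ll in enumerate(ll_values)
        ]

    def test_linear_loglik_gives_zero_delta_k(self):
        runs = {K: self._runs([-100.0 + 10 * K, -100.2 + 10 * K], K) for K in range(1, 5)}
        tab = ps.evanno_delta_k(runs)
        interior = tab.dropna(subset=["delta_K"])
        assert list(interior["K"]) == [2, 3]
        assert np.allclose(interior["delta_K"], 0.0, atol=1e-9)

    def test_endpoints_carry_no_delta_k(self):
        runs = {K: self._runs([-50.0 * K, -50.0 * K - K * K], K) for K in range(1, 5)}
        tab = ps.evanno_delta_k(runs)
        assert np.isnan(tab.loc[tab["K"] == 1, "delta_K"]).all()
        assert np.isnan(tab.loc[tab["K"] == 4, "delta_K"]).all()

    def test_zero_sd_reports_infinity_with_warning(self):
        runs = {K: self._runs([-10.0 * K, -10.0 * K], K) for K in range(1, 4)}
        runs[3] = self._runs([-35.0, -36.0], 3)
        with pytest.warns(UserWarning, match="inf"):
            tab = ps.evanno_delta_k(runs)
        assert np.isinf(tab.loc[tab["K"] == 2, "delta_K"]).all()


class TestAssignment:
    def test_threshold_rule_and_boundary(self):
        q = ps.QMatrix(["a", "b", "c"], np.array([[0.7, 0.2, 0.1], [0.5, 0.3, 0.2], [0.34, 0.33, 0.33]]))
        labels = ps.assign_subpopulations(q).labels
        assert labels["a"] != "admixture"
        assert labels["b"] == "admixture"
        assert labels["c"] == "admixture"
        q2 = ps.QMatrix(["a"], np.array([[0.6, 0.4]]))
        assert ps.assign_subpopulations(q2).labels["a"] != "admixture"  # inclusive

    def test_groups_named_by_descending_size(self):
        q = np.array([[0.9, 0.1]] * 2 + [[0.1, 0.9]] * 5)
        labels = ps.assign_subpopulations(ps.QMatrix(list("abcdefg"), q)).labels
        assert labels["g"] == "A" and labels["a"] == "B"  # bigger group is A

    def test_invalid_threshold(self):
        q = ps.QMatrix(["a"], np.array([[1.0]]))
        with pytest.raises(ConfigError):
            ps.assign_subpopulations(q, threshold=0.4)


class TestDistanceTreeOrdination:
    def test_nei_distance_identical_and_disjoint(self):
        panel = make_panel(
            [[(100, 100), (200, 200)], [(100, 100), (200, 200)], [(110, 110), (210, 210)]]
        )
        d = ps.nei_distance(panel, cap=10.0)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.iloc[0, 2] == pytest.approx(10.0)  # -ln 0 capped
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_nj_recovers_additive_tree(self):
        dm = pd.DataFrame(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        tree = ps.nj_tree(dm)
        for x, y in [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]:
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(dm.loc[x, y])

    def test_nj_newick_round_trips(self, tmp_path, small_sim):
        from skbio import TreeNode

        panel, _, _ = small_sim
        tree = ps.nj_tree(ps.nei_distance(panel))
        path = tmp_path / "t.nwk"
        tree.write(str(path), format="newick")
        again = TreeNode.read(str(path))
        assert {t.name for t in again.tips()} == set(panel.line_ids)

    def test_nj_requires_three_taxa(self):
        dm = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"], dtype=float)
        with pytest.raises(AnalysisError):
            ps.nj_tree(dm)

    def test_pcoa_exact_on_euclidean_input(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        dm = pd.DataFrame(d, index=[str(i) for i in range(12)], columns=[str(i) for i in range(12)])
        coords, explained = ps.pcoa(dm, n_axes=3)
        rec = np.linalg.norm(coords.values[:, None] - coords.values[None, :], axis=2)
        assert np.allclose(rec, d, atol=1e-8)
        assert explained.sum() == pytest.approx(1.0, abs=1e-8)

    def test_pcoa_collinear_points_need_one_axis(self):
        x = np.arange(8, dtype=float)
        d = np.abs(x[:, None] - x[None, :])
        dm = pd.DataFrame(d, index=[str(i) for i in x], columns=[str(i) for i in x])
        _, explained = ps.pcoa(dm, n_axes=2)
        assert explained.iloc[0] == pytest.approx(1.0, abs=1e-8)


class TestKinship:
    def test_self_and_disjoint_sharing(self):
        panel = make_panel([[(100, 100), (200, 200)], [(110, 110), (220, 220)]])
        k = ps.kinship(panel)
        assert k.k[0, 0] == pytest.approx(1.0)
        assert k.k[0, 1] == pytest.approx(0.0)

    def test_heterozygote_half_share(self):
        panel = make_panel([[(100, 104)], [(100, 100)], [(104, 108)]])
        k = ps.kinship(panel)
        assert k.k[0, 1] == pytest.approx(0.5)
        assert k.k[0, 2] == pytest.approx(0.5)
        assert k.k[1, 2] == pytest.approx(0.0)

    def test_within_subpop_exceeds_between(self, small_sim):
        panel, _, truth = small_sim
        k = ps.kinship(panel).k
        lab = truth.q_true.q.argmax(axis=1)
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        assert k[same & off].mean() > k[~same].mean()


class TestAmova:
    def test_partition_identity_and_percent_sum(self, default_sim):
        panel, _, truth = default_sim
        assign = ps.assign_subpopulations(truth.q_true)
        res = ps.amova(panel, assign, n_perm=49, seed=1)
        # SS(total) recomputed independently from pooled allele counts
        from milletmap.population_structure import _ss_from_counts

        G, _ = panel.dosage_padded()
        ss_total = _ss_from_counts(G.astype(np.int64).sum(axis=0))
        assert res.ss_among + res.ss_among_individuals + res.ss_within == pytest.approx(
            ss_total, abs=1e-9
        )
        assert res.pct_among + res.pct_among_individuals + res.pct_within == pytest.approx(
            100.0, abs=0.01
        )
        assert 0.0 <= res.f_st <= 1.0
        assert res.df_among == 3  # A, B, C + admixture

    def test_maximal_differentiation(self):
        calls = [[(100, 100)] * 5] * 6 + [[(108, 108)] * 5] * 6
        panel = make_panel(calls)
        assign = ps.SubpopAssignment({f"L{i + 1}": ("A" if i < 6 else "B") for i in range(12)})
        res = ps.amova(panel, assign, n_perm=19, seed=0)
        assert res.pct_among > 95.0

    def test_single_group_gives_zero_fst(self):
        calls = [[(100, 104)], [(100, 100)], [(104, 104)], [(100, 104)]]
        panel = make_panel(calls)
        assign = ps.SubpopAssignment({f"L{i + 1}": "A" for i in range(4)})
        res = ps.amova(panel, assign, n_perm=9, seed=0)
        assert res.var_among == 0.0 and res.f_st == 0.0

    def test_permutation_p_uniform_under_null(self):
        # panels with random labels: p-values should look uniform
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(120):
            calls = rng.choice([100, 104, 108], size=(16, 12, 2)).astype(np.int32)
            panel = make_panel(calls)
            labels = {f"L{i + 1}": ("A" if x else "B") for i, x in enumerate(rng.integers(0, 2, 16))}
            if min(list(labels.values()).count(g) for g in "AB") < 2:
                continue
            res = ps.amova(panel, ps.SubpopAssignment(labels), n_perm=49, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        stat = stats.kstest(pvals, "uniform").pvalue
        assert stat > 0.01
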