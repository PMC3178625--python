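"""Expression normalization, clustering, DE reanalysis, enrichment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import reflectchip as rc
from reflectchip.expression import (RatioMatrix, UncenteredCentroidClustering,
                                    cluster_genes, differential_expression,
                                    direction_counts, filter_low_intensity,
                                    fisher_enrichment, normalize_expression,
                                    read_gmt, select_variable_genes,
                                    uncentered_correlation, write_gmt)


def _ratio_matrix(ratios, intensities=None):
    r = pd.DataFrame(ratios)
    r.index = [f"g{i}" for i in range(len(r))]
    i = pd.DataFrame(intensities if intensities is not None
                     else np.full_like(r.to_numpy(float), 10.0),
                     index=r.index, columns=r.columns)
    return RatioMatrix(r, i)


class TestNormalizeAndFilter:
    def test_identical_channels_give_zero_ratios(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(10, 1e4, 300)
        tab = pd.DataFrame({"gene_id": [f"g{i}" for i in range(300)],
                            "ch_cy3": v, "ch_cy5": v})
        rm = normalize_expression([tab])
        assert np.allclose(rm.ratios.to_numpy(), 0.0, atol=1e-9)

    def test_injected_dye_bias_removed(self, default_expr_sim):
        rm = normalize_expression(default_expr_sim.tables)
        truth = default_expr_sim.truth.expression.set_index("gene_id")
        nulls = truth.index[truth["cluster"] == 0]
        # null ratios recentred near zero in every intensity decile
        col = rm.ratios.columns[0]
        sub = rm.ratios.loc[nulls, col]
        deciles = pd.qcut(rm.intensities.loc[nulls, col], 10)
        assert np.all(np.abs(sub.groupby(deciles, observed=True).mean()) < 0.06)

    def test_zero_threshold_is_identity(self):
        rm = _ratio_matrix(np.random.default_rng(1).normal(size=(20, 4)))
        out = filter_low_intensity(rm, min_intensity=0.0)
        pd.testing.assert_frame_equal(out.ratios, rm.ratios)

    def test_threshold_above_everything_empties_the_matrix(self):
        rm = _ratio_matrix(np.random.default_rng(2).normal(size=(20, 4)))
        out = filter_low_intensity(rm, min_intensity=100.0)
        assert len(out.ratios) == 0

    def test_surviving_count_matches_brute_force(self, default_expr_sim):
        rm = normalize_expression(default_expr_sim.tables)
        thr = 7.5
        out = filter_low_intensity(rm, thr)
        brute = (~(rm.intensities < thr)).any(axis=1).sum()
        assert len(out.ratios) == brute
        masked = out.ratios.isna() & ~rm.ratios.loc[out.genes].isna()
        assert masked.to_numpy().sum() == \
            (rm.intensities.loc[out.genes] < thr).to_numpy().sum()


class TestUncenteredCorrelation:
    def test_reference_values(self):
        x = np.array([1.0, 2.0, -1.0])
        assert uncentered_correlation(x, x) == pytest.approx(1.0)
        assert uncentered_correlation(x, -x) == pytest.approx(-1.0)
        assert uncentered_correlation([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_zero_vector_is_an_error(self):
        with pytest.raises(ValueError):
            uncentered_correlation([0.0, 0.0], [1.0, 2.0])

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert uncentered_correlation(3.7 * x, y) == \
            pytest.approx(uncentered_correlation(x, y))


class TestClustering:
    def test_noise_free_two_pattern_partition_is_perfect(self):
        sim = rc.simulate_expression(rc.ExprSimConfig(
            n_clusters=2, genes_per_cluster=10, n_null_genes=1,
            noise_sd=0.0, seed=10))
        truth = sim.truth.expression.set_index("gene_id")
        ratios = pd.DataFrame(
            {f"r{k}": np.log2(t.set_index("gene_id")["ch_cy5"]
                              / t.set_index("gene_id")["ch_cy3"])
             for k, t in enumerate(sim.tables)})
        patterned = truth.index[truth["cluster"] > 0]
        cl = cluster_genes(ratios.loc[patterned], n_clusters=2)
        assert adjusted_rand_score(truth.loc[patterned, "cluster"],
                                   cl.assignments.loc[patterned]) == 1.0

    def test_default_simulation_recovery(self, default_expr_sim):
        rm = filter_low_intensity(normalize_expression(default_expr_sim.tables))
        variable = select_variable_genes(rm)
        cl = cluster_genes(rm.ratios.loc[variable].fillna(0.0), n_clusters=7)
        truth = default_expr_sim.truth.expression.set_index("gene_id")
        ari = adjusted_rand_score(truth.loc[cl.assignments.index, "cluster"],
                                  cl.assignments)
        assert ari >= 0.9

    def test_three_gene_merge_order_by_hand(self):
        # g0 ~ g1 (corr ~ 1), g2 distant: first merge must join g0, g1
        X = pd.DataFrame([[1.0, 1.0, 1.0, 1.0],
                          [1.1, 0.9, 1.0, 1.0],
                          [1.0, -1.0, 1.0, -1.0]],
                         index=["g0", "g1", "g2"])
        model = UncenteredCentroidClustering(n_clusters=1).fit(X)
        first = model.linkage_[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        d01 = 1 - uncentered_correlation(X.loc["g0"], X.loc["g1"])
        assert first[2] == pytest.approx(d01)
        # second merge joins the centroid of {g0,g1} with g2
        centroid = X.loc[["g0", "g1"]].mean()
        d = 1 - uncentered_correlation(centroid, X.loc["g2"])
        assert model.linkage_[1][2] == pytest.approx(d)

    def test_gene_order_invariance(self, default_expr_sim):
        rm = filter_low_intensity(normalize_expression(default_expr_sim.tables))
        variable = select_variable_genes(rm)
        X = rm.ratios.loc[variable].fillna(0.0)
        a = cluster_genes(X, 7).assignments
        shuffled = X.sample(frac=1.0, random_state=5)
        b = cluster_genes(shuffled, 7).assignments
        assert adjusted_rand_score(a, b.loc[a.index]) == 1.0

    def test_positive_gene_scaling_leaves_leaf_distances_unchanged(self):
        # uncentered correlation is scale-free, so every leaf-leaf distance
        # and hence the first merge are unchanged under a positive rescale.
        # The FULL centroid-linkage dendrogram is not invariant: after a
        # merge the centroid is the mean of raw profiles, which a rescaled
        # gene dominates (documented limitation of centroid linkage).
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(20, 6)),
                         index=[f"g{i:02d}" for i in range(20)])
        X2 = X.copy()
        X2.iloc[7] *= 5.0       # positive rescale of one profile
        for i in range(20):
            for j in range(i + 1, 20):
                assert uncentered_correlation(X2.iloc[i], X2.iloc[j]) == \
                    pytest.approx(uncentered_correlation(X.iloc[i], X.iloc[j]))
        a = UncenteredCentroidClustering(n_clusters=4).fit(X)
        b = UncenteredCentroidClustering(n_clusters=4).fit(X2)
        assert (a.linkage_[0][:2] == b.linkage_[0][:2]).all()
        assert a.linkage_[0][2] == pytest.approx(b.linkage_[0][2])

    def test_all_zero_profile_is_an_error(self):
        X = pd.DataFrame([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="zero"):
            UncenteredCentroidClustering(n_clusters=2).fit(X)


class TestDirectionCounts:
    def test_all_positive_matrix_counts_all_up(self):
        rm = _ratio_matrix(np.abs(np.random.default_rng(7).normal(size=(15, 4))) + 0.1)
        out = direction_counts(rm)
        assert out.loc["all", "n_up"] == 15
        assert out.loc["all", "n_down"] == 0

    def test_counts_equal_brute_force_sign_counting(self, default_expr_sim):
        rm = normalize_expression(default_expr_sim.tables)
        assignments = pd.Series(1, index=rm.genes)
        out = direction_counts(rm, assignments)
        mean = rm.ratios.mean(axis=1)
        assert out.loc["overall", "n_up"] == int((mean > 0).sum())
        assert out.loc["overall", "n_down"] == int((mean < 0).sum())
        total = out.loc["overall", ["n_up", "n_down", "n_zero"]].sum()
        assert total == len(rm.genes)


class TestDifferentialExpression:
    def test_identical_groups_yield_no_significant_genes(self):
        rng = np.random.default_rng(8)
        base = rng.normal(8, 1, (200, 4))
        X = pd.DataFrame(np.hstack([base, base]),
                         columns=[f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)])
        res = differential_expression(X, ["A"] * 4 + ["B"] * 4)
        assert not res["significant"].any()

    def test_bh_step_up_by_hand(self):
        # raw (0.01, 0.02, 0.03, 0.04), m=4 -> all adjusted to 0.04
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(adj, 0.04)
        # and the estimator reproduces it through its own path
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(4, 8)))
        de = rc.DifferentialExpression().fit(X, ["A"] * 4 + ["B"] * 4)
        _, expect, _, _ = multipletests(de.results_["p"], method="fdr_bh")
        assert np.allclose(de.results_["p_adj"], expect)

    def test_signed_fold_change_convention(self):
        X = pd.DataFrame({"A1": [3.0, 1.0], "A2": [3.0, 1.0],
                          "B1": [1.0, 3.0], "B2": [1.0, 3.0]})
        res = differential_expression(X, ["A", "A", "B", "B"])
        # gene0: linear ratio 2^3/2^1 = 4 -> +4; gene1: 1/4 -> -4
        assert res["fold_change"].iloc[0] == pytest.approx(4.0)
        assert res["fold_change"].iloc[1] == pytest.approx(-4.0)

    def test_empirical_fdr_calibration_over_seeded_runs(self):
        fdrs = []
        for k in range(10):
            mat, labels, truth = rc.simulate_two_group(seed=500 + k)
            res = differential_expression(mat, labels)
            de = truth.set_index("gene_id")["de"]
            called = res["significant"]
            fp = int((called & ~de).sum())
            fdrs.append(fp / max(int(called.sum()), 1))
        se = np.std(fdrs, ddof=1) / np.sqrt(len(fdrs))
        assert np.mean(fdrs) <= 0.05 + 3 * se


class TestFisherEnrichment:
    def test_category_equals_background_has_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        rows = fisher_enrichment(bg[:5], bg, {"all": set(bg)}, min_genes=1)
        assert rows["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_enumeration_toy(self):
        # N=4, K=2, n=2, k=2: p = C(2,2)C(2,0)/C(4,2) = 1/6
        bg = ["a", "b", "c", "d"]
        rows = fisher_enrichment(["a", "b"], bg, {"cat": {"a", "b"}},
                                 min_genes=1)
        assert rows["p"].iloc[0] == pytest.approx(1 / 6)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(10)
        bg = [f"g{i}" for i in range(40)]
        cat = set(rng.choice(bg, 12, replace=False))
        lst = list(rng.choice(bg, 10, replace=False))
        k_obs = len(cat & set(lst))
        rows = fisher_enrichment(lst, bg, {"cat": cat}, min_genes=0)
        perm = np.array([
            len(cat & set(rng.choice(bg, 10, replace=False)))
            for _ in range(20000)])
        mc = (perm >= k_obs).mean()
        assert rows["p"].iloc[0] == pytest.approx(mc, abs=4 * np.sqrt(mc / 20000) + 1e-3)

    def test_small_hit_categories_excluded_and_gmt_round_trip(self, tmp_path):
        bg = [f"g{i}" for i in range(30)]
        sets = {"big": set(bg[:10]), "small": {"g0"}}
        write_gmt(sets, tmp_path / "sets.gmt")
        back = read_gmt(tmp_path / "sets.gmt")
        assert {k: v for k, v in back.items()} == \
            {k: {g.upper() for g in v} for k, v in sets.items()}
        rows = fisher_enrichment(bg[:8], bg, back, min_genes=3)
        assert list(rows["category"]) == ["BIG"] if False else \
            list(rows["category"]) == ["big"]

    def test_list_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["x"], ["a", "b"], {"c": {"a"}})
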