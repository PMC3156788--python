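import numpy as np
import pandas as pd
import pytest

from kinomet.discovery import (
    MetageneCoverageError,
    basal_upregulated_genes,
    build_metagene,
    hierarchical_cluster,
    qt_cluster,
    resampling_null,
    screen_metagenes_cox,
)
from kinomet.subtyping import SUBTYPE_LABELS

from _oracles import exhaustive_qt, grid_search_cox_beta
from conftest import make_clinical, make_matrix


def subtype_labels(n_per: int, samples) -> pd.Series:
    return pd.Series(np.repeat(SUBTYPE_LABELS, n_per), index=samples)


class TestBasalUpregulated:
    def test_null_yield_near_zero_after_fdr(self):
        # exchangeable genes across subtypes -> BH keeps false positives ~0
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (1000, 50))
        m = make_matrix(X)
        labels = subtype_labels(10, m.sample_ids)
        de = basal_upregulated_genes(m, labels)
        assert len(de.selected) <= 5

    def test_single_comparison_shift_detected(self):
        # gene shifted +3 sd in basal vs luminal A only, 20 per group
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 100))
        labels = subtype_labels(20, [f"s{j + 1}" for j in range(100)])
        X[7, (labels == "basal").to_numpy()] += 3.0
        X[7, (labels != "basal").to_numpy() & (labels != "luminalA").to_numpy()] += 3.0
        # now gene 7 is high everywhere except luminal A: only that
        # comparison can fire, which is enough for selection
        m = make_matrix(X)
        de = basal_upregulated_genes(m, labels)
        assert "g8" in de.selected
        row = de.table[(de.table.gene == "g8")
                       & (de.table.comparison == "luminalA")]
        assert bool(row.selected_in_comparison.iloc[0])

    def test_downregulated_gene_never_selected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 100))
        labels = subtype_labels(20, [f"s{j + 1}" for j in range(100)])
        X[3, (labels == "basal").to_numpy()] -= 5.0  # strongly DOWN in basal
        m = make_matrix(X)
        de = basal_upregulated_genes(m, labels)
        assert "g4" not in de.selected
        down = basal_upregulated_genes(m, labels, direction="down")
        assert "g4" in down.selected

    def test_undersized_subtype_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(0, 1, (10, 41)))
        labels = pd.Series(["basal"] * 20 + ["luminalA"] * 20 + ["luminalB"],
                           index=m.sample_ids)
        with pytest.warns(UserWarning, match="skipped"):
            de = basal_upregulated_genes(m, labels)
        assert de.comparisons == ["luminalA"]
        assert de.skipped == ["luminalB"]

    def test_no_valid_comparison_rejected(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(0, 1, (5, 21)))
        labels = pd.Series(["basal"] * 20 + ["luminalA"], index=m.sample_ids)
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError, match="no comparison"):
                basal_upregulated_genes(m, labels)

    def test_selected_rows_satisfy_typed_invariant(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (200, 75))
        labels = subtype_labels(15, [f"s{j + 1}" for j in range(75)])
        X[:30, (labels == "basal").to_numpy()] += 1.5
        m = make_matrix(X)
        de = basal_upregulated_genes(m, labels)
        tab = de.table
        for g in de.selected:
            rows = tab[(tab.gene == g) & tab.selected_in_comparison]
            assert len(rows) >= 1
            assert (rows.t > 0).all()
            assert (rows.p < de.alpha).all() and (rows.q < de.fdr).all()


class TestHierarchical:
    def test_identical_genes_merge_at_zero(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 10)
        X = np.vstack([base, base, rng.normal(0, 1, 10)])
        layout = hierarchical_cluster(make_matrix(X))
        first = layout.gene_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-10)

    def test_correlated_pair_merges_first(self):
        rng = np.random.default_rng(6)
        f = rng.normal(0, 1, 30)
        g1 = f + rng.normal(0, 0.3, 30)
        g2 = f + rng.normal(0, 0.3, 30)
        g3 = rng.normal(0, 1, 30)
        layout = hierarchical_cluster(make_matrix(np.vstack([g1, g2, g3])))
        first = layout.gene_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_column_permutation_keeps_topology(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (8, 20))
        m1 = make_matrix(X)
        perm = rng.permutation(20)
        m2 = make_matrix(X[:, perm])
        l1 = hierarchical_cluster(m1).gene_linkage
        l2 = hierarchical_cluster(m2).gene_linkage
        np.testing.assert_allclose(l1, l2, atol=1e-10)

    def test_constant_genes_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        X = np.vstack([np.full(10, 2.0), rng.normal(0, 1, (3, 10))])
        with pytest.warns(UserWarning, match="constant"):
            layout = hierarchical_cluster(make_matrix(X))
        assert layout.dropped_genes == ["g1"]


class TestQTCluster:
    def test_near_identical_genes_form_one_cluster(self):
        rng = np.random.default_rng(9)
        f = rng.normal(0, 1, 40)
        X = f + rng.normal(0, 0.05, (20, 40))
        clusters = qt_cluster(make_matrix(X, is_centered=True), min_size=15,
                              min_corr=0.6)
        assert len(clusters) == 1
        assert clusters[0].size == 20

    def test_too_few_genes_empty_result(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(0, 1, (10, 30)), is_centered=True)
        assert qt_cluster(m, min_size=15, min_corr=0.6) == []

    def test_two_planted_blocks_match_bruteforce(self):
        # 12 genes in two tight blocks; exhaustive subset search is feasible
        rng = np.random.default_rng(11)
        n = 60
        f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        X = np.vstack([
            f1 + rng.normal(0, 0.33, (6, n)),   # r ~ 0.9
            f2 + rng.normal(0, 0.33, (6, n)),
        ])
        m = make_matrix(X, is_centered=True)
        clusters = qt_cluster(m, min_size=4, min_corr=0.6)
        got = [sorted(int(g[1:]) - 1 for g in c.genes) for c in clusters]
        assert got == exhaustive_qt(np.corrcoef(X), 4, 0.6)
        assert sorted(map(tuple, got)) == [(0, 1, 2, 3, 4, 5),
                                           (6, 7, 8, 9, 10, 11)]

    def test_emitted_clusters_disjoint_and_within_constraints(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n_genes, n = 30, 50
            X = rng.normal(0, 1, (n_genes, n))
            for start in (0, 8, 16):
                f = rng.normal(0, 1, n)
                X[start:start + 8] = f + rng.normal(0, 0.4, (8, n))
            m = make_matrix(X, is_centered=True)
            clusters = qt_cluster(m, min_size=4, min_corr=0.5)
            seen: set[str] = set()
            C = np.corrcoef(X)
            names = m.gene_ids
            for c in clusters:
                assert c.size >= 4
                assert not (set(c.genes) & seen)
                seen |= set(c.genes)
                idx = [names.index(g) for g in c.genes]
                sub = C[np.ix_(idx, idx)]
                assert sub[np.triu_indices(len(idx), 1)].min() >= 0.5
                assert c.quality == pytest.approx(
                    sub[np.triu_indices(len(idx), 1)].min())

    def test_min_size_below_two_rejected(self):
        m = make_matrix(np.eye(3), is_centered=True)
        with pytest.raises(ValueError, match="min_size"):
            qt_cluster(m, min_size=1, min_corr=0.5)


class TestMetagene:
    def test_singleton_equals_gene_row(self, expr3x2):
        mg = build_metagene(expr3x2, ["g2"])
        np.testing.assert_allclose(mg.score, expr3x2.values.loc["g2"])

    def test_mean_of_members(self, expr3x2):
        mg = build_metagene(expr3x2, ["g1", "g3"])
        np.testing.assert_allclose(mg.score, [(1 + 5) / 2, (2 + 6) / 2])

    def test_partial_coverage_uses_present_genes(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(25)]
        m = make_matrix(rng.normal(0, 1, (25, 4)), genes=genes)
        requested = genes + ["gA", "gB", "gC"]     # 25 of 28 present
        mg = build_metagene(m, requested, coverage_floor=25)
        assert mg.coverage == (25, 28)
        np.testing.assert_allclose(mg.score, m.values.mean(axis=0))

    def test_coverage_floor_error_names_missing(self, expr3x2):
        with pytest.raises(MetageneCoverageError, match="gX"):
            build_metagene(expr3x2, ["g1", "gX", "gY"], coverage_floor=2)

    def test_order_invariance_and_linearity(self, expr3x2):
        mg1 = build_metagene(expr3x2, ["g1", "g2"]).score
        mg2 = build_metagene(expr3x2, ["g2", "g1"]).score
        np.testing.assert_allclose(mg1, mg2)
        scaled = make_matrix(2.0 * expr3x2.values.to_numpy() + 5.0,
                             genes=expr3x2.gene_ids)
        mg3 = build_metagene(scaled, ["g1", "g2"]).score
        np.testing.assert_allclose(mg3, 2.0 * mg1 + 5.0)


class TestCoxScreen:
    def test_null_metagene_not_flagged_large_n(self):
        rng = np.random.default_rng(14)
        n = 2000
        m = make_matrix(rng.normal(0, 1, (5, n)))
        clin = make_clinical(rng.exponential(50, n),
                             (rng.random(n) < 0.7).astype(int),
                             index=m.sample_ids)
        mg = build_metagene(m, m.gene_ids)
        table = screen_metagenes_cox({"mg": mg}, clin)
        assert 0.9 < table.loc["mg", "hr"] < 1.1

    def test_six_sample_fixture_matches_gridsearch(self):
        t = np.array([3.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([0.2, -0.4, 1.0, 0.5, -0.9, 0.3])
        m = make_matrix(x[None, :], genes=["g1"])
        clin = make_clinical(t, e, index=m.sample_ids)
        mg = build_metagene(m, ["g1"])
        table = screen_metagenes_cox({"mg": mg}, clin)
        oracle = grid_search_cox_beta(x, t, e)
        assert np.log(table.loc["mg", "hr"]) == pytest.approx(oracle,
                                                              abs=1e-3)


class TestResamplingNull:
    def _null_data(self, rng, n=80, n_genes=60):
        m = make_matrix(rng.normal(0, 1, (n_genes, n)))
        clin = make_clinical(rng.exponential(40, n),
                             (rng.random(n) < 0.7).astype(int),
                             index=m.sample_ids)
        return m, clin

    def test_observed_one_gives_tail_near_one(self):
        rng = np.random.default_rng(15)
        m, clin = self._null_data(rng)
        null = resampling_null(m, clin, k=5, B=200, observed_stat=1.0,
                               seed=0)
        assert null.tail_probability == pytest.approx(1.0, abs=0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(16)
        m, clin = self._null_data(rng)
        a = resampling_null(m, clin, k=5, B=50, observed_stat=0.5, seed=3)
        b = resampling_null(m, clin, k=5, B=50, observed_stat=0.5, seed=3)
        np.testing.assert_array_equal(a.null_pvalues, b.null_pvalues)

    def test_pool_smaller_than_k_rejected(self):
        rng = np.random.default_rng(17)
        m, clin = self._null_data(rng, n_genes=10)
        with pytest.raises(ValueError, match="pool"):
            resampling_null(m, clin, k=12, B=10, observed_stat=0.5)

    def test_median_observed_gives_tail_near_half(self):
        rng = np.random.default_rng(18)
        m, clin = self._null_data(rng, n=100, n_genes=80)
        probe = resampling_null(m, clin, k=8, B=400, observed_stat=1.0,
                                seed=5)
        med = float(np.median(probe.null_pvalues))
        null = resampling_null(m, clin, k=8, B=400, observed_stat=med,
                               seed=6)
        assert null.tail_probability == pytest.approx(
            0.5, abs=3 * np.sqrt(0.25 / 400) + 0.05)

    def test_planted_signal_beats_random_sets(self):
        # cohort where 10 correlated genes drive survival: their metagene's
        # Wald p should rarely be matched by random 10-gene sets
        rng = np.random.default_rng(19)
        n = 120
        f = rng.normal(0, 1, n)
        X = np.vstack([f + rng.normal(0, 0.5, (10, n)),
                       rng.normal(0, 1, (90, n))])
        m = make_matrix(X)
        hazard = 0.02 * np.exp(np.log(0.3) * f)
        t = rng.exponential(1 / hazard)
        clin = make_clinical(np.minimum(t, 120),
                             (t <= 120).astype(int), index=m.sample_ids)
        from kinomet.survstats import UnivariateCox

        observed = UnivariateCox(clin.times, clin.events).fit(
            X[:10].mean(axis=0)).p
        null = resampling_null(m, clin, k=10, B=500, observed_stat=observed,
                               seed=7)
        assert null.tail_probability < 0.05
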