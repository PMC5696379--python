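import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mamlin import de_nb, synthetic
from mamlin.de_nb import (DispersionModel, SignatureSet, bh_adjust,
                          derive_signatures, estimate_dispersions,
                          hypergeom_enrichment, lrt_de, top_lineage_panels,
                          treat_test)
from mamlin.iofmt import CountMatrix, GeneSetCollection


def nb_counts(rng, mu, phi, size):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def make_cm(counts):
    counts = np.asarray(counts)
    return CountMatrix(counts, [f"g{i}" for i in range(counts.shape[0])],
                       [f"s{j}" for j in range(counts.shape[1])])


# ---------------------------------------------------------------------------
# reference values computed once with edgeR (glmFit/glmLRT, fixed dispersion
# 0.1, explicit library sizes) on this frozen fixture
# ---------------------------------------------------------------------------

EDGER_COUNTS = np.array([
    [57, 91, 95, 71, 87, 135], [35, 40, 36, 46, 68, 26],
    [65, 58, 95, 34, 98, 112], [54, 61, 79, 155, 282, 179],
    [12, 16, 15, 0, 3, 2], [51, 231, 40, 59, 52, 148],
    [54, 61, 64, 380, 693, 632], [117, 136, 108, 85, 82, 40]])
EDGER_LIBS = np.array([800_000, 1_200_000, 1_000_000, 900_000, 1_100_000, 1_000_000])
EDGER_LOGFC = [0.274493760322, 0.304561472694, 0.097259406414, 1.626252601393,
               -3.122002703419, -0.195297984985, 3.211494914571, -0.814415030992]
EDGER_LR = [0.4866879050854, 0.5361670856787, 0.0602146983579, 16.6479189342656,
            21.0006615230688, 0.2484194181936, 59.2538146868748, 4.2462449802088]
EDGER_P = [4.85408485908e-01, 4.64025565770e-01, 8.06156922290e-01,
           4.49996516926e-05, 4.59124816844e-06, 6.18190219040e-01,
           1.38591414254e-14, 3.93372176688e-02]


def test_lrt_matches_edger_reference():
    """Two-group NB GLM LRT agrees with an independent reference fit."""
    # a filler gene per column forces the exact reference library sizes
    pad = EDGER_LIBS - EDGER_COUNTS.sum(axis=0)
    cm = make_cm(np.vstack([EDGER_COUNTS, pad]))
    res = lrt_de(cm, ["A"] * 3 + ["B"] * 3, DispersionModel.fixed(0.1, 9))
    np.testing.assert_allclose(res["log2fc"][:8], EDGER_LOGFC, atol=1e-9)
    np.testing.assert_allclose(res["lr_stat"][:8], EDGER_LR, rtol=1e-6)
    np.testing.assert_allclose(res["p"][:8], EDGER_P, rtol=1e-6)


class TestDispersionEstimation:
    def test_recovers_known_phi(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(20, 200, 200)
        counts = nb_counts(rng, mu[:, None], 0.1, (200, 20))
        dm = estimate_dispersions(make_cm(counts), ["A"] * 10 + ["B"] * 10)
        assert 0.05 <= dm.common_phi <= 0.2

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(50, 500, 300)
        counts = rng.poisson(mu[:, None], (300, 20))
        dm = estimate_dispersions(make_cm(counts), ["A"] * 10 + ["B"] * 10)
        assert dm.common_phi <= 0.01

    def test_infinite_shrinkage_gives_common(self):
        rng = np.random.default_rng(2)
        counts = nb_counts(rng, 50, 0.2, (100, 10))
        dm = estimate_dispersions(make_cm(counts), ["A"] * 5 + ["B"] * 5,
                                  shrink_weight=1e9)
        np.testing.assert_array_equal(dm.tagwise_phi, dm.common_phi)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            estimate_dispersions(make_cm(np.zeros((5, 4), dtype=int)),
                                 ["A", "A", "B", "B"])


class TestLrt:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(3)
        mu = np.full((1, 40), 50.0)
        mu[0, 20:] *= 16  # log2FC = 4
        counts = nb_counts(rng, mu, 0.1, (1, 40))
        # constant filler gene keeps library sizes informative
        filler = np.full((1, 40), 10_000)
        res = lrt_de(make_cm(np.vstack([counts, filler])), ["A"] * 20 + ["B"] * 20,
                     DispersionModel.fixed(0.1, 2))
        assert res["p"][0] < 1e-6
        assert 3.0 < res["log2fc"][0] < 5.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            lrt_de(make_cm([[1, 2]]), ["A", "A"], DispersionModel.fixed(0.1, 1))

    def test_permutation_invariance_within_groups(self):
        rng = np.random.default_rng(4)
        counts = nb_counts(rng, 60, 0.1, (20, 10))
        cm = make_cm(counts)
        groups = np.array(["A"] * 5 + ["B"] * 5)
        r1 = lrt_de(cm, groups, DispersionModel.fixed(0.1, 20))
        perm = [3, 1, 4, 0, 2, 8, 6, 5, 9, 7]
        cm2 = make_cm(counts[:, perm])
        r2 = lrt_de(cm2, groups[perm], DispersionModel.fixed(0.1, 20))
        np.testing.assert_allclose(r1["lr_stat"], r2["lr_stat"], atol=1e-8)

    def test_three_group_df(self):
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, 60, 0.1, (300, 12))
        res = lrt_de(make_cm(counts), ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
                     DispersionModel.fixed(0.1, 300))
        # null data: lr_stat should look chi-square with 2 df
        assert abs(res["lr_stat"].mean() - 2.0) < 0.35


class TestTreat:
    def test_tau_one_equals_lrt(self):
        rng = np.random.default_rng(6)
        counts = nb_counts(rng, 80, 0.1, (50, 12))
        cm = make_cm(counts)
        groups = ["A"] * 6 + ["B"] * 6
        disp = DispersionModel.fixed(0.1, 50)
        p_lrt = lrt_de(cm, groups, disp)["p"]
        p_tr = treat_test(cm, groups, disp, tau=1.0)["p"]
        np.testing.assert_allclose(p_tr, p_lrt, atol=1e-8)

    def test_never_more_liberal_than_lrt(self):
        rng = np.random.default_rng(7)
        mu = np.tile(np.concatenate([np.full(6, 50.0), np.full(6, 130.0)]), (80, 1))
        counts = nb_counts(rng, mu, 0.1, (80, 12))
        cm = make_cm(counts)
        groups = ["A"] * 6 + ["B"] * 6
        disp = DispersionModel.fixed(0.1, 80)
        p_lrt = lrt_de(cm, groups, disp)["p"].to_numpy()
        p_tr = treat_test(cm, groups, disp, tau=2.0)["p"].to_numpy()
        assert np.all(p_tr >= p_lrt - 1e-12)

    def test_power_at_large_effect(self):
        rng = np.random.default_rng(8)
        n_sims = 500
        mu = np.tile(np.concatenate([np.full(10, 40.0), np.full(10, 320.0)]), (n_sims, 1))
        counts = nb_counts(rng, mu, 0.05, (n_sims, 20))
        # equal-count background genes keep library sizes comparable between
        # groups (the simulated effect genes all move the same way)
        background = nb_counts(rng, 300.0, 0.05, (4 * n_sims, 20))
        cm = make_cm(np.vstack([counts, background]))
        res = treat_test(cm, ["A"] * 10 + ["B"] * 10,
                         DispersionModel.fixed(0.05, 5 * n_sims), tau=3.0)
        assert (res["p"][:n_sims] < 0.05).mean() >= 0.8

    def test_tau_below_one_rejected(self):
        with pytest.raises(ValueError):
            treat_test(make_cm([[1, 2]]), ["A", "B"],
                       DispersionModel.fixed(0.1, 1), tau=0.5)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_nan_propagates(self):
        with pytest.warns(UserWarning):
            out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    @staticmethod
    def brute_force_bh(p):
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running_min = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, p[i] * n / rank)
            adj[i] = running_min
        return adj

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 1000))
    def test_matches_brute_force(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        np.testing.assert_allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_fdr_never_below_p(self):
        p = np.random.default_rng(9).uniform(size=200)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestSignatures:
    def test_planted_recovery_small(self):
        d = synthetic.bulk_three_type_design(seed=11, n_reps=4, n_specific=30)
        d.n_genes = 500
        bulk, truth = synthetic.simulate_bulk(d)
        tau_map = {("basal", "LP"): 2.0, ("basal", "ML"): 2.0, ("LP", "ML"): 1.3}
        sigs = derive_signatures(bulk, tau_map=tau_map)
        for t in ("basal", "LP", "ML"):
            got = set(sigs.genes(t))
            planted = set(truth.specific_genes[t])
            assert len(got & planted) / len(planted) >= 0.9
            if got:
                assert len(got - planted) / len(got) <= 0.1

    def test_up_in_one_contrast_only_excluded(self):
        # gene up in A vs B but flat vs C must not be A-specific
        rng = np.random.default_rng(12)
        mu = np.full((40, 9), 100.0)
        mu[0, 0:3] = 800.0   # A high
        mu[0, 6:9] = 800.0   # C equally high -> not A-specific
        counts = nb_counts(rng, mu, 0.02, (40, 9))
        cm = make_cm(counts)
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        tau_map = {("A", "B"): 1.5, ("A", "C"): 1.5, ("B", "C"): 1.5}
        sigs = derive_signatures(cm, groups, tau_map=tau_map,
                                 disp=DispersionModel.fixed(0.02, 40))
        assert "g0" not in sigs.genes("A")

    def test_no_genes_pass_is_empty_not_error(self):
        rng = np.random.default_rng(13)
        counts = nb_counts(rng, 50, 0.1, (30, 9))
        tau_map = {("A", "B"): 4.0, ("A", "C"): 4.0, ("B", "C"): 4.0}
        sigs = derive_signatures(make_cm(counts), ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                                 tau_map=tau_map, disp=DispersionModel.fixed(0.1, 30))
        assert all(len(sigs.genes(t)) == 0 for t in sigs.names())

    def test_missing_tau_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            derive_signatures(make_cm(np.ones((4, 6), dtype=int)),
                              ["A", "A", "B", "B", "C", "C"],
                              tau_map={("A", "B"): 2.0})


class TestTopPanels:
    def _bulk(self, seed=14):
        rng = np.random.default_rng(seed)
        mu = np.full((60, 10), 100.0)
        mu[:20, 5:] = 1500.0   # up in B
        mu[20:35, :5] = 1500.0  # up in A
        return make_cm(nb_counts(rng, mu, 0.02, (60, 10)))

    def test_planted_panels_subset(self):
        cm = self._bulk()
        groups = ["A"] * 5 + ["B"] * 5
        sigs = top_lineage_panels(cm, groups, tau=3.0, n_top=10,
                                  disp=DispersionModel.fixed(0.02, 60))
        assert set(sigs.genes("B")) <= {f"g{i}" for i in range(20)}
        assert set(sigs.genes("A")) <= {f"g{i}" for i in range(20, 35)}
        assert len(sigs.genes("B")) == 10

    def test_label_flip_swaps_panels(self):
        # relabeling the samples' groups swaps which panel each gene lands in
        cm = self._bulk()
        disp = DispersionModel.fixed(0.02, 60)
        g1 = ["A"] * 5 + ["B"] * 5
        g2 = ["B"] * 5 + ["A"] * 5
        s1 = top_lineage_panels(cm, g1, tau=3.0, n_top=10, disp=disp)
        s2 = top_lineage_panels(cm, g2, tau=3.0, n_top=10, disp=disp)
        assert s1.genes("A") == s2.genes("B") and s1.genes("B") == s2.genes("A")

    def test_n_top_zero(self):
        cm = self._bulk()
        sigs = top_lineage_panels(cm, ["A"] * 5 + ["B"] * 5, tau=3.0, n_top=0,
                                  disp=DispersionModel.fixed(0.02, 60))
        assert sigs.genes("A") == [] and sigs.genes("B") == []


class TestHypergeom:
    @staticmethod
    def brute_force_p(n_uni, set_genes, hits, overlap):
        """Enumerate all hit subsets of the universe of the same size."""
        from itertools import combinations
        universe = list(range(n_uni))
        k = len(hits)
        total = hit_count = 0
        for combo in combinations(universe, k):
            total += 1
            if len(set(combo) & set_genes) >= overlap:
                hit_count += 1
        return hit_count / total

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_uni = int(rng.integers(4, 13))
        universe = [f"g{i}" for i in range(n_uni)]
        k_hits = int(rng.integers(1, n_uni))
        hits = list(rng.choice(universe, size=k_hits, replace=False))
        set_size = int(rng.integers(1, n_uni + 1))
        members = list(rng.choice(universe, size=set_size, replace=False))
        res = hypergeom_enrichment(hits, universe, GeneSetCollection({"s": members}))
        overlap = int(res["overlap"][0])
        expected = self.brute_force_p(n_uni, {int(m[1:]) for m in members},
                                      [int(h[1:]) for h in hits], overlap)
        np.testing.assert_allclose(res["p"][0], expected, rtol=1e-9)

    def test_set_equals_hits_minimal_p(self):
        universe = [f"g{i}" for i in range(8)]
        hits = ["g0", "g1", "g2"]
        res = hypergeom_enrichment(hits, universe, GeneSetCollection({"s": hits}))
        np.testing.assert_allclose(res["p"][0], 1.0 / 56.0, rtol=1e-9)  # 1 / C(8,3)

    def test_empty_overlap_large_set(self):
        universe = [f"g{i}" for i in range(12)]
        res = hypergeom_enrichment(["g0"], universe,
                                   GeneSetCollection({"s": universe[1:]}))
        np.testing.assert_allclose(res["p"][0], 1.0)

    def test_disjoint_set_skipped(self):
        with pytest.warns(UserWarning, match="disjoint"):
            res = hypergeom_enrichment(["g0"], ["g0", "g1"],
                                       GeneSetCollection({"s": ["x", "y"]}))
        assert res.empty

    def test_hit_outside_universe(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["zz"], ["g0"], GeneSetCollection({"s": ["g0"]}))


def test_signature_set_gene_set_round_trip():
    sigs = SignatureSet(tables={
        "basal": pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [2.0, 1.5],
                               "fdr": [0.01, 0.02]})})
    gsc = sigs.to_gene_sets()
    assert gsc["basal"] == ["a", "b"]
    back = SignatureSet.from_gene_sets(gsc)
    assert back.genes("basal") == ["a", "b"]
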