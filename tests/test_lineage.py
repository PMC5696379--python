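import numpy as np
import pandas as pd
import pytest

from mamlin.de_nb import SignatureSet
from mamlin.lineage import (MixedLineageCall, TernaryScore, classify_cells,
                            detect_mixed_lineage, flag_marker_positive,
                            ternary_cell_scores, ternary_gene_composition)
from mamlin.normalize import ExpressionMatrix


def sigset(**sets):
    return SignatureSet(tables={
        name: pd.DataFrame({"gene_id": genes, "log2fc": 1.0, "fdr": 0.01})
        for name, genes in sets.items()})


def em(values, gene_ids, sample_ids, normalization="quantile_log2cpm"):
    return ExpressionMatrix(np.asarray(values, dtype=float), gene_ids,
                            sample_ids, normalization)


THREE_SETS = dict(basal=["b1", "b2"], LP=["l1", "l2"], ML=["m1", "m2"])
GENES = ["b1", "b2", "l1", "l2", "m1", "m2"]


class TestTernaryScores:
    def test_pure_cell_hits_vertex(self):
        vals = [[5], [7], [0], [0], [0], [0]]
        scores = ternary_cell_scores(em(vals, GENES, ["c"]), sigset(**THREE_SETS),
                                     floor=1.0)
        s = scores[0]
        np.testing.assert_allclose(s.proportions, [1.0, 0.0, 0.0])
        assert s.label == "basal" and not s.degenerate

    def test_all_below_floor_degenerate(self):
        vals = np.zeros((6, 2))
        scores = ternary_cell_scores(em(vals, GENES, ["c1", "c2"]),
                                     sigset(**THREE_SETS), floor=1.0)
        for s in scores:
            assert s.degenerate and s.label == "unclassified"
            np.testing.assert_allclose(s.proportions, [1 / 3] * 3)

    def test_hand_arithmetic(self):
        # floor 1: basal excesses (2,0)->mean 1; LP (3,1)->2; ML (0,0)->0
        vals = [[3], [1], [4], [2], [0.5], [1]]
        scores = ternary_cell_scores(em(vals, GENES, ["c"]), sigset(**THREE_SETS),
                                     floor=1.0)
        np.testing.assert_allclose(scores[0].proportions, [1 / 3, 2 / 3, 0.0])
        assert scores[0].label == "LP"

    def test_set_size_bias_removed(self):
        # a 4-gene set with the same per-gene excess scores the same as a 2-gene set
        sets = sigset(basal=["b1", "b2", "b3", "b4"], LP=["l1", "l2"], ML=["m1", "m2"])
        genes = ["b1", "b2", "b3", "b4", "l1", "l2", "m1", "m2"]
        vals = [[2]] * 4 + [[2]] * 2 + [[0]] * 2
        scores = ternary_cell_scores(em(vals, genes, ["c"]), sets, floor=1.0)
        np.testing.assert_allclose(scores[0].proportions, [0.5, 0.5, 0.0])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 8, size=(6, 20))
        scores = ternary_cell_scores(em(vals, GENES, [f"c{j}" for j in range(20)]),
                                     sigset(**THREE_SETS))
        for s in scores:
            assert abs(s.proportions.sum() - 1) < 1e-9
            assert np.all(s.proportions >= 0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 8, size=(6, 5))
        cells = [f"c{j}" for j in range(5)]
        s1 = ternary_cell_scores(em(vals, GENES, cells), sigset(**THREE_SETS), floor=2.0)
        perm = [4, 2, 0, 5, 1, 3]
        s2 = ternary_cell_scores(em(vals[perm], [GENES[i] for i in perm], cells),
                                 sigset(**THREE_SETS), floor=2.0)
        for a, b in zip(s1, s2):
            np.testing.assert_allclose(a.proportions, b.proportions)

    def test_duplicating_cells_invariance(self):
        # the median floor is unchanged by duplicating the whole matrix
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 8, size=(6, 4))
        s1 = ternary_cell_scores(em(vals, GENES, list("abcd")), sigset(**THREE_SETS))
        s2 = ternary_cell_scores(em(np.hstack([vals, vals]), GENES,
                                    list("abcdwxyz")), sigset(**THREE_SETS))
        for a, b in zip(s1, s2[:4]):
            np.testing.assert_allclose(a.proportions, b.proportions)

    def test_missing_set_errors(self):
        sets = sigset(basal=["zz1"], LP=["l1"], ML=["m1"])
        with pytest.raises(ValueError, match="basal"):
            ternary_cell_scores(em(np.ones((6, 1)), GENES, ["c"]), sets)

    def test_count_detected_mode(self):
        vals = [[5], [0], [5], [5], [0], [0]]
        scores = ternary_cell_scores(em(vals, GENES, ["c"]), sigset(**THREE_SETS),
                                     floor=1.0, mode="count_detected")
        np.testing.assert_allclose(scores[0].proportions, [1 / 3, 2 / 3, 0.0])


class TestClassifyCells:
    def _score(self, props, names=("basal", "LP", "ML")):
        props = np.asarray(props, dtype=float)
        label = names[int(np.argmax(props))]
        return TernaryScore("c", tuple(names), props.copy(), props, label, False)

    def test_argmax(self):
        assert classify_cells([self._score([0.1, 0.8, 0.1])]) == ["LP"]

    def test_intermediate_band(self):
        got = classify_cells([self._score([0.1, 0.46, 0.44])], intermediate_band=0.05)
        assert got == ["LumInt"]

    def test_band_not_applied_when_basal_wins(self):
        got = classify_cells([self._score([0.5, 0.26, 0.24])], intermediate_band=0.05)
        assert got == ["basal"]

    def test_tie_break_fixed_order(self):
        got = classify_cells([self._score([0.4, 0.4, 0.2])])
        assert got == ["basal"]   # first class in declared order wins ties


class TestGeneComposition:
    def test_single_stage_expression(self):
        e = em([[8, 8, 0, 0, 0, 0]], ["g"], list("abcdef"), normalization="cpm")
        out = ternary_gene_composition(e, ["wk2", "wk2", "wk5", "wk5", "wk10", "wk10"])
        np.testing.assert_allclose(
            out[["prop_wk2", "prop_wk5", "prop_wk10"]].to_numpy()[0], [1, 0, 0])

    def test_equal_means(self):
        e = em([[4, 4, 4]], ["g"], list("abc"), normalization="cpm")
        out = ternary_gene_composition(e, ["x", "y", "z"])
        np.testing.assert_allclose(out.iloc[0, 1:4].astype(float), [1 / 3] * 3)

    def test_log_input_delogged(self):
        # log2 values (3, 2, 1) -> linear 8, 4, 2 -> proportions 8/14, 4/14, 2/14
        e = em([[3, 2, 1]], ["g"], list("abc"), normalization="log2cpm")
        out = ternary_gene_composition(e, ["x", "y", "z"])
        np.testing.assert_allclose(out.iloc[0, 1:4].astype(float),
                                   np.array([8, 4, 2]) / 14)

    def test_empty_stage_errors(self):
        e = em([[1, 2]], ["g"], ["a", "b"], normalization="cpm")
        with pytest.raises(ValueError):
            ternary_gene_composition(e, ["x", "y"])


class TestDetectMixed:
    def _expr(self, host_vals, foreign_vals, n_cells):
        genes = [f"b{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
        return em(np.vstack([np.full((4, n_cells), host_vals),
                             np.full((4, n_cells), foreign_vals)]),
                  genes, [f"c{j}" for j in range(n_cells)], normalization="log2rpkm")

    def _sigs(self):
        return sigset(basal=[f"b{i}" for i in range(4)],
                      luminal=[f"l{i}" for i in range(4)])

    def test_no_foreign_not_mixed(self):
        e = self._expr(6.0, 0.0, 3)
        calls = detect_mixed_lineage(e, "basal", self._sigs(), min_foreign_genes=1,
                                     detect_level=np.log2(5.0), floor=1.0)
        assert all(not c.is_mixed for c in calls)
        assert all(c.n_foreign_detected == 0 for c in calls)

    def test_min_foreign_one_semantics(self):
        genes = [f"b{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
        vals = np.full((8, 1), 0.0)
        vals[:4] = 6.0
        vals[4] = 3.0     # one foreign gene above log2(5) ~ 2.32
        e = em(vals, genes, ["c"], normalization="log2rpkm")
        calls = detect_mixed_lineage(e, "basal", self._sigs(), min_foreign_genes=1,
                                     detect_level=np.log2(5.0), floor=1.0)
        assert calls[0].is_mixed and calls[0].foreign_genes == ["l0"]

    def test_host_dominance_blocks_luminal_like_cells(self):
        genes = [f"b{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
        vals = np.full((8, 1), 8.0)     # all luminal genes high, host equal
        e = em(vals, genes, ["c"], normalization="log2rpkm")
        calls = detect_mixed_lineage(e, "basal", self._sigs(), min_foreign_genes=1,
                                     detect_level=np.log2(5.0),
                                     host_dominance=1.0, floor=1.0)
        assert not calls[0].is_mixed   # host score not strictly greater

    def test_identical_sets_rejected(self):
        sets = sigset(basal=["g0"], luminal=["g0"])
        e = em(np.ones((1, 1)), ["g0"], ["c"], normalization="log2rpkm")
        with pytest.raises(ValueError, match="identical"):
            detect_mixed_lineage(e, "basal", sets)


class TestMarkerFlag:
    def _em(self, rpkm_values):
        return em(np.log2(np.asarray(rpkm_values, dtype=float))[None, :], ["Cd55"],
                  [f"c{j}" for j in range(len(rpkm_values))],
                  normalization="log2rpkm")

    def test_threshold_strictly_above(self):
        flags = flag_marker_positive(self._em([41.0, 40.0, 39.0]), "Cd55", 40.0)
        assert flags.tolist() == [True, False, False]

    def test_threshold_zero_flags_nonzero(self):
        flags = flag_marker_positive(self._em([0.5, 2.0]), "Cd55", 0.0)
        assert flags.tolist() == [True, True]

    def test_absent_gene(self):
        with pytest.raises(ValueError):
            flag_marker_positive(self._em([1.0]), "Krt5", 40.0)
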