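import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from sedimeta.io import FeatureTable, Reaction
from sedimeta.prmt import (
    ETM,
    NormalizedAbundance,
    PRMTScores,
    annotate_metabolite_directions,
    build_etm,
    compare_prmt_groups,
    normalize_ec_abundance,
    prmt_scores,
)


def _rxn(rid, ec, subs, prods, reversible=False):
    return Reaction(rid, (ec,), tuple(subs), tuple(prods), reversible)


def _ec_table(arr, ecs=None, samples=None):
    arr = np.asarray(arr)
    ecs = ecs or [f"1.1.1.{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(arr, index=ecs, columns=samples), units_tag="counts")


class TestBuildEtm:
    def test_sign_convention_single_reaction(self):
        etm = build_etm([_rxn("R1", "1.7.5.1", [("NO3-", 1)], [("NO2-", 1)])])
        assert etm.W.loc["NO3-", "1.7.5.1"] == 1.0
        assert etm.W.loc["NO2-", "1.7.5.1"] == -1.0

    def test_average_over_ec_reactions(self):
        r1 = _rxn("R1", "1.1.1.1", [("M", 1), ("X", 1)], [("Y", 1)])
        r2 = _rxn("R2", "1.1.1.1", [("M", 1)], [("Z", 1)])
        r3 = _rxn("R3", "1.1.1.1", [("X", 1)], [("Z", 1)])
        etm = build_etm([r1, r2])
        assert etm.W.loc["M", "1.1.1.1"] == 1.0  # consumed in both of two reactions
        etm3 = build_etm([r1, r2, r3])
        assert etm3.W.loc["M", "1.1.1.1"] == pytest.approx(2 / 3)
        # consumed in exactly one of two reactions -> +0.5
        assert etm.W.loc["X", "1.1.1.1"] == pytest.approx(0.5)

    def test_sum_aggregation_flag(self):
        r1 = _rxn("R1", "1.1.1.1", [("M", 1)], [("Y", 1)])
        r2 = _rxn("R2", "1.1.1.1", [("M", 2)], [("Z", 1)])
        etm = build_etm([r1, r2], ec_aggregation="sum")
        assert etm.W.loc["M", "1.1.1.1"] == 3.0

    def test_currency_metabolites_excluded(self):
        etm = build_etm([_rxn("R1", "1.1.1.1", [("A", 1), ("H2O", 2)], [("B", 1)])])
        assert "H2O" not in etm.W.index
        assert set(etm.W.index) == {"A", "B"}

    def test_skip_reversible(self):
        fwd = _rxn("R1", "1.1.1.1", [("A", 1)], [("B", 1)])
        rev = _rxn("R2", "2.2.2.2", [("C", 1)], [("D", 1)], reversible=True)
        etm = build_etm([fwd, rev], skip_reversible=True)
        assert "2.2.2.2" not in etm.W.columns
        # default: reversible scored in the written direction
        etm_default = build_etm([fwd, rev])
        assert etm_default.W.loc["C", "2.2.2.2"] == 1.0

    def test_empty_reaction_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_etm([])


class TestNormalizeEcAbundance:
    def test_two_column_oracle(self):
        out = normalize_ec_abundance(_ec_table([[1, 4], [2, 5], [3, 6]]))
        expected = np.log2(np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]]) + 1)
        assert np.allclose(out.A.to_numpy(), expected, atol=1e-12)

    def test_identical_columns_unchanged_before_log(self):
        out = normalize_ec_abundance(_ec_table([[3, 3], [1, 1], [7, 7]]))
        assert np.allclose(2 ** out.A.to_numpy() - 1, [[3, 3], [1, 1], [7, 7]], atol=1e-9)

    def test_ties_get_mean_of_rank_reference(self):
        # sorted ref = mean([3,5,5],[1,2,3]) = [2, 3.5, 4]; ties in column 0
        # at ranks {2, 3} -> both get (3.5 + 4) / 2 = 3.75
        out = normalize_ec_abundance(_ec_table([[5, 1], [5, 2], [3, 3]]))
        pre_log = 2 ** out.A.to_numpy() - 1
        assert np.allclose(pre_log[:, 0], [3.75, 3.75, 2.0], atol=1e-9)
        assert np.allclose(pre_log[:, 1], [2.0, 3.5, 4.0], atol=1e-9)

    def test_sorted_columns_identical(self):
        # tie-free columns: every column is a permutation of distinct values
        rng = np.random.default_rng(0)
        cols = np.stack([rng.permutation(20) * (j + 1) for j in range(5)], axis=1)
        out = normalize_ec_abundance(_ec_table(cols))
        cols = np.sort(out.A.to_numpy(), axis=0)
        assert np.allclose(cols, cols[:, [0]], atol=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            normalize_ec_abundance(_ec_table([[1], [2]]))


class TestPrmtScores:
    @staticmethod
    def _etm_one_ec():
        return ETM(W=pd.DataFrame({"1.1.1.1": [1.0]}, index=["M"]))

    def test_identical_samples_score_zero(self):
        a = NormalizedAbundance(A=pd.DataFrame({"s1": [2.0], "s2": [2.0]}, index=["1.1.1.1"]))
        s = prmt_scores(a, self._etm_one_ec())
        assert np.allclose(s.S.to_numpy(), 0.0)

    def test_linearity_in_deviations(self):
        a = NormalizedAbundance(A=pd.DataFrame({"s1": [3.0], "s2": [1.0]}, index=["1.1.1.1"]))
        s = prmt_scores(a, self._etm_one_ec())
        assert np.allclose(s.S.loc["M"].to_numpy(), [1.0, -1.0])

    def test_rows_sum_to_zero(self, small_cfg):
        rng = np.random.default_rng(1)
        table = _ec_table(rng.integers(0, 500, size=(4, 6)),
                          ecs=["1.7.5.1", "1.9.6.1", "1.7.2.1", "1.7.2.5"])
        from sedimeta.synthetic import nitrogen_cycle_reactions

        etm = build_etm(nitrogen_cycle_reactions())
        s = prmt_scores(normalize_ec_abundance(table), etm)
        assert np.allclose(s.S.to_numpy().sum(axis=1), 0.0, atol=1e-9)

    def test_scaling_deviations_scales_scores(self):
        a1 = NormalizedAbundance(A=pd.DataFrame({"s1": [3.0], "s2": [1.0]}, index=["1.1.1.1"]))
        a2 = NormalizedAbundance(A=pd.DataFrame({"s1": [6.0], "s2": [2.0]}, index=["1.1.1.1"]))
        s1 = prmt_scores(a1, self._etm_one_ec())
        s2 = prmt_scores(a2, self._etm_one_ec())
        assert np.allclose(s2.S.to_numpy(), 2 * s1.S.to_numpy())

    def test_disjoint_ec_sets_rejected(self):
        a = NormalizedAbundance(A=pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["9.9.9.9"]))
        with pytest.raises(ValueError, match="no ECs shared"):
            prmt_scores(a, self._etm_one_ec())


def _scores(matrix, samples):
    df = pd.DataFrame(matrix, index=[f"m{i}" for i in range(len(matrix))], columns=samples)
    df = df.sub(df.mean(axis=1), axis=0)  # mean reference by construction
    return PRMTScores(S=df)


class TestComparePrmtGroups:
    def test_complete_separation_seven_vs_seven(self):
        a = [f"a{i}" for i in range(7)]
        b = [f"b{i}" for i in range(7)]
        vals = np.concatenate([np.arange(7) + 10.0, np.arange(7)])
        scores = _scores([vals], a + b)
        (res,) = compare_prmt_groups(scores, a, b, n_permutations=1000, seed=0)
        exact_two_sided = 2 / comb(14, 7)  # the two extreme label assignments
        assert res.p_value >= 1 / 1001
        # generous Monte-Carlo allowance above the exact enumeration tail
        assert res.p_value <= exact_two_sided + 5 * math.sqrt(exact_two_sided / 1000) + 1 / 1001

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(3)
        a = [f"a{i}" for i in range(7)]
        b = [f"b{i}" for i in range(7)]
        ps = []
        for s in range(30):
            vals = np.random.default_rng(s).normal(size=14)
            scores = _scores([vals], a + b)
            (res,) = compare_prmt_groups(scores, a, b, n_permutations=200, seed=s)
            ps.append(res.p_value)
        assert np.mean(np.array(ps) <= 0.05) < 0.25  # near alpha, not inflated

    def test_constant_scores_give_p_one(self):
        scores = _scores([[1.0] * 6], [f"s{i}" for i in range(6)])
        (res,) = compare_prmt_groups(scores, ["s0", "s1", "s2"], ["s3", "s4", "s5"], seed=0)
        assert res.p_value == 1.0

    def test_single_sample_groups_rejected(self):
        scores = _scores([[1.0, 2.0]], ["s0", "s1"])
        with pytest.raises(ValueError, match=">= 2"):
            compare_prmt_groups(scores, ["s0"], ["s1"])

    def test_paired_mode_sign_flip(self):
        a = [f"a{i}" for i in range(6)]
        b = [f"b{i}" for i in range(6)]
        base = np.arange(6, dtype=float)
        vals = np.concatenate([base + 5.0, base])
        scores = _scores([vals], a + b)
        (res,) = compare_prmt_groups(scores, a, b, n_permutations=500, seed=1, paired=True)
        assert res.paired and res.p_value <= 0.05
        with pytest.raises(ValueError, match="equal group sizes"):
            compare_prmt_groups(scores, a, b[:-1], paired=True)


class TestAnnotateDirections:
    def test_sign_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(7)
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        scores = _scores(rng.normal(size=(3, 8)), a + b)
        fwd = annotate_metabolite_directions(compare_prmt_groups(scores, a, b, seed=0))
        rev = annotate_metabolite_directions(compare_prmt_groups(scores, b, a, seed=0))
        for m in fwd.index:
            assert fwd.loc[m, "score_gap"] == pytest.approx(-rev.loc[m, "score_gap"], abs=1e-12)
            if fwd.loc[m, "direction"] == "consumption_up":
                assert rev.loc[m, "direction"] == "accumulation_up"

    def test_zero_gap_flagged_ambiguous(self):
        scores = _scores([[1.0, 2.0, 1.0, 2.0]], ["a0", "a1", "b0", "b1"])
        df = annotate_metabolite_directions(
            compare_prmt_groups(scores, ["a0", "a1"], ["b0", "b1"], seed=0)
        )
        assert df.loc["m0", "direction"] == "ambiguous"
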