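import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from sedimeta.community import (
    _nmds_single,
    bray_curtis,
    envfit,
    filter_min_count,
    nmds,
    rarefy,
    relative_abundance,
    species_scores,
)
from sedimeta.io import FeatureTable


def _table(arr, samples=None, features=None, units="counts"):
    arr = np.asarray(arr)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    return FeatureTable(pd.DataFrame(arr, index=features, columns=samples), units_tag=units)


class TestFilterMinCount:
    def test_boundary_inclusive(self):
        t = _table([[9, 0], [10, 0], [5, 6]])
        kept = filter_min_count(t, 10)
        assert kept.feature_ids == ["f1", "f2"]
        assert kept.sample_ids == t.sample_ids

    def test_zero_threshold_is_identity(self, counts_table):
        assert filter_min_count(counts_table, 0).equals(counts_table)

    def test_all_below_gives_empty(self):
        t = _table([[1, 1], [2, 0]])
        assert filter_min_count(t, 100).shape == (0, 2)


class TestRarefy:
    def test_column_sums_exact_and_bounded(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 200, size=(30, 5)))
        out = rarefy(t, 500, seed=1)
        assert (out.counts.sum(axis=0) == 500).all()
        assert (out.counts <= t.counts).all()

    def test_sample_at_exact_depth_unchanged(self):
        t = _table([[3, 10], [2, 10]])
        out = rarefy(t, 5, seed=0)
        assert list(out.data["s0"]) == [3, 2]

    def test_hypergeometric_expectation(self):
        # two features (5, 5), draw 5 of 10: mean of feature 1 is 2.5
        t = _table([[5], [5]])
        draws = np.array([rarefy(t, 5, seed=s).counts[0, 0] for s in range(1000)])
        # variance of hypergeometric(N=10, K=5, n=5): n*K/N*(1-K/N)*(N-n)/(N-1)
        se = np.sqrt(5 * 0.5 * 0.5 * (5 / 9) / 1000)
        assert abs(draws.mean() - 2.5) <= 3 * se

    def test_shallow_samples_dropped_with_warning(self, caplog):
        t = _table([[5, 100], [5, 100]])
        with caplog.at_level("WARNING"):
            out = rarefy(t, 50, seed=0)
        assert out.sample_ids == ["s1"]
        assert "dropping" in caplog.text

    def test_all_samples_shallow_gives_empty(self, caplog):
        t = _table([[1], [1]])
        with caplog.at_level("WARNING"):
            out = rarefy(t, 10, seed=0)
        assert out.shape[1] == 0

    def test_nonpositive_depth_rejected(self, counts_table):
        with pytest.raises(ValueError):
            rarefy(counts_table, 0, seed=0)


class TestBrayCurtis:
    def test_worked_example(self):
        t = _table([[6, 2], [2, 2]])
        dm = bray_curtis(t)
        assert dm["s0", "s1"] == pytest.approx(4 / 12, abs=1e-12)

    def test_identical_and_disjoint_columns(self):
        t = _table([[3, 3, 0], [1, 1, 0], [0, 0, 7]])
        dm = bray_curtis(t)
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == 1.0

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(_table([[1, 0], [2, 0]]))

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
            min_size=4,
            max_size=8,
        ).filter(lambda rows: all(any(r[j] for r in rows) for j in range(3)))
    )
    @settings(max_examples=50, deadline=None)
    def test_metric_properties_fuzzed(self, rows):
        t = _table(np.asarray(rows))
        d = np.asarray(bray_curtis(t).data)
        x = t.counts
        # direct formula as the oracle
        for i in range(d.shape[0]):
            for j in range(d.shape[0]):
                num = np.abs(x[:, i] - x[:, j]).sum()
                den = (x[:, i] + x[:, j]).sum()
                assert d[i, j] == pytest.approx(num / den, abs=1e-12)
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()
        assert ((d >= 0) & (d <= 1)).all()


class TestNmds:
    def test_unit_square_embeds_exactly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        ordn = nmds(dm, k=2, n_restarts=4, seed=0)
        assert ordn.stress < 1e-4
        assert np.allclose(ordn.coords.mean(axis=0), 0, atol=1e-9)

    def test_collinear_points(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abc"))
        assert nmds(dm, k=2, n_restarts=2, seed=0).stress < 1e-6

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.random((12, 4))))
        x0 = rng.normal(size=(12, 2))
        _, _, _, trace = _nmds_single(d, x0, max_iter=100, tol=1e-9)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_stress_invariant_under_input_isometry(self):
        rng = np.random.default_rng(2)
        pts = rng.random((10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([3.0, -1.0])
        ids = [str(i) for i in range(10)]
        s1 = nmds(DistanceMatrix(squareform(pdist(pts)), ids=ids), seed=1, n_restarts=3).stress
        s2 = nmds(DistanceMatrix(squareform(pdist(moved)), ids=ids), seed=1, n_restarts=3).stress
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_k_must_be_small(self):
        dm = DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nmds(dm, k=2)


class TestEnvfit:
    @staticmethod
    def _ordination(n=20, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2))
        ids = [f"s{i}" for i in range(n)]
        return nmds(DistanceMatrix(squareform(pdist(pts)), ids=ids), n_restarts=2, seed=seed)

    def test_axis_aligned_variable_is_perfect_fit(self):
        ordn = self._ordination()
        v = pd.Series(ordn.coords[:, 0], index=ordn.sample_ids)
        fit = envfit(ordn, v, n_permutations=999, seed=0)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.p_value == pytest.approx(1 / 1000)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-6)

    def test_r2_matches_ols_oracle(self):
        import statsmodels.api as sm

        ordn = self._ordination(n=5, seed=3)
        rng = np.random.default_rng(4)
        v = pd.Series(rng.random(5), index=ordn.sample_ids)
        fit = envfit(ordn, v, n_permutations=9, seed=0)
        model = sm.OLS(v.to_numpy(), sm.add_constant(ordn.coords)).fit()
        assert fit.r_squared == pytest.approx(model.rsquared, abs=1e-10)

    def test_missing_samples_excluded(self):
        ordn = self._ordination(n=10, seed=1)
        v = pd.Series(np.arange(10.0), index=ordn.sample_ids)
        v.iloc[:3] = np.nan
        fit = envfit(ordn, v, n_permutations=99, seed=0)
        assert fit.n_samples_used == 7

    def test_constant_variable_rejected(self):
        ordn = self._ordination(n=6, seed=2)
        with pytest.raises(ValueError, match="constant"):
            envfit(ordn, pd.Series(1.0, index=ordn.sample_ids))

    def test_p_value_lower_bound(self):
        ordn = self._ordination(n=8, seed=5)
        v = pd.Series(ordn.coords[:, 1], index=ordn.sample_ids)
        fit = envfit(ordn, v, n_permutations=19, seed=0)
        assert fit.p_value >= 1 / 20


class TestSpeciesScores:
    def test_single_sample_feature_sits_on_that_sample(self):
        ordn = TestEnvfit._ordination(n=4, seed=7)
        counts = np.ones((3, 4), dtype=int)
        counts[0] = [0, 0, 5, 0]
        t = _table(counts, samples=ordn.sample_ids)
        scores = species_scores(t, ordn, ["f0"])
        assert np.allclose(scores.loc["f0"].to_numpy(), ordn.coords[2], atol=1e-12)

    def test_uniform_feature_at_centroid(self):
        ordn = TestEnvfit._ordination(n=5, seed=8)
        t = _table(np.full((2, 5), 4), samples=ordn.sample_ids)
        scores = species_scores(t, ordn, ["f0"])
        assert np.allclose(scores.loc["f0"].to_numpy(), 0.0, atol=1e-9)

    def test_two_sample_hand_weighted_average(self):
        ordn = TestEnvfit._ordination(n=3, seed=9)
        t = _table([[3, 1, 0], [1, 3, 4]], samples=ordn.sample_ids)
        scores = species_scores(t, ordn, ["f0"])
        # equal column sums (4), so relative abundances are (0.75, 0.25, 0)
        w = np.array([0.75, 0.25, 0.0])
        w = w / w.sum()
        assert np.allclose(scores.loc["f0"].to_numpy(), w @ ordn.coords, atol=1e-12)

    def test_all_zero_feature_rejected(self):
        ordn = TestEnvfit._ordination(n=3, seed=10)
        t = _table([[0, 0, 0], [1, 1, 1]], samples=ordn.sample_ids)
        with pytest.raises(ValueError, match="all-zero"):
            species_scores(t, ordn, ["f0"])


class TestRelativeAbundance:
    def test_percent_scale(self):
        t = _table([[18], [82]])
        out = relative_abundance(t)
        assert list(out.data["s0"]) == [18.0, 82.0]
        assert out.units_tag == "proportions"

    def test_columns_sum_to_100(self, counts_table):
        out = relative_abundance(counts_table)
        assert np.allclose(out.counts.sum(axis=0), 100.0, atol=1e-9)

    def test_idempotent(self, counts_table):
        once = relative_abundance(counts_table)
        twice = relative_abundance(once)
        assert twice.equals(once)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            relative_abundance(_table([[0, 1], [0, 2]]))
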