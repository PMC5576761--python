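import numpy as np
import pytest

from screenrep.clustering import (
    ClusterPartition,
    StudyCorrelation,
    bootstrap_correlation,
    cluster_studies,
    estimate_correlations,
    pairwise_joint_prior,
    study_correlation,
)
from screenrep.models import Scale, StudyMatrix, pvals_to_zscores
from screenrep.pipeline import fit_study_models
from screenrep.simulate import simulate_clustered

from conftest import make_model


def _two_group_sample(n, pi1, mu, rng, joint_with=None, rho=None):
    h = rng.random(n) < pi1
    z = np.where(h, rng.normal(mu, 1.0, n), rng.standard_normal(n))
    return h, z


class TestStudyCorrelation:
    def test_independence_gives_zero(self):
        assert study_correlation(0.1, 0.2, 0.02) == pytest.approx(0.0)

    def test_identical_indicators_give_one(self):
        assert study_correlation(0.3, 0.3, 0.3) == pytest.approx(1.0)

    def test_formula_oracle(self):
        # (0.03 - 0.0036) / sqrt(0.06*0.94*0.06*0.94)
        expected = (0.03 - 0.06 * 0.06) / (0.06 * 0.94)
        got = study_correlation(0.06, 0.06, 0.03)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.468, abs=1e-3)

    def test_degenerate_marginal_warns_zero(self):
        with pytest.warns(UserWarning):
            assert study_correlation(0.0, 0.5, 0.0) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_clipped_to_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a_i, a_j = rng.uniform(0.01, 0.99, 2)
        a_ij = rng.uniform(0, min(a_i, a_j))
        assert -1.0 <= study_correlation(a_i, a_j, a_ij) <= 1.0


class TestPairwiseJointPrior:
    def test_independent_columns(self):
        rng = np.random.default_rng(71)
        n = 5000
        model = make_model(pi0=0.9, mu=3.0)
        hi, zi = _two_group_sample(n, 0.1, 3.0, rng)
        hj, zj = _two_group_sample(n, 0.1, 3.0, rng)
        a_ij = pairwise_joint_prior(zi, zj, model, model)
        assert a_ij == pytest.approx(0.1 * 0.1, abs=0.02)

    def test_duplicated_column(self):
        rng = np.random.default_rng(72)
        model = make_model(pi0=0.9, mu=3.0)
        _, z = _two_group_sample(5000, 0.1, 3.0, rng)
        a_ij = pairwise_joint_prior(z, z, model, model)
        assert a_ij == pytest.approx(0.1, abs=0.05)

    def test_all_null_data(self):
        rng = np.random.default_rng(73)
        model = make_model(pi0=0.9, mu=3.0)
        zi = rng.standard_normal(4000)
        zj = rng.standard_normal(4000)
        assert pairwise_joint_prior(zi, zj, model, model) <= 0.05


class TestBootstrapCorrelation:
    def _zmatrix(self, rng, n=2000, m=2, mu=3.0, pi1=0.1):
        Z = rng.standard_normal((n, m))
        for j in range(m):
            nn = rng.random(n) < pi1
            Z[nn, j] = rng.normal(mu, 1.0, int(nn.sum()))
        return StudyMatrix(
            Z, [f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)], Scale.zscore
        )

    def test_identity_resampler_equals_single_shot(self):
        rng = np.random.default_rng(81)
        Z = self._zmatrix(rng)
        models = [make_model(pi0=0.9, mu=3.0)] * 2
        hook = lambda _rng, n: np.arange(n)
        boot = bootstrap_correlation(Z, 0, 1, models, B=1, resampler=hook)
        a_ij = pairwise_joint_prior(Z.column(0), Z.column(1), models[0], models[1])
        single = study_correlation(0.1, 0.1, a_ij)
        assert boot == pytest.approx(single, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_near_zero_under_independence(self, seed):
        rng = np.random.default_rng(100 + seed)
        Z = self._zmatrix(rng)
        models = [make_model(pi0=0.9, mu=3.0)] * 2
        r = bootstrap_correlation(Z, 0, 1, models, B=10, seed=seed)
        assert abs(r) < 0.1

    def test_same_cluster_pair_exceeds_edge_threshold(self):
        ds = simulate_clustered(n=3000, M=2, cluster_size=2, r=0.8, seed=82)
        Z = pvals_to_zscores(ds.P)
        models = fit_study_models(Z)
        r = bootstrap_correlation(Z, 0, 1, models, B=10, seed=82)
        assert r >= 0.1

    def test_invalid_b(self, rng):
        Z = self._zmatrix(rng)
        with pytest.raises(ValueError):
            bootstrap_correlation(Z, 0, 1, [make_model()] * 2, B=0)


class TestClusterStudies:
    def _corr(self, r):
        r = np.asarray(r, dtype=float)
        a = np.full(r.shape[0], 0.1)
        return StudyCorrelation(a, np.outer(a, a), r)

    def test_empty_graph_gives_singletons(self):
        r = np.eye(4)
        part = cluster_studies(self._corr(r))
        assert part.clusters == [[0], [1], [2], [3]]

    @pytest.mark.parametrize("method", ["infomap", "components"])
    def test_two_blocks(self, method):
        r = np.eye(6)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            r[i, j] = r[j, i] = 0.5
        part = cluster_studies(self._corr(r), method=method)
        assert sorted(map(tuple, part.clusters)) == [(0, 1, 2), (3, 4, 5)]

    def test_negative_correlation_counts_as_edge(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = -0.5
        part = cluster_studies(self._corr(r), method="components")
        assert [0, 1] in part.clusters

    def test_partition_validity_random_graphs(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(3, 12))
            r = np.eye(m)
            for i in range(m):
                for j in range(i + 1, m):
                    r[i, j] = r[j, i] = rng.uniform(-0.3, 0.3)
            part = cluster_studies(self._corr(r), seed=seed)
            assert sorted(i for c in part.clusters for i in c) == list(range(m))

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            cluster_studies(self._corr(np.eye(2)), method="louvain")


class TestBlockRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_scenario2_adjusted_rand_is_one(self, seed):
        from sklearn.metrics import adjusted_rand_score

        # n = 4000: at smaller n the bootstrap phi estimates are noisy
        # enough that a spurious cross-block edge (> 0.1) can merge blocks
        ds = simulate_clustered(n=4000, M=3, cluster_size=4, r=0.8, x=100, seed=seed)
        Z = pvals_to_zscores(ds.P)
        models = fit_study_models(Z)
        corr = estimate_correlations(Z, models, B=5, seed=seed)
        part = cluster_studies(corr, 0.1, seed=seed)
        truth = np.repeat(np.arange(3), 4)
        assert adjusted_rand_score(truth, part.labels()) == 1.0


class TestClusterPartition:
    def test_rejects_non_cover(self):
        with pytest.raises(ValueError):
            ClusterPartition([[0, 1]], m=3)

    def test_rejects_overlap(self):
        with pytest.raises(ValueError):
            ClusterPartition([[0, 1], [1, 2]], m=3)

    def test_labels_round_trip(self):
        part = ClusterPartition([[0, 2], [1]], m=3)
        assert part.labels().tolist() == [0, 1, 0]
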