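"""PCA/k-means/DAPC, EM admixture recovery, Evanno ΔK, lineage assignment."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mixploid import cluster
from mixploid.containers import RunTable
from mixploid.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def blobs():
    # high-dimensional like PCA scores of genotypes: separation on the first
    # axis, isotropic noise spread over many axes
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, size=(60, 40))
    b = rng.normal(0, 1, size=(60, 40))
    b[:, 0] += 12
    return np.vstack([a, b]), np.array([0] * 60 + [1] * 60)


class TestPca:
    def test_eigenvalue_sum_equals_total_variance(self, toy_genotypes):
        scores, eig = cluster.pca_genotypes(toy_genotypes)
        from mixploid.cluster import _impute_locus_mean
        X = _impute_locus_mean(toy_genotypes.dosage)
        total = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        assert eig.sum() == pytest.approx(total)
        assert np.all(np.diff(eig) <= 1e-9)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.4, size=(10, 30)).astype(float)
        X[1] = X[0]
        scores, _ = cluster.pca_genotypes(X)
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-9)

    def test_two_cluster_pc1_separates(self, two_cluster_dataset):
        ds = two_cluster_dataset
        scores, _ = cluster.pca_genotypes(ds.true_dosage.astype(float))
        labels = ds.samples["dominant_cluster"].to_numpy()
        pc1 = scores[:, 0]
        best = max(
            np.mean((pc1 > t) == (labels == 1))
            for t in np.quantile(pc1, np.linspace(0.02, 0.98, 97)))
        best = max(best, 1 - best)
        assert best >= 0.99

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cluster.pca_genotypes(np.ones((1, 5)))


class TestKmeansBic:
    def test_two_blobs_selects_two(self, blobs):
        X, _ = blobs
        scan = cluster.kmeans_bic_scan(X, kmax=8, seed=0)
        assert scan.selected_k == 2
        assert max(scan.k_values) == 8
        assert np.all(np.isfinite(scan.bic))

    def test_kmax_bounds(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError):
            cluster.kmeans_bic_scan(X, kmax=len(X))


class TestAScore:
    def test_null_near_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 10))
        labels = rng.integers(0, 2, size=80)
        _, means = cluster.a_score(X, labels, n_pcs_grid=[2, 5],
                                   n_permutations=20, seed=0)
        assert all(abs(v) < 0.15 for v in means.values())

    def test_separated_groups_positive(self, blobs):
        X, y = blobs
        best, means = cluster.a_score(X, y, n_pcs_grid=[1, 2, 3],
                                      n_permutations=10, seed=0)
        assert means[best] > 0.3
        assert best in (1, 2, 3)

    def test_single_group_rejected(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError):
            cluster.a_score(X, np.zeros(len(X)))


class TestDapc:
    def test_memberships_normalised_and_axis_bound(self, blobs):
        X, y = blobs
        model = cluster.dapc_fit(X, y, n_pcs=4)
        np.testing.assert_allclose(model.posterior.sum(axis=1), 1.0,
                                   atol=1e-6)
        assert model.coordinates.shape[1] == 1  # 2 groups -> 1 axis
        assert np.all(np.diff(model.percent_variance) <= 1e-9)
        assert model.percent_variance.sum() <= 100 + 1e-6

    def test_five_cluster_reassignment(self):
        cfg = SimulationConfig(
            cluster_sizes=(60, 40, 10, 45, 15), n_nuclear_sites=1000,
            hybrid_specs=(), n_clones=0, missing_rate=0.02, seed=17)
        ds = simulate_dataset(cfg)
        scores, _ = cluster.pca_genotypes(ds.true_dosage.astype(float))
        labels = ds.samples["dominant_cluster"].to_numpy()
        model = cluster.dapc_fit(scores, labels, n_pcs=30)
        assert (model.assigned == labels).mean() >= 0.95


class TestAdmixtureEM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, size=(20, 50)).astype(float)
        res = cluster.admixture_em(g, K=1)
        np.testing.assert_allclose(res.Q, 1.0)
        expected = g.sum(axis=0) / (2 * g.shape[0])
        np.testing.assert_allclose(res.F[0], expected, atol=1e-12)

    def test_loglik_monotone(self, two_cluster_dataset):
        ds = two_cluster_dataset
        g = ds.true_dosage[:40, :200].astype(float)
        res = cluster.admixture_em(g, K=2, n_init=1, seed=0)
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-6).all()

    def test_q_recovery_two_clusters(self):
        cfg = SimulationConfig(
            n_clusters=2, cluster_sizes=(50, 50), cluster_ploidy=(2, 2),
            cluster_divergence=(0.2, 0.2), cluster_regions=(("a",), ("b",)),
            n_nuclear_sites=1000, hybrid_specs=(), n_clones=0,
            missing_rate=0.02, seed=19)
        ds = simulate_dataset(cfg)
        res = cluster.admixture_em(ds.true_dosage.astype(float), K=2,
                                   n_init=10, seed=1)
        # best label permutation by F against truth
        err = {}
        for perm in ([0, 1], [1, 0]):
            err[tuple(perm)] = np.abs(res.Q[:, perm] - ds.true_Q).mean()
        assert min(err.values()) < 0.1

    def test_init_permutation_invariance(self, two_cluster_dataset):
        # different random initialisations reach the same optimum up to
        # cluster relabelling (matched on F)
        ds = two_cluster_dataset
        g = ds.true_dosage[:60, :300].astype(float)
        r1 = cluster.admixture_em(g, K=2, n_init=5, seed=11)
        r2 = cluster.admixture_em(g, K=2, n_init=5, seed=12)
        cost = np.abs(r1.F[:, None, :] - r2.F[None, :, :]).mean(axis=2)
        ri, ci = linear_sum_assignment(cost)
        assert np.abs(r1.Q[:, ri] - r2.Q[:, ci]).mean() < 0.05


class TestEvanno:
    def test_hand_example(self):
        runs = RunTable()
        # mean L(1..3) = -100, -50, -45 with sd(L(2)) = 2
        for rep, v in enumerate([-100.0, -100.0]):
            runs.add(1, rep, v, np.ones((4, 1)))
        for rep, v in enumerate([-52.0, -48.0]):  # mean -50, sd ~2.828
            runs.add(2, rep, v, np.full((4, 2), 0.5))
        for rep, v in enumerate([-45.0, -45.0]):
            runs.add(3, rep, v, np.full((4, 3), 1 / 3))
        out = cluster.evanno_delta_k(runs)
        sd2 = np.std([-52.0, -48.0], ddof=1)
        expected = abs(-45 - 2 * (-50) + (-100)) / sd2
        row = out[out["K"] == 2].iloc[0]
        assert row["delta_K"] == pytest.approx(expected)
        assert np.isnan(out[out["K"] == 1].iloc[0]["delta_K"])
        assert np.isnan(out[out["K"] == 3].iloc[0]["delta_K"])

    def test_linear_lnp_gives_zero(self):
        # replicate noise symmetric around an exactly linear mean: the second
        # difference of means vanishes, so interior ΔK is zero
        runs = RunTable()
        for K in (1, 2, 3, 4):
            for rep, eps in enumerate((-1.0, 1.0)):
                runs.add(K, rep, -100.0 + 10 * K + eps,
                         np.full((3, K), 1 / K))
        out = cluster.evanno_delta_k(runs)
        inner = out[out["K"].isin([2, 3])]["delta_K"]
        assert (inner.abs() < 1e-9).all()

    def test_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        runs = RunTable()
        lnps = {}
        for K in range(1, 6):
            lnps[K] = rng.normal(-1000 + 50 * K, 5, size=4)
            for rep, v in enumerate(lnps[K]):
                runs.add(K, rep, v, np.full((3, K), 1 / K))
        out = cluster.evanno_delta_k(runs).set_index("K")
        for K in range(2, 5):
            means = {k: lnps[k].mean() for k in lnps}
            expected = abs(means[K + 1] - 2 * means[K] + means[K - 1]) / np.std(
                lnps[K], ddof=1)
            assert out.loc[K, "delta_K"] == pytest.approx(expected)

    def test_single_replicate_rejected(self):
        runs = RunTable()
        runs.add(1, 0, -10.0, np.ones((2, 1)))
        runs.add(2, 0, -9.0, np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            cluster.evanno_delta_k(runs)


class TestLineages:
    def test_threshold_rule(self):
        Q = np.array([[0.8, 0.2], [0.6, 0.4], [0.1, 0.9]])
        out = cluster.assign_lineages(Q)
        assert out == ["K1", "admixed", "K2"]

    def test_geographic_split(self):
        Q = np.array([[0.9, 0.1], [0.85, 0.15], [0.1, 0.9]])
        out = cluster.assign_lineages(
            Q, regions=["Alaska", "Europe", "Alaska"])
        assert out[0] == "K1@Alaska"
        assert out[1] == "K1@Europe"
        assert out[2] == "K2"

    def test_unnormalised_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster.assign_lineages(np.array([[0.5, 0.4]]))
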