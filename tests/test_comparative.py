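"""Phylogenetic covariance, Pagel's lambda, Mantel and phylogenetic Mantel."""

import numpy as np
import pytest
from scipy import stats

from isotroph.core import DistanceMatrix, Phylogeny
from isotroph.comparative import (
    lambda_transform,
    mantel,
    mantel_exact,
    pagel_lambda,
    phylo_covariance,
    phylo_mantel,
    restricted_permutation,
)
from isotroph.errors import AnalysisError
from isotroph.simulate import SimulationScenario, simulate_brownian_trait, simulate_tree

from conftest import random_distance_matrix


class TestPhyloCovariance:
    def test_hand_constructed_three_tips(self, three_tip_tree):
        C = phylo_covariance(three_tip_tree)
        m = C.matrix
        i = {l: k for k, l in enumerate(C.labels)}
        np.testing.assert_allclose(np.diag(m), [2.0, 2.0, 2.0])
        assert m[i["A"], i["B"]] == pytest.approx(1.0)
        assert m[i["A"], i["C"]] == pytest.approx(0.0)

    def test_star_tree_is_scaled_identity(self):
        p = Phylogeny.from_newick("(A:3,B:3,C:3,D:3);")
        C = phylo_covariance(p).matrix
        np.testing.assert_allclose(C, 3.0 * np.eye(4), atol=1e-12)

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(5):
            tree = simulate_tree(SimulationScenario(n_species=20, seed=seed))
            C = phylo_covariance(tree).matrix
            eig = np.linalg.eigvalsh(C)
            assert eig.min() > -1e-10

    def test_consistent_with_patristic(self, three_tip_tree):
        C = phylo_covariance(three_tip_tree).matrix
        pat = three_tip_tree.patristic_matrix().values
        depths = np.diag(C)
        expected = depths[:, None] + depths[None, :] - 2 * C
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(pat[off], expected[off], atol=1e-12)


class TestLambdaTransform:
    def test_identity_at_one(self, three_tip_tree):
        C = phylo_covariance(three_tip_tree)
        np.testing.assert_allclose(lambda_transform(C, 1.0).matrix, C.matrix)

    def test_diagonal_at_zero(self, three_tip_tree):
        C = phylo_covariance(three_tip_tree)
        out = lambda_transform(C, 0.0).matrix
        np.testing.assert_allclose(out, np.diag(np.diag(C.matrix)))

    def test_halves_off_diagonal(self, three_tip_tree):
        C = phylo_covariance(three_tip_tree)
        out = lambda_transform(C, 0.5).matrix
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(out[off], 0.5 * C.matrix[off])
        np.testing.assert_allclose(np.diag(out), np.diag(C.matrix))

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain_error(self, three_tip_tree, lam):
        with pytest.raises(AnalysisError):
            lambda_transform(phylo_covariance(three_tip_tree), lam)


class TestPagelLambda:
    def test_lambda0_loglik_is_iid_normal(self, rng):
        """At lambda = 0 on an ultrametric tree of depth T the log-likelihood
        equals the sum of iid normal log-densities with variance sigma2*T."""
        tree = simulate_tree(SimulationScenario(n_species=16, seed=4))
        y = rng.standard_normal(16) * 2.0 + 5.0
        trait = dict(zip(tree.tip_labels, y))
        res = pagel_lambda(tree, trait)
        T = tree.depth
        sigma2 = np.mean((y - y.mean()) ** 2) / T
        expected = stats.norm.logpdf(y, loc=y.mean(), scale=np.sqrt(sigma2 * T)).sum()
        assert res.logL_lambda0 == pytest.approx(expected, abs=1e-5)

    def test_matches_dense_grid_brute_force(self, rng):
        """Reported optimum matches an independent dense-grid evaluation of
        the profiled MVN likelihood (step 1e-3) to 1e-6 log-units."""
        tree = simulate_tree(SimulationScenario(n_species=16, seed=7))
        trait = simulate_brownian_trait(tree, lambda_true=0.6, sigma2=1.0,
                                        rng=np.random.default_rng(7))
        res = pagel_lambda(tree, trait)

        order = list(tree.tip_labels)
        y = np.array([trait[l] for l in order])
        C = phylo_covariance(tree, order).matrix
        T = np.diag(C).mean()
        n = len(y)
        one = np.ones(n)
        ridge = 1e-9 * T

        def brute_logL(lam):
            V = C * lam
            np.fill_diagonal(V, np.diag(C) + ridge)
            Vi = np.linalg.inv(V)
            mu = (one @ Vi @ y) / (one @ Vi @ one)
            r = y - mu
            sigma2 = (r @ Vi @ r) / n
            sign, logdet = np.linalg.slogdet(V)
            return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

        grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        brute = np.array([brute_logL(l) for l in grid])
        k = int(np.argmax(brute))
        assert res.logL_hat >= brute[k] - 1e-6
        assert abs(res.lambda_hat - grid[k]) <= 1e-3 + 1e-9
        # the likelihood code itself agrees with the brute evaluation
        assert brute_logL(res.lambda_hat) == pytest.approx(res.logL_hat, abs=1e-6)

    def test_logL_at_optimum_not_below_null(self, rng):
        tree = simulate_tree(SimulationScenario(n_species=24, seed=5))
        trait = dict(zip(tree.tip_labels, rng.standard_normal(24)))
        res = pagel_lambda(tree, trait)
        assert res.logL_hat >= res.logL_lambda0 - 1e-9
        assert 0.0 <= res.lambda_hat <= 1.0
        assert 0.0 <= res.lrt_p <= 1.0

    def test_zero_variance_trait_is_error(self):
        tree = simulate_tree(SimulationScenario(n_species=8, seed=1))
        with pytest.raises(AnalysisError, match="variance"):
            pagel_lambda(tree, {l: 1.0 for l in tree.tip_labels})

    def test_too_few_species_is_error(self, three_tip_tree):
        with pytest.raises(AnalysisError, match="4 species"):
            pagel_lambda(three_tip_tree, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestMantel:
    def test_affine_relation_gives_r_one(self, rng):
        labels = [f"s{i}" for i in range(8)]
        d1 = random_distance_matrix(rng, labels)
        v = 0.5 + 2.0 * d1.values
        np.fill_diagonal(v, 0.0)
        d2 = DistanceMatrix(tuple(labels), v)
        res = mantel(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_invariant_under_common_relabeling(self, rng):
        labels = [f"s{i}" for i in range(9)]
        d1 = random_distance_matrix(rng, labels)
        d2 = random_distance_matrix(rng, labels)
        r0 = mantel(d1, d2, n_perm=99, seed=1).r
        perm = rng.permutation(9)
        new = [labels[i] for i in perm]
        r1 = mantel(d1.reindex(new), d2.reindex(new), n_perm=99, seed=1).r
        assert r1 == pytest.approx(r0)

    def test_p_has_identity_floor(self, rng):
        labels = [f"s{i}" for i in range(8)]
        d1 = random_distance_matrix(rng, labels)
        res = mantel(d1, d1, n_perm=999, seed=3)
        assert res.p >= 1 / 1000
        assert res.r == pytest.approx(1.0)

    def test_upper_tail_p_near_one_for_negative_r(self, rng):
        """Anti-correlated matrices give an upper-tail p close to 1."""
        labels = [f"s{i}" for i in range(10)]
        pts = rng.standard_normal((10, 1))
        d1 = DistanceMatrix.from_points(labels, pts)
        # distances from reflected points: strongly negatively associated
        v = d1.values.max() - d1.values
        np.fill_diagonal(v, 0.0)
        d2 = DistanceMatrix(tuple(labels), v)
        res = mantel(d1, d2, n_perm=199, seed=5)
        assert res.r < -0.5
        assert res.p > 0.9

    def test_zero_variance_triangle_is_error(self):
        labels = ["a", "b", "c", "d"]
        flat = DistanceMatrix(tuple(labels), np.ones((4, 4)) - np.eye(4))
        other = DistanceMatrix.from_points(labels, np.arange(4.0)[:, None])
        with pytest.raises(AnalysisError, match="variance"):
            mantel(flat, other, n_perm=99)

    def test_label_mismatch_is_error(self, rng):
        d1 = random_distance_matrix(rng, ["a", "b", "c", "d"])
        d2 = random_distance_matrix(rng, ["a", "b", "c", "e"])
        with pytest.raises(Exception, match="labels"):
            mantel(d1, d2, n_perm=99)


class TestPhyloMantel:
    def test_degenerate_control_is_error(self, rng):
        labels = [f"s{i}" for i in range(6)]
        d1 = random_distance_matrix(rng, labels)
        d2 = random_distance_matrix(rng, labels)
        flat = DistanceMatrix(tuple(labels), np.ones((6, 6)) - np.eye(6))
        with pytest.raises(AnalysisError, match="variance"):
            phylo_mantel(d1, d2, None, flat, n_perm=99)

    def test_partial_reduces_to_plain_with_independent_control(self, rng):
        """With a control matrix independent of both inputs, the partial r
        stays within 0.05 of the plain Mantel r (50 species, 20 replicates)."""
        gaps = []
        for rep in range(20):
            rr = np.random.default_rng(1000 + rep)
            labels = [f"s{i}" for i in range(50)]
            base = rr.standard_normal((50, 2))
            d1 = DistanceMatrix.from_points(labels, base)
            d2 = DistanceMatrix.from_points(labels, base + 0.8 * rr.standard_normal((50, 2)))
            d3 = random_distance_matrix(rr, labels)
            plain = mantel(d1, d2, n_perm=99, seed=rep).r
            partial = phylo_mantel(d1, d2, None, d3, n_perm=99, seed=rep).r
            gaps.append(abs(plain - partial))
        assert np.mean(gaps) < 0.05

    def test_restricted_permutation_is_permutation(self, rng):
        tree = simulate_tree(SimulationScenario(n_species=15, seed=3))
        pat = tree.patristic_matrix().values
        for _ in range(20):
            perm = restricted_permutation(pat, rng)
            assert sorted(perm) == list(range(15))

    def test_restricted_null_rejects_less_under_phylogenetic_signal(self):
        """When both matrices inherit strong phylogenetic signal, the
        phylogenetically restricted null rejects less often than the free
        null (the motivation for phylogenetic permutations)."""
        alpha = 0.05
        naive_rej = phylo_rej = 0
        n_rep = 300
        for rep in range(n_rep):
            rr = np.random.default_rng(5000 + rep)
            tree = simulate_tree(SimulationScenario(n_species=20, seed=9000 + rep))
            t1 = simulate_brownian_trait(tree, lambda_true=1.0, sigma2=1.0, rng=rr)
            t2 = simulate_brownian_trait(tree, lambda_true=1.0, sigma2=1.0, rng=rr)
            labels = list(tree.tip_labels)
            d1 = DistanceMatrix.from_points(labels, np.array([[t1[l]] for l in labels]))
            d2 = DistanceMatrix.from_points(labels, np.array([[t2[l]] for l in labels]))
            if mantel(d1, d2, n_perm=99, seed=rep).p <= alpha:
                naive_rej += 1
            if phylo_mantel(d1, d2, tree, n_perm=99, seed=rep).p <= alpha:
                phylo_rej += 1
        assert phylo_rej <= naive_rej


class TestMantelExact:
    def test_enumeration_count(self, rng):
        labels = ["a", "b", "c", "d"]
        res = mantel_exact(
            random_distance_matrix(rng, labels), random_distance_matrix(rng, labels)
        )
        assert res.n_perm == 24
        assert 1 / 24 <= res.p <= 1.0
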