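"""Tests for tree handling, Pagel's lambda, contrasts and the gate."""

import itertools

import numpy as np
import pytest
from scipy import stats

from symdiv import phylo
from symdiv.phylo import (
    lambda_covariance,
    lambda_gated_regression,
    lambda_loglik,
    ols_regression,
    pagel_lambda_test,
    parse_newick,
    pic_contrasts,
    pic_regression,
    prune_to_taxa,
    resolve_polytomies,
    tip_labels,
)
from symdiv.synth import TraitSimSpec, simulate_pure_birth_tree, simulate_traits

THREE_TIP = "((A:1,B:1):1,C:2);"


def pairwise_distances(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    return {
        (a, b): pdm.distance(tx[a], tx[b])
        for a, b in itertools.combinations(sorted(labels), 2)
    }


class TestParse:
    def test_three_tips(self):
        tree = parse_newick(THREE_TIP)
        assert sorted(tip_labels(tree)) == ["A", "B", "C"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_malformed_input(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_newick("((A:1,B:1")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            parse_newick("((A:1,B):1,C:2);")

    def test_file_roundtrip_matches_generator(self, tmp_path):
        tree = simulate_pure_birth_tree(12, seed=5)
        path = tmp_path / "t.nwk"
        tree.write(path=str(path), schema="newick", unquoted_underscores=True)
        back = parse_newick(path)
        assert sorted(tip_labels(back)) == sorted(tip_labels(tree))


class TestPrune:
    def test_identity_prune_preserves_distances(self):
        tree = simulate_pure_birth_tree(5, seed=1)
        labels = tip_labels(tree)
        pruned = prune_to_taxa(tree, labels)
        d0, d1 = pairwise_distances(tree, labels), pairwise_distances(pruned, labels)
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], abs=1e-12)

    def test_path_lengths_preserved_on_random_subset(self):
        tree = simulate_pure_birth_tree(50, seed=2)
        rng = np.random.default_rng(3)
        keep = sorted(rng.choice(tip_labels(tree), size=20, replace=False))
        pruned = prune_to_taxa(tree, keep)
        assert sorted(tip_labels(pruned)) == keep
        d0, d1 = pairwise_distances(tree, keep), pairwise_distances(pruned, keep)
        for k in d0:
            assert d1[k] == pytest.approx(d0[k], abs=1e-9)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            prune_to_taxa(parse_newick(THREE_TIP), ["A", "C"])


class TestLambdaCovariance:
    def test_hand_example(self):
        labels, cov = lambda_covariance(parse_newick(THREE_TIP), 0.5)
        assert labels == ["A", "B", "C"]
        assert np.diag(cov) == pytest.approx([2.0, 2.0, 2.0])
        assert cov[0, 1] == pytest.approx(0.5)  # shared path 1, scaled by lambda
        assert cov[0, 2] == 0.0

    def test_lambda_zero_is_diagonal(self):
        _, cov = lambda_covariance(simulate_pure_birth_tree(10, seed=4), 0.0)
        assert np.allclose(cov, np.diag(np.diag(cov)))

    def test_lambda_one_is_brownian(self):
        tree = simulate_pure_birth_tree(10, seed=4)
        _, c1 = lambda_covariance(tree, 1.0)
        _, c2 = phylo.tip_covariance(tree)
        assert np.allclose(c1, c2)

    def test_domain(self):
        with pytest.raises(ValueError):
            lambda_covariance(parse_newick(THREE_TIP), 1.5)


class TestPagelLambda:
    def test_star_tree_likelihood_flat_in_lambda(self):
        star = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        values = {"A": 0.3, "B": -1.2, "C": 0.7, "D": 2.0, "E": -0.5}
        res = pagel_lambda_test(star, values)
        assert res.loglik_hat == pytest.approx(res.loglik_zero, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_loglik_at_zero_matches_closed_form(self):
        """At lambda = 0 the model is independent normals with variance
        sigma2 * (tip height); profile mu and sigma2 analytically."""
        tree = simulate_pure_birth_tree(12, seed=8)
        values = simulate_traits(tree, TraitSimSpec(lambda_true=0.5, seed=9))
        labels, cov = phylo.tip_covariance(tree)
        d = np.diag(cov)
        y = np.array([values[lab] for lab in labels])
        mu = (y / d).sum() / (1.0 / d).sum()
        sigma2 = ((y - mu) ** 2 / d).sum() / y.size
        ll = -0.5 * (
            y.size * np.log(2 * np.pi * sigma2) + np.log(d).sum() + y.size
        )
        assert lambda_loglik(tree, values, 0.0) == pytest.approx(ll, abs=1e-9)

    def test_optimizer_matches_grid_oracle(self):
        tree = simulate_pure_birth_tree(10, seed=14)
        values = simulate_traits(
            tree, TraitSimSpec(lambda_true=0.7, noise_sd=0.5, seed=15)
        )
        res = pagel_lambda_test(tree, values)
        grid = np.linspace(0.0, 1.0, 2001)
        lls = [lambda_loglik(tree, values, g) for g in grid]
        best = int(np.argmax(lls))
        assert abs(res.lambda_hat - grid[best]) <= 1e-3 + (grid[1] - grid[0])
        assert res.loglik_hat >= max(lls) - 1e-9

    def test_zero_variance_rejected(self):
        tree = simulate_pure_birth_tree(5, seed=1)
        with pytest.raises(ValueError, match="variance"):
            pagel_lambda_test(tree, {lab: 1.0 for lab in tip_labels(tree)})

    def test_invariants(self):
        tree = simulate_pure_birth_tree(30, seed=16)
        values = simulate_traits(tree, TraitSimSpec(lambda_true=0.9, seed=17))
        res = pagel_lambda_test(tree, values)
        assert 0.0 <= res.lambda_hat <= 1.0
        assert res.loglik_hat >= res.loglik_zero
        assert 0.0 <= res.p_value <= 1.0


class TestContrasts:
    def test_two_tip_contrast(self):
        tree = parse_newick("(A:1,B:1);")
        c = pic_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert np.abs(c) == pytest.approx([2 / np.sqrt(2)], abs=1e-12)

    def test_identical_values_give_zero_contrasts(self):
        tree = simulate_pure_birth_tree(8, seed=3)
        vals = {lab: 2.5 + 0 for lab in tip_labels(tree)}
        assert pic_contrasts(tree, vals) == pytest.approx(np.zeros(7), abs=1e-12)

    def test_four_tip_hand_trace(self):
        """Pruning recursion traced by hand on ((A:1,B:2):1,(C:3,D:1):2)."""
        tree = parse_newick("((A:1,B:2):1,(C:3,D:1):2);")
        got = np.sort(np.abs(pic_contrasts(tree, {"A": 1.0, "B": 3.0, "C": 5.0, "D": 2.0})))
        c1 = (1 - 3) / np.sqrt(1 + 2)
        x12 = (1 / 1 + 3 / 2) / (1 / 1 + 1 / 2)
        v12 = 1 + (1 * 2) / (1 + 2)
        c2 = (5 - 2) / np.sqrt(3 + 1)
        x34 = (5 / 3 + 2 / 1) / (1 / 3 + 1 / 1)
        v34 = 2 + (3 * 1) / (3 + 1)
        c3 = (x12 - x34) / np.sqrt(v12 + v34)
        assert got == pytest.approx(np.sort(np.abs([c1, c2, c3])), abs=1e-12)

    def test_polytomy_requires_resolution(self):
        star = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="polytom"):
            pic_contrasts(star, {"A": 1.0, "B": 2.0, "C": 3.0})
        resolved = resolve_polytomies(star, seed=0)
        assert pic_contrasts(resolved, {"A": 1.0, "B": 2.0, "C": 3.0}).size == 2

    def test_child_order_invariance_up_to_sign(self):
        vals = {"A": 1.0, "B": 3.0, "C": 5.0, "D": 2.0}
        a = pic_contrasts(parse_newick("((A:1,B:2):1,(C:3,D:1):2);"), vals)
        b = pic_contrasts(parse_newick("((D:1,C:3):2,(B:2,A:1):1);"), vals)
        assert np.sort(np.abs(a)) == pytest.approx(np.sort(np.abs(b)), abs=1e-12)


class TestRegressions:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = ols_regression(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert (res.slope, res.intercept) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_perfect_anticorrelation(self):
        res = ols_regression([1, 2, 3], [3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ols_regression([1, 1, 1], [1, 2, 3])

    def test_recovers_population_correlation(self, rng):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        res = ols_regression(xy[:, 0], xy[:, 1])
        assert abs(res.r - 0.5) < 0.03

    def test_pic_regression_identity_trait(self):
        tree = simulate_pure_birth_tree(15, seed=6)
        x = simulate_traits(tree, TraitSimSpec(seed=7))
        res = pic_regression(tree, x, x)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == 0.0
        assert res.method == "phylogenetic"

    def test_pic_r_converges_as_noise_vanishes(self):
        tree = simulate_pure_birth_tree(30, seed=8)
        x = simulate_traits(tree, TraitSimSpec(seed=9))
        rs = []
        for noise in (2.0, 0.5, 0.05):
            y = {
                k: v + n
                for (k, v), n in zip(
                    x.items(),
                    np.random.default_rng(10).normal(0, noise, len(x)),
                )
            }
            rs.append(pic_regression(tree, x, y).r)
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.99

    def test_star_tree_pic_equals_pearson(self):
        """On a star tree with equal branch lengths the contrasts are an
        orthonormal rotation of the centered data, so the contrast
        correlation equals the ordinary Pearson correlation."""
        n = 12
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        star = resolve_polytomies(parse_newick(newick), seed=1)
        gen = np.random.default_rng(11)
        x = {f"t{i}": float(v) for i, v in enumerate(gen.normal(size=n))}
        y = {f"t{i}": float(v) for i, v in enumerate(gen.normal(size=n))}
        res = pic_regression(star, x, y)
        xv = np.array([x[f"t{i}"] for i in range(n)])
        yv = np.array([y[f"t{i}"] for i in range(n)])
        assert res.r == pytest.approx(stats.pearsonr(xv, yv).statistic, abs=1e-10)


class TestGate:
    def test_star_tree_residuals_accept_linear(self):
        n = 20
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        star = parse_newick(newick)
        gen = np.random.default_rng(12)
        x = {f"t{i}": float(v) for i, v in enumerate(gen.normal(size=n))}
        y = {f"t{i}": float(v) for i, v in enumerate(gen.normal(size=n))}
        gated = lambda_gated_regression(star, x, y)
        assert gated.accepted == "linear"
        assert gated.accepted_result is gated.ols
        assert gated.pic is not None  # both fits retained for reporting

    def test_gate_switches_exactly_at_lambda_p(self):
        tree = simulate_pure_birth_tree(25, seed=13)
        x = simulate_traits(tree, TraitSimSpec(lambda_true=1.0, seed=14))
        y = simulate_traits(tree, TraitSimSpec(lambda_true=1.0, seed=15))
        p = lambda_gated_regression(tree, x, y).lambda_test.p_value
        assert 0.0 < p < 1.0
        below = lambda_gated_regression(tree, x, y, alpha=min(p * 0.5, 0.999))
        above = lambda_gated_regression(tree, x, y, alpha=min(p * 1.5, 0.999))
        assert below.accepted == "linear"
        assert above.accepted == "phylogenetic"

    def test_structured_residuals_accept_phylogenetic(self):
        """Strongly phylogenetically structured residuals flip the gate in
        nearly every replicate."""
        accepted = 0
        reps = 20
        for i in range(reps):
            tree = simulate_pure_birth_tree(60, seed=100 + i)
            x = simulate_traits(tree, TraitSimSpec(lambda_true=1.0, seed=200 + i))
            y = simulate_traits(tree, TraitSimSpec(lambda_true=1.0, seed=300 + i))
            gated = lambda_gated_regression(tree, x, y)
            accepted += gated.accepted == "phylogenetic"
        assert accepted >= int(0.9 * reps)

    def test_requires_shared_taxa(self):
        tree = parse_newick(THREE_TIP)
        with pytest.raises(ValueError, match="shared"):
            lambda_gated_regression(tree, {"A": 1.0}, {"A": 2.0})
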