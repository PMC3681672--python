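"""Irreversible substitution model, LUCA-conditioned likelihood, coalescent."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from sgaclock.demography import LogisticDemography
from sgaclock.likelihood import (
    EpochModel,
    branch_expected_events,
    logistic_coalescent_log_density,
    luca_branch_log_prior,
    transition_probabilities,
    tree_log_likelihood,
)
from sgaclock.matrix import Character, SgaMatrix
from sgaclock.trees import SampledTree, TreeNode


def enumeration_loglik(tree, matrix, epochs, n_univ=None):
    """Independent oracle: sum over all interior-node state assignments."""
    n_univ = n_univ or max(matrix.n_characters, 1)
    internal = [n for n in tree.postorder() if not n.is_leaf and n is not tree.luca]
    row = {b: i for i, b in enumerate(matrix.biopsy_ids)}
    total = 0.0
    for j in range(matrix.n_characters):
        like = 0.0
        for assign in itertools.product([0, 1], repeat=len(internal)):
            state = {id(tree.luca): 0}
            for node, s in zip(internal, assign):
                state[id(node)] = s
            for tip in tree.tips():
                state[id(tip)] = int(matrix.data[row[tip.name], j])
            p = 1.0
            for node in tree.postorder():
                if node.parent is None:
                    continue
                lam = branch_expected_events((node.parent.time, node.time), epochs)
                P = transition_probabilities(lam / n_univ, 1.0)
                p *= P[state[id(node.parent)], state[id(node)]]
            like += p
        total += math.log(like) if like > 0 else -math.inf
    return total


def random_tree(names, rng, span=10.0):
    nodes = [TreeNode(nm, float(rng.uniform(0, 2))) for nm in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(time=min(a.time, b.time) - float(rng.uniform(0.1, span)))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    luca = TreeNode("LUCA", nodes[0].time - float(rng.uniform(0.5, span)))
    luca.add_child(nodes[0])
    return SampledTree(luca)


def matrix_for(names, data):
    chars = [Character("c", j, j + 1, "") for j in range(data.shape[1])]
    return SgaMatrix(list(names), chars, data)


class TestTransitionProbabilities:
    def test_zero_duration_is_identity(self):
        assert np.allclose(transition_probabilities(2.0, 0.0), np.eye(2))

    def test_zero_rate_is_identity(self):
        assert np.allclose(transition_probabilities(0.0, 5.0), np.eye(2))

    def test_matches_matrix_exponential(self):
        mu, t = 0.25, 4.0  # mu*t = 1
        Q = np.array([[-mu, mu], [0.0, 0.0]])
        assert np.allclose(
            transition_probabilities(mu, t), expm(Q * t), atol=1e-12
        )

    def test_rows_sum_to_one_and_irreversible(self):
        P = transition_probabilities(0.7, 3.0)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert P[1, 0] == 0.0 and P[1, 1] == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(-1.0, 1.0)


class TestBranchExpectedEvents:
    def test_single_epoch_branch(self):
        ep = EpochModel("off_on", 10.0, 8.0, 0.6)
        assert branch_expected_events((0.0, 2.0), ep) == pytest.approx(16.0)

    def test_straddling_branch_is_additive(self):
        ep = EpochModel("off_on", 1.0, 8.0, 0.6)
        assert branch_expected_events((0.0, 2.0), ep) == pytest.approx(8.6)

    def test_pre_baseline_accrues_first_epoch_rate(self):
        ep = EpochModel("off_on", 5.0, 8.0, 0.6)
        assert branch_expected_events((-10.0, -5.0), ep) == pytest.approx(40.0)

    def test_continuous_monotone_in_switch_time(self):
        lam = np.array(
            [
                branch_expected_events(
                    (0.0, 4.0), EpochModel("off_on", ts, 8.0, 0.6)
                )
                for ts in np.linspace(0, 4, 41)
            ]
        )
        assert np.all(np.diff(lam) >= 0)
        assert np.max(np.abs(np.diff(lam))) < 1.0  # no jumps


class TestTreeLikelihood:
    def test_all_zero_matrix_zero_rates(self):
        rng = np.random.default_rng(0)
        tree = random_tree(["a", "b", "c"], rng)
        m = matrix_for(["a", "b", "c"], np.zeros((3, 4), dtype=np.uint8))
        ep = EpochModel("off_on", 0.0, 1e-5, 1e-5)
        ll = tree_log_likelihood(tree, m, ep)
        assert ll.log_likelihood == pytest.approx(0.0, abs=1e-3)

    def test_matches_enumeration_on_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(2, 6))
            names = [f"t{i}" for i in range(n)]
            tree = random_tree(names, rng)
            data = rng.integers(0, 2, size=(n, int(rng.integers(1, 8))))
            m = matrix_for(names, data.astype(np.uint8))
            ep = EpochModel(
                "off_on", float(rng.uniform(-5, 5)),
                float(rng.uniform(0.1, 5)), float(rng.uniform(0.1, 5)),
            )
            got = tree_log_likelihood(tree, m, ep).log_likelihood
            want = enumeration_loglik(tree, m, ep)
            assert got == pytest.approx(want, abs=1e-9)

    def test_pattern_probabilities_sum_to_one(self):
        # over all 2^n tip patterns the likelihood must total 1
        rng = np.random.default_rng(2)
        names = ["a", "b", "c", "d"]
        tree = random_tree(names, rng)
        ep = EpochModel("off_on", 1.0, 2.0, 0.5)
        total = 0.0
        for bits in itertools.product([0, 1], repeat=4):
            m = matrix_for(names, np.array(bits, dtype=np.uint8).reshape(4, 1))
            total += math.exp(
                tree_log_likelihood(tree, m, ep, n_character_universe=1).log_likelihood
            )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_column_order_and_tip_relabeling(self):
        rng = np.random.default_rng(3)
        names = ["a", "b", "c", "d", "e"]
        tree = random_tree(names, rng)
        data = rng.integers(0, 2, size=(5, 10)).astype(np.uint8)
        ep = EpochModel("off_on", 0.5, 1.5, 0.7)
        base = tree_log_likelihood(tree, matrix_for(names, data), ep).log_likelihood
        perm = rng.permutation(10)
        shuffled = tree_log_likelihood(
            tree, matrix_for(names, data[:, perm]), ep
        ).log_likelihood
        assert shuffled == pytest.approx(base, abs=1e-12)
        # relabel tips with matched matrix rows
        mapping = {"a": "x1", "b": "x2", "c": "x3", "d": "x4", "e": "x5"}
        for tip in tree.tips():
            tip.name = mapping[tip.name]
        renamed = tree_log_likelihood(
            tree, matrix_for([mapping[n] for n in names], data), ep
        ).log_likelihood
        assert renamed == pytest.approx(base, abs=1e-12)

    def test_unique_interior_maximum_in_rate(self):
        rng = np.random.default_rng(4)
        names = ["a", "b", "c", "d"]
        tree = random_tree(names, rng)
        data = rng.integers(0, 2, size=(4, 6)).astype(np.uint8)
        data[0, 0] = 1  # at least one observed event
        m = matrix_for(names, data)
        grid = np.logspace(-3, 1.5, 100)  # below the underflow regime
        ll = np.array(
            [
                tree_log_likelihood(
                    tree, m, EpochModel("off_on", -100.0, 1.0, lam)
                ).log_likelihood
                for lam in grid
            ]
        )
        k = int(np.argmax(ll))
        assert 0 < k < len(grid) - 1  # interior maximum
        # single peak: increasing then decreasing
        assert np.all(np.diff(ll[: k + 1]) >= -1e-9)
        assert np.all(np.diff(ll[k:]) <= 1e-9)

    def test_impossible_pattern_reports_neg_inf(self):
        # a character present in every tip with zero rate everywhere can
        # never arise from the all-zero LUCA
        a, b = TreeNode("a", 0.0), TreeNode("b", 0.0)
        root = TreeNode(time=-1.0)
        root.add_child(a)
        root.add_child(b)
        luca = TreeNode("LUCA", -2.0)
        luca.add_child(root)
        tree = SampledTree(luca)
        m = matrix_for(["a", "b"], np.ones((2, 1), dtype=np.uint8))
        ep = EpochModel("off_on", 0.0, 1e-5, 1e-5)
        ll = tree_log_likelihood(tree, m, ep)
        assert ll.log_likelihood < -10  # vanishing, tends to -inf with rate -> 0

    def test_single_tip_all_zero_closed_form(self):
        # one lineage, all-zero characters: log L = -(total intensity)
        a, b = TreeNode("a", 0.0), TreeNode("b", 0.0)
        root = TreeNode(time=-3.0)
        root.add_child(a)
        root.add_child(b)
        luca = TreeNode("LUCA", -5.0)
        luca.add_child(root)
        tree = SampledTree(luca)
        n_char = 6
        m = matrix_for(["a", "b"], np.zeros((2, n_char), dtype=np.uint8))
        lam = 2.0
        ep = EpochModel("off_on", 100.0, lam, 0.6)
        ll = tree_log_likelihood(tree, m, ep)
        total_years = 3.0 + 3.0 + 2.0
        assert ll.log_likelihood == pytest.approx(-lam * total_years, rel=1e-12)

    def test_luca_prior_reported_separately(self):
        a, b = TreeNode("a", 0.0), TreeNode("b", 0.0)
        root = TreeNode(time=-1.0)
        root.add_child(a)
        root.add_child(b)
        luca = TreeNode("LUCA", -4.0)
        luca.add_child(root)
        tree = SampledTree(luca)
        assert luca_branch_log_prior(tree, 3.0) == pytest.approx(
            -math.log(3.0) - 1.0
        )


class TestCoalescentDensity:
    def _contemporaneous_tree(self, ages):
        a, b, c = (TreeNode(nm, 0.0) for nm in "abc")
        n1 = TreeNode(time=-ages[0])
        n1.add_child(a)
        n1.add_child(b)
        n2 = TreeNode(time=-ages[1])
        n2.add_child(n1)
        n2.add_child(c)
        luca = TreeNode("LUCA", -380.0)
        luca.add_child(n2)
        return SampledTree(luca)

    def test_matches_constant_size_closed_form(self):
        d = LogisticDemography(K=20.0, N_t=20.0 - 1e-9, T_r=3650.0)
        tree = self._contemporaneous_tree([5.0, 30.0])
        N = 20.0
        closed = (-3.0 * 5.0 / N - math.log(N)) + (-(30.0 - 5.0) / N - math.log(N))
        got = logistic_coalescent_log_density(tree, d)
        assert got == pytest.approx(closed, abs=1e-8)

    def test_two_tip_textbook_form(self):
        d = LogisticDemography(K=50.0, N_t=50.0 - 1e-9, T_r=3650.0)
        a, b = TreeNode("a", 0.0), TreeNode("b", 0.0)
        root = TreeNode(time=-7.0)
        root.add_child(a)
        root.add_child(b)
        luca = TreeNode("LUCA", -500.0)
        luca.add_child(root)
        got = logistic_coalescent_log_density(SampledTree(luca), d)
        assert got == pytest.approx(-7.0 / 50.0 - math.log(50.0), abs=1e-8)

    def test_doubling_population_halves_intensity(self):
        tree = self._contemporaneous_tree([2.0, 6.0])
        d = LogisticDemography(K=40.0, N_t=40.0 - 1e-9, T_r=3650.0)
        single = logistic_coalescent_log_density(tree, d, pop_scale=1.0)
        double = logistic_coalescent_log_density(tree, d, pop_scale=2.0)
        # survival exponent halves; each coalescence factor gains log 2
        n_coal = 2
        hazard_single = -(single + n_coal * math.log(40.0))
        hazard_double = -(double + n_coal * math.log(80.0))
        assert hazard_double == pytest.approx(hazard_single / 2.0, rel=1e-9)
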