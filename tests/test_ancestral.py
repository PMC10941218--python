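import numpy as np
import pytest

import evoregion as ev
from evoregion.ancestral import (DiscreteCharacter, mk_transition_matrix,
                                 mk_marginal_posteriors)


@pytest.fixture
def balanced4():
    return ev.read_newick("((A:0.5,B:0.5):0.5,(C:0.7,D:0.7):0.3);")


def enumeration_loglik(rate, tip_idx, k=3):
    """Brute-force sum over all internal-state assignments of the fixed
    4-tip topology ((A,B),(C,D)) with the branch lengths of ``balanced4``."""
    def p(t):
        return mk_transition_matrix(k, rate, t)

    total = 0.0
    for r in range(k):
        for n1 in range(k):
            for n2 in range(k):
                pr = (1 / k) * p(0.5)[r, n1] * p(0.3)[r, n2]
                pr *= p(0.5)[n1, tip_idx["A"]] * p(0.5)[n1, tip_idx["B"]]
                pr *= p(0.7)[n2, tip_idx["C"]] * p(0.7)[n2, tip_idx["D"]]
                total += pr
    return np.log(total)


class TestMkLoglik:
    def test_two_tip_closed_form(self):
        t = ev.read_newick("(A:1,B:1);")
        char = DiscreteCharacter(tip_states={"A": "x", "B": "x"},
                                 states=["x", "y"])
        pm = mk_transition_matrix(2, 0.5, 1.0)
        expected = np.log(0.5 * (pm[0, 0] ** 2 + pm[1, 0] ** 2))
        assert ev.mk_loglik(t, char, 0.5) == pytest.approx(expected, abs=1e-10)

    def test_low_rate_limit_equal_states(self):
        t = ev.read_newick("(A:1,B:1);")
        char = DiscreteCharacter(tip_states={"A": "x", "B": "x"},
                                 states=["x", "y", "z"])
        assert ev.mk_loglik(t, char, 1e-9) == pytest.approx(np.log(1 / 3),
                                                            abs=1e-6)

    @pytest.mark.parametrize("rate", [0.2, 0.8, 2.5])
    @pytest.mark.parametrize("states", [
        {"A": "x", "B": "y", "C": "z", "D": "x"},
        {"A": "x", "B": "x", "C": "y", "D": "y"},
    ])
    def test_matches_enumeration(self, balanced4, rate, states):
        char = DiscreteCharacter(tip_states=states, states=["x", "y", "z"])
        idx = {sp: char.index_of(s) for sp, s in states.items()}
        assert ev.mk_loglik(balanced4, char, rate) == pytest.approx(
            enumeration_loglik(rate, idx), abs=1e-10)


def simulate_character(tree, rate, k, rng):
    """Independent forward simulation of the ER chain down the tree."""
    states = {}
    state_of = {id(tree.seed_node): int(rng.integers(k))}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        p = mk_transition_matrix(k, rate, node.edge.length)
        parent = state_of[id(node.parent_node)]
        state_of[id(node)] = int(rng.choice(k, p=p[parent]))
        if node.is_leaf():
            states[node.taxon.label] = "xyz"[state_of[id(node)]]
    return states


class TestFitMkRate:
    def test_recovery_from_simulated_data(self):
        rng = np.random.default_rng(0)
        hits = 0
        for trial in range(20):
            tree = ev.simulate_tree(64, seed=trial)
            # depth-1 tree; q = rate/(k-1) = 0.5 per off-diagonal, k=3
            true_rate = 1.0
            char = DiscreteCharacter(
                tip_states=simulate_character(tree, true_rate, 3, rng),
                states=["x", "y", "z"])
            if len(set(char.tip_states.values())) < 2:
                hits += 1  # uninformative draw; do not count against
                continue
            fit = ev.fit_mk_rate(tree, char)
            if 0.5 * true_rate <= fit <= 1.5 * true_rate:
                hits += 1
        assert hits >= 16  # 80% of trials

    def test_identical_states_pinned_low(self):
        t = ev.read_newick("(A:1,B:1);")
        char = DiscreteCharacter(tip_states={"A": "x", "B": "x"},
                                 states=["x", "y"])
        with pytest.warns(UserWarning):
            assert ev.fit_mk_rate(t, char) == pytest.approx(1e-6)

    def test_two_tips_different_states_finite(self):
        t = ev.read_newick("(A:1,B:1);")
        char = DiscreteCharacter(tip_states={"A": "x", "B": "y"},
                                 states=["x", "y"])
        fit = ev.fit_mk_rate(t, char)
        assert 1e-6 < fit < 1e3


@pytest.fixture
def six_tip():
    return ev.read_newick(
        "(((A:0.4,B:0.4):0.3,(C:0.5,D:0.5):0.2):0.3,(E:0.6,F:0.6):0.4);")


@pytest.fixture
def six_tip_char():
    return DiscreteCharacter(
        tip_states={"A": "x", "B": "x", "C": "y", "D": "x",
                    "E": "y", "F": "y"},
        states=["x", "y"])


class TestSimmap:
    def test_deterministic_per_seed(self, six_tip, six_tip_char):
        a = ev.simmap(six_tip, six_tip_char, rate=0.7, n_maps=10, seed=3)
        b = ev.simmap(six_tip, six_tip_char, rate=0.7, n_maps=10, seed=3)
        assert a.maps == b.maps

    def test_low_rate_monophyletic_clade(self):
        t = ev.read_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        char = DiscreteCharacter(
            tip_states={"A": "x", "B": "x", "C": "y", "D": "y"},
            states=["x", "y"])
        summ = ev.simmap(t, char, rate=1e-4, n_maps=200, seed=0)
        # the (A,B) ancestor is all but certainly in the clade's state
        node_post = summ.node_posteriors
        assert node_post["x"].max() >= 0.99

    def test_histories_consistent(self, six_tip, six_tip_char):
        summ = ev.simmap(six_tip, six_tip_char, rate=1.5, n_maps=20, seed=1)
        tips = {lf._mk_id: lf.taxon.label
                for lf in six_tip.leaf_node_iter()}
        edge_len = {nd._mk_id: nd.edge.length
                    for nd in six_tip.preorder_node_iter()
                    if nd.parent_node is not None}
        for m in summ.maps:
            for nid, segs in m.items():
                assert all(dt > 0 for _, dt in segs)
                assert sum(dt for _, dt in segs) == pytest.approx(
                    edge_len[nid], abs=1e-9)
                for (s1, _), (s2, _) in zip(segs, segs[1:]):
                    assert s1 != s2  # every jump is a real state change
                if nid in tips:  # history must end in the observed tip state
                    assert segs[-1][0] == six_tip_char.tip_states[tips[nid]]

    def test_matches_marginal_posteriors(self, six_tip, six_tip_char):
        rate = 0.8
        exact = mk_marginal_posteriors(six_tip, six_tip_char, rate)
        summ = ev.simmap(six_tip, six_tip_char, rate=rate, n_maps=2000, seed=2)
        mc = summ.node_posteriors.loc[exact.index]
        se = np.sqrt(exact * (1 - exact) / 2000).to_numpy()
        assert np.all(np.abs(mc.to_numpy() - exact.to_numpy())
                      <= 3 * se + 1e-12)

    def test_changes_nondecreasing_in_rate(self, six_tip, six_tip_char):
        means = []
        for rate in (0.2, 0.8, 2.0, 5.0):
            summ = ev.simmap(six_tip, six_tip_char, rate=rate, n_maps=500,
                             seed=4)
            means.append(summ.change_counts.mean())
        assert all(a <= b + 0.15 for a, b in zip(means, means[1:]))

    def test_posteriors_sum_to_one(self, six_tip, six_tip_char):
        summ = ev.simmap(six_tip, six_tip_char, rate=1.0, n_maps=50, seed=0)
        assert np.allclose(summ.node_posteriors.sum(axis=1), 1.0, atol=1e-9)
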