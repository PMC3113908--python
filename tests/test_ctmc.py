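import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from ancstate.coding import builtin_scheme
from ancstate.ctmc import (
    ConstrainedRateMatrix,
    NodeConstraint,
    all_node_marginals,
    enumeration_loglik,
    marginal_node_probs,
    prune_loglik,
    transition_matrices,
    transition_matrix,
)
from ancstate.phylo import CladeQuery, Phylogeny
from ancstate.simulate import enumerate_topologies
from conftest import binary_scheme, random_constrained_scheme


def random_instance(rng, n_tips=None, k=None, absorbing=None, constrain=True):
    """Random (tree, Q, scheme, constraints) oracle instance."""
    n_tips = n_tips or int(rng.integers(2, 8))
    k = k or int(rng.integers(2, 6))
    absorbing = rng.uniform() < 0.3 if absorbing is None else absorbing
    topos = enumerate_topologies(n_tips)
    base = topos[rng.integers(len(topos))]
    tree = Phylogeny(base.parent, rng.uniform(0.05, 1.5, base.n_nodes), base.tip_labels)
    scheme = random_constrained_scheme(rng, k, n_tips, absorbing=absorbing)
    Q = ConstrainedRateMatrix.from_free(
        scheme.mask, rng.uniform(0.1, 3.0, scheme.mask.n_allowed)
    )
    constraints = None
    if constrain and rng.uniform() < 0.4 and n_tips >= 3:
        taxa = [f"t{i + 1}" for i in rng.choice(n_tips, size=2, replace=False)]
        n_states = int(rng.integers(1, k + 1))
        states = [scheme.space.abbrevs[s] for s in rng.choice(k, n_states, replace=False)]
        constraints = NodeConstraint({CladeQuery(taxa, "c"): states})
    return tree, Q, scheme, constraints


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, rng):
        s = builtin_scheme("traditional")
        Q = ConstrainedRateMatrix.from_free(s.mask, rng.uniform(0, 5, 7))
        np.testing.assert_array_equal(transition_matrix(Q, 0.0), np.eye(4))

    def test_negative_time_rejected(self):
        s = builtin_scheme("traditional")
        Q = ConstrainedRateMatrix.from_free(s.mask, np.ones(7))
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)

    def test_absorbing_row_stays_indicator(self, rng):
        s = builtin_scheme("traditional")
        Q = ConstrainedRateMatrix.from_free(s.mask, rng.uniform(0.5, 2, 7))
        adv = s.space.index("Adv")
        for t in (0.1, 1.0, 10.0):
            P = transition_matrix(Q, t)
            expected = np.zeros(4)
            expected[adv] = 1.0
            np.testing.assert_allclose(P[adv], expected, atol=1e-12)

    def test_two_state_symmetric_closed_form(self):
        # stay probability (1 + e^{-2rt})/2 for symmetric rate r
        scheme = binary_scheme({"X": "0", "Y": "1"})
        Q = ConstrainedRateMatrix.from_free(scheme.mask, [1.0, 1.0])
        P = transition_matrix(Q, 0.5)
        assert P[0, 0] == pytest.approx(0.5 * (1 + np.exp(-1.0)), abs=1e-12)
        assert P[0, 0] == pytest.approx(0.68394, abs=1e-5)

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            _, Q, _, _ = random_instance(rng)
            P = transition_matrix(Q, float(rng.uniform(0, 4)))
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert P.min() >= 0 and P.max() <= 1

    def test_batch_matches_expm(self, rng):
        for _ in range(20):
            _, Q, _, _ = random_instance(rng)
            ts = np.concatenate([[0.0], rng.uniform(0, 3, 10)])
            P = transition_matrices(Q, ts)
            for i, t in enumerate(ts):
                np.testing.assert_allclose(P[i], expm(Q.Q * t), atol=1e-10)

    def test_forbidden_single_step_multi_step_allowed(self):
        # Sol -> Adv is structurally zero in Q yet P(t) can route via Prim
        s = builtin_scheme("traditional")
        Q = ConstrainedRateMatrix.from_free(s.mask, np.ones(7))
        assert Q.Q[0, 2] == 0.0
        assert transition_matrix(Q, 1.0)[0, 2] > 0


class TestRateMatrix:
    def test_forbidden_cell_rejected(self):
        s = builtin_scheme("traditional")
        rates = np.zeros((4, 4))
        rates[0, 2] = 1.0  # Sol -> Adv is forbidden
        with pytest.raises(ValueError, match="forbidden"):
            ConstrainedRateMatrix(s.mask, rates)

    def test_negative_rate_rejected(self):
        s = builtin_scheme("traditional")
        with pytest.raises(ValueError):
            ConstrainedRateMatrix.from_free(s.mask, [-1] + [1] * 6)

    def test_rows_sum_to_zero(self, rng):
        s = builtin_scheme("complex")
        Q = ConstrainedRateMatrix.from_free(s.mask, rng.uniform(0, 2, 14))
        np.testing.assert_allclose(Q.Q.sum(axis=1), 0.0, atol=1e-14)
        assert np.array_equal(Q.free_values(), Q.free_values())


class TestPruneLoglik:
    def test_all_ambiguous_tips_likelihood_one(self, rng):
        tree = Phylogeny.from_newick("(X:0.7,Y:1.3);")
        scheme = binary_scheme({"X": "-", "Y": "-"})
        Q = ConstrainedRateMatrix.from_free(scheme.mask, rng.uniform(0, 3, 2))
        assert prune_loglik(tree, Q, scheme) == pytest.approx(0.0, abs=1e-12)

    def test_root_fossilized_to_absorbing_with_other_tip(self):
        s = builtin_scheme("traditional", tips={"a": "0", "b": "3"})
        tree = Phylogeny.from_newick("(a:1,b:1);")
        Q = ConstrainedRateMatrix.from_free(s.mask, np.ones(7))
        cons = NodeConstraint({CladeQuery({"a", "b"}, "root"): ("Adv",)})
        assert prune_loglik(tree, Q, s, None, cons) == -np.inf

    def test_matches_enumeration_random_sweep(self, rng):
        for _ in range(60):
            tree, Q, scheme, cons = random_instance(rng)
            l1 = prune_loglik(tree, Q, scheme, None, cons)
            l2 = enumeration_loglik(tree, Q, scheme, None, cons)
            if np.isneginf(l1) or np.isneginf(l2):
                assert l1 == l2
            else:
                assert l1 == pytest.approx(l2, abs=1e-10)

    def test_child_order_invariance(self, rng):
        tree, Q, scheme, _ = random_instance(rng, n_tips=5, constrain=False)
        swapped = Phylogeny(tree.parent, tree.brlen, tree.tip_labels)
        for v in range(swapped.n_nodes):
            swapped.children[v] = swapped.children[v][::-1]
        # rebuild flat arrays after the swap
        swapped = Phylogeny(tree.parent, tree.brlen, tree.tip_labels)
        assert prune_loglik(tree, Q, scheme) == pytest.approx(
            prune_loglik(swapped, Q, scheme), abs=1e-12
        )

    def test_state_relabeling_invariance(self, rng):
        from ancstate.coding import CodingScheme, StateSpace, TipStateMap, TransitionConstraintMask

        tree, Q, scheme, _ = random_instance(rng, n_tips=4, k=3, constrain=False)
        perm = rng.permutation(3)
        inv = np.argsort(perm)
        space2 = StateSpace([scheme.space.states[i] for i in perm])
        mask2 = TransitionConstraintMask(space2, scheme.mask.allowed[np.ix_(perm, perm)])
        tips2 = TipStateMap(space2)
        for taxon, states in scheme.tips.items():
            tips2.set_states(taxon, [int(inv[s]) for s in states])
        scheme2 = CodingScheme("perm", space2, tips2, mask2)
        Q2 = ConstrainedRateMatrix(mask2, Q.rates[np.ix_(perm, perm)])
        assert prune_loglik(tree, Q, scheme) == pytest.approx(
            prune_loglik(tree, Q2, scheme2), abs=1e-10
        )

    def test_ambiguity_never_decreases_likelihood(self, rng):
        for _ in range(10):
            tree, Q, scheme, _ = random_instance(rng, constrain=False)
            base = prune_loglik(tree, Q, scheme)
            taxon = tree.tip_labels[rng.integers(tree.n_tips)]
            enlarged = set(scheme.tips[taxon]) | {int(rng.integers(scheme.space.k))}
            scheme.tips.set_states(taxon, sorted(enlarged))
            wider = prune_loglik(tree, Q, scheme)
            assert wider >= base - 1e-10

    def test_rate_time_scaling_identity(self, rng):
        tree, Q, scheme, _ = random_instance(rng, n_tips=5, constrain=False)
        c = 3.7
        Qc = ConstrainedRateMatrix(Q.mask, Q.rates * c)
        scaled = Phylogeny(tree.parent, tree.brlen / c, tree.tip_labels)
        assert prune_loglik(tree, Q, scheme) == pytest.approx(
            prune_loglik(scaled, Qc, scheme), abs=1e-10
        )

    def test_zero_length_branch_exact_identity(self, rng):
        tree = Phylogeny.from_newick("((X:0.0,Y:0.5):0.3,Z:1);")
        scheme = binary_scheme({"X": "0", "Y": "1", "Z": "0"})
        Q = ConstrainedRateMatrix.from_free(scheme.mask, [1.2, 0.7])
        assert prune_loglik(tree, Q, scheme) == pytest.approx(
            enumeration_loglik(tree, Q, scheme), abs=1e-12
        )


class TestEnumeration:
    def test_two_tip_hand_sum(self):
        # one-way A->B character, tips X=A, Y=B, both branches length 1
        tree = Phylogeny.from_newick("(X:1,Y:1);")
        scheme = binary_scheme({"X": "0", "Y": "1"}, one_way=True)
        r = 0.8
        Q = ConstrainedRateMatrix.from_free(scheme.mask, [r])
        # root A: stays A on X branch (e^-r), becomes B on Y branch (1-e^-r);
        # root B: cannot produce tip X=A (B is absorbing in the one-way model)
        manual = 0.5 * np.exp(-r) * (1 - np.exp(-r))
        assert enumeration_loglik(tree, Q, scheme) == pytest.approx(np.log(manual), abs=1e-12)
        assert prune_loglik(tree, Q, scheme) == pytest.approx(np.log(manual), abs=1e-12)

    def test_fossilized_equals_restricted_sum(self, rng):
        tree, Q, scheme, _ = random_instance(rng, n_tips=4, k=3, constrain=False)
        q = CladeQuery(tree.tip_labels[:2], "pair")
        free = enumeration_loglik(tree, Q, scheme)
        parts = []
        for s in range(3):
            cons = NodeConstraint({q: (scheme.space.abbrevs[s],)})
            parts.append(enumeration_loglik(tree, Q, scheme, None, cons))
        total = np.logaddexp.reduce([p for p in parts if np.isfinite(p)])
        assert total == pytest.approx(free, abs=1e-10)

    def test_refuses_large_trees(self, rng):
        # 14-tip caterpillar: 13 internal nodes, over the 12-node enumeration cap
        nwk = "t1:1"
        for i in range(2, 15):
            nwk = f"({nwk},t{i}:1):1"
        tree = Phylogeny.from_newick(nwk[:-2] + ";")
        assert tree.n_nodes - tree.n_tips == 13
        scheme = random_constrained_scheme(rng, 2, 14, polymorphic=False)
        Q = ConstrainedRateMatrix.from_free(scheme.mask, np.ones(scheme.mask.n_allowed))
        with pytest.raises(ValueError, match="12 internal nodes"):
            enumeration_loglik(tree, Q, scheme)


class TestMarginals:
    def test_sum_to_one_and_match_enumeration(self, rng):
        for _ in range(15):
            tree, Q, scheme, _ = random_instance(rng, n_tips=4, k=3, constrain=False)
            q = CladeQuery(tree.tip_labels[:2], "pair")
            try:
                probs = marginal_node_probs(tree, Q, scheme, None, q)
            except ValueError:
                continue  # inconsistent data/mask combination
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)
            logs = []
            for s in range(3):
                cons = NodeConstraint({q: (scheme.space.abbrevs[s],)})
                logs.append(enumeration_loglik(tree, Q, scheme, None, cons))
            logs = np.array(logs)
            finite = np.isfinite(logs)
            expected = np.zeros(3)
            expected[finite] = np.exp(logs[finite] - logs[finite].max())
            expected /= expected.sum()
            np.testing.assert_allclose(probs, expected, atol=1e-9)

    def test_fossilized_node_is_indicator(self, rng):
        tree, Q, scheme, _ = random_instance(rng, n_tips=5, k=4, constrain=False)
        q = CladeQuery(tree.tip_labels[:2], "pair")
        target = scheme.space.abbrevs[1]
        cons = NodeConstraint({q: (target,)})
        probs = marginal_node_probs(tree, Q, scheme, None, q, cons)
        expected = np.zeros(4)
        expected[1] = 1.0
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_downpass_agrees_with_fossilization(self, rng):
        from ancstate.phylo import mrca

        for _ in range(10):
            tree, Q, scheme, cons = random_instance(rng, constrain=True)
            try:
                marg = all_node_marginals(tree, Q, scheme, None, cons)
            except ValueError:
                continue
            for taxa in itertools.combinations(tree.tip_labels, 2):
                q = CladeQuery(taxa, "q")
                node = mrca(tree, q)
                np.testing.assert_allclose(
                    marg[node],
                    marginal_node_probs(tree, Q, scheme, None, q, cons),
                    atol=1e-9,
                )

    def test_impossible_everywhere_raises(self):
        s = builtin_scheme("traditional", tips={"a": "0", "b": "3"})
        tree = Phylogeny.from_newick("(a:1,b:1);")
        Q = ConstrainedRateMatrix.from_free(s.mask, np.ones(7))
        cons = NodeConstraint({CladeQuery({"a", "b"}, "r"): ("Adv",)})
        with pytest.raises(ValueError, match="inconsistent"):
            marginal_node_probs(
                tree, Q, s, None, CladeQuery({"a", "b"}, "r2"), cons
            )
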