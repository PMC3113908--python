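import numpy as np
import pytest

from ancstate.coding import builtin_scheme, read_trait_file, tip_partial, write_trait_file
from ancstate.ctmc import ConstrainedRateMatrix, prune_loglik
from ancstate.phylo import mrca, node_age
from ancstate.simulate import (
    SimConfig,
    enumerate_topologies,
    make_apid_fixture,
    make_tree_sample,
    add_polymorphism,
    random_rates,
    read_ground_truth,
    simulate_dataset,
    simulate_history,
    simulate_lineages_through_time,
    simulate_tree,
    write_ground_truth,
)
from conftest import binary_scheme


class TestSimulateTree:
    def test_exact_tip_count_and_ultrametric(self, rng):
        for n in (2, 10, 50):
            t = simulate_tree(SimConfig(seed=int(rng.integers(2**31)), n_tips=n))
            assert t.n_tips == n
            d = t.depths()[: t.n_tips]
            assert d.max() - d.min() < 1e-6 * max(d.max(), 1.0)

    def test_pure_birth_two_tips_single_split(self):
        t = simulate_tree(SimConfig(seed=5, n_tips=2, death=0.0))
        assert t.n_tips == 2 and t.n_nodes == 3
        assert t.brlen[0] == pytest.approx(t.brlen[1])

    def test_depth_rescaled(self):
        t = simulate_tree(SimConfig(seed=9, n_tips=20, depth=87.0))
        assert t.depth() == pytest.approx(87.0)

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, birth=0.5, death=0.5)

    def test_lineage_growth_matches_birth_death_expectation(self, rng):
        # E[N(t)] = e^{(b-d)t} for a linear birth-death process from one lineage
        b, d, t_max = 1.0, 0.4, 2.0
        counts = [
            simulate_lineages_through_time(b, d, t_max, rng) for _ in range(500)
        ]
        expected = np.exp((b - d) * t_max)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(expected, abs=3 * se + 1e-9)


class TestSimulateHistory:
    def test_zero_rates_inherit_root_state(self, rng):
        scheme = builtin_scheme("traditional")
        tree = simulate_tree(SimConfig(seed=3, n_tips=10))
        Q = ConstrainedRateMatrix.from_free(scheme.mask, np.zeros(7))
        states, events, tips = simulate_history(tree, Q, "Prim", rng)
        assert set(states.tolist()) == {scheme.space.index("Prim")}
        assert all(len(e) == 0 for e in events)

    def test_absorbing_state_never_left(self, rng):
        scheme = builtin_scheme("traditional")
        adv = scheme.space.index("Adv")
        tree = simulate_tree(SimConfig(seed=4, n_tips=200, depth=5.0))
        Q = random_rates(scheme, rng, 1.0, 4.0)
        _, events, _ = simulate_history(tree, Q, "Prim", rng)
        for ev in events:
            entered = False
            for _, frm, to in ev:
                assert not entered, "event after entering the absorbing state"
                assert frm != adv
                if to == adv:
                    entered = True

    def test_no_forbidden_transition_ever(self, rng):
        # sweep over random constrained matrices and branches
        from conftest import random_constrained_scheme

        for _ in range(30):
            k = int(rng.integers(2, 6))
            scheme = random_constrained_scheme(rng, k, 4, polymorphic=False)
            reachable = sorted(scheme.mask.reachable_from({0}))
            tree = simulate_tree(SimConfig(seed=int(rng.integers(2**31)), n_tips=4))
            Q = random_rates(scheme, rng, 0.5, 5.0)
            _, events, _ = simulate_history(tree, Q, 0, rng)
            for ev in events:
                for _, frm, to in ev:
                    assert scheme.mask.allowed[frm, to]

    def test_two_state_stay_probability(self, rng):
        # closed form: P(stay) = (1 + e^{-2rt})/2 at rate 1, t=0.5 -> 0.68394
        from ancstate.phylo import Phylogeny

        n = 100_000
        parent = np.concatenate([np.full(n, n, dtype=np.int64), [-1]])
        brlen = np.concatenate([np.full(n, 0.5), [0.0]])
        star = Phylogeny(parent, brlen, [f"t{i}" for i in range(n)])
        scheme = binary_scheme({f"t{i}": "0" for i in range(n)})
        Q = ConstrainedRateMatrix.from_free(scheme.mask, [1.0, 1.0])
        states, _, _ = simulate_history(star, Q, 0, rng)
        stay = np.mean(states[:n] == 0)
        p = 0.5 * (1 + np.exp(-1.0))
        mc_sd = np.sqrt(p * (1 - p) / n)
        assert stay == pytest.approx(p, abs=3 * mc_sd)


class TestTreeSampleJitter:
    def test_zero_jitter_identical(self, rng):
        t = simulate_tree(SimConfig(seed=6, n_tips=8))
        sample = make_tree_sample(t, 10, 0.0, rng)
        for s in sample.trees:
            np.testing.assert_array_equal(s.brlen, t.brlen)

    def test_sample_size(self, rng):
        t = simulate_tree(SimConfig(seed=6, n_tips=5))
        assert len(make_tree_sample(t, 200, 0.1, rng)) == 200

    def test_lognormal_mean_inflation(self, rng):
        t = simulate_tree(SimConfig(seed=6, n_tips=5))
        sigma = 0.4
        n = 2000
        sample = make_tree_sample(t, n, sigma, rng)
        keep = (t.parent >= 0) & (t.brlen > 0)
        per_tree_mean = np.array([s.brlen[keep].mean() for s in sample.trees])
        expected = t.brlen[keep].mean() * np.exp(sigma**2 / 2)
        se = per_tree_mean.std(ddof=1) / np.sqrt(n)
        assert per_tree_mean.mean() == pytest.approx(expected, abs=3 * se)


class TestPolymorphism:
    def test_prob_zero_identity(self, rng):
        scheme = builtin_scheme("traditional", tips={"a": "0", "b": "3"})
        out = add_polymorphism(scheme.tips, 0.0, rng, scheme)
        assert out == scheme.tips

    def test_prob_one_everything_polymorphic(self, rng):
        scheme = builtin_scheme(
            "traditional", tips={f"t{i}": s for i, s in enumerate("0234" * 3)}
        )
        out = add_polymorphism(scheme.tips, 1.0, rng, scheme)
        assert all(len(v) >= 2 for v in out.values())

    def test_added_state_is_mask_adjacent(self, rng):
        scheme = builtin_scheme("traditional", tips={f"t{i}": "0" for i in range(50)})
        out = add_polymorphism(scheme.tips, 1.0, rng, scheme)
        allowed = scheme.mask.allowed
        for states in out.values():
            extra = set(states) - {0}
            for s in extra:
                assert allowed[0, s] or allowed[s, 0]

    def test_polymorphism_never_decreases_likelihood(self, rng):
        ds = simulate_dataset(SimConfig(seed=21, n_tips=12, polymorphism=0.0))
        base = prune_loglik(ds.tree, ds.true_rates, ds.scheme)
        wider_tips = add_polymorphism(ds.scheme.tips, 0.5, rng, ds.scheme)
        scheme2 = builtin_scheme("traditional")
        for taxon, states in wider_tips.items():
            scheme2.tips.set_states(taxon, sorted(states))
        assert prune_loglik(ds.tree, ds.true_rates, scheme2) >= base - 1e-10


class TestApidFixture:
    def test_codings_match_study_design(self):
        fx = make_apid_fixture()
        trad, cplx = fx.schemes["traditional"], fx.schemes["complex"]
        np.testing.assert_array_equal(tip_partial("Apini_1", trad), [0, 0, 1, 0])
        np.testing.assert_array_equal(tip_partial("Meliponini_2", trad), [0, 0, 1, 0])
        np.testing.assert_array_equal(tip_partial("Ceratina_1", cplx), [1, 1, 1, 0, 0])
        np.testing.assert_array_equal(tip_partial("Xylocopa_1", cplx), [1, 1, 0, 0, 0])
        np.testing.assert_array_equal(tip_partial("Allodapini_1", cplx), [0, 1, 1, 0, 0])
        np.testing.assert_array_equal(tip_partial("Nomada_1", cplx), [0, 0, 0, 0, 1])

    def test_chronogram_clade_ages(self):
        fx = make_apid_fixture()
        ages = {
            q.label: node_age(fx.chronogram, mrca(fx.chronogram, q)) for q in fx.queries
        }
        assert ages["Corbiculates"] == pytest.approx(87.0)
        assert ages["Meliponini"] == pytest.approx(58.0)
        assert ages["Allodapini"] == pytest.approx(53.0)

    def test_queries_resolve_in_every_sampled_tree(self):
        fx = make_apid_fixture(sample_size=10)
        for t in fx.tree_sample.trees:
            for q in fx.queries:
                mrca(t, q)

    def test_trait_file_roundtrip(self, tmp_path):
        fx = make_apid_fixture()
        for name, scheme in fx.schemes.items():
            p = tmp_path / f"{name}.tsv"
            write_trait_file(scheme.tips, p)
            assert read_trait_file(p, scheme.space) == scheme.tips

    def test_deterministic(self):
        a, b = make_apid_fixture(), make_apid_fixture()
        assert a.tree.to_newick() == b.tree.to_newick()
        assert all(
            x.to_newick() == y.to_newick()
            for x, y in zip(a.tree_sample.trees, b.tree_sample.trees)
        )


class TestEnumerateTopologies:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_double_factorial_counts(self, n, count):
        topos = enumerate_topologies(n)
        assert len(topos) == count

    def test_distinct_and_fully_resolved(self):
        seen = set()
        for t in enumerate_topologies(4):
            assert t.n_tips == 4 and t.n_nodes == 7  # binary: n-1 internals
            key = _topology_key(t)
            assert key not in seen
            seen.add(key)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_topologies(1)
        with pytest.raises(ValueError):
            enumerate_topologies(8)


def _topology_key(tree):
    def clade(v):
        if v < tree.n_tips:
            return (tree.tip_labels[v],)
        return tuple(sorted(sum((clade(c) for c in tree.children[v]), ())))

    def shape(v):
        if v < tree.n_tips:
            return tree.tip_labels[v]
        return tuple(sorted((shape(c) for c in tree.children[v]), key=repr))

    return repr(shape(tree.root))


class TestDatasetReproducibility:
    def test_same_config_same_dataset(self):
        cfg = SimConfig(seed=33, n_tips=15, sample_size=5)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.scheme.tips == b.scheme.tips
        np.testing.assert_array_equal(a.true_rates.rates, b.true_rates.rates)
        np.testing.assert_array_equal(a.node_states, b.node_states)

    def test_ground_truth_sidecar_roundtrip(self, tmp_path):
        ds = simulate_dataset(SimConfig(seed=8, n_tips=10))
        p = tmp_path / "truth.yaml"
        write_ground_truth(ds, p)
        doc = read_ground_truth(p)
        assert doc["root_state"] == ds.root_state
        np.testing.assert_allclose(doc["free_rates"], ds.true_rates.free_values())
        assert doc["node_states"] == [int(s) for s in ds.node_states]


class TestStrongSignalDataset:
    def test_conditioned_on_root_signal_and_deterministic(self):
        from ancstate.ctmc import marginal_node_probs
        from ancstate.phylo import CladeQuery
        from ancstate.simulate import simulate_strong_signal_dataset

        data, Q = simulate_strong_signal_dataset(424242)
        tree = data["tree_sample"][0]
        pp = marginal_node_probs(
            tree, Q, data["scheme"], None, CladeQuery(tree.tip_labels, "root")
        )
        assert pp[data["scheme"].space.index("Prim")] >= 0.99
        data2, _ = simulate_strong_signal_dataset(424242)
        assert tree.to_newick() == data2["tree_sample"][0].to_newick()
        assert data["scheme"].tips == data2["scheme"].tips
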