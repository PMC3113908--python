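"""Synthetic data with known ground truth for every stage of the pipeline.

Generates birth-death trees, pseudo-posterior tree samples (branch-length
jitter emulating the spread of a Bayesian posterior sample), character
histories simulated under a constrained rate matrix (Gillespie along each
branch, so forbidden transitions can never occur by construction), polymorphic
tip codings, and a deterministic apid-like fixture whose clades mirror the
corbiculate study design (orchid bees solitary, bumble bees primitively
eusocial, honey/stingless bees advanced eusocial, parasitic clades, and the
polymorphic carpenter-bee/allodapine codings).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import yaml
from dendropy.simulate import treesim

from .coding import CodingScheme, TipStateMap, builtin_scheme
from .ctmc import ConstrainedRateMatrix
from .phylo import CladeQuery, Phylogeny, TreeSample

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_history",
    "make_tree_sample",
    "add_polymorphism",
    "simulate_dataset",
    "make_apid_fixture",
    "ApidFixture",
    "enumerate_topologies",
    "random_rates",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class SimConfig:
    """Study-condition knobs for a synthetic dataset.

    Defaults emulate a desk-scale version of a posterior-sample analysis:
    a 100-tip birth-death tree rescaled to unit depth, a 100-tree
    pseudo-posterior with mild branch-length spread, and a 10% chance per tip
    of a polymorphic coding.
    """

    seed: int = 0
    n_tips: int = 100
    birth: float = 1.0
    death: float = 0.3
    depth: float = 1.0          # rescale the tree to this root-to-tip depth
    sample_size: int = 100      # pseudo-posterior tree count
    jitter: float = 0.1         # log-normal sigma of branch-length spread
    polymorphism: float = 0.1   # per-tip probability of an added adjacent state
    root_state: str = "Prim"
    rates: np.ndarray | None = None  # free-rate vector; None = draw in rate_range
    rate_range: tuple = (0.5, 5.0)

    def __post_init__(self):
        if self.birth <= self.death or self.death < 0:
            raise ValueError("need birth > death >= 0")
        if self.jitter < 0 or not (0 <= self.polymorphism <= 1):
            raise ValueError("jitter must be >= 0 and polymorphism in [0, 1]")


@dataclass
class SimulatedDataset:
    """A synthetic dataset plus its full generating truth."""

    tree: Phylogeny
    tree_sample: TreeSample
    scheme: CodingScheme          # tips filled with the simulated codings
    true_rates: ConstrainedRateMatrix
    root_state: str
    node_states: np.ndarray       # true state index at every node of `tree`
    events: list                  # per node: [(time-on-branch, from, to), ...]
    config: SimConfig | None = None


def random_scheme(rng, k: int, n_tips: int, absorbing: bool = False,
                  polymorphic: bool = True) -> CodingScheme:
    """Random state space, constraint mask and tip codings (for oracle sweeps).

    Keeps a random ~70% of off-diagonal cells, optionally making the last
    state absorbing. Connectivity is not enforced: zero-likelihood instances
    are legitimate cases the likelihood paths must agree on.
    """
    from .coding import State, StateSpace, TipStateMap, TransitionConstraintMask

    space = StateSpace([State(f"state{i}", f"S{i}", str(i)) for i in range(k)])
    while True:
        allowed = rng.uniform(size=(k, k)) < 0.7
        np.fill_diagonal(allowed, False)
        if absorbing:
            allowed[k - 1, :] = False
        if allowed.sum() >= 1:
            break
    mask = TransitionConstraintMask(space, allowed)
    tips = TipStateMap(space)
    for i in range(n_tips):
        if polymorphic and rng.uniform() < 0.3:
            size = int(rng.integers(2, k + 1))
            states = rng.choice(k, size=size, replace=False)
        else:
            states = [int(rng.integers(k))]
        tips.set_states(f"t{i + 1}", [int(s) for s in states])
    return CodingScheme("random", space, tips, mask)


def random_rates(scheme: CodingScheme, rng, lo: float = 0.5, hi: float = 5.0):
    """Uniform random free rates on the scheme's allowed cells."""
    return ConstrainedRateMatrix.from_free(
        scheme.mask, rng.uniform(lo, hi, scheme.mask.n_allowed)
    )


# ---------------------------------------------------------------------------
# trees


def simulate_tree(config: SimConfig, rng=None, max_attempts: int = 100) -> Phylogeny:
    """Complete birth-death tree conditioned on ``n_tips`` extant survivors.

    Extinct lineages are pruned (dendropy's forward simulator), so the result
    is ultrametric; it is then rescaled to ``config.depth``.
    """
    seed = config.seed if rng is None else int(rng.integers(2**31))
    for attempt in range(max_attempts):
        try:
            dtree = treesim.birth_death_tree(
                birth_rate=config.birth,
                death_rate=config.death,
                num_extant_tips=config.n_tips,
                rng=random.Random(seed + attempt),
            )
            break
        except Exception:
            continue
    else:
        raise RuntimeError(
            f"birth-death simulation failed to reach {config.n_tips} tips "
            f"in {max_attempts} attempts"
        )
    tree = Phylogeny.from_dendropy(dtree)
    d = tree.depth()
    if d > 0 and config.depth:
        tree = Phylogeny(tree.parent, tree.brlen * (config.depth / d), tree.tip_labels)
    return tree


def simulate_lineages_through_time(
    birth: float, death: float, t_max: float, rng
) -> int:
    """Number of surviving lineages of a linear birth-death process at ``t_max``.

    Small exact Gillespie forward simulation from one lineage; used to check
    the e^{(b-d)t} expectation of the generator.
    """
    n, t = 1, 0.0
    while n > 0:
        total = n * (birth + death)
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        n += 1 if rng.uniform() < birth / (birth + death) else -1
    return n


def make_tree_sample(tree: Phylogeny, size: int, jitter: float, rng) -> TreeSample:
    """``size`` copies of ``tree`` with branch lengths jittered by log-normal(0, jitter) factors.

    Emulates the branch-length spread of a post-burnin posterior tree sample;
    topology is kept fixed so MRCA queries resolve identically in every tree.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    trees = []
    for _ in range(size):
        if jitter == 0:
            trees.append(Phylogeny(tree.parent, tree.brlen.copy(), tree.tip_labels))
        else:
            f = rng.lognormal(0.0, jitter, tree.n_nodes)
            f[tree.root] = 1.0
            trees.append(Phylogeny(tree.parent, tree.brlen * f, tree.tip_labels))
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# character histories


def simulate_history(tree: Phylogeny, Q: ConstrainedRateMatrix, root_state, rng):
    """Gillespie simulation of the character along every branch.

    Returns ``(node_states, events, tips)``: the true state index at every
    node, the per-node event list ``(time, from, to)`` on the branch above the
    node, and a single-state TipStateMap. Waiting times are exponential with
    rate ``-q_ss``; jumps go to ``j`` with probability ``q_sj / -q_ss`` — a
    forbidden transition therefore has probability exactly 0.
    """
    space = Q.space
    s0 = root_state if isinstance(root_state, (int, np.integer)) else space.index(root_state)
    Qm = Q.Q
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_states[tree.root] = s0
    events = [[] for _ in range(tree.n_nodes)]
    for v in tree.postorder[::-1]:  # preorder: parent state known first
        p = tree.parent[v]
        if p < 0:
            continue
        s = node_states[p]
        t, t_end = 0.0, float(tree.brlen[v])
        while True:
            out_rate = -Qm[s, s]
            if out_rate <= 0.0:
                break
            t += rng.exponential(1.0 / out_rate)
            if t >= t_end:
                break
            probs = np.clip(Qm[s], 0.0, None)
            probs[s] = 0.0
            j = int(rng.choice(len(probs), p=probs / probs.sum()))
            events[v].append((t, int(s), j))
            s = j
        node_states[v] = s
    tips = TipStateMap(space)
    for i, lab in enumerate(tree.tip_labels):
        tips.set_states(lab, [int(node_states[i])])
    return node_states, events, tips


def add_polymorphism(
    tips: TipStateMap, prob: float, rng, scheme: CodingScheme
) -> TipStateMap:
    """With probability ``prob`` per tip, add one mask-adjacent state to its coding.

    Adjacency means an allowed transition in either direction, so synthetic
    polymorphic codings stay coherent with the transition graph. Tips whose
    states have no un-coded neighbour are left unchanged.
    """
    if not 0 <= prob <= 1:
        raise ValueError("prob must be in [0, 1]")
    allowed = scheme.mask.allowed
    out = TipStateMap(tips.space)
    for taxon, states in tips.items():
        states = set(states)
        if prob > 0 and rng.uniform() < prob:
            nbrs = set()
            for s in states:
                nbrs |= {j for j in range(tips.space.k) if allowed[s, j] or allowed[j, s]}
            nbrs -= states
            if nbrs:
                states.add(int(rng.choice(sorted(nbrs))))
        out.set_states(taxon, sorted(states))
    return out


def simulate_dataset(config: SimConfig, scheme_name: str = "traditional") -> SimulatedDataset:
    """End-to-end generator: tree, pseudo-posterior sample, history, codings.

    Fully determined by ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    scheme = builtin_scheme(scheme_name)
    tree = simulate_tree(config, rng)
    if config.rates is not None:
        Q = ConstrainedRateMatrix.from_free(scheme.mask, config.rates)
    else:
        Q = random_rates(scheme, rng, *config.rate_range)
    node_states, events, tips = simulate_history(tree, Q, config.root_state, rng)
    tips = add_polymorphism(tips, config.polymorphism, rng, scheme)
    for taxon in tips:
        scheme.tips.set_states(taxon, sorted(tips[taxon]))
    sample = make_tree_sample(tree, config.sample_size, config.jitter, rng)
    return SimulatedDataset(
        tree=tree,
        tree_sample=sample,
        scheme=scheme,
        true_rates=Q,
        root_state=scheme.space.abbrevs[
            config.root_state
            if isinstance(config.root_state, int)
            else scheme.space.index(config.root_state)
        ],
        node_states=node_states,
        events=events,
        config=config,
    )


def simulate_strong_signal_dataset(
    seed: int,
    n_tips: int = 100,
    rate: float = 0.1,
    root_state: str = "Prim",
    min_root_pp: float = 0.99,
    max_attempts: int = 30,
):
    """A dataset defined to carry strong root-state signal.

    Simulates a slow 4-state character (all cells of a fully connected mask at
    ``rate``) from ``root_state`` on ``n_tips``-tip unit-depth trees, and
    accepts the first draw whose marginal root probability at the generating
    parameters reaches ``min_root_pp`` — i.e. the study population is
    *conditioned* on the signal being present, since the amount of change a
    birth-death tree accumulates varies widely between draws. Returns
    ``(data, Q)`` where ``data`` is the ``{tree_sample, scheme}`` mapping the
    sampler consumes.
    """
    from .coding import load_scheme
    from .ctmc import marginal_node_probs

    base = builtin_scheme("traditional")
    states = [[s.name, s.abbrev, s.symbol] for s in base.space]
    for attempt in range(max_attempts):
        cfg = SimConfig(seed=(seed + 7919 * attempt) % 2**31, n_tips=n_tips)
        tree = simulate_tree(cfg)
        scheme = load_scheme({"name": "full4", "states": states})
        rng = np.random.default_rng((seed + 104729 * attempt + 1) % 2**31)
        Q = ConstrainedRateMatrix.from_free(
            scheme.mask, np.full(scheme.mask.n_allowed, rate)
        )
        _, _, tips = simulate_history(tree, Q, root_state, rng)
        for taxon, st in tips.items():
            scheme.tips.set_states(taxon, sorted(st))
        pp = marginal_node_probs(
            tree, Q, scheme, None, CladeQuery(tree.tip_labels, "root")
        )
        if pp[scheme.space.index(root_state)] >= min_root_pp:
            return {"tree_sample": TreeSample([tree]), "scheme": scheme}, Q
    raise RuntimeError(
        f"no draw reached root PP >= {min_root_pp} in {max_attempts} attempts; "
        "lower the rate or the threshold"
    )


# ---------------------------------------------------------------------------
# the apid-like fixture

_APID_CLADES = {
    # clade: (tips, traditional symbols, complex symbols)
    "Centris": (2, "0", "0"),
    "Xylocopa": (2, "0", "01"),
    "Ceratina": (2, "02", "012"),
    "Allodapini": (3, "2", "12"),
    "Nomada": (3, "4", "4"),
    "Euglossini": (3, "0", "0"),
    "Bombini": (3, "2", "2"),
    "Meliponini": (3, "3", "3"),
    "Apini": (2, "3", "3"),
}


@dataclass
class ApidFixture:
    tree: Phylogeny                  # unit-depth likelihood tree
    tree_sample: TreeSample          # jittered pseudo-posterior sample
    chronogram: Phylogeny            # same topology in My, corbiculate crown at 87
    schemes: dict                    # {"traditional": ..., "complex": ...}
    queries: list                    # the seven key-node queries
    corbiculate_tips: list = field(default_factory=list)


def _apid_newick() -> str:
    """Ultrametric apid-like chronogram (My). Crown ages echo the study clades:
    corbiculates 87, allodapines 53, stingless bees 58, honey bees 22,
    bumble bees 21, orchid bees 28."""
    return (
        "((Centris_1:30,Centris_2:30):110,"
        "(((Xylocopa_1:40,Xylocopa_2:40):70,"
        "((Ceratina_1:35,Ceratina_2:35):55,"
        "(Allodapini_1:53,(Allodapini_2:25,Allodapini_3:25):28):37):20):20,"
        "((Nomada_1:70,(Nomada_2:30,Nomada_3:30):40):50,"
        "(((Bombini_1:21,(Bombini_2:10,Bombini_3:10):11):59,"
        "(Meliponini_1:58,(Meliponini_2:30,Meliponini_3:30):28):22):7,"
        "((Apini_1:22,Apini_2:22):62,"
        "(Euglossini_1:28,(Euglossini_2:15,Euglossini_3:15):13):56):3):33):10):10);"
    )


def make_apid_fixture(
    sample_size: int = 50, jitter: float = 0.08, seed: int = 2011
) -> ApidFixture:
    """Deterministic 23-tip fixture with the study's clade structure and codings."""
    chrono = Phylogeny.from_newick(_apid_newick())
    depth = chrono.depth()
    tree = Phylogeny(chrono.parent, chrono.brlen / depth, chrono.tip_labels)
    rng = np.random.default_rng(seed)
    sample = make_tree_sample(tree, sample_size, jitter, rng)

    schemes = {}
    for name, col in (("traditional", 1), ("complex", 2)):
        scheme = builtin_scheme(name)
        for clade, spec in _APID_CLADES.items():
            n, trad, cplx = spec
            symbols = trad if name == "traditional" else cplx
            for i in range(1, n + 1):
                scheme.tips.set_states(f"{clade}_{i}", symbols)
        schemes[name] = scheme

    def clade_tips(*clades):
        out = []
        for clade in clades:
            out.extend(f"{clade}_{i}" for i in range(1, _APID_CLADES[clade][0] + 1))
        return out

    corb = clade_tips("Bombini", "Meliponini", "Apini", "Euglossini")
    queries = [
        CladeQuery(tree.tip_labels, "Apidae"),
        CladeQuery(corb, "Corbiculates"),
        CladeQuery(clade_tips("Bombini", "Meliponini"), "Bombini+Meliponini"),
        CladeQuery(clade_tips("Apini", "Euglossini"), "Apini+Euglossini"),
        CladeQuery(clade_tips("Meliponini"), "Meliponini"),
        CladeQuery(clade_tips("Allodapini"), "Allodapini"),
        CladeQuery(clade_tips("Xylocopa", "Ceratina", "Allodapini"), "Xylocopinae"),
    ]
    return ApidFixture(
        tree=tree,
        tree_sample=sample,
        chronogram=chrono,
        schemes=schemes,
        queries=queries,
        corbiculate_tips=corb,
    )


# ---------------------------------------------------------------------------
# exhaustive small-tree sweeps


def enumerate_topologies(n_tips: int) -> list[Phylogeny]:
    """All distinct rooted, binary, labeled topologies on ``n_tips`` tips (unit branches).

    Counts follow the double factorial (2n-3)!!: 1, 3, 15, 105, 945 for
    n = 2..6. Limited to n <= 7.
    """
    if not 2 <= n_tips <= 7:
        raise ValueError(f"n_tips must be in [2, 7], got {n_tips}")
    labels = [f"t{i + 1}" for i in range(n_tips)]

    def grow(shape, leaf):
        # attach `leaf` on every edge, including the root edge
        yield (shape, leaf)
        if isinstance(shape, tuple):
            left, right = shape
            for sub in grow(left, leaf):
                yield (sub, right)
            for sub in grow(right, leaf):
                yield (left, sub)

    shapes = [labels[0]]
    for leaf in labels[1:]:
        shapes = [s for old in shapes for s in grow(old, leaf)]

    def to_newick(shape):
        if isinstance(shape, str):
            return f"{shape}:1"
        return f"({to_newick(shape[0])},{to_newick(shape[1])}):1"

    return [Phylogeny.from_newick(to_newick(s)[:-2] + ";") for s in shapes]


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_ground_truth(dataset: SimulatedDataset, path) -> None:
    doc = {
        "root_state": dataset.root_state,
        "states": list(dataset.scheme.space.abbrevs),
        "free_rates": [float(x) for x in dataset.true_rates.free_values()],
        "cells": [
            f"{dataset.scheme.space.abbrevs[i]}->{dataset.scheme.space.abbrevs[j]}"
            for i, j in dataset.scheme.mask.allowed_cells()
        ],
        "node_states": [int(s) for s in dataset.node_states],
        "n_events": int(sum(len(e) for e in dataset.events)),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
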