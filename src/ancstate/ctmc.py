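"""Likelihood machinery for constrained multistate Markov models on trees.

The model is a k-state continuous-time Markov chain (an Mk-type model with
structural zeros): off-diagonal rates ``q_ij >= 0`` wherever the transition
constraint mask allows the move and exactly 0 where it forbids it; each
diagonal entry is minus its row sum. Tip observations may be ambiguous
(polymorphic codings become 0/1 indicator partials). Internal nodes can be
*fossilized* — constrained to a state subset — both for Bayes Factor tests
and for marginal ancestral-state probabilities.

``prune_loglik`` is the production path (post-order pruning with per-node
rescaling); ``enumeration_loglik`` is a brute-force sum over all joint
internal-state assignments, kept deliberately independent as a test oracle.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

from . import _kernels
from .coding import CodingScheme, TransitionConstraintMask, tip_partial
from .phylo import CladeQuery, Phylogeny, mrca

__all__ = [
    "ConstrainedRateMatrix",
    "NodeConstraint",
    "uniform_root_prior",
    "resolve_root_prior",
    "transition_matrix",
    "transition_matrices",
    "prune_loglik",
    "enumeration_loglik",
    "marginal_node_probs",
    "all_node_marginals",
    "build_partial_mask",
]

#: max reconstruction error (relative to ||Q||) tolerated for the eigen fast path
_EIG_RTOL = 1e-11


class ConstrainedRateMatrix:
    """Off-diagonal rates over a state space with forbidden cells structurally zero."""

    def __init__(self, mask: TransitionConstraintMask, rates: np.ndarray):
        k = mask.space.k
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (k, k):
            raise ValueError(f"rates must be {k}x{k}")
        offdiag = ~np.eye(k, dtype=bool)
        bad = offdiag & ~mask.allowed & (rates != 0)
        if bad.any():
            raise ValueError(f"nonzero rate on forbidden cells {np.argwhere(bad).tolist()}")
        if np.any(rates[mask.allowed] < 0):
            raise ValueError("negative transition rate")
        self.mask = mask
        self.space = mask.space
        self.rates = rates.copy()
        np.fill_diagonal(self.rates, 0.0)

    @classmethod
    def from_free(cls, mask: TransitionConstraintMask, values) -> "ConstrainedRateMatrix":
        """Build from a vector of rates over ``mask.allowed_cells()`` (row-major)."""
        values = np.asarray(values, dtype=float)
        cells = mask.allowed_cells()
        if len(values) != len(cells):
            raise ValueError(f"expected {len(cells)} free rates, got {len(values)}")
        rates = np.zeros((mask.space.k, mask.space.k))
        for (i, j), v in zip(cells, values):
            rates[i, j] = v
        return cls(mask, rates)

    def free_values(self) -> np.ndarray:
        return np.array([self.rates[i, j] for i, j in self.mask.allowed_cells()])

    @property
    def Q(self) -> np.ndarray:
        Q = self.rates.copy()
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ConstrainedRateMatrix k={self.space.k} free={self.mask.n_allowed}>"


class NodeConstraint(dict):
    """CladeQuery -> allowed state keys; a singleton set fossilizes the node."""

    def __init__(self, mapping=None):
        super().__init__()
        for q, states in (mapping or {}).items():
            self.set(q, states)

    def set(self, query: CladeQuery, states) -> None:
        states = (states,) if isinstance(states, (str, int)) else tuple(states)
        if not states:
            raise ValueError(f"constraint on {query.label!r} has an empty state set")
        self[query] = states

    def resolve(self, tree: Phylogeny, scheme: CodingScheme) -> dict:
        """Map each query to (node index, indicator vector) on a particular tree."""
        out = {}
        for q, states in self.items():
            node = mrca(tree, q)
            out[node] = scheme.space.indicator(states)
        return out


def uniform_root_prior(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def resolve_root_prior(root, scheme: CodingScheme) -> np.ndarray:
    """Accept None (uniform), a state key (indicator) or an explicit vector."""
    k = scheme.space.k
    if root is None:
        return uniform_root_prior(k)
    if isinstance(root, str):
        return scheme.space.indicator([root])
    pi = np.asarray(root, dtype=float)
    if pi.shape != (k,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("root prior must be a length-k probability vector")
    return pi


# ---------------------------------------------------------------------------
# transition probabilities


def transition_matrix(Q, t: float) -> np.ndarray:
    """P(t) = exp(Qt) by scipy's scaling-and-squaring Pade expm."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    Qm = Q.Q if isinstance(Q, ConstrainedRateMatrix) else np.asarray(Q, dtype=float)
    if t == 0.0:
        return np.eye(Qm.shape[0])
    P = expm(Qm * t)
    return np.clip(P, 0.0, 1.0)


def transition_matrices(Q, ts: np.ndarray) -> np.ndarray:
    """P(t) for a whole vector of branch lengths at once.

    Uses one eigendecomposition of Q (rates are shared across branches) and
    falls back to per-branch expm when Q is near-defective.
    """
    Qm = Q.Q if isinstance(Q, ConstrainedRateMatrix) else np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("branch lengths must be >= 0")
    k = Qm.shape[0]
    scale = max(np.abs(Qm).max(), 1.0)
    use_eig = True
    try:
        lam, V = np.linalg.eig(Qm)
        Vinv = np.linalg.inv(V)
        recon = (V * lam) @ Vinv
        # cheap conditioning guard (1-norm condition estimate, no SVD)
        cond1 = np.abs(V).sum(axis=0).max() * np.abs(Vinv).sum(axis=0).max()
        if np.abs(recon - Qm).max() > _EIG_RTOL * scale or cond1 > 1e8:
            use_eig = False
    except np.linalg.LinAlgError:
        use_eig = False
    if use_eig:
        E = np.exp(np.outer(ts, lam))  # (n, k) possibly complex
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv).real
    else:
        P = np.empty((len(ts), k, k))
        for i, t in enumerate(ts):
            P[i] = expm(Qm * t) if t > 0 else np.eye(k)
    np.clip(P, 0.0, 1.0, out=P)
    if np.any(ts == 0.0):
        P[ts == 0.0] = np.eye(k)
    return P


# ---------------------------------------------------------------------------
# pruning likelihood


def build_partial_mask(
    tree: Phylogeny, scheme: CodingScheme, constraints: NodeConstraint | None = None
) -> np.ndarray:
    """Per-node partial initialisation: tip indicators, internal constraint indicators."""
    k = scheme.space.k
    mask = np.ones((tree.n_nodes, k))
    for i, lab in enumerate(tree.tip_labels):
        mask[i] = tip_partial(lab, scheme)
    if constraints:
        for node, ind in constraints.resolve(tree, scheme).items():
            mask[node] *= ind
    return mask


def prune_loglik(
    tree: Phylogeny,
    Q: ConstrainedRateMatrix,
    scheme: CodingScheme,
    root=None,
    constraints: NodeConstraint | None = None,
    P: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Log-likelihood by Felsenstein pruning; ``-inf`` when the likelihood is exactly 0.

    ``P``/``mask`` may be passed to reuse precomputed per-branch matrices and
    partial initialisers (the MCMC hot path does).
    """
    pi = resolve_root_prior(root, scheme)
    if mask is None:
        scheme.check_taxa(tree.tip_labels)
        mask = build_partial_mask(tree, scheme, constraints)
    if P is None:
        P = transition_matrices(Q, tree.brlen)
    return float(
        _kernels.prune_loglik_kernel(
            tree.postorder, tree.child_flat, tree.child_ptr, P, mask, pi
        )
    )


def enumeration_loglik(
    tree: Phylogeny,
    Q: ConstrainedRateMatrix,
    scheme: CodingScheme,
    root=None,
    constraints: NodeConstraint | None = None,
) -> float:
    """Brute-force likelihood: explicit sum over all joint internal-state assignments.

    Independent of the pruning path (per-branch scipy expm, itertools
    enumeration); refuses trees with more than 12 internal nodes.
    """
    k = scheme.space.k
    internals = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    if len(internals) > 12:
        raise ValueError(
            f"enumeration oracle limited to 12 internal nodes, got {len(internals)}"
        )
    pi = resolve_root_prior(root, scheme)
    scheme.check_taxa(tree.tip_labels)
    cons = constraints.resolve(tree, scheme) if constraints else {}
    allowed_internal = []
    for v in internals:
        ind = cons.get(v, np.ones(k))
        allowed_internal.append([s for s in range(k) if ind[s] > 0])
    tip_sets = []
    for i, lab in enumerate(tree.tip_labels):
        ind = tip_partial(lab, scheme)
        if i in cons:
            ind = ind * cons[i]
        tip_sets.append([s for s in range(k) if ind[s] > 0])
    Pb = [expm(Q.Q * t) if t > 0 else np.eye(k) for t in tree.brlen]
    pos = {v: i for i, v in enumerate(internals)}
    total = 0.0
    for assign in itertools.product(*allowed_internal):
        term = pi[assign[pos[tree.root]]]
        for v in internals:
            p = tree.parent[v]
            if p >= 0:
                term *= Pb[v][assign[pos[p]], assign[pos[v]]]
        for tip in range(tree.n_tips):
            ps = assign[pos[tree.parent[tip]]]
            term *= sum(Pb[tip][ps, s] for s in tip_sets[tip])
        total += term
    return float(np.log(total)) if total > 0 else -np.inf


# ---------------------------------------------------------------------------
# marginal node-state probabilities


def marginal_node_probs(
    tree: Phylogeny,
    Q: ConstrainedRateMatrix,
    scheme: CodingScheme,
    root,
    query: CladeQuery,
    constraints: NodeConstraint | None = None,
) -> np.ndarray:
    """Posterior state probabilities at the query's MRCA, by fossilizing each state in turn.

    Component ``s`` is proportional to exp(prune_loglik with the node
    constrained to ``s``); states unreachable at the node get exactly 0.
    """
    k = scheme.space.k
    scheme.check_taxa(tree.tip_labels)
    node = mrca(tree, query)
    base = build_partial_mask(tree, scheme, constraints)
    P = transition_matrices(Q, tree.brlen)
    logs = np.empty(k)
    for s in range(k):
        m = base.copy()
        ind = np.zeros(k)
        ind[s] = 1.0
        m[node] *= ind  # fossilize on top of (intersected with) any input constraint
        logs[s] = prune_loglik(tree, Q, scheme, root, P=P, mask=m)
    if np.all(np.isneginf(logs)):
        raise ValueError(
            f"likelihood is 0 for every state at node {query.label!r}: "
            "data and model/constraints are inconsistent"
        )
    finite = ~np.isneginf(logs)
    probs = np.zeros(k)
    probs[finite] = np.exp(logs[finite] - logsumexp(logs[finite]))
    return probs


def all_node_marginals(
    tree: Phylogeny,
    Q: ConstrainedRateMatrix,
    scheme: CodingScheme,
    root=None,
    constraints: NodeConstraint | None = None,
    P: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Marginal state probabilities at every node in one up/down pass (n_nodes x k).

    Agrees with :func:`marginal_node_probs` node-by-node; used by the sampler
    because it costs two pruning passes for all nodes at once.
    """
    pi = resolve_root_prior(root, scheme)
    if mask is None:
        scheme.check_taxa(tree.tip_labels)
        mask = build_partial_mask(tree, scheme, constraints)
    if P is None:
        P = transition_matrices(Q, tree.brlen)
    ok, marg = _kernels.node_marginals_kernel(
        tree.postorder, tree.child_flat, tree.child_ptr, P, mask, pi
    )
    if not ok:
        raise ValueError("likelihood is 0: data and model/constraints are inconsistent")
    return marg
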