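"""Metropolis-Hastings sampling of transition rates over a posterior tree sample.

The sampler integrates over phylogenetic uncertainty by proposing, at each
iteration, either a fresh tree drawn uniformly from the input tree sample
(accepted by its likelihood ratio — BayesTraits-style tree hopping), a rate
move, or, in reversible-jump mode, a move on the rate-class structure.

Two prior regimes are supported:

* ``uniform_fixed`` — independent uniform(lo, hi) priors on every free rate
  (default 0-100); the rate move is a joint sliding-window proposal with
  reflection at the bounds, so one likelihood evaluation updates all rates.
* ``exp_hyper`` — a hyperprior regime: rates are exponential with mean ``m``,
  and ``m`` itself is uniform(0, 10). Rates move by per-rate multiplier
  proposals; ``m`` does not enter the likelihood, so it is refreshed every
  iteration by an exact Gibbs draw from its truncated inverse-gamma full
  conditional.

Reversible-jump mode groups the allowed rate cells into shared rate classes,
including a ZERO class whose cells have rate exactly 0, with a uniform prior
over structures and prior-draw rate proposals (rate-prior densities then
cancel in the acceptance ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincc, gammainccinv, logsumexp

from .coding import CodingScheme
from .ctmc import (
    NodeConstraint,
    all_node_marginals,
    build_partial_mask,
    resolve_root_prior,
    transition_matrices,
)
from .phylo import TreeSample, mrca
from . import _kernels

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "ChainState",
    "ChainTrace",
    "run_chain",
    "propose_rate",
    "rj_move",
    "harmonic_mean_logml",
    "detect_burnin",
    "derive_seed",
    "reflect",
]

ZERO = -1  # class id of the reversible-jump zero class


@dataclass
class PriorSpec:
    """Rate priors: fixed uniform bounds, or exponential with a uniform hypermean."""

    kind: str = "uniform_fixed"  # {"uniform_fixed", "exp_hyper"}
    lo: float = 0.0
    hi: float = 100.0
    hyper_lo: float = 0.0
    hyper_hi: float = 10.0
    rj: bool = False

    def __post_init__(self):
        if self.kind not in ("uniform_fixed", "exp_hyper"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError("prior bounds must be finite with lo < hi")
        if not (0 <= self.hyper_lo < self.hyper_hi):
            raise ValueError("hyperprior bounds must satisfy 0 <= lo < hi")

    def draw_rate(self, m: float, rng) -> float:
        if self.kind == "uniform_fixed":
            return float(rng.uniform(self.lo, self.hi))
        return float(rng.exponential(m))

    def log_rate_density(self, r: float, m: float) -> float:
        if self.kind == "uniform_fixed":
            if not (self.lo <= r <= self.hi):
                return -np.inf
            return -math.log(self.hi - self.lo)
        if r < 0:
            return -np.inf
        return -math.log(m) - r / m


@dataclass
class MCMCSettings:
    iterations: int
    thin: int = 10
    seed: int = 0
    constraints: NodeConstraint | None = None
    queries: tuple = ()
    move_weights: tuple = (1.0, 2.0, 1.0)  # tree : rate : RJ-structure
    likelihood_off: bool = False
    record_all_nodes: bool = False
    tune_fraction: float = 0.1
    root_prior: object = None
    init_retries: int = 50

    def __post_init__(self):
        if self.iterations < 10 * self.thin:
            raise ValueError("iterations must be >= 10 * thin")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


@dataclass
class ChainState:
    """Current sampler position (tree index, rate-class structure, rates, hypermean)."""

    tree_index: int
    assign: np.ndarray       # per allowed cell: class id, or ZERO
    class_rates: np.ndarray  # one rate per class
    hyper_mean: float
    loglik: float = np.nan
    logprior: float = np.nan

    @property
    def n_classes(self) -> int:
        return len(self.class_rates)

    def cell_rates(self) -> np.ndarray:
        out = np.zeros(len(self.assign))
        nz = self.assign != ZERO
        out[nz] = self.class_rates[self.assign[nz]]
        return out

    def copy(self) -> "ChainState":
        return ChainState(
            self.tree_index,
            self.assign.copy(),
            self.class_rates.copy(),
            self.hyper_mean,
            self.loglik,
            self.logprior,
        )


@dataclass
class ChainTrace:
    """Thinned MCMC samples plus acceptance bookkeeping."""

    iterations: np.ndarray
    tree_index: np.ndarray
    rates: np.ndarray             # (n_samples, n_cells) per-cell expanded rates
    logL: np.ndarray
    logprior: np.ndarray
    hyper_mean: np.ndarray
    n_classes: np.ndarray
    n_zero: np.ndarray
    node_probs: dict              # query label -> (n_samples, k)
    cells: list                   # (i, j) per free-rate column
    state_labels: tuple
    burnin: int = 0
    acceptance: dict = field(default_factory=dict)
    all_node_probs: np.ndarray | None = None
    structures: list | None = None  # RJ: canonical structure signature per sample

    def __post_init__(self):
        if self.burnin >= len(self.iterations):
            raise ValueError("burn-in index must be < trace length")

    def __len__(self) -> int:
        return len(self.iterations)

    def post_burnin_logL(self, burnin: int | None = None) -> np.ndarray:
        b = self.burnin if burnin is None else burnin
        return self.logL[b:]

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "iteration": self.iterations,
            "tree_index": self.tree_index,
            "logL": self.logL,
            "logprior": self.logprior,
            "hyper_mean": self.hyper_mean,
            "n_classes": self.n_classes,
            "n_zero": self.n_zero,
        }
        a, b = self.state_labels, self.cells
        for c, (i, j) in enumerate(b):
            cols[f"q_{a[i]}_{a[j]}"] = self.rates[:, c]
        for label, probs in self.node_probs.items():
            for s in range(probs.shape[1]):
                cols[f"pp_{label}_{a[s]}"] = probs[:, s]
        return pd.DataFrame(cols)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.8g")


def derive_seed(master: int, *indices: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and counter indices."""
    s = int(master) % (2**31)
    for x in indices:
        s = (s * 1000003 + int(x) * 7919 + 12345) % (2**31)
    return s


def reflect(x, lo: float, hi: float):
    """Fold proposals back into [lo, hi] (triangle-wave reflection; symmetric)."""
    span = 2.0 * (hi - lo)
    y = np.mod(np.asarray(x, dtype=float) - lo, span)
    y = np.where(y < 0, y + span, y)
    return lo + np.minimum(y, span - y)


# ---------------------------------------------------------------------------
# proposal kernels


def propose_rate(state: ChainState, prior: PriorSpec, rng, window: float = 1.0,
                 index: int | None = None):
    """Propose new class rates; returns (new_class_rates, log_hastings).

    uniform_fixed: joint sliding-window move with reflection at the bounds
    (symmetric, Hastings 0). exp_hyper: multiplier move on one class (or all),
    Hastings = sum log(r'/r).
    """
    if state.n_classes == 0:
        raise ValueError("no free rate to propose")
    r = state.class_rates
    if prior.kind == "uniform_fixed":
        delta = rng.uniform(-window, window, size=len(r))
        if index is not None:
            keep = np.ones(len(r), dtype=bool)
            keep[index] = False
            delta[keep] = 0.0
        return reflect(r + delta, prior.lo, prior.hi), 0.0
    # multiplier kernel
    new = r.copy()
    idxs = range(len(r)) if index is None else [index]
    logh = 0.0
    for i in idxs:
        f = math.exp(window * (rng.uniform() - 0.5))
        new[i] = r[i] * f
        logh += math.log(f)
    return new, logh


def _canonicalize(assign: np.ndarray, class_rates: np.ndarray):
    """Relabel classes in first-occurrence order; drop empty classes."""
    new_assign = np.full(len(assign), ZERO, dtype=np.int64)
    order = []
    for i, a in enumerate(assign):
        if a == ZERO:
            continue
        if a not in order:
            order.append(a)
        new_assign[i] = order.index(a)
    return new_assign, np.array([class_rates[a] for a in order])


def rj_move(state: ChainState, prior: PriorSpec, rng):
    """One reversible-jump structure proposal.

    Returns ``(new_state, log_accept_adjust, submove, available)`` where the
    adjustment term contains the structure-proposal Hastings factors (rate
    priors cancel because new class rates are drawn from the prior).
    """
    assign = state.assign
    n_cells = len(assign)
    C = state.n_classes
    submove = ("split", "merge", "zero", "redraw")[rng.integers(4)]
    new = state.copy()
    m_hyper = state.hyper_mean

    if submove == "split":
        sizes = np.bincount(assign[assign != ZERO], minlength=C)
        big = np.flatnonzero(sizes >= 2)
        if len(big) == 0:
            return new, 0.0, submove, False
        c = int(big[rng.integers(len(big))])
        members = np.flatnonzero(assign == c)
        mlen = len(members)
        while True:
            bits = rng.integers(0, 2, size=mlen)
            if 0 < bits.sum() < mlen:
                break
        new_id = C
        new.assign = assign.copy()
        new.assign[members[bits == 1]] = new_id
        new.class_rates = np.append(state.class_rates, prior.draw_rate(m_hyper, rng))
        new.assign, new.class_rates = _canonicalize(new.assign, new.class_rates)
        Cp = C + 1
        log_adj = math.log(len(big) * (2.0**mlen - 2.0)) - math.log(Cp * (Cp - 1))
        return new, log_adj, submove, True

    if submove == "merge":
        if C < 2:
            return new, 0.0, submove, False
        c1, c2 = rng.choice(C, size=2, replace=False)
        keep, drop = (c1, c2) if rng.uniform() < 0.5 else (c2, c1)
        new.assign = assign.copy()
        new.assign[new.assign == drop] = keep
        # canonicalize drops the now-empty class (and its rate) automatically
        new.assign, new.class_rates = _canonicalize(new.assign, state.class_rates)
        sizes = np.bincount(new.assign[new.assign != ZERO], minlength=new.n_classes)
        big_after = int(np.sum(sizes >= 2))
        mlen = int(np.sum(assign == c1) + np.sum(assign == c2))
        log_adj = math.log(C * (C - 1)) - math.log(big_after * (2.0**mlen - 2.0))
        return new, log_adj, submove, True

    if submove == "zero":
        i = int(rng.integers(n_cells))
        new.assign = assign.copy()
        if assign[i] != ZERO:
            new.assign[i] = ZERO
            new.assign, new.class_rates = _canonicalize(new.assign, state.class_rates)
            log_adj = -math.log(new.n_classes + 1)
        else:
            t = int(rng.integers(C + 1))
            if t == C:  # fresh singleton class
                new.assign[i] = C
                new.class_rates = np.append(state.class_rates, prior.draw_rate(m_hyper, rng))
            else:
                new.assign[i] = t
                new.class_rates = state.class_rates.copy()
            new.assign, new.class_rates = _canonicalize(new.assign, new.class_rates)
            log_adj = math.log(C + 1)
        return new, log_adj, submove, True

    # redraw: independence draw of one class rate from the prior
    if C == 0:
        return new, 0.0, submove, False
    c = int(rng.integers(C))
    new.class_rates = state.class_rates.copy()
    new.class_rates[c] = prior.draw_rate(m_hyper, rng)
    return new, 0.0, submove, True


def _gibbs_hyper_mean(state: ChainState, prior: PriorSpec, rng) -> float:
    """Exact draw of the exponential hypermean from its truncated full conditional.

    p(m | rates) ∝ m^{-n} exp(-S/m) on (hyper_lo, hyper_hi): a truncated
    inverse-gamma(n-1, S). The n <= 1 corner (improper untruncated shape) is
    handled on a grid.
    """
    lo = max(prior.hyper_lo, 1e-12)
    hi = prior.hyper_hi
    n = state.n_classes
    if n == 0:
        return float(rng.uniform(lo, hi))
    S = float(state.class_rates.sum())
    if S <= 0 or n == 1:
        # grid inverse-CDF on log-density m^{-n} e^{-S/m}
        grid = np.linspace(lo, hi, 2048)
        logd = -n * np.log(grid) - (S / grid if S > 0 else 0.0)
        d = np.exp(logd - logd.max())
        cdf = np.cumsum(d)
        cdf /= cdf[-1]
        u = rng.uniform()
        j = int(np.searchsorted(cdf, u))
        step = grid[1] - grid[0]
        return float(grid[j] - step * rng.uniform())
    # inverse-gamma(a, S) via X = S / G, G ~ Gamma(a, 1):
    # CDF_X(x) = P(G >= S/x) = gammaincc(a, S/x); ppf(u) = S / gammainccinv(a, u)
    a = n - 1
    flo = float(gammaincc(a, S / lo))
    fhi = float(gammaincc(a, S / hi))
    if fhi - flo < 1e-300:  # conditional mass numerically outside the bounds
        return hi if S / max(a, 1) > hi else lo
    u = rng.uniform(flo, fhi)
    return float(np.clip(S / gammainccinv(a, u), lo, hi))


# ---------------------------------------------------------------------------
# the chain


class _TreeCtx:
    """Cached per-tree arrays: partial mask with constraints, resolved query nodes."""

    def __init__(self, tree, scheme, constraints, queries):
        self.tree = tree
        self.mask = build_partial_mask(tree, scheme, constraints)
        self.qnodes = {q.label: mrca(tree, q) for q in queries}


def _total_logprior(state: ChainState, prior: PriorSpec) -> float:
    lp = 0.0
    for r in state.class_rates:
        lp += prior.log_rate_density(float(r), state.hyper_mean)
    return lp


def run_chain(data, prior: PriorSpec, settings: MCMCSettings) -> ChainTrace:
    """Run one MCMC chain and return its thinned trace.

    ``data`` is a mapping with keys ``tree_sample`` (:class:`TreeSample`) and
    ``scheme`` (:class:`CodingScheme`). Records every ``thin``-th state,
    including marginal node-state probabilities for each query. Identical
    seed and settings give a bit-identical trace.
    """
    sample: TreeSample = data["tree_sample"]
    scheme: CodingScheme = data["scheme"]
    rng = np.random.default_rng(settings.seed)
    queries = tuple(settings.queries)
    constraints = settings.constraints
    pi = resolve_root_prior(getattr(settings, "root_prior", None), scheme)
    scheme.check_taxa(sample.tip_labels)
    if settings.record_all_nodes and len(sample) > 1:
        raise ValueError("record_all_nodes requires a single-tree sample (fixed topology)")

    cells = scheme.mask.allowed_cells()
    n_cells = len(cells)
    if n_cells == 0:
        raise ValueError("the constraint mask leaves no allowed transition")
    rj = prior.rj or scheme.rj

    ctxs: dict[int, _TreeCtx] = {}

    def ctx(ti: int) -> _TreeCtx:
        if ti not in ctxs:
            ctxs[ti] = _TreeCtx(sample[ti], scheme, constraints, queries)
        return ctxs[ti]

    k = scheme.space.k
    cell_rows = np.array([i for i, _ in cells])
    cell_cols = np.array([j for _, j in cells])

    def q_matrix(state: ChainState) -> np.ndarray:
        Q = np.zeros((k, k))
        Q[cell_rows, cell_cols] = state.cell_rates()
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def loglik_P(state: ChainState):
        if settings.likelihood_off:
            return 0.0, None
        c = ctx(state.tree_index)
        t = c.tree
        Q = q_matrix(state)
        try:
            ok, ll, P = _kernels.loglik_eig_kernel(
                Q, t.brlen, t.postorder, t.child_flat, t.child_ptr, c.mask, pi
            )
            if ok:
                return float(ll), P
        except Exception:
            pass  # defective/singular eigenbasis: robust path below
        P = transition_matrices(Q, t.brlen)
        ll = float(
            _kernels.prune_loglik_kernel(
                t.postorder, t.child_flat, t.child_ptr, P, c.mask, pi
            )
        )
        return ll, P

    # --- initial state ---------------------------------------------------
    state = None
    for _ in range(settings.init_retries):
        m0 = float(rng.uniform(max(prior.hyper_lo, 1e-6), prior.hyper_hi))
        if rj:
            assign = np.zeros(n_cells, dtype=np.int64)
            class_rates = np.array([prior.draw_rate(m0, rng)])
        else:
            assign = np.arange(n_cells, dtype=np.int64)
            class_rates = np.array([prior.draw_rate(m0, rng) for _ in range(n_cells)])
        cand = ChainState(int(rng.integers(len(sample))), assign, class_rates, m0)
        cand.loglik, P_cur = loglik_P(cand)
        if np.isfinite(cand.loglik):
            state = cand
            break
    if state is None:
        raise RuntimeError(
            f"could not find a finite-likelihood initial state in "
            f"{settings.init_retries} prior draws; check codings, mask and constraints"
        )
    state.logprior = _total_logprior(state, prior)

    # --- bookkeeping ------------------------------------------------------
    w_tree, w_rate, w_rj = settings.move_weights
    if len(sample) == 1:
        w_tree = w_tree if w_tree > 0 else 0.0
    if not rj:
        w_rj = 0.0
    wsum = w_tree + w_rate + w_rj
    if wsum <= 0:
        raise ValueError("move weights sum to 0")
    p_moves = np.array([w_tree, w_rate, w_rj]) / wsum

    window = 0.1 * (prior.hi - prior.lo) if prior.kind == "uniform_fixed" else 1.0
    w_lo, w_hi = (
        (1e-4 * (prior.hi - prior.lo), 2.0 * (prior.hi - prior.lo))
        if prior.kind == "uniform_fixed"
        else (0.02, 8.0)
    )
    tune_until = int(settings.tune_fraction * settings.iterations)
    tune_acc = [0, 0]
    rate_move_count = 0

    acc = {m: [0, 0] for m in ("tree", "rate", "rj")}
    consec_rej = {m: 0 for m in ("tree", "rate", "rj")}

    n_rec = settings.iterations // settings.thin
    it_rec = np.empty(n_rec, dtype=np.int64)
    ti_rec = np.empty(n_rec, dtype=np.int64)
    rates_rec = np.empty((n_rec, n_cells))
    ll_rec = np.empty(n_rec)
    lp_rec = np.empty(n_rec)
    hm_rec = np.empty(n_rec)
    ncls_rec = np.empty(n_rec, dtype=np.int64)
    nzero_rec = np.empty(n_rec, dtype=np.int64)
    k = scheme.space.k
    np_rec = {q.label: np.empty((n_rec, k)) for q in queries}
    all_rec = (
        np.empty((n_rec, sample[0].n_nodes, k)) if settings.record_all_nodes else None
    )
    structures = [] if rj else None

    def bump(move: str, accepted: bool):
        acc[move][1] += 1
        if accepted:
            acc[move][0] += 1
            consec_rej[move] = 0
        else:
            consec_rej[move] += 1
            if consec_rej[move] >= 10_000:
                raise RuntimeError(
                    f"{move} move rejected 10000 times in a row "
                    f"(acceptance {acc[move][0]}/{acc[move][1]}); "
                    "the proposal kernel cannot move — check priors and data"
                )

    rec_i = 0
    for it in range(settings.iterations):
        mv = ("tree", "rate", "rj")[rng.choice(3, p=p_moves)]

        if mv == "tree":
            j = int(rng.integers(len(sample)))
            if j == state.tree_index:
                bump("tree", True)
            else:
                cand = state.copy()
                cand.tree_index = j
                cand.loglik, P_cand = loglik_P(cand)
                logw = math.log(sample.weights[j]) - math.log(
                    sample.weights[state.tree_index]
                )
                if math.log(rng.uniform()) < (cand.loglik - state.loglik) + logw:
                    state, P_cur = cand, P_cand
                    bump("tree", True)
                else:
                    bump("tree", False)

        elif mv == "rate":
            if prior.kind == "uniform_fixed":
                new_rates, logh = propose_rate(state, prior, rng, window=window)
                cand = state.copy()
                cand.class_rates = new_rates
                cand.loglik, P_cand = loglik_P(cand)
                # reflection keeps rates inside the uniform support: prior ratio 1
                cand.logprior = state.logprior
                a = (cand.loglik - state.loglik) + logh
                ok = math.log(rng.uniform()) < a
                if ok:
                    state, P_cur = cand, P_cand
                bump("rate", ok)
                if it < tune_until:
                    tune_acc[0] += int(ok)
                    tune_acc[1] += 1
                # every other rate move: a single-rate multiplier refinement, so
                # the chain can traverse rate magnitudes that the additive
                # window cannot resolve (rates span orders of magnitude under
                # a wide uniform prior)
                rate_move_count += 1
                if rate_move_count % 2 == 0 and state.n_classes > 0:
                    ci = int(rng.integers(state.n_classes))
                    f = math.exp(1.5 * (rng.uniform() - 0.5))
                    cand = state.copy()
                    cand.class_rates[ci] = state.class_rates[ci] * f
                    if prior.lo <= cand.class_rates[ci] <= prior.hi:
                        cand.loglik, P_cand = loglik_P(cand)
                        a = (cand.loglik - state.loglik) + math.log(f)
                        if math.log(rng.uniform()) < a:
                            state, P_cur = cand, P_cand
            else:
                any_ok = False
                for ci in range(state.n_classes):
                    new_rates, logh = propose_rate(
                        state, prior, rng, window=window, index=ci
                    )
                    cand = state.copy()
                    cand.class_rates = new_rates
                    cand.loglik, P_cand = loglik_P(cand)
                    cand.logprior = _total_logprior(cand, prior)
                    a = (
                        (cand.loglik - state.loglik)
                        + (cand.logprior - state.logprior)
                        + logh
                    )
                    if math.log(rng.uniform()) < a:
                        state, P_cur = cand, P_cand
                        any_ok = True
                        if it < tune_until:
                            tune_acc[0] += 1
                    if it < tune_until:
                        tune_acc[1] += 1
                bump("rate", any_ok)
            if it < tune_until and tune_acc[1] >= 50:
                frac = tune_acc[0] / tune_acc[1]
                if frac > 0.4:
                    window = min(window * 1.4, w_hi)
                elif frac < 0.2:
                    window = max(window / 1.4, w_lo)
                tune_acc = [0, 0]

        else:  # rj structure move
            cand, log_adj, submove, available = rj_move(state, prior, rng)
            if not available:
                bump("rj", False)
            else:
                cand.loglik, P_cand = loglik_P(cand)
                cand.logprior = _total_logprior(cand, prior)
                # structure prior is uniform; rate priors for created/destroyed
                # classes cancel against their prior-draw proposals, so only the
                # likelihood and the structure-proposal adjustment remain
                a = (cand.loglik - state.loglik) + log_adj
                ok = math.log(rng.uniform()) < a
                if ok:
                    state, P_cur = cand, P_cand
                bump("rj", ok)

        if prior.kind == "exp_hyper":
            state.hyper_mean = _gibbs_hyper_mean(state, prior, rng)
            state.logprior = _total_logprior(state, prior)

        if (it + 1) % settings.thin == 0:
            it_rec[rec_i] = it + 1
            ti_rec[rec_i] = state.tree_index
            rates_rec[rec_i] = state.cell_rates()
            ll_rec[rec_i] = state.loglik
            lp_rec[rec_i] = state.logprior
            hm_rec[rec_i] = state.hyper_mean
            ncls_rec[rec_i] = state.n_classes
            nzero_rec[rec_i] = int(np.sum(state.assign == ZERO))
            if rj:
                structures.append(_structure_signature(state.assign))
            if (queries or settings.record_all_nodes) and not settings.likelihood_off:
                c = ctx(state.tree_index)
                marg = all_node_marginals(
                    c.tree, q_matrix(state), scheme, root=pi, P=P_cur, mask=c.mask
                )
                for q in queries:
                    np_rec[q.label][rec_i] = marg[c.qnodes[q.label]]
                if all_rec is not None:
                    all_rec[rec_i] = marg
            elif queries:
                for q in queries:
                    np_rec[q.label][rec_i] = np.nan
            rec_i += 1

    trace = ChainTrace(
        iterations=it_rec,
        tree_index=ti_rec,
        rates=rates_rec,
        logL=ll_rec,
        logprior=lp_rec,
        hyper_mean=hm_rec,
        n_classes=ncls_rec,
        n_zero=nzero_rec,
        node_probs=np_rec,
        cells=cells,
        state_labels=scheme.space.abbrevs,
        burnin=0,
        acceptance={m: tuple(v) for m, v in acc.items()},
        all_node_probs=all_rec,
        structures=structures,
    )
    # default burn-in: fixed quarter (callers may re-detect with geweke)
    trace.burnin = int(math.ceil(0.25 * n_rec))
    return trace


def _structure_signature(assign: np.ndarray) -> tuple:
    """Canonical hashable signature of an RJ structure (zero set + partition)."""
    new, _ = _canonicalize(assign, np.zeros(int(assign.max()) + 1 if len(assign) else 0))
    return tuple(int(a) for a in new)


# ---------------------------------------------------------------------------
# trace diagnostics


def harmonic_mean_logml(trace, burnin: int | None = None, min_samples: int = 100) -> float:
    """Harmonic-mean log marginal-likelihood: log[n / sum exp(-logL_i)], stably.

    Accepts a ChainTrace (post-burn-in logL) or a raw logL array. Production
    use requires ``min_samples`` (default 100) post-burn-in values; the
    estimator itself is defined for any n >= 1 and is order-invariant.
    """
    if isinstance(trace, ChainTrace):
        logL = trace.post_burnin_logL(burnin)
    else:
        logL = np.asarray(trace, dtype=float)
        if burnin:
            logL = logL[burnin:]
    if len(logL) < max(min_samples, 1):
        raise ValueError(
            f"need >= {min_samples} post-burn-in samples for the harmonic mean, "
            f"got {len(logL)}"
        )
    if np.any(np.isneginf(logL)):
        return -np.inf
    return float(math.log(len(logL)) - logsumexp(-logL))


def _integrated_autocorr_time(x: np.ndarray) -> float:
    """Initial-positive-sequence estimate of the integrated autocorrelation time."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    v = float(np.dot(x, x) / n)
    if v == 0:
        return 1.0
    tau = 1.0
    for lag in range(1, min(n // 3, 1000)):
        rho = float(np.dot(x[:-lag], x[lag:]) / n) / v
        if rho <= 0.0:
            break
        tau += 2.0 * rho
    return tau


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = len(x)
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    va = a.var(ddof=1) * _integrated_autocorr_time(a) / len(a)
    vb = b.var(ddof=1) * _integrated_autocorr_time(b) / len(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def detect_burnin(trace, policy: str = "fixed_fraction", fraction: float = 0.25) -> int:
    """Burn-in index: a fixed fraction, or the first window where Geweke |z| < 2 on logL."""
    x = trace.logL if isinstance(trace, ChainTrace) else np.asarray(trace, dtype=float)
    n = len(x)
    if n < 200:
        raise ValueError(f"trace too short for burn-in detection ({n} < 200)")
    if policy == "fixed_fraction":
        return int(math.ceil(fraction * n))
    if policy == "geweke":
        step = max(1, n // 20)
        for start in range(0, n - 100, step):
            if abs(_geweke_z(x[start:])) < 2.0:
                return start
        raise RuntimeError(
            "Geweke diagnostic never stabilized; run the chain longer before summarizing"
        )
    raise ValueError(f"unknown burn-in policy {policy!r}")
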