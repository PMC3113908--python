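"""Replicate-level summaries: ancestral posterior probabilities, Bayes Factor
node tests, and state-annotated chronograms.

Ancestral-state tables report, for each queried node and state, the mean and
standard error of the posterior probability over replicate chains (SE =
sd of the per-chain means / sqrt(n), the "mean ± SE over n replicates"
presentation). Bayes Factors follow the Pagel convention

    BF = 2 [log HM(s1) - log HM(s2)]

with the harmonic-mean marginal likelihood HM computed per replicate and
replicate i of one fixed state paired with replicate i of the other (a
common seed stream), and categorised as: BF <= 0 against, 0-2 weak, 2-5
positive, > 5 strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ctmc import NodeConstraint
from .mcmc import (
    ChainTrace,
    MCMCSettings,
    PriorSpec,
    derive_seed,
    harmonic_mean_logml,
    run_chain,
)
from .phylo import CladeQuery, Phylogeny, TreeSample, clade_age_report, mrca

__all__ = [
    "AncestralSummary",
    "BayesFactorResult",
    "StateAnnotatedChronogram",
    "summarize_ancestral",
    "run_replicates",
    "bayes_factor_test",
    "bf_from_log_marginals",
    "categorize_bf",
    "annotate_chronogram",
    "write_ancestral_tsv",
    "write_bf_tsv",
]


@dataclass
class AncestralSummary:
    """Per node x state posterior-probability mean and SE over replicate chains."""

    queries: list                  # query labels, in order
    states: tuple                  # state abbreviations
    pp_mean: np.ndarray            # (n_queries, k)
    pp_se: np.ndarray              # (n_queries, k)
    n_replicates: int
    per_replicate: np.ndarray | None = None  # (n_rep, n_queries, k)

    def modal_state(self, query_label: str) -> tuple[str, float]:
        """Modal state and its mean PP; exact ties return 'ambiguous'."""
        qi = self.queries.index(query_label)
        row = self.pp_mean[qi]
        top = float(row.max())
        winners = [self.states[s] for s in range(len(row)) if row[s] == top]
        if len(winners) > 1:
            return "ambiguous(" + "/".join(winners) + ")", top
        return winners[0], top


@dataclass
class BayesFactorResult:
    """One pairwise node test: 2*(logHM(s1) - logHM(s2)) over paired replicates."""

    comparison: str
    state1: str
    state2: str
    bf_per_replicate: np.ndarray
    bf_mean: float
    bf_se: float
    n: int
    category: str
    impossible: str | None = None   # state label whose fossilization has likelihood 0


@dataclass
class StateAnnotatedChronogram:
    chronogram: Phylogeny
    node_labels: dict              # node index -> modal state label
    branch_labels: dict            # node index -> state label of the branch above
    ages: list                     # AgeSummary rows for focal-state clades


def categorize_bf(bf: float) -> str:
    if bf > 5:
        return "strong"
    if bf > 2:
        return "positive"
    if bf >= 0:
        return "weak"
    return "against"


def bf_from_log_marginals(
    ref_loghm, other_loghm, state1: str = "s1", state2: str = "s2", double: bool = True
) -> BayesFactorResult:
    """Paired Bayes Factor from two arrays of per-replicate log marginal likelihoods."""
    ref = np.asarray(ref_loghm, dtype=float)
    other = np.asarray(other_loghm, dtype=float)
    if ref.shape != other.shape:
        raise ValueError("replicate arrays must have equal length (paired comparison)")
    factor = 2.0 if double else 1.0
    diff = factor * (ref - other)
    impossible = None
    if np.all(np.isneginf(other)):
        impossible = state2
    elif np.all(np.isneginf(ref)):
        impossible = state1
    finite = diff[np.isfinite(diff)]
    if impossible is not None or len(finite) == 0:
        mean = float(np.inf if impossible == state2 else -np.inf)
        se = 0.0
    else:
        mean = float(finite.mean())
        se = float(finite.std(ddof=1) / math.sqrt(len(finite))) if len(finite) > 1 else 0.0
    return BayesFactorResult(
        comparison=f"{state1} vs {state2}",
        state1=state1,
        state2=state2,
        bf_per_replicate=diff,
        bf_mean=mean,
        bf_se=se,
        n=len(ref),
        category="state impossible" if impossible else categorize_bf(mean),
        impossible=impossible,
    )


def summarize_ancestral(traces: list[ChainTrace], queries) -> AncestralSummary:
    """Mean and SE over replicate chains of post-burn-in node-state probabilities."""
    if not traces:
        raise ValueError("need at least one trace")
    labels = [q.label if isinstance(q, CladeQuery) else str(q) for q in queries]
    k = len(traces[0].state_labels)
    per = np.empty((len(traces), len(labels), k))
    for r, tr in enumerate(traces):
        for qi, lab in enumerate(labels):
            if lab not in tr.node_probs:
                raise KeyError(f"trace {r} lacks node probabilities for query {lab!r}")
            per[r, qi] = tr.node_probs[lab][tr.burnin:].mean(axis=0)
    mean = per.mean(axis=0)
    if len(traces) > 1:
        se = per.std(axis=0, ddof=1) / math.sqrt(len(traces))
    else:
        se = np.zeros_like(mean)
    return AncestralSummary(
        queries=labels,
        states=traces[0].state_labels,
        pp_mean=mean,
        pp_se=se,
        n_replicates=len(traces),
        per_replicate=per,
    )


def run_replicates(
    data, prior: PriorSpec, settings: MCMCSettings, n_replicates: int,
    master_seed: int | None = None,
) -> list[ChainTrace]:
    """Independent replicate chains with seeds derived from a master seed."""
    master = settings.seed if master_seed is None else master_seed
    traces = []
    for i in range(n_replicates):
        s = MCMCSettings(
            iterations=settings.iterations,
            thin=settings.thin,
            seed=derive_seed(master, i),
            constraints=settings.constraints,
            queries=settings.queries,
            move_weights=settings.move_weights,
            likelihood_off=settings.likelihood_off,
            record_all_nodes=settings.record_all_nodes,
            tune_fraction=settings.tune_fraction,
            root_prior=settings.root_prior,
        )
        traces.append(run_chain(data, prior, s))
    return traces


def bayes_factor_test(
    data,
    prior: PriorSpec,
    settings: MCMCSettings,
    node: CladeQuery,
    states: list,
    n_replicates: int = 20,
    reference: str | None = None,
    double: bool = True,
) -> list[BayesFactorResult]:
    """Fossilize ``node`` to each state in turn, n_replicates chains per state,
    then pairwise-compare harmonic-mean log marginal likelihoods.

    ``reference`` (default: first entry of ``states``) is compared against each
    other state: the returned comparisons are "ref vs other". Replicate i uses
    the same derived seed in every arm, so comparisons are paired. A state
    whose fossilization makes the data impossible in every replicate is
    reported with BF = +inf against it rather than raising. ``double=False``
    gives raw log-HM differences instead of the doubled (Pagel) convention.
    """
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2 for a standard error")
    scheme = data["scheme"]
    for s in states:
        scheme.space.index(s)
    ref = states[0] if reference is None else reference
    loghm = {}
    for s in states:
        cons = NodeConstraint(settings.constraints or {})
        cons.set(node, (s,))
        arm = []
        for i in range(n_replicates):
            st = MCMCSettings(
                iterations=settings.iterations,
                thin=settings.thin,
                seed=derive_seed(settings.seed, i),
                constraints=cons,
                queries=(),
                move_weights=settings.move_weights,
                tune_fraction=settings.tune_fraction,
                root_prior=settings.root_prior,
            )
            try:
                arm.append(harmonic_mean_logml(run_chain(data, prior, st)))
            except RuntimeError:
                # no finite-likelihood state exists under this fossilization
                arm.append(-np.inf)
        loghm[s] = np.asarray(arm)

    return [
        bf_from_log_marginals(loghm[ref], loghm[s], state1=ref, state2=s, double=double)
        for s in states
        if s != ref
    ]


# ---------------------------------------------------------------------------
# chronogram annotation


def annotate_chronogram(
    chronograms,
    ancestral: AncestralSummary,
    queries: list,
    scheme,
    focal_states=(),
    mass: float = 0.95,
) -> StateAnnotatedChronogram:
    """Label queried nodes with their modal reconstructed state on a chronogram.

    Branches between a queried node and its queried descendants inherit the
    ancestral node's modal state. Clade ages (with HPD over the chronogram
    sample) are attached for queried clades whose modal state is in
    ``focal_states``.
    """
    sample = (
        chronograms
        if isinstance(chronograms, TreeSample)
        else TreeSample([chronograms])
    )
    tree = sample[0]
    node_labels = {}
    focal_queries = []
    qmap = {q.label: q for q in queries}
    for lab in ancestral.queries:
        if lab not in qmap:
            continue
        node = mrca(tree, qmap[lab])
        modal, _pp = ancestral.modal_state(lab)
        node_labels[node] = modal
        if modal in focal_states:
            focal_queries.append(qmap[lab])
    # each labeled node pushes its state down onto descendant branches until
    # the next labeled node takes over
    branch_labels = {}
    state_above = {tree.root: node_labels.get(tree.root)}
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p >= 0:
            inherited = node_labels.get(p, state_above.get(p))
            branch_labels[v] = inherited
            state_above[v] = inherited
    ages = clade_age_report(sample, focal_queries, mass) if focal_queries else []
    return StateAnnotatedChronogram(tree, node_labels, branch_labels, ages)


# ---------------------------------------------------------------------------
# tabular output


def write_ancestral_tsv(summary: AncestralSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tstate\tpp_mean\tpp_se\tn_replicates\n")
        for qi, lab in enumerate(summary.queries):
            for s, st in enumerate(summary.states):
                fh.write(
                    f"{lab}\t{st}\t{summary.pp_mean[qi, s]:.6g}"
                    f"\t{summary.pp_se[qi, s]:.6g}\t{summary.n_replicates}\n"
                )


def write_bf_tsv(results: list[BayesFactorResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tbf_mean\tbf_se\tn\tcategory\n")
        for r in results:
            fh.write(f"{r.comparison}\t{r.bf_mean:.6g}\t{r.bf_se:.6g}\t{r.n}\t{r.category}\n")


def write_annotated_nexus(annotated: StateAnnotatedChronogram, path) -> None:
    """NEXUS trees block with per-node state comments ([&state=...])."""
    tree = annotated.chronogram

    def render(v):
        if v < tree.n_tips:
            core = tree.tip_labels[v].replace(" ", "_")
        else:
            core = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        lab = annotated.node_labels.get(v)
        comment = f"[&state={lab}]" if lab is not None else ""
        if v == tree.root:
            return f"{core}{comment}"
        return f"{core}{comment}:{tree.brlen[v]:.10g}"

    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin trees;\n")
        fh.write(f"    tree annotated = [&R] {render(tree.root)};\n")
        fh.write("end;\n")
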