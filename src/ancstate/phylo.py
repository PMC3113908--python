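"""Rooted phylogenies, posterior tree samples, MRCA queries, node ages and HPD intervals.

Trees are stored in a flat array form (postorder index arrays) so that the
likelihood machinery can iterate over them cheaply; parsing and serialisation
are delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeSample",
    "CladeQuery",
    "AgeSummary",
    "TreeValidationError",
    "read_trees",
    "write_trees",
    "mrca",
    "node_age",
    "hpd_interval",
    "clade_age_report",
    "write_age_report",
]

#: relative ultrametricity tolerance, as a fraction of tree depth
ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """A tree or tree sample violates a structural invariant."""


class Phylogeny:
    """A rooted tree with branch lengths, in flat postorder-array form.

    Nodes are integers ``0 .. n_nodes-1``; tips occupy ``0 .. n_tips-1`` in the
    order of :attr:`tip_labels`. ``parent[root] == -1`` and ``brlen[root] == 0``.
    Branch lengths are non-negative: substitutions/site for likelihood trees,
    millions of years for chronograms.
    """

    __slots__ = (
        "n_nodes",
        "n_tips",
        "parent",
        "brlen",
        "postorder",
        "children",
        "child_flat",
        "child_ptr",
        "tip_labels",
        "_tip_index",
        "root",
    )

    def __init__(self, parent, brlen, tip_labels, validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.brlen = np.asarray(brlen, dtype=np.float64)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        root = -1
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p < 0:
                root = v
            else:
                children[p].append(v)
        self.root = root
        self.children = children
        # flat child arrays for the jitted kernels
        ptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        flat = []
        for v in range(self.n_nodes):
            flat.extend(children[v])
            ptr[v + 1] = len(flat)
        self.child_flat = np.asarray(flat, dtype=np.int64)
        self.child_ptr = ptr
        self.postorder = self._compute_postorder()
        if validate:
            self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        tips = [nd for nd in nodes if nd.is_leaf()]
        labels = []
        for nd in tips:
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(str(nd.label))
        # tips first (in their preorder position order), then internals
        order = tips + [nd for nd in nodes if not nd.is_leaf()]
        remap = {index[id(nd)]: i for i, nd in enumerate(order)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        brlen = np.zeros(len(nodes), dtype=np.float64)
        for nd in nodes:
            i = remap[index[id(nd)]]
            if nd.parent_node is not None:
                parent[i] = remap[index[id(nd.parent_node)]]
            el = nd.edge.length
            brlen[i] = 0.0 if el is None else float(el)
        return cls(parent, brlen, labels)

    @classmethod
    def from_newick(cls, s: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=s, schema="newick", preserve_underscores=True, rooting="force-rooted"
            )
        except Exception as e:
            raise TreeValidationError(f"could not parse newick string: {e}") from e
        return cls.from_dendropy(tree)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v < self.n_tips:
                dnodes[v].taxon = tns.require_taxon(label=self.tip_labels[v])
            dnodes[v].edge.length = float(self.brlen[v])
            for c in self.children[v]:
                dnodes[v].add_child(dnodes[c])
        tree.seed_node = dnodes[self.root]
        tree.seed_node.edge.length = None
        return tree

    def to_newick(self) -> str:
        return self._newick_of(self.root) + ";"

    def _newick_of(self, v: int) -> str:
        if v < self.n_tips:
            lab = self.tip_labels[v]
            if any(ch in lab for ch in " (),:;[]'"):
                lab = "'" + lab.replace("'", "''") + "'"
            return f"{lab}:{self.brlen[v]:.10g}"
        inner = ",".join(self._newick_of(c) for c in self.children[v])
        if v == self.root:
            return f"({inner})"
        return f"({inner}):{self.brlen[v]:.10g}"

    # -- structure ----------------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        # reversed preorder (children pushed after their parent) is a valid
        # postorder: every parent appears after all of its descendants
        stack = [self.root]
        seq = []
        while stack:
            v = stack.pop()
            seq.append(v)
            stack.extend(self.children[v])
        return np.array(seq[::-1], dtype=np.int64)

    def _validate(self) -> None:
        if self.root < 0:
            raise TreeValidationError("tree has no root (no node with parent == -1)")
        if int(np.sum(self.parent < 0)) != 1:
            raise TreeValidationError("tree must have exactly one root")
        if len(set(self.tip_labels)) != self.n_tips:
            dup = sorted({l for l in self.tip_labels if self.tip_labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dup}")
        if np.any(self.brlen < 0):
            bad = int(np.argmin(self.brlen))
            raise TreeValidationError(
                f"negative branch length {self.brlen[bad]} above node {bad}"
            )
        for v in range(self.n_nodes):
            if v >= self.n_tips and len(self.children[v]) < 2:
                raise TreeValidationError(
                    f"internal node {v} has {len(self.children[v])} children (needs >= 2)"
                )
            if v < self.n_tips and self.children[v]:
                raise TreeValidationError(f"tip node {v} has children")

    # -- queries ------------------------------------------------------------

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"taxon {label!r} not found in tree") from None

    def depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.brlen[v]
        return d

    def clade_tips(self, v: int) -> list[int]:
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(u)
            stack.extend(self.children[u])
        return sorted(out)

    def depth(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


@dataclass
class TreeSample:
    """An ordered sample of trees over one tip set (e.g. a post-burnin posterior sample)."""

    trees: list[Phylogeny]
    weights: np.ndarray | None = None

    def __post_init__(self):
        if len(self.trees) < 1:
            raise TreeValidationError("TreeSample needs at least one tree")
        tipset = frozenset(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if frozenset(t.tip_labels) != tipset:
                extra = sorted(frozenset(t.tip_labels) ^ tipset)
                raise TreeValidationError(
                    f"tree {i} has a different tip set (symmetric difference {extra[:5]}...)"
                )
        if self.weights is None:
            self.weights = np.full(len(self.trees), 1.0 / len(self.trees))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.trees):
                raise TreeValidationError("weights length != number of trees")
            self.weights = self.weights / self.weights.sum()

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


@dataclass(frozen=True)
class CladeQuery:
    """A node addressed as the MRCA of a set of >= 2 tip labels."""

    taxa: frozenset
    label: str

    def __init__(self, taxa, label: str):
        taxa = frozenset(taxa)
        if len(taxa) < 2:
            raise ValueError(f"clade query {label!r} needs >= 2 taxa, got {len(taxa)}")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "label", label)


@dataclass
class AgeSummary:
    """Mean and HPD of a clade's crown age (My) over a chronogram sample."""

    clade: str
    n_trees: int
    mean_age: float
    hpd_low: float
    hpd_high: float
    mass: float = 0.95

    def __post_init__(self):
        if self.hpd_low > self.hpd_high:
            raise ValueError("hpd_low > hpd_high")


# ---------------------------------------------------------------------------
# i/o


def read_trees(path, format: str = "newick", underscores_to_spaces: bool = False) -> TreeSample:
    """Read a file of trees (Newick lines or a NEXUS trees block) into a TreeSample.

    NEXUS translate tables are applied. Underscores in unquoted labels are kept
    literal unless ``underscores_to_spaces`` is set.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tl = dendropy.TreeList.get(
            path=str(path),
            schema=format,
            preserve_underscores=not underscores_to_spaces,
            rooting="force-rooted",
        )
    except Exception as e:  # dendropy raises schema-specific errors
        raise TreeValidationError(f"could not parse {path} as {format}: {e}") from e
    if len(tl) == 0:
        raise TreeValidationError(f"no trees found in {path}")
    return TreeSample([Phylogeny.from_dendropy(t) for t in tl])


def write_trees(sample: TreeSample, path, format: str = "newick") -> None:
    if format == "newick":
        with open(path, "w") as fh:
            for t in sample.trees:
                fh.write(t.to_newick() + "\n")
    elif format == "nexus":
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList(taxon_namespace=tns)
        for t in sample.trees:
            tl.append(t.to_dendropy(taxon_namespace=tns))
        tl.write(path=str(path), schema="nexus", unquoted_underscores=True,
                 suppress_rooting=True, real_value_format_specifier=".10g")
    else:
        raise ValueError(f"unknown tree format {format!r}")


# ---------------------------------------------------------------------------
# node queries


def mrca(tree: Phylogeny, query: CladeQuery) -> int:
    """Most recent common ancestor (node index) of the query taxa.

    The realized clade may be larger than the query set; use
    ``tree.clade_tips`` on the result to inspect it.
    """
    want = {tree.tip_index(lab) for lab in query.taxa}
    count = np.zeros(tree.n_nodes, dtype=np.int64)
    for i in want:
        count[i] = 1
    target = len(want)
    for v in tree.postorder:
        p = tree.parent[v]
        if count[v] == target:
            return int(v)
        if p >= 0:
            count[p] += count[v]
    return int(tree.root)


def node_age(tree: Phylogeny, node: int, rtol: float = ULTRAMETRIC_RTOL) -> float:
    """Age of ``node`` = distance to its descendant tips, requiring ultrametricity.

    All tips of the tree must sit at (relatively) equal depth; otherwise a
    validation error names the worst tip pair.
    """
    d = tree.depths()
    tipd = d[: tree.n_tips]
    depth = float(tipd.max())
    tol = rtol * max(depth, 1.0) if depth > 0 else rtol
    lo, hi = int(np.argmin(tipd)), int(np.argmax(tipd))
    if tipd[hi] - tipd[lo] > tol:
        raise TreeValidationError(
            "tree is not ultrametric within tolerance: tips "
            f"{tree.tip_labels[lo]!r} (depth {tipd[lo]:.6g}) vs "
            f"{tree.tip_labels[hi]!r} (depth {tipd[hi]:.6g})"
        )
    tips = tree.clade_tips(node)
    return float(np.mean([tipd[i] for i in tips]) - d[node])


def hpd_interval(sample, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of the sorted sample holding >= ceil(mass*n) points.

    Among equal-width windows the left-most is returned.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError(f"need >= 20 draws for an HPD interval, got {n}")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    w = int(np.ceil(mass * n))
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: left-most tie
    return float(x[i]), float(x[i + w - 1])


def clade_age_report(
    chronograms: TreeSample, queries: list[CladeQuery], mass: float = 0.95
) -> list[AgeSummary]:
    """Per query: mean MRCA age over the chronogram sample and the HPD of that age sample.

    For samples of fewer than 20 trees the interval degenerates to (min, max).
    """
    out = []
    for q in queries:
        ages = []
        for i, t in enumerate(chronograms.trees):
            try:
                ages.append(node_age(t, mrca(t, q)))
            except (TreeValidationError, KeyError) as e:
                raise type(e)(f"tree {i}: {e}") from e
        ages = np.asarray(ages)
        if len(ages) >= 20:
            lo, hi = hpd_interval(ages, mass)
        else:
            lo, hi = float(ages.min()), float(ages.max())
        out.append(AgeSummary(q.label, len(ages), float(ages.mean()), lo, hi, mass))
    return out


def write_age_report(summaries: list[AgeSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("clade\tn_trees\tmean_age\thpd_low\thpd_high\tmass\n")
        for s in summaries:
            fh.write(
                f"{s.clade}\t{s.n_trees}\t{s.mean_age:.6g}\t{s.hpd_low:.6g}"
                f"\t{s.hpd_high:.6g}\t{s.mass:g}\n"
            )
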