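"""Rooted-tree algebra: parsing, covariance, branch transforms, rerooting.

Trees are held in a lightweight node structure built from dendropy's parser
(Newick or NEXUS, annotation-tolerant).  Node ids are post-order ordinals,
stable across copies, transforms, and serialization round-trips.  Branch
lengths are interpreted as durations (Ma).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

from mimicevo.errors import TreeError

__all__ = [
    "Node",
    "Phylogeny",
    "TreeSample",
    "parse_tree",
    "phylo_covariance",
    "transform_tree",
    "reroot",
]


class Node:
    """A tree node; ``length`` is the branch above it (0 for the root)."""

    __slots__ = ("children", "parent", "length", "label", "id")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = float(length)
        self.label = label
        self.id: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """Rooted phylogeny with post-order node indexing.

    Attributes
    ----------
    root : Node
    nodes : list[Node]
        All nodes in post-order; ``nodes[i].id == i``.
    tips : list[Node]
        Tip nodes in post-order.
    """

    def __init__(self, root: Node, metadata: Optional[dict] = None):
        self.root = root
        self.metadata = metadata or {}
        self._index()

    # -- construction / bookkeeping ------------------------------------
    def _index(self) -> None:
        nodes: list[Node] = []

        def walk(n: Node) -> None:
            for c in n.children:
                walk(c)
            nodes.append(n)

        walk(self.root)
        for i, n in enumerate(nodes):
            n.id = i
        self.nodes = nodes
        self.tips = [n for n in nodes if n.is_tip]
        labels = [t.label for t in self.tips]
        if any(l is None for l in labels):
            raise TreeError("all tips must be labeled")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        self.tip_labels: list[str] = labels  # post-order

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def node(self, node_id: int) -> Node:
        if not 0 <= node_id < len(self.nodes):
            raise TreeError(f"node id {node_id} not in tree (0..{len(self.nodes) - 1})")
        return self.nodes[node_id]

    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(clone(c))
            return m

        return Phylogeny(clone(self.root), dict(self.metadata))

    # -- geometry -------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Time from the root to each node (root edge excluded), indexed by id."""
        d = np.zeros(len(self.nodes))
        # pre-order via reversed post-order
        for n in reversed(self.nodes):
            for c in n.children:
                d[c.id] = d[n.id] + c.length
        return d

    @property
    def height(self) -> float:
        d = self.depths()
        return float(max(d[t.id] for t in self.tips))

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        td = [d[t.id] for t in self.tips]
        h = max(td)
        if h == 0:
            return True
        return (h - min(td)) <= rel_tol * h

    def tip_depths(self) -> np.ndarray:
        d = self.depths()
        return np.array([d[t.id] for t in self.tips])

    def mrca_depths(self) -> np.ndarray:
        """Matrix M (tips x tips, post-order): depth of the MRCA of each tip
        pair; diagonal is each tip's own depth.  Under unit-rate Brownian
        motion this is the tip covariance."""
        n = self.n_tips
        tip_index = {t.id: k for k, t in enumerate(self.tips)}
        d = self.depths()
        M = np.zeros((n, n))
        below: dict[int, list[int]] = {}
        for node in self.nodes:  # post-order
            if node.is_tip:
                k = tip_index[node.id]
                below[node.id] = [k]
                M[k, k] = d[node.id]
                continue
            groups = [below.pop(c.id) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    M[np.ix_(groups[gi], groups[gj])] = d[node.id]
                    M[np.ix_(groups[gj], groups[gi])] = d[node.id]
            below[node.id] = [k for g in groups for k in g]
        return M

    # -- serialization --------------------------------------------------
    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_tip:
                core = _quote_label(n.label)
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.label:
                    core += _quote_label(n.label)
            return f"{core}:{n.length:.17g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"<Phylogeny n_tips={self.n_tips} height={self.height:.4g}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TreeSample:
    """An ordered collection of trees sharing one tip set."""

    trees: list[Phylogeny]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise TreeError(f"tree {k} has a different tip set than tree 0")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        n = Node(label, dnode.edge.length or 0.0)
        for c in dnode.child_nodes():
            n.add(convert(c))
        return n

    root = convert(dtree.seed_node)
    meta = {}
    if dtree.label:
        meta["tree_label"] = dtree.label
    return Phylogeny(root, meta)


def parse_tree(text: str) -> Phylogeny:
    """Parse a single tree from a Newick or NEXUS string.

    Square-bracket comments and support annotations are tolerated; duplicate
    tip labels raise.  Zero-length branches are retained.
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped.lower().startswith("#nexus") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    return _from_dendropy(dtree)


def parse_trees(text: str) -> TreeSample:
    """Parse all trees in a Newick or NEXUS document into a TreeSample."""
    stripped = text.lstrip()
    schema = "nexus" if stripped.lower().startswith("#nexus") else "newick"
    try:
        dlist = dendropy.TreeList.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"could not parse {schema} trees: {exc}") from exc
    return TreeSample([_from_dendropy(t) for t in dlist], provenance="parsed")


def read_tree(path: str) -> Phylogeny:
    with open(path) as fh:
        return parse_tree(fh.read())


def read_trees(path: str) -> TreeSample:
    with open(path) as fh:
        return parse_trees(fh.read())


# ---------------------------------------------------------------------------
# Covariance and transforms
# ---------------------------------------------------------------------------

def phylo_covariance(t: Phylogeny, order: Optional[Sequence[str]] = None) -> np.ndarray:
    """Shared root-to-tip path length for every tip pair (BM covariance at
    unit rate).  Rows/columns follow ``order`` (default: post-order tips)."""
    M = t.mrca_depths()
    if order is None:
        return M
    idx = {lab: k for k, lab in enumerate(t.tip_labels)}
    try:
        perm = [idx[lab] for lab in order]
    except KeyError as exc:
        raise TreeError(f"label {exc.args[0]!r} not a tip of the tree") from exc
    return M[np.ix_(perm, perm)]


def _rescale_depths(t: Phylogeny, f) -> Phylogeny:
    """Copy of ``t`` with each node depth x mapped to f(x) (f increasing,
    f(0)=0); branch p->c gets length f(depth_c) - f(depth_p)."""
    out = t.copy()
    d = t.depths()
    for n in out.nodes:
        if n.parent is not None:
            n.length = f(d[n.id]) - f(d[n.parent.id])
            if n.length < 0:
                raise TreeError("depth transform produced a negative branch length")
    return out

def ou_transform(t: Phylogeny, alpha: float) -> Phylogeny:
    """Rescale branches so BM on the result has the fixed-root single-optimum
    OU covariance of the source tree: depth t -> (e^{-2a(T-t)} - e^{-2aT})/(2a)."""
    if alpha <= 0:
        raise TreeError(f"OU transform requires alpha > 0, got {alpha}")
    if not t.is_ultrametric():
        raise TreeError("OU transform requires an ultrametric tree")
    T = t.height
    two_a = 2.0 * alpha

    def f(x: float) -> float:
        return (math.exp(-two_a * (T - x)) - math.exp(-two_a * T)) / two_a

    return _rescale_depths(t, f)


def eb_transform(t: Phylogeny, a: float) -> Phylogeny:
    """Early-burst time transform: a branch spanning depths t1->t2 becomes
    (e^{a t2} - e^{a t1})/a; the a -> 0 limit is the identity."""
    if a > 0:
        raise TreeError(f"EB transform requires a <= 0, got {a}")
    if a == 0:
        return t.copy()

    def f(x: float) -> float:
        return (math.exp(a * x) - 1.0) / a

    return _rescale_depths(t, f)


def lambda_transform(t: Phylogeny, lam: float) -> Phylogeny:
    """Pagel's lambda rescaling: internal-node depths are multiplied by lam
    (off-diagonal covariance x lam) while tip depths are preserved."""
    if lam < 0:
        raise TreeError(f"lambda must be >= 0, got {lam}")
    out = t.copy()
    d = t.depths()
    for n in out.nodes:
        if n.parent is None:
            continue
        if n.is_tip:
            n.length = d[n.id] - lam * d[n.parent.id]
        else:
            n.length = lam * (d[n.id] - d[n.parent.id])
        if n.length < 0:
            raise TreeError(f"lambda={lam} exceeds the tree's maximum feasible lambda")
    return out


def lambda_max(t: Phylogeny) -> float:
    """Largest lambda keeping all pendant branch lengths non-negative
    (hence the transformed covariance positive semi-definite)."""
    d = t.depths()
    vals = [
        d[tip.id] / d[tip.parent.id]
        for tip in t.tips
        if tip.parent is not None and d[tip.parent.id] > 0
    ]
    return float(min(vals)) if vals else math.inf


def transform_tree(t: Phylogeny, model: str, **params: float) -> Phylogeny:
    """Dispatch to a branch-length transform.

    ``model`` is one of ``"OU"`` (param ``alpha``), ``"EB"`` (param ``a``),
    ``"lambda"`` (param ``lam``), or ``"BM"`` (identity).
    """
    m = model.upper()
    if m == "BM":
        return t.copy()
    if m == "OU":
        return ou_transform(t, params["alpha"])
    if m == "EB":
        return eb_transform(t, params["a"])
    if m == "LAMBDA":
        return lambda_transform(t, params["lam"])
    raise TreeError(f"unknown transform {model!r}")


# ---------------------------------------------------------------------------
# Rerooting
# ---------------------------------------------------------------------------

def reroot(t: Phylogeny, node_id: int) -> Phylogeny:
    """Return a copy of ``t`` rooted at the node with post-order id
    ``node_id``.  All tip-to-tip path lengths are preserved; the old root is
    kept as a (possibly degree-2) internal node."""
    target = t.node(node_id)
    if target.is_tip:
        raise TreeError("can only reroot at an internal node")
    if target is t.root:
        return t.copy()

    # Undirected adjacency over the original nodes; edge weight is the branch
    # length of the child side.
    adj: dict[int, list[tuple[Node, float]]] = {n.id: [] for n in t.nodes}
    for n in t.nodes:
        if n.parent is not None:
            adj[n.id].append((n.parent, n.length))
            adj[n.parent.id].append((n, n.length))

    def build(src: Node, parent_orig: Optional[Node], length: float) -> Node:
        m = Node(src.label, length)
        for nbr, w in adj[src.id]:
            if parent_orig is not None and nbr is parent_orig:
                continue
            m.add(build(nbr, src, w))
        return m

    return Phylogeny(build(target, None, 0.0), dict(t.metadata))
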