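"""Phylogenetic tree container, Newick I/O, patristic distances and comparison metrics.

The :class:`PhyloTree` is a light rooted tree with parent/children links and a
stable integer *edge id* per non-root node (edge identity is child-node
identity).  Newick parsing is delegated to dendropy; writing is a small
recursive serializer so that jplace-style ``{edge_num}`` tags can be emitted.

Metrics provided here are the ones used to evaluate placement and tree
update: the topological placement-error (number of edges separating two
attachment edges), the Robinson--Foulds bipartition distance, and the quartet
distance (exhaustive for small trees, seeded uniform sampling otherwise).
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "PhyloTree",
    "DistanceMatrix",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "patristic_distances",
    "placement_edge_error",
    "rf_distance",
    "quartet_distance",
    "restrict_to_taxa",
    "prune_with_attachments",
    "attach_query",
    "midpoint_root",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input or duplicate leaf labels."""


class TreeError(ValueError):
    """Raised for structural violations (bad labels, negative lengths, ...)."""


class TreeNode:
    """A node of a rooted (possibly multifurcating) phylogeny."""

    __slots__ = ("parent", "children", "length", "label", "edge_id")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.length = float(length)
        self.label = label
        self.edge_id: int | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> None:
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, len={self.length}, edge={self.edge_id})"


def _postorder(root: TreeNode):
    """Iterative post-order traversal (children before parents)."""
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return reversed(out)


def _preorder(root: TreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with an optional missing-value mask.

    ``mask[i, j]`` is True where the entry is observed.  The matrix is kept
    symmetric with a zero diagonal; negative entries are rejected.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError(f"matrix shape {self.values.shape} != ({k}, {k})")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not np.array_equal(self.mask, self.mask.T):
                raise ValueError("mask must be symmetric")
        obs = self.values if self.mask is None else self.values[self.mask]
        if obs.size and np.any(obs < 0):
            raise ValueError("negative distances are not allowed")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        sub = self.values[np.ix_(idx, idx)]
        m = None if self.mask is None else self.mask[np.ix_(idx, idx)]
        return DistanceMatrix(tuple(labels), sub, m)


class PhyloTree:
    """Rooted weighted tree with unique leaf labels and stable edge ids.

    Edge ids are assigned in post-order at construction and preserved by
    :meth:`copy`; operations that add nodes (see :func:`attach_query`)
    allocate fresh ids above the current maximum so existing ids never move.
    """

    def __init__(self, root: TreeNode, preserve_edge_ids: bool = False):
        self.root = root
        self._validate()
        self._assign_edge_ids(preserve=preserve_edge_ids)

    # -- construction / bookkeeping ------------------------------------
    def _validate(self):
        seen = set()
        for node in _postorder(self.root):
            if node.is_leaf():
                if node.label is None:
                    raise TreeError("leaf without a label")
                if node.label in seen:
                    raise NewickParseError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            if node is not self.root and node.length < 0:
                raise TreeError(f"negative branch length on {node.label or 'internal node'}")

    def _assign_edge_ids(self, preserve: bool = False):
        nodes = [n for n in _postorder(self.root) if n is not self.root]
        if preserve and all(n.edge_id is not None for n in nodes):
            ids = [n.edge_id for n in nodes]
            if len(set(ids)) != len(ids):
                raise TreeError("edge ids not unique")
        else:
            for i, n in enumerate(nodes):
                n.edge_id = i
        self.root.edge_id = None
        self._by_edge = {n.edge_id: n for n in nodes}
        self._leaf_by_label = {n.label: n for n in nodes if n.is_leaf()}
        if self.root.is_leaf():  # single-node degenerate tree
            self._leaf_by_label[self.root.label] = self.root

    def _reindex(self):
        """Rebuild lookup tables after an in-place mutation; ids preserved."""
        self._assign_edge_ids(preserve=True)

    # -- basic queries --------------------------------------------------
    def postorder(self):
        return _postorder(self.root)

    def preorder(self):
        return _preorder(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in _postorder(self.root) if n.is_leaf()]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_by_label)

    def node_for_edge(self, edge_id: int) -> TreeNode:
        try:
            return self._by_edge[edge_id]
        except KeyError:
            raise TreeError(f"unknown edge id {edge_id}") from None

    def node_for_leaf(self, label: str) -> TreeNode:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise TreeError(f"unknown leaf label {label!r}") from None

    def edge_ids(self) -> list[int]:
        return sorted(self._by_edge)

    def max_edge_id(self) -> int:
        return max(self._by_edge) if self._by_edge else -1

    def depths(self) -> dict[TreeNode, float]:
        """Distance from the root to every node."""
        depth = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + node.length
        return depth

    def leafset_below(self) -> dict[TreeNode, frozenset]:
        below: dict[TreeNode, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf():
                below[node] = frozenset([node.label])
            else:
                s = frozenset()
                for c in node.children:
                    s |= below[c]
                below[node] = s
        return below

    def copy(self, with_map: bool = False):
        """Deep structural copy preserving edge ids."""
        mapping: dict[TreeNode, TreeNode] = {}
        new_root = TreeNode(self.root.label, self.root.length)
        new_root.edge_id = self.root.edge_id
        mapping[self.root] = new_root
        for node in self.preorder():
            if node is self.root:
                continue
            cp = TreeNode(node.label, node.length)
            cp.edge_id = node.edge_id
            mapping[node.parent].add_child(cp)
            mapping[node] = cp
        new_tree = PhyloTree(new_root, preserve_edge_ids=True)
        return (new_tree, mapping) if with_map else new_tree

    # -- Newick ---------------------------------------------------------
    def to_newick(self, edge_numbers: bool = False) -> str:
        return write_newick(self, edge_numbers=edge_numbers)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Missing branch lengths default to 0.  Malformed input and duplicate leaf
    labels raise :class:`NewickParseError`.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = TreeNode(label, length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        root = convert(dtree.seed_node)
    finally:
        sys.setrecursionlimit(old)
    return PhyloTree(root)


def write_newick(tree: PhyloTree, edge_numbers: bool = False) -> str:
    """Serialize to Newick; with ``edge_numbers`` emits jplace ``{id}`` tags."""

    out: list[str] = []

    def fmt(node: TreeNode):
        if node.children:
            out.append("(")
            for i, c in enumerate(node.children):
                if i:
                    out.append(",")
                fmt(c)
            out.append(")")
            if node.label:
                out.append(_escape(node.label))
        else:
            out.append(_escape(node.label or ""))
        if node is not tree.root:
            out.append(f":{node.length:.10g}")
            if edge_numbers:
                out.append("{%d}" % node.edge_id)

    fmt(tree.root)
    out.append(";")
    return "".join(out)


def parse_edge_numbered_newick(text: str) -> PhyloTree:
    """Parse Newick carrying jplace-style ``{edge_num}`` tags.

    Tags appear after branch lengths in the same order that
    :func:`write_newick` emits them (each node after its subtree), so they
    are captured positionally and re-attached to the parsed nodes.
    """
    import re

    ids = [int(m) for m in re.findall(r"\{(\d+)\}", text)]
    plain = re.sub(r"\{\d+\}", "", text)
    tree = parse_newick(plain)

    # write_newick emits ":len{id}" for every non-root node immediately after
    # serializing that node (children first), i.e. in this recursive order:
    order: list[TreeNode] = []

    def visit(node: TreeNode):
        for c in node.children:
            visit(c)
        if node.parent is not None:
            order.append(node)

    visit(tree.root)
    if len(ids) != len(order):
        raise NewickParseError(
            f"{len(ids)} edge tags for {len(order)} non-root nodes"
        )
    for node, eid in zip(order, ids):
        node.edge_id = eid
    return PhyloTree(tree.root, preserve_edge_ids=True)


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def patristic_distances(tree: PhyloTree, labels=None) -> DistanceMatrix:
    """All pairwise path-length (patristic) distances among ``labels``.

    Post-order accumulation: each node carries distances from itself to the
    selected leaves below it; pairs meeting at a node are combined there.
    Runs in O(n * k) for k selected leaves.
    """
    if labels is None:
        labels = sorted(tree.leaf_labels())
    labels = list(labels)
    for lab in labels:
        tree.node_for_leaf(lab)  # raises on unknown label
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    D = np.zeros((k, k))
    below: dict[TreeNode, dict[int, float]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            below[node] = {idx[node.label]: 0.0} if node.label in idx else {}
            continue
        merged: dict[int, float] = {}
        for child in node.children:
            cmap = below.pop(child)
            shifted = {i: di + child.length for i, di in cmap.items()}
            for i, di2 in shifted.items():
                for j, dj in merged.items():
                    D[i, j] = D[j, i] = di2 + dj
            merged.update(shifted)
        below[node] = merged
    return DistanceMatrix(tuple(labels), D)


# ---------------------------------------------------------------------------
# Placement edge error
# ---------------------------------------------------------------------------

def _edge_adjacency(tree: PhyloTree) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {e: set() for e in tree._by_edge}
    for node in tree.postorder():
        incident = [c.edge_id for c in node.children]
        if node is not tree.root:
            incident.append(node.edge_id)
        for a, b in itertools.combinations(incident, 2):
            adj[a].add(b)
            adj[b].add(a)
    return adj


def placement_edge_error(tree: PhyloTree, true_edge: int, predicted_edge: int) -> int:
    """Number of edges separating two attachment edges (0 iff identical).

    This is the shortest-path distance in the tree's edge-adjacency graph,
    the standard topological placement-error measure.
    """
    tree.node_for_edge(true_edge)
    tree.node_for_edge(predicted_edge)
    if true_edge == predicted_edge:
        return 0
    adj = _edge_adjacency(tree)
    dist = {true_edge: 0}
    queue = deque([true_edge])
    while queue:
        e = queue.popleft()
        for nb in adj[e]:
            if nb not in dist:
                dist[nb] = dist[e] + 1
                if nb == predicted_edge:
                    return dist[nb]
                queue.append(nb)
    raise TreeError("edges are not connected")  # pragma: no cover


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def _check_same_leafset(t1: PhyloTree, t2: PhyloTree) -> list[str]:
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        diff = sorted(l1 ^ l2)
        raise TreeError(f"leaf sets differ; symmetric difference: {diff}")
    return sorted(l1)


def rf_distance(t1: PhyloTree, t2: PhyloTree, normalized: bool = False) -> float:
    """Robinson--Foulds bipartition distance between two unrooted topologies.

    ``normalized`` divides by the maximum 2(n-3).
    """
    labels = _check_same_leafset(t1, t2)
    n = len(labels)
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d1.is_rooted = False
    d2.is_rooted = False
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    rf = float(dendropy.calculate.treecompare.symmetric_difference(d1, d2))
    if normalized:
        denom = 2.0 * (n - 3)
        return rf / denom if denom > 0 else 0.0
    return rf


# ---------------------------------------------------------------------------
# Quartet distance
# ---------------------------------------------------------------------------

def _topological_matrix(tree: PhyloTree, labels: list[str]) -> np.ndarray:
    """Pairwise path lengths counted in edges (each edge weight 1)."""
    # breadth-first search from every selected leaf over the node graph
    idx = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    T = np.zeros((k, k), dtype=np.int32)
    for lab in labels:
        start = tree.node_for_leaf(lab)
        dist = {start: 0}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            nbrs = list(node.children)
            if node.parent is not None:
                nbrs.append(node.parent)
            for nb in nbrs:
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    queue.append(nb)
        i = idx[lab]
        for other, j in idx.items():
            T[i, j] = dist[tree.node_for_leaf(other)]
    return T


def _quartet_topologies(T: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Topology code per quartet: 0 unresolved, 1=ab|cd, 2=ac|bd, 3=ad|bc."""
    a, b, c, d = Q[:, 0], Q[:, 1], Q[:, 2], Q[:, 3]
    s1 = T[a, b] + T[c, d]
    s2 = T[a, c] + T[b, d]
    s3 = T[a, d] + T[b, c]
    S = np.stack([s1, s2, s3], axis=1)
    amin = S.min(axis=1, keepdims=True)
    n_min = (S == amin).sum(axis=1)
    code = S.argmin(axis=1) + 1
    code[n_min > 1] = 0
    return code


def quartet_distance(
    t1: PhyloTree,
    t2: PhyloTree,
    sample_size="all",
    seed: int = 0,
    require_taxa=None,
) -> float:
    """Fraction of 4-leaf subsets with different induced unrooted topologies.

    Exhaustive enumeration is allowed only for n <= 30; above that a seeded
    uniform sample of quartets is used (default 100 000 when ``sample_size``
    is an int).  ``require_taxa`` restricts to quartets containing at least
    one of the given labels.
    """
    labels = _check_same_leafset(t1, t2)
    n = len(labels)
    if n < 4:
        return 0.0
    T1 = _topological_matrix(t1, labels)
    T2 = _topological_matrix(t2, labels)
    req = None
    if require_taxa is not None:
        lab_idx = {lab: i for i, lab in enumerate(labels)}
        req = {lab_idx[l] for l in require_taxa if l in lab_idx}
    if sample_size == "all":
        if n > 30:
            raise ValueError("exhaustive quartet enumeration limited to n <= 30")
        Q = np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        s = int(sample_size)
        Q = np.empty((s, 4), dtype=np.int64)
        for r in range(s):
            Q[r] = rng.choice(n, size=4, replace=False)
        Q.sort(axis=1)
    if req is not None:
        keep = np.array([any(int(x) in req for x in row) for row in Q])
        Q = Q[keep]
        if Q.shape[0] == 0:
            return 0.0
    c1 = _quartet_topologies(T1, Q)
    c2 = _quartet_topologies(T2, Q)
    return float(np.mean(c1 != c2))


# ---------------------------------------------------------------------------
# Pruning / grafting / rooting utilities
# ---------------------------------------------------------------------------

def prune_with_attachments(tree: PhyloTree, remove_labels):
    """Remove leaves and return the pruned backbone plus true attachments.

    Returns ``(backbone, attachments)`` where ``attachments[label]`` is a
    ``(edge_id, distal, pendant)`` triple on the *backbone*: the edge its
    original attachment point falls on, the distance of that point from the
    edge's parent end, and the path length from the removed leaf up to the
    point.  Degree-2 nodes created by removal are suppressed with branch
    lengths summed, so attachment points keep their geometric position.
    """
    remove = set(remove_labels)
    all_labels = set(tree.leaf_labels())
    unknown = remove - all_labels
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    if len(all_labels) - len(remove) < 2:
        raise TreeError("fewer than 2 leaves would remain")

    copy_tree, mapping = tree.copy(with_map=True)
    rev = {v: k for k, v in mapping.items()}  # copy -> original
    depth = tree.depths()

    # 1. detach the doomed leaves, cleaning up emptied internal nodes
    removed_orig: set[TreeNode] = set()
    for lab in remove:
        node = copy_tree.node_for_leaf(lab)
        removed_orig.add(rev[node])
        parent = node.parent
        node.detach()
        while parent is not None and not parent.children and parent.label is None:
            removed_orig.add(rev[parent])
            nxt = parent.parent
            parent.detach()
            parent = nxt

    # 2. suppress degree-2 internal nodes; record what edge absorbed them
    onto: dict[TreeNode, TreeNode] = {}  # original node -> original child whose edge holds it
    root = copy_tree.root
    changed = True
    while changed:
        changed = False
        for node in list(_postorder(root)):
            if node.label is None and len(node.children) == 1:
                child = node.children[0]
                if node is root:
                    onto[rev[node]] = rev[child]
                    child.parent = None
                    root = child
                    root.length = 0.0
                else:
                    child.length += node.length
                    par = node.parent
                    i = par.children.index(node)
                    par.children[i] = child
                    child.parent = par
                    onto[rev[node]] = rev[child]
                changed = True

    for n in _postorder(root):
        n.edge_id = None
    backbone = PhyloTree(root)
    alive = {rev[n]: n for n in _postorder(root) if n in rev}

    # resolve onto-chains down to a surviving node
    def surviving(orig: TreeNode) -> TreeNode:
        while orig not in alive:
            orig = onto[orig]
        return alive[orig]

    # 3. attachment resolution per removed leaf
    pat = None  # lazy patristic matrix for the root-attachment corner case
    below = backbone.leafset_below()
    attachments: dict[str, tuple[int, float, float]] = {}
    for lab in sorted(remove):
        q = tree.node_for_leaf(lab)
        x = q.parent
        while x is not None and x not in alive and x not in onto:
            x = x.parent
        if x is None:
            raise TreeError("attachment resolution failed")  # pragma: no cover
        pendant = depth[q] - depth[x]
        node = surviving(x) if x in onto else alive[x]
        if x in onto and node.parent is not None:
            distal = node.length - (depth[rev[node]] - depth[x])
            attachments[lab] = (node.edge_id, float(distal), float(pendant))
        else:
            if node.parent is not None:
                attachments[lab] = (node.edge_id, float(node.length), float(pendant))
            else:
                # point sits at/above the backbone root: any child edge at its
                # parent end is geometrically equivalent; pick the one toward
                # the query's nearest surviving leaf (ties by label).  The
                # pendant absorbs any stub between the point and the root.
                if pat is None:
                    pat = patristic_distances(tree)
                best_leaf = min(
                    (l for l in backbone.leaf_labels()),
                    key=lambda l: (pat.get(lab, l), l),
                )
                child = next(c for c in node.children if best_leaf in below[c])
                stub = depth[rev[node]] - depth[x]
                attachments[lab] = (child.edge_id, 0.0, float(pendant + stub))
    return backbone, attachments


def restrict_to_taxa(tree: PhyloTree, keep_labels) -> PhyloTree:
    """Induced subtree on ``keep_labels`` (branch lengths summed on paths)."""
    keep = set(keep_labels)
    remove = [l for l in tree.leaf_labels() if l not in keep]
    if not remove:
        return tree.copy()
    backbone, _ = prune_with_attachments(tree, remove)
    return backbone


def attach_query(
    tree: PhyloTree,
    edge_id: int,
    distal: float,
    pendant: float,
    label: str,
) -> int:
    """Graft a new leaf onto ``edge_id`` in place; returns the new leaf's edge id.

    The edge (parent u, child v) is split at ``distal`` from u; v keeps its
    edge id, the split node and the new leaf get fresh ids.
    """
    if label in tree._leaf_by_label:
        raise TreeError(f"label {label!r} already present")
    v = tree.node_for_edge(edge_id)
    u = v.parent
    if u is None:
        raise TreeError("cannot attach on the root")
    l = v.length
    distal = min(max(float(distal), 0.0), l)
    nxt = tree.max_edge_id() + 1
    mid = TreeNode(None, distal)
    mid.edge_id = nxt
    leaf = TreeNode(label, max(float(pendant), 0.0))
    leaf.edge_id = nxt + 1
    i = u.children.index(v)
    u.children[i] = mid
    mid.parent = u
    mid.add_child(v)
    v.length = l - distal
    mid.add_child(leaf)
    tree._reindex()
    return leaf.edge_id


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Re-root a copy of the tree at the midpoint of its longest leaf-leaf path."""
    labels = sorted(tree.leaf_labels())
    if len(labels) < 2:
        return tree.copy()
    pat = patristic_distances(tree, labels)
    i, j = np.unravel_index(np.argmax(pat.values), pat.values.shape)
    a, b = labels[i], labels[j]
    half = pat.values[i, j] / 2.0

    work = tree.copy()
    # node path a -> b
    na, nb = work.node_for_leaf(a), work.node_for_leaf(b)
    anc_a = []
    x = na
    while x is not None:
        anc_a.append(x)
        x = x.parent
    anc_set = set(anc_a)
    path_b = []
    x = nb
    while x not in anc_set:
        path_b.append(x)
        x = x.parent
    lca = x
    path = anc_a[: anc_a.index(lca) + 1] + list(reversed(path_b))
    # walk from a toward b until the midpoint falls inside an edge
    walked = 0.0
    for t in range(len(path) - 1):
        cur, nxt = path[t], path[t + 1]
        edge_child = cur if nxt is cur.parent else nxt
        step = edge_child.length
        if walked + step >= half - 1e-12:
            frac_from_child = (
                (half - walked) / step if step > 0 else 0.0
            )
            if nxt is cur.parent:
                dist_from_child_end = half - walked
            else:
                dist_from_child_end = step - (half - walked)
            return _reroot_on_edge(work, edge_child, dist_from_child_end)
        walked += step
    return work  # pragma: no cover


def _reroot_on_edge(tree: PhyloTree, child: TreeNode, dist_from_child: float) -> PhyloTree:
    """Place a new root on the edge above ``child`` at the given distance."""
    dist_from_child = min(max(dist_from_child, 0.0), child.length)
    old_parent = child.parent
    if old_parent is None:
        return tree
    new_root = TreeNode(None, 0.0)
    # reverse the parent chain above old_parent
    chain = []
    x = old_parent
    while x is not None:
        chain.append(x)
        x = x.parent
    old_parent.children.remove(child)
    child.parent = None
    upper_len = child.length - dist_from_child
    child.length = dist_from_child
    new_root.add_child(child)
    # re-hang old_parent (and, recursively, its former ancestors)
    lengths = [n.length for n in chain]
    for t, node in enumerate(chain):
        node.parent = None
    prev = new_root
    prev_len = upper_len
    for t, node in enumerate(chain):
        if t + 1 < len(chain):
            chain[t].children.remove(chain[t + 1])
        prev.add_child(node)
        node.length = prev_len
        prev_len = lengths[t]
        prev = node
    # suppress a degree-1 leftover old root
    for node in list(_postorder(new_root)):
        if node.label is None and len(node.children) == 1 and node is not new_root:
            c = node.children[0]
            c.length += node.length
            par = node.parent
            i = par.children.index(node)
            par.children[i] = c
            c.parent = par
    for n in _postorder(new_root):
        n.edge_id = None
    return PhyloTree(new_root)
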