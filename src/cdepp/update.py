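"""Tree update: extend the backbone with queries, re-inferring local subtrees.

Each query is assigned to one first-level subtree (argmax of classifier
scores averaged across genes).  Per subtree, a complete distance matrix over
its backbone members and assigned queries is assembled — query-involved
entries are medians of per-gene model estimates, backbone-backbone entries
are pinned to backbone patristic distances — and the subtree is re-inferred
with a distance method (neighbor joining, or NJ followed by
balanced-minimum-evolution NNI hill climbing with OLS branch lengths).
Finally the re-inferred subtrees are merged onto the full backbone by
sequential least-squares grafting: each query is placed on the growing tree
using its path lengths in the updated subtree to the members already
present, which preserves the backbone topology by construction while keeping
the query-query structure the subtree resolved.
"""

from __future__ import annotations

import io

from dataclasses import dataclass

import dendropy
import numpy as np

from .placement import DistanceProfile, place_query
from .trees import (
    DistanceMatrix,
    PhyloTree,
    attach_query,
    parse_newick,
    patristic_distances,
    _topological_matrix,
)

__all__ = [
    "UpdateMatrix",
    "assign_queries_for_update",
    "build_update_matrix",
    "infer_subtree",
    "merge_updated_subtrees",
    "export_supertree_inputs",
]


@dataclass
class UpdateMatrix:
    """Complete distance matrix for one subtree's re-inference.

    ``pinned`` flags backbone-backbone entries, which equal backbone
    patristic distances exactly.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    pinned: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        k = len(self.labels)
        self.values = np.asarray(self.values, float)
        self.pinned = np.asarray(self.pinned, bool)
        if self.values.shape != (k, k) or self.pinned.shape != (k, k):
            raise ValueError("matrix shapes must match labels")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")


def assign_queries_for_update(per_gene_scores: list[dict[str, dict[int, float]]]
                              ) -> dict[str, int]:
    """Assign each query to the first-level subtree with the highest score,
    averaging scores across the genes that cover the query (ties -> smaller
    cluster id)."""
    if not per_gene_scores:
        raise ValueError("at least one gene's scores required")
    queries = sorted({q for gene in per_gene_scores for q in gene})
    out: dict[str, int] = {}
    for q in queries:
        sums: dict[int, float] = {}
        n = 0
        for gene in per_gene_scores:
            if q not in gene:
                continue  # gene skipped for this query
            n += 1
            for cid, s in gene[q].items():
                sums[cid] = sums.get(cid, 0.0) + s
        if n == 0:
            raise ValueError(f"query {q!r} missing from all genes")
        out[q] = min(sums, key=lambda cid: (-sums[cid] / n, cid))
    return out


def _lookup(source, a: str, b: str):
    if isinstance(source, DistanceMatrix):
        if a in source._index and b in source._index:
            if source.mask is not None:
                i, j = source._index[a], source._index[b]
                if not source.mask[i, j]:
                    return None
            return source.get(a, b)
        return None
    row = source.get(a)
    if row is not None and b in row:
        return row[b]
    row = source.get(b)
    if row is not None and a in row:
        return row[a]
    return None


def build_update_matrix(subtree_members, queries, per_gene_distances,
                        backbone: PhyloTree) -> UpdateMatrix:
    """Assemble the complete per-subtree distance matrix.

    Query-query and query-backbone entries are medians across genes of the
    supplied estimates; backbone-backbone entries are pinned to patristic
    distances.  A query-involved pair no gene covers is an error.
    """
    if not per_gene_distances:
        raise ValueError("at least one gene required")
    members = sorted(subtree_members)
    queries = sorted(queries)
    labels = members + queries
    k = len(labels)
    V = np.zeros((k, k))
    P = np.zeros((k, k), bool)
    pat = patristic_distances(backbone, members)
    mi = {m: t for t, m in enumerate(members)}
    for i, a in enumerate(labels):
        for j in range(i + 1, k):
            b = labels[j]
            if a in mi and b in mi:
                V[i, j] = V[j, i] = pat.get(a, b)
                P[i, j] = P[j, i] = True
                continue
            vals = []
            for gene in per_gene_distances:
                v = _lookup(gene, a, b)
                if v is not None:
                    vals.append(v)
            if not vals:
                raise ValueError(f"no gene provides a distance for pair ({a!r}, {b!r})")
            V[i, j] = V[j, i] = float(np.median(vals))
    # saturated (infinite) estimates are capped so distance methods stay finite
    finite = V[np.isfinite(V)]
    if np.any(~np.isfinite(V)):
        cap = 2.0 * (finite.max() if finite.size else 1.0)
        V[~np.isfinite(V)] = cap
    return UpdateMatrix(tuple(labels), V, P)


# ---------------------------------------------------------------------------
# Distance-based inference
# ---------------------------------------------------------------------------

def _nj_tree(matrix: UpdateMatrix) -> PhyloTree:
    labels = matrix.labels
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{v:.10g}" for v in matrix.values[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    dtree = pdm.nj_tree()
    # NJ can estimate negative branch lengths; clamp before conversion
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return parse_newick(dtree.as_string(schema="newick", suppress_rooting=True))


def _pauplin_length(tree: PhyloTree, dmat: DistanceMatrix) -> float:
    """Balanced minimum-evolution tree length (Pauplin's formula):
    sum over leaf pairs of d_ij * 2^(1 - topological path length)."""
    labels = list(dmat.labels)
    T = _topological_matrix(tree, labels)
    iu = np.triu_indices(len(labels), 1)
    return float((dmat.values[iu] * np.exp2(1.0 - T[iu])).sum())


def _nni_neighbors(tree: PhyloTree):
    """Yield (v, child_of_v, unit_of_u) swap descriptors for internal edges."""
    for v in list(tree.postorder()):
        if v is tree.root or v.is_leaf() or v.parent is None:
            continue
        u = v.parent
        if len(v.children) != 2:
            continue
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            continue
        c = sibs[0]
        yield v, v.children[0], c
        yield v, v.children[1], c


def _swap(v, b, c):
    """Exchange subtree b (child of v) with subtree c (child of v.parent)."""
    u = v.parent
    bi = v.children.index(b)
    ci = u.children.index(c)
    v.children[bi] = c
    c.parent = v
    u.children[ci] = b
    b.parent = u


def _ols_branch_lengths(tree: PhyloTree, dmat: DistanceMatrix) -> None:
    """Ordinary least-squares branch lengths given the topology; clamped >= 0."""
    labels = list(dmat.labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    edges = [n for n in tree.postorder() if n is not tree.root]
    below = tree.leafset_below()
    n = len(labels)
    iu, ju = np.triu_indices(n, 1)
    A = np.zeros((len(iu), len(edges)))
    for e, node in enumerate(edges):
        inside = np.zeros(n, bool)
        for lab in below[node]:
            inside[idx[lab]] = True
        A[:, e] = inside[iu] ^ inside[ju]
    y = dmat.values[iu, ju]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    for e, node in enumerate(edges):
        node.length = float(max(x[e], 0.0))


def infer_subtree(matrix: UpdateMatrix, method: str = "bme",
                  max_sweeps: int = 20) -> PhyloTree:
    """Distance-based re-inference of one subtree.

    ``nj`` is canonical neighbor joining; ``bme`` starts from NJ and applies
    nearest-neighbor-interchange hill climbing on the balanced
    minimum-evolution length, then fits OLS branch lengths.  Negative branch
    length estimates are clamped to zero.
    """
    if len(matrix.labels) < 3:
        raise ValueError("subtree inference needs at least 3 labels")
    tree = _nj_tree(matrix)
    if method == "nj":
        return tree
    if method != "bme":
        raise ValueError(f"unknown method {method!r}")
    dmat = DistanceMatrix(matrix.labels, matrix.values)
    best = _pauplin_length(tree, dmat)
    for _ in range(max_sweeps):
        improved = False
        for v, b, c in list(_nni_neighbors(tree)):
            if v.parent is None or b not in v.children or c not in v.parent.children:
                continue  # stale descriptor after an accepted swap this sweep
            _swap(v, b, c)
            score = _pauplin_length(tree, dmat)
            if score < best - 1e-12:
                best = score
                improved = True
            else:
                _swap(v, c, b)  # revert
        if not improved:
            break
    tree._reindex()
    _ols_branch_lengths(tree, dmat)
    return tree


# ---------------------------------------------------------------------------
# Backbone-preserving merge
# ---------------------------------------------------------------------------

def merge_updated_subtrees(backbone: PhyloTree, updated: dict[int, PhyloTree],
                           assignments: dict[str, int],
                           weighting: str = "fm") -> PhyloTree:
    """Graft every query onto the full backbone, preserving its topology.

    Queries of each subtree are placed one at a time (nearest to the backbone
    first) on the growing tree via constrained least squares, using the
    query's path-length distances in its updated subtree to the subtree
    members already present.  The restriction of the result to backbone
    leaves is therefore topologically identical to the backbone.
    """
    merged = backbone.copy()
    backbone_leaves = set(backbone.leaf_labels())
    seen: set[str] = set()
    for cid in sorted(updated):
        sub = updated[cid]
        members = set(sub.leaf_labels())
        queries = sorted(members - backbone_leaves)
        for q in queries:
            if assignments.get(q) != cid:
                raise ValueError(f"query {q!r} appears in subtree {cid} but is "
                                 f"assigned to {assignments.get(q)!r}")
        pat = patristic_distances(sub)
        anchors = sorted(members & backbone_leaves)
        if len(anchors) < 1:
            raise ValueError(f"updated subtree {cid} shares no leaf with the backbone")
        order = sorted(queries, key=lambda q: (min(pat.get(q, a) for a in anchors), q))
        present = list(anchors)
        for q in order:
            dists = {l: pat.get(q, l) for l in present}
            if len(dists) < 2:
                raise ValueError(
                    f"subtree {cid} gives fewer than 2 reference distances for {q!r}"
                )
            profile = DistanceProfile.from_dict(q, sorted(dists), dists)
            tie_filter = _split_tie_filter(sub, merged, q, present)
            pl = place_query(profile, merged, weighting=weighting,
                             tie_filter=tie_filter)
            attach_query(merged, pl.edge_id, pl.distal, pl.pendant, q)
            present.append(q)
            seen.add(q)
    missing = set(assignments) - seen
    if missing:
        raise ValueError(f"queries in no updated subtree: {sorted(missing)}")
    return merged


def _split_tie_filter(subtree: PhyloTree, merged: PhyloTree, q: str,
                      present: list[str]):
    """Tie filter preferring attachment edges consistent with the updated
    subtree's topology.

    With one-sided reference distances the least-squares residual can tie
    along a whole path of edges; the re-inferred subtree's bipartitions then
    disambiguate: attaching ``q`` on edge e makes it sibling to the present
    members below e, which must form a split with ``q`` in the subtree
    restricted to the members placed so far.
    """
    from .trees import restrict_to_taxa

    try:
        rest = restrict_to_taxa(subtree, set(present) | {q})
    except Exception:
        return None
    leafset = frozenset(rest.leaf_labels())
    splits = set()
    below_r = rest.leafset_below()
    for node in rest.postorder():
        if node is rest.root:
            continue
        side = frozenset(below_r[node])
        splits.add(side)
        splits.add(leafset - side)
    present_set = set(present)
    below_m = merged.leafset_below()

    def _filter(tied):
        good = []
        for r in tied:
            node = merged.node_for_edge(r[1])
            a = below_m[node] & present_set
            if not a or a == present_set:
                # only the trivial pendant split is created: consistent
                good.append(r)
                continue
            side = frozenset(a | {q})
            if side in splits or (leafset - side) in splits:
                good.append(r)
        return good

    return _filter


def export_supertree_inputs(backbone: PhyloTree, updated: dict[int, PhyloTree]) -> str:
    """Multi-tree Newick (backbone first) for an external supertree tool."""
    lines = [backbone.to_newick()]
    for cid in sorted(updated):
        lines.append(updated[cid].to_newick())
    return "\n".join(lines) + "\n"
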