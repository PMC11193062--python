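"""Distance-based placement of queries onto a backbone tree.

For each candidate edge (u parent, v child, length l) the attachment is
parameterized by the pendant length p >= 0 and the distal position
x in [0, l] measured from u.  The expected distance to an observed leaf i is

    p + x + dist(u, i)        for leaves on the proximal (u) side,
    p + (l - x) + dist(v, i)  for leaves below v,

and the placement minimizes the weighted residual
Q(p, x) = sum_i w_i (d_i - dhat_i)^2 with w_i in {1, 1/d_i, 1/d_i^2} (OLS /
balanced / Fitch-Margoliash weighting).  The quadratic is convex, so the
box-constrained optimum is found exactly by comparing the unconstrained
stationary point with the re-optimized boundary faces and corners.  Missing
distances are simply left out of the sum, so ensembles that cover only part
of the backbone still place every query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .encoding import EncodedAlignment
from .neural import ModelSelection, SequenceEmbedder
from .trees import PhyloTree, patristic_distances, write_newick

__all__ = [
    "DistanceProfile",
    "Placement",
    "merge_distance_profiles",
    "jc_distance",
    "place_query",
    "place_with_ensemble",
    "write_jplace",
    "read_jplace",
]

JC_SATURATED = float("inf")
_WEIGHTINGS = ("ols", "be", "fm")


@dataclass
class DistanceProfile:
    """Per-backbone-leaf distance estimates for one query, with missing mask."""

    query_id: str
    labels: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray  # True where observed
    provenance: np.ndarray  # number of models contributing per leaf

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        self.provenance = np.asarray(self.provenance, int)
        k = len(self.labels)
        if not (self.values.shape == self.mask.shape == self.provenance.shape == (k,)):
            raise ValueError("profile arrays must align with labels")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("negative distances in profile")
        if np.any(self.mask != (self.provenance > 0)):
            raise ValueError("mask inconsistent with provenance counts")

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def observed(self) -> dict[str, float]:
        return {l: float(v) for l, v, m in zip(self.labels, self.values, self.mask) if m}

    @classmethod
    def from_dict(cls, query_id: str, labels, dists: dict[str, float],
                  counts: dict[str, int] | None = None) -> "DistanceProfile":
        labels = tuple(labels)
        vals = np.zeros(len(labels))
        mask = np.zeros(len(labels), bool)
        prov = np.zeros(len(labels), int)
        for i, lab in enumerate(labels):
            if lab in dists:
                vals[i] = dists[lab]
                mask[i] = True
                prov[i] = counts.get(lab, 1) if counts else 1
        return cls(query_id, labels, vals, mask, prov)


@dataclass
class Placement:
    """One query's placement: edge, pendant length, distal position, residual."""

    query_id: str
    edge_id: int
    pendant: float
    distal: float
    residual: float
    n_used: int

    def __post_init__(self):
        if self.pendant < 0 or self.distal < -1e-12 or self.residual < -1e-9:
            raise ValueError("placement violates box constraints")


# ---------------------------------------------------------------------------
# Profile merging and JC baseline distances
# ---------------------------------------------------------------------------

def merge_distance_profiles(query_id: str, labels, partials: list[dict[str, float]]
                            ) -> DistanceProfile:
    """Combine per-model distance vectors into one profile by the median.

    A leaf covered by a single model keeps that value; a leaf covered by
    several gets the median (midpoint of the central two for even counts);
    an uncovered leaf stays missing with provenance 0.
    """
    labels = tuple(labels)
    vals = np.zeros(len(labels))
    mask = np.zeros(len(labels), bool)
    prov = np.zeros(len(labels), int)
    for i, lab in enumerate(labels):
        contributions = [p[lab] for p in partials if lab in p]
        if any(v < 0 for v in contributions):
            raise ValueError(f"negative input distance for leaf {lab!r}")
        if contributions:
            vals[i] = float(np.median(contributions))
            mask[i] = True
            prov[i] = len(contributions)
    return DistanceProfile(query_id, labels, vals, mask, prov)


def jc_distance(seq1: str, seq2: str) -> float:
    """Jukes--Cantor distance between two aligned sequences.

    Computed over sites where both sequences are non-gap nucleotides;
    saturated pairs (mismatch fraction >= 3/4) return +inf.  Raises if no
    overlapping non-gap site exists (distance undefined).
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal lengths")
    nuc = frozenset("ACGTU")
    n = mm = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        a = "T" if a == "U" else a
        b = "T" if b == "U" else b
        if a in nuc and b in nuc:
            n += 1
            mm += a != b
    if n == 0:
        raise ValueError("no overlapping non-gap sites; JC distance undefined")
    p = mm / n
    if p >= 0.75:
        return JC_SATURATED
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


# ---------------------------------------------------------------------------
# Constrained least-squares placement
# ---------------------------------------------------------------------------

def _node_distances(tree: PhyloTree, leaf_labels) -> dict:
    """For each observed leaf, distance to every node (dict node -> float)."""
    from collections import deque

    out = {}
    for lab in leaf_labels:
        start = tree.node_for_leaf(lab)
        dist = {start: 0.0}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            nbrs = [(c, c.length) for c in node.children]
            if node.parent is not None:
                nbrs.append((node.parent, node.length))
            for nb, w in nbrs:
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    queue.append(nb)
        out[lab] = dist
    return out


def _solve_edge(r: np.ndarray, a: np.ndarray, w: np.ndarray, l: float):
    """Minimize sum w_i (r_i - p - a_i x)^2 over p >= 0, 0 <= x <= l."""
    sw = w.sum()
    swa = (w * a).sum()
    swaa = sw  # a_i^2 == 1
    swr = (w * r).sum()
    swar = (w * a * r).sum()

    def q(p, x):
        e = r - p - a * x
        return float((w * e * e).sum())

    cands = []
    det = sw * swaa - swa * swa
    if det > 1e-14 * sw * sw:
        p0 = (swr * swaa - swa * swar) / det
        x0 = (sw * swar - swa * swr) / det
        if p0 >= 0 and 0 <= x0 <= l:
            cands.append((p0, x0))
    # p = 0 face: x* = swar / swaa
    x1 = min(max(swar / swaa, 0.0), l)
    cands.append((0.0, x1))
    # x = 0 face: p* = swr / sw
    cands.append((max(swr / sw, 0.0), 0.0))
    # x = l face: p* = sum w (r - a l) / sw
    pl = max((w * (r - a * l)).sum() / sw, 0.0)
    cands.append((pl, l))
    best = min(cands, key=lambda px: q(*px))
    return best[0], best[1], q(*best)


def _edge_fits(profile: DistanceProfile, backbone: PhyloTree,
               weighting: str = "fm") -> list[tuple[float, int, float, float]]:
    """Constrained least-squares fit (Q*, edge_id, p, x) on every edge."""
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
    obs = profile.observed()
    if len(obs) < 2:
        raise ValueError("placement requires at least 2 observed distances")
    obs_labels = sorted(obs)
    d = np.array([obs[l] for l in obs_labels])
    d_safe = np.maximum(d, 1e-8)
    if weighting == "ols":
        w = np.ones_like(d)
    elif weighting == "be":
        w = 1.0 / d_safe
    else:
        w = 1.0 / d_safe ** 2

    node_dist = _node_distances(backbone, obs_labels)
    below = backbone.leafset_below()
    results = []
    for eid in backbone.edge_ids():
        v = backbone.node_for_edge(eid)
        u = v.parent
        l = v.length
        distal_set = below[v]
        a = np.empty(len(obs_labels))
        c = np.empty(len(obs_labels))
        for t, lab in enumerate(obs_labels):
            if lab in distal_set:
                a[t] = -1.0
                c[t] = l + node_dist[lab][v]
            else:
                a[t] = 1.0
                c[t] = node_dist[lab][u]
        p, x, q = _solve_edge(d - c, a, w, l)
        results.append((q, eid, p, x))
    return results


def _pick_result(results, profile: DistanceProfile, backbone: PhyloTree,
                 tie_filter=None) -> Placement:
    """Select the best edge; break residual ties toward the edge nearest the
    leaf with the smallest observed distance, then by smaller edge id.  An
    optional ``tie_filter`` may first narrow the tied set (e.g. using
    topological side information)."""
    obs = profile.observed()
    qmin = min(r[0] for r in results)
    tol = 1e-10 * max(1.0, qmin)
    tied = [r for r in results if r[0] <= qmin + tol]
    if len(tied) > 1 and tie_filter is not None:
        narrowed = tie_filter(tied)
        if narrowed:
            tied = narrowed
    if len(tied) > 1:
        nearest_leaf = min(obs, key=lambda lab: (obs[lab], lab))
        from .trees import placement_edge_error

        ref_edge = backbone.node_for_leaf(nearest_leaf).edge_id
        tied.sort(key=lambda r: (placement_edge_error(backbone, r[1], ref_edge), r[1]))
    q, eid, p, x = tied[0]
    return Placement(profile.query_id, eid, float(p), float(x),
                     float(max(q, 0.0)), len(obs))


def place_query(profile: DistanceProfile, backbone: PhyloTree,
                weighting: str = "fm", tie_filter=None,
                max_observed: int | None = None) -> Placement:
    """Least-squares placement of one query from its distance profile.

    Ties between edges with (numerically) equal residual are broken toward
    the edge nearest to the leaf with the smallest observed distance, then by
    the smaller edge id.  ``max_observed`` optionally restricts the fit to
    the B smallest observed distances (off by default): distant references
    carry the least signal under the 1/d² weighting.
    """
    if max_observed is not None and profile.n_observed > max_observed:
        obs = profile.observed()
        keep = set(sorted(obs, key=lambda l: (obs[l], l))[:max_observed])
        profile = DistanceProfile.from_dict(
            profile.query_id, profile.labels,
            {l: obs[l] for l in keep},
            {l: int(c) for l, c in zip(profile.labels, profile.provenance)
             if l in keep})
    results = _edge_fits(profile, backbone, weighting)
    return _pick_result(results, profile, backbone, tie_filter=tie_filter)


def place_with_ensemble(query_id: str, query_row: np.ndarray,
                        selection: ModelSelection,
                        models: dict[int, SequenceEmbedder],
                        model_alignments: dict[int, EncodedAlignment],
                        backbone: PhyloTree,
                        weighting: str = "fm") -> Placement:
    """Embed a query under each selected cluster's model, merge, place.

    Leaves outside every selected model's augmented cluster stay missing in
    the merged profile; the median rule applies where models overlap.
    """
    from .neural import embed_distances

    if not selection.selected:
        raise ValueError("empty model selection")
    partials = []
    for cid in selection.cluster_ids:
        model = models[cid]
        partials.append(embed_distances(model, query_row, model_alignments[cid]))
    labels = sorted(backbone.leaf_labels())
    profile = merge_distance_profiles(query_id, labels, partials)
    return place_query(profile, backbone, weighting=weighting)


# ---------------------------------------------------------------------------
# jplace I/O
# ---------------------------------------------------------------------------

_JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio",
                  "distal_length", "pendant_length"]


def write_jplace(placements: list[Placement], backbone: PhyloTree, path=None) -> str:
    """Serialize placements as jplace v3 over the edge-numbered backbone."""
    doc = {
        "version": 3,
        "tree": write_newick(backbone, edge_numbers=True),
        "fields": _JPLACE_FIELDS,
        "placements": [
            {
                "p": [[pl.edge_id, -pl.residual, 1.0, pl.distal, pl.pendant]],
                "n": [pl.query_id],
            }
            for pl in placements
        ],
        "metadata": {"software": "cdepp"},
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_jplace(text: str) -> list[Placement]:
    """Parse a jplace v3 document produced by :func:`write_jplace`."""
    doc = json.loads(text)
    fields = doc["fields"]
    idx = {f: i for i, f in enumerate(fields)}
    out = []
    for rec in doc["placements"]:
        row = rec["p"][0]
        name = rec["n"][0] if "n" in rec else rec["nm"][0][0]
        out.append(Placement(
            query_id=name,
            edge_id=int(row[idx["edge_num"]]),
            pendant=float(row[idx["pendant_length"]]),
            distal=float(row[idx["distal_length"]]),
            residual=-float(row[idx["likelihood"]]),
            n_used=0,
        ))
    return out
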