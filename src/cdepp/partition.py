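"""Backbone decomposition into overlapping training clusters.

The first level splits the backbone into the minimum number of clusters of at
most ``m`` leaves, each the leaf set of a connected subgraph (the min-count /
max-size criterion of TreeCluster-style decomposition).  Each first-level
cluster is then augmented with the k nearest outside leaves (by patristic
distance to the cluster) to give the embedders diverse training data, and
subdivided into second-level clusters of at most ``m'`` leaves that define
the classifier's label space.  Subsampling and random-partition baselines are
included for ablation experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import PhyloTree, midpoint_root, patristic_distances

__all__ = [
    "PartitionSet",
    "max_size_partition",
    "compute_k",
    "augment_with_representatives",
    "second_level_partition",
    "baseline_partition",
    "build_partition",
]

DEFAULT_M = 1500
DEFAULT_M_PRIME = 30


@dataclass
class PartitionSet:
    """First-level clusters, their augmented versions and second-level splits.

    ``first_level[i]`` are disjoint leaf sets covering the backbone;
    ``augmented[i]`` is ``first_level[i]`` plus up to ``k`` nearby
    representatives; ``second_level[i]`` partitions ``first_level[i]`` into
    sets of at most ``m_prime`` leaves.
    """

    first_level: list[frozenset]
    augmented: list[frozenset]
    second_level: dict[int, list[frozenset]]
    m: int
    m_prime: int
    k: int

    def __post_init__(self):
        self.validate()

    @property
    def n_clusters(self) -> int:
        return len(self.first_level)

    def validate(self):
        all_leaves = set()
        for i, t in enumerate(self.first_level):
            if len(t) > self.m:
                raise ValueError(f"first-level cluster {i} exceeds m={self.m}")
            if all_leaves & t:
                raise ValueError("first-level clusters overlap")
            all_leaves |= t
        for i, (t, th) in enumerate(zip(self.first_level, self.augmented)):
            if not t <= th:
                raise ValueError(f"augmented cluster {i} does not contain its cluster")
            if len(th - t) > self.k:
                raise ValueError(f"augmented cluster {i} has more than k extras")
        covered = set()
        for i, subs in self.second_level.items():
            home = self.first_level[i]
            for s in subs:
                if not s <= home:
                    raise ValueError("second-level set escapes its first-level cluster")
                if len(s) > self.m_prime:
                    raise ValueError("second-level set exceeds m'")
                if covered & s:
                    raise ValueError("second-level sets overlap")
                covered |= s
        if covered != all_leaves:
            raise ValueError("second-level sets do not cover all leaves")

    def home_cluster(self) -> dict[str, int]:
        """Map each leaf to its first-level cluster index."""
        out = {}
        for i, t in enumerate(self.first_level):
            for lab in t:
                out[lab] = i
        return out

    def second_level_labels(self) -> dict[str, tuple[int, int]]:
        """Map each leaf to its (first_level, second_level) index pair."""
        out = {}
        for i, subs in self.second_level.items():
            for j, s in enumerate(subs):
                for lab in s:
                    out[lab] = (i, j)
        return out

    # -- TSV serialization ---------------------------------------------
    def to_tsv(self) -> str:
        rep_in: dict[str, list[int]] = {}
        for i, (t, th) in enumerate(zip(self.first_level, self.augmented)):
            for lab in th - t:
                rep_in.setdefault(lab, []).append(i)
        lab2 = self.second_level_labels()
        lines = ["leaf\tfirst_level_id\tsecond_level_id\tis_representative_in"]
        for lab in sorted(lab2):
            i, j = lab2[lab]
            reps = ",".join(str(r) for r in sorted(rep_in.get(lab, [])))
            lines.append(f"{lab}\t{i}\t{j}\t{reps}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, m: int, m_prime: int, k: int) -> "PartitionSet":
        first: dict[int, set] = {}
        second: dict[tuple[int, int], set] = {}
        reps: dict[int, set] = {}
        for line in text.strip().splitlines()[1:]:
            lab, i, j, rep = (line.split("\t") + [""])[:4]
            i, j = int(i), int(j)
            first.setdefault(i, set()).add(lab)
            second.setdefault((i, j), set()).add(lab)
            for r in rep.split(","):
                if r:
                    reps.setdefault(int(r), set()).add(lab)
        c = max(first) + 1
        first_level = [frozenset(first[i]) for i in range(c)]
        augmented = [frozenset(first[i] | reps.get(i, set())) for i in range(c)]
        second_level = {
            i: [frozenset(second[(i, j)]) for j in sorted(jj for ii, jj in second if ii == i)]
            for i in range(c)
        }
        return cls(first_level, augmented, second_level, m=m, m_prime=m_prime, k=k)


# ---------------------------------------------------------------------------
# First-level decomposition
# ---------------------------------------------------------------------------

def _cluster_sort_key(cluster: set) -> tuple:
    # close larger clusters first; ties by smaller lexicographic minimum label
    return (-len(cluster), min(cluster))


def max_size_partition(tree: PhyloTree, m: int) -> list[frozenset]:
    """Partition the leaf set into the fewest clusters of size <= m, each the
    leaf set of a connected subgraph.

    Greedy linear-time post-order sweep: every subtree carries one open
    cluster; when the children's open clusters jointly exceed ``m`` leaves,
    children clusters are closed in decreasing size order until the remainder
    fits; the root closes the final open cluster.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if tree.n_leaves == 0:
        return []
    root = tree.root
    if len(root.children) > 2:
        tree = midpoint_root(tree)
        root = tree.root
    closed: list[frozenset] = []
    open_at: dict = {}
    order = list(tree.postorder())
    for node in order:
        if node.is_leaf():
            open_at[node] = {node.label}
            continue
        parts = [open_at.pop(c) for c in node.children]
        total = sum(len(p) for p in parts)
        if total > m:
            parts.sort(key=_cluster_sort_key)
            while total > m:
                biggest = parts.pop(0)
                closed.append(frozenset(biggest))
                total -= len(biggest)
        merged = set()
        for p in parts:
            merged |= p
        open_at[node] = merged
    last = open_at[root]
    if last:
        closed.append(frozenset(last))
    return sorted(closed, key=lambda s: min(s))


def compute_k(m: int, c: int) -> int:
    """Number of representatives per cluster: ceil(m * ln(c) / 3).

    Zero when there is a single cluster (nothing outside to borrow).
    """
    if m < 1 or c < 1:
        raise ValueError("m and c must be >= 1")
    if c == 1:
        return 0
    return int(math.ceil(m * math.log(c) / 3.0))


def augment_with_representatives(
    tree: PhyloTree, clusters: list[frozenset], k: int
) -> list[frozenset]:
    """Add to each cluster the k outside leaves closest to it.

    Closeness of an outside leaf is its minimum patristic distance to any
    member of the cluster; ties are broken by label order.
    """
    labels = sorted(tree.leaf_labels())
    if k == 0 or len(clusters) <= 1:
        return [frozenset(t) for t in clusters]
    pat = patristic_distances(tree, labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    out = []
    for t in clusters:
        inside = np.array([idx[l] for l in t])
        outside = [l for l in labels if l not in t]
        if not outside:
            out.append(frozenset(t))
            continue
        o_idx = np.array([idx[l] for l in outside])
        dmin = pat.values[np.ix_(o_idx, inside)].min(axis=1)
        ranked = sorted(zip(dmin, outside))
        chosen = {lab for _, lab in ranked[:k]}
        out.append(frozenset(t | chosen))
    return out


def second_level_partition(
    tree: PhyloTree, first_level: list[frozenset], m_prime: int
) -> dict[int, list[frozenset]]:
    """Split each first-level cluster into connected sets of <= m' leaves by
    running :func:`max_size_partition` on its induced subtree."""
    if m_prime < 1:
        raise ValueError(f"m_prime must be >= 1, got {m_prime}")
    from .trees import restrict_to_taxa

    out: dict[int, list[frozenset]] = {}
    for i, t in enumerate(first_level):
        if len(t) <= m_prime:
            out[i] = [frozenset(t)]
        elif len(t) == 1:
            out[i] = [frozenset(t)]
        else:
            sub = restrict_to_taxa(tree, t)
            out[i] = max_size_partition(sub, m_prime)
    return out


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def baseline_partition(leaves, mode: str, size: int, seed: int = 0) -> list[frozenset]:
    """Non-phylogenetic baselines: seeded random partition or one subsample."""
    if size < 1:
        raise ValueError("size must be >= 1")
    leaves = sorted(leaves)
    rng = np.random.default_rng(seed)
    if mode == "subsample":
        if size > len(leaves):
            raise ValueError(f"subsample size {size} exceeds {len(leaves)} leaves")
        pick = rng.choice(len(leaves), size=size, replace=False)
        return [frozenset(leaves[i] for i in pick)]
    if mode == "random":
        perm = rng.permutation(len(leaves))
        n_sets = math.ceil(len(leaves) / size)
        out = []
        for s in range(n_sets):
            chunk = perm[s * size:(s + 1) * size]
            out.append(frozenset(leaves[i] for i in chunk))
        return out
    raise ValueError(f"unknown baseline mode {mode!r}")


# ---------------------------------------------------------------------------
# Convenience: full PartitionSet construction
# ---------------------------------------------------------------------------

def build_partition(
    tree: PhyloTree,
    m: int = DEFAULT_M,
    m_prime: int = DEFAULT_M_PRIME,
    k: int | None = None,
    use_representatives: bool = True,
) -> PartitionSet:
    """Run the full three-stage decomposition on a backbone tree."""
    first = max_size_partition(tree, m)
    c = len(first)
    if k is None:
        k = compute_k(m, c)
    if not use_representatives:
        k_eff = 0
    else:
        k_eff = k
    augmented = augment_with_representatives(tree, first, k_eff)
    second = second_level_partition(tree, first, m_prime)
    return PartitionSet(first, augmented, second, m=m, m_prime=m_prime, k=k_eff)
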