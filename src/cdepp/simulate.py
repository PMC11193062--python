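"""Synthetic data generation: species trees, discordant gene trees, sequences.

The generator emulates a prokaryote-style marker-gene study: a birth--death
species tree; gene trees derived from it by random subtree-prune-and-regraft
(SPR) moves until a target normalized Robinson--Foulds discordance is reached
(a topology-level proxy for horizontal gene transfer); indel-free nucleotide
sequences evolved under JC or GTR (so alignments are exact); deduplication of
identical sequences; and query generation either as a random fraction of
leaves or as pruned clades, with the true attachment edge recorded on the
resulting backbone.  Everything is a pure function of the configuration,
including its seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .trees import PhyloTree, TreeNode, parse_newick, prune_with_attachments, rf_distance

__all__ = [
    "SimConfig",
    "simulate_species_tree",
    "perturb_to_discordance",
    "evolve_sequences",
    "dedup_identical",
    "make_queries",
    "simulate_dataset",
]

DEFAULT_TARGET_NRF = 0.38
DEFAULT_QUERY_FRACTION = 0.05


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults follow the desk-scale profile: 256 species, gene trees at
    normalized-RF 0.38 from the species tree, 400 bp indel-free JC
    sequences, 5% of leaves as placement queries.
    """

    n_species: int = 256
    birth_rate: float = 1.0
    death_rate: float = 0.2
    n_genes: int = 1
    target_nrf: float = DEFAULT_TARGET_NRF
    seq_length: int = 400
    model: str = "jc"
    gtr_rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    gtr_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    query_fraction: float = DEFAULT_QUERY_FRACTION
    clade_count: int = 0
    clade_min: int = 5
    clade_max: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_nrf <= 1.0:
            raise ValueError("target_nrf must be in [0, 1]")
        if not 0.0 < self.query_fraction < 1.0:
            raise ValueError("query_fraction must be in (0, 1)")
        if self.clade_min > self.clade_max:
            raise ValueError("clade_min must be <= clade_max")


def simulate_species_tree(n: int, birth: float = 1.0, death: float = 0.2,
                          seed: int = 0) -> PhyloTree:
    """Birth--death species tree with n extant leaves labelled S0..S(n-1)."""
    if n < 4:
        raise ValueError("need at least 4 species")
    if not (birth > death >= 0):
        raise ValueError("rates must satisfy birth > death >= 0")
    rng = _random.Random(seed)
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n, rng=rng,
    )
    # the process stops exactly at the n-th speciation, leaving that cherry
    # with zero-length pendants; run it on for the waiting time to the next
    # event so every tip edge is strictly positive
    extra = rng.expovariate(n * (birth + death)) if birth + death > 0 else 0.0
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"S{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    text = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(text)
    for node in tree.postorder():
        if node is not tree.root and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# SPR perturbation toward a target discordance
# ---------------------------------------------------------------------------

def _random_spr(tree: PhyloTree, rng: np.random.Generator) -> bool:
    """One random SPR move in place; returns False if no legal move found."""
    nodes = [n for n in tree.postorder()
             if n is not tree.root and n.parent is not tree.root]
    if not nodes:
        return False
    for _ in range(20):
        s = nodes[int(rng.integers(len(nodes)))]
        inside = set()
        stack = [s]
        while stack:
            x = stack.pop()
            inside.add(x)
            stack.extend(x.children)
        targets = [n for n in tree.postorder()
                   if n is not tree.root and n not in inside
                   and n is not s.parent and n.parent not in inside]
        targets = [t for t in targets if t is not s]
        if not targets:
            continue
        t = targets[int(rng.integers(len(targets)))]
        # detach s, suppress its old parent
        par = s.parent
        s.detach()
        if len(par.children) == 1 and par.label is None:
            only = par.children[0]
            if par.parent is None:
                only.detach()
                only.length = 0.0
                tree.root = only
            else:
                only.length += par.length
                gp = par.parent
                i = gp.children.index(par)
                gp.children[i] = only
                only.parent = gp
                par.parent = None
        if t.parent is None:  # regraft target vanished with the suppression
            t = t.children[0] if t.children else t
        # split t's edge at its midpoint and hang s there
        mid = TreeNode(None, t.length / 2.0)
        gp = t.parent
        if gp is None:
            continue  # should not happen; retry
        i = gp.children.index(t)
        gp.children[i] = mid
        mid.parent = gp
        t.length = t.length / 2.0
        mid.add_child(t)
        mid.add_child(s)
        for n in tree.postorder():
            n.edge_id = None
        tree._assign_edge_ids()
        return True
    return False


def perturb_to_discordance(species_tree: PhyloTree, target_nrf: float,
                           seed: int = 0, tol: float = 0.05,
                           max_moves: int | None = None) -> PhyloTree:
    """Random SPR moves until the normalized RF to the species tree is within
    ``tol`` of ``target_nrf``; moves overshooting the band are reverted."""
    if not 0.0 <= target_nrf <= 1.0:
        raise ValueError("target_nrf must be in [0, 1]")
    gene = species_tree.copy()
    if target_nrf <= tol:
        return gene
    rng = np.random.default_rng(seed)
    if max_moves is None:
        max_moves = 50 * species_tree.n_leaves
    nrf = 0.0
    for _ in range(max_moves):
        backup = gene.copy()
        if not _random_spr(gene, rng):
            gene = backup
            continue
        new_nrf = rf_distance(species_tree, gene, normalized=True)
        if new_nrf > target_nrf + tol:
            gene = backup  # overshoot: revert and retry with another move
            continue
        nrf = new_nrf
        if abs(nrf - target_nrf) <= tol:
            return gene
    raise RuntimeError(
        f"could not reach nRF {target_nrf}+-{tol} within {max_moves} moves "
        f"(achieved {nrf:.3f})"
    )


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_NUC = "ACGT"


def _jc_transition(t: float) -> np.ndarray:
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _gtr_matrices(rates, freqs):
    """Normalized GTR rate matrix (expected 1 substitution per unit time)."""
    pi = np.asarray(freqs, float)
    pi = pi / pi.sum()
    ac, ag, at, cg, ct, gt = rates
    R = np.array([
        [0, ac, ag, at],
        [ac, 0, cg, ct],
        [ag, cg, 0, gt],
        [at, ct, gt, 0],
    ], float)
    Q = R * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi


def evolve_sequences(tree: PhyloTree, length: int, model: str = "jc",
                     seed: int = 0, gtr_rates=None, gtr_freqs=None
                     ) -> dict[str, str]:
    """Simulate indel-free sequences down the tree; returns label->sequence.

    The root state is drawn from the stationary distribution; sites are
    i.i.d.; each edge applies the model's transition matrix for its length.
    Non-positive branch lengths act as identity.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if model == "jc":
        pi = np.full(4, 0.25)
        trans = _jc_transition
    elif model == "gtr":
        Q, pi = _gtr_matrices(gtr_rates or (1,) * 6, gtr_freqs or (0.25,) * 4)
        cache: dict[float, np.ndarray] = {}

        def trans(t, _Q=Q, _cache=cache):
            if t not in _cache:
                _cache[t] = expm(_Q * t)
            return _cache[t]
    else:
        raise ValueError(f"unknown substitution model {model!r}")

    states: dict = {}
    states[tree.root] = rng.choice(4, size=length, p=pi)
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            t = max(node.length, 0.0)
            P = trans(t)
            cum = P.cumsum(axis=1)
            parent_state = states[node.parent]
            u = rng.random(length)
            rows = cum[parent_state]
            states[node] = (u[:, None] > rows).sum(axis=1)
        if node.is_leaf():
            out[node.label] = "".join(_NUC[s] for s in states[node])
    # free internal states as soon as possible is unnecessary at this scale
    return dict(sorted(out.items()))


def dedup_identical(seqs: dict[str, str], seed: int = 0
                    ) -> tuple[dict[str, str], list[str]]:
    """Keep one seeded-random representative per identical-sequence group."""
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for lab in sorted(seqs):
        groups.setdefault(seqs[lab], []).append(lab)
    kept: dict[str, str] = {}
    removed: list[str] = []
    for seq, labs in sorted(groups.items(), key=lambda kv: kv[1][0]):
        keep = labs[int(rng.integers(len(labs)))]
        kept[keep] = seq
        removed.extend(l for l in labs if l != keep)
    return dict(sorted(kept.items())), sorted(removed)


# ---------------------------------------------------------------------------
# Query generation
# ---------------------------------------------------------------------------

def make_queries(tree: PhyloTree, mode: str = "leaf_fraction", fraction: float = 0.05,
                 clade_count: int = 2, clade_min: int = 5, clade_max: int = 10,
                 seed: int = 0):
    """Remove queries from the tree and record their true attachments.

    Returns ``(backbone, query_labels, attachments)`` where
    ``attachments[q] = (edge_id, distal, pendant)`` on the backbone.

    ``leaf_fraction`` removes a seeded uniform sample of round(fraction * n)
    leaves; ``clades`` removes whole clades whose sizes fall in
    [clade_min, clade_max].
    """
    rng = np.random.default_rng(seed)
    labels = sorted(tree.leaf_labels())
    n = len(labels)
    if mode == "leaf_fraction":
        n_q = max(1, int(round(fraction * n)))
        if n - n_q < 4:
            raise ValueError("too few leaves would remain")
        pick = rng.choice(n, size=n_q, replace=False)
        queries = sorted(labels[i] for i in pick)
    elif mode == "clades":
        below = tree.leafset_below()
        chosen: list[frozenset] = []
        taken: set = set()
        candidates = [
            (min(below[node]), below[node])
            for node in tree.postorder()
            if node is not tree.root and clade_min <= len(below[node]) <= clade_max
        ]
        candidates.sort()
        order = rng.permutation(len(candidates))
        for idx in order:
            _, leafset = candidates[idx]
            if leafset & taken:
                continue
            chosen.append(leafset)
            taken |= leafset
            if len(chosen) == clade_count:
                break
        if len(chosen) < clade_count:
            raise ValueError(
                f"could not find {clade_count} disjoint clades of size "
                f"[{clade_min}, {clade_max}]"
            )
        if n - len(taken) < 4:
            raise ValueError("too few leaves would remain")
        queries = sorted(taken)
    else:
        raise ValueError(f"unknown query mode {mode!r}")
    backbone, attachments = prune_with_attachments(tree, queries)
    return backbone, queries, attachments


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Bundle of everything one simulator run produces."""

    config: SimConfig
    species_tree: PhyloTree
    gene_trees: list[PhyloTree]
    gene_seqs: list[dict[str, str]]  # post-dedup, including future queries
    backbone: PhyloTree
    queries: list[str]
    attachments: dict[str, tuple[int, float, float]]

    def backbone_seqs(self, gene: int) -> dict[str, str]:
        qs = set(self.queries)
        return {l: s for l, s in self.gene_seqs[gene].items()
                if l not in qs and l in set(self.backbone.leaf_labels())}

    def query_seqs(self, gene: int) -> dict[str, str]:
        return {l: s for l, s in self.gene_seqs[gene].items() if l in set(self.queries)}


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: species tree, gene trees, sequences, queries.

    The species tree is restricted to the taxa that survive deduplication in
    every gene, then queries are pruned from it to form the backbone.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(3 + 2 * cfg.n_genes)
    species = simulate_species_tree(cfg.n_species, cfg.birth_rate, cfg.death_rate,
                                    seed=int(seeds[0]) % (2**31))
    gene_trees = []
    gene_seqs = []
    for g in range(cfg.n_genes):
        gt = perturb_to_discordance(species, cfg.target_nrf,
                                    seed=int(seeds[1 + g]) % (2**31))
        seqs = evolve_sequences(gt, cfg.seq_length, cfg.model,
                                seed=int(seeds[1 + cfg.n_genes + g]) % (2**31),
                                gtr_rates=cfg.gtr_rates, gtr_freqs=cfg.gtr_freqs)
        gene_trees.append(gt)
        gene_seqs.append(seqs)
    # drop taxa whose sequences duplicate another's in any gene
    keep = set(species.leaf_labels())
    for g in range(cfg.n_genes):
        kept, _removed = dedup_identical(gene_seqs[g],
                                         seed=int(seeds[2 + 2 * cfg.n_genes - 1]) % (2**31))
        keep &= set(kept)
    species_kept = species if keep == set(species.leaf_labels()) else _restrict(species, keep)
    gene_seqs = [{l: s for l, s in seqs.items() if l in keep} for seqs in gene_seqs]
    if cfg.clade_count > 0:
        backbone, queries, att = make_queries(
            species_kept, mode="clades", clade_count=cfg.clade_count,
            clade_min=cfg.clade_min, clade_max=cfg.clade_max,
            seed=int(seeds[2]) % (2**31))
    else:
        backbone, queries, att = make_queries(
            species_kept, mode="leaf_fraction", fraction=cfg.query_fraction,
            seed=int(seeds[2]) % (2**31))
    return SimulatedDataset(cfg, species_kept, gene_trees, gene_seqs,
                            backbone, queries, att)


def _restrict(tree: PhyloTree, keep: set) -> PhyloTree:
    from .trees import restrict_to_taxa

    return restrict_to_taxa(tree, keep)
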