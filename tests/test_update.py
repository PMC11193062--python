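"""Tree update: assignment, matrix assembly, distance inference, merging."""

import numpy as np
import pytest

from cdepp.partition import build_partition
from cdepp.simulate import make_queries, perturb_to_discordance, simulate_species_tree
from cdepp.trees import (
    parse_newick,
    patristic_distances,
    quartet_distance,
    restrict_to_taxa,
    rf_distance,
)
from cdepp.update import (
    UpdateMatrix,
    assign_queries_for_update,
    build_update_matrix,
    export_supertree_inputs,
    infer_subtree,
    merge_updated_subtrees,
)


class TestAssignment:
    def test_single_gene_argmax(self):
        out = assign_queries_for_update([{"q": {1: 0.7, 2: 0.3}}])
        assert out == {"q": 1}

    def test_tie_breaks_to_smaller_id(self):
        genes = [{"q": {1: 0.2, 2: 0.8}}, {"q": {1: 0.8, 2: 0.2}}]
        assert assign_queries_for_update(genes) == {"q": 1}

    def test_consensus(self):
        genes = [{"q": {1: 0.1, 2: 0.9}}] * 3
        assert assign_queries_for_update(genes) == {"q": 2}

    def test_gene_missing_query_skipped(self):
        genes = [{"q": {1: 0.9, 2: 0.1}}, {"other": {1: 0.0, 2: 1.0}}]
        out = assign_queries_for_update(genes)
        assert out["q"] == 1 and out["other"] == 2


class TestUpdateMatrix:
    @pytest.fixture
    def backbone(self):
        return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_single_gene_with_pinning(self, backbone):
        src = {"q": {"A": 9.9, "B": 1.0, "C": 2.0, "D": 3.0}}
        um = build_update_matrix(["A", "B", "C", "D"], ["q"], [src], backbone)
        i = {l: t for t, l in enumerate(um.labels)}
        # backbone pair pinned to patristic even if a gene disagrees
        assert um.values[i["A"], i["B"]] == 2.0
        assert um.pinned[i["A"], i["B"]]
        assert um.values[i["A"], i["q"]] == 9.9
        assert not um.pinned[i["A"], i["q"]]

    def test_median_across_genes(self, backbone):
        genes = [{"q": {"A": 1.0, "B": 1, "C": 1, "D": 1}},
                 {"q": {"A": 3.0, "B": 1, "C": 1, "D": 1}}]
        um = build_update_matrix(["A", "B", "C", "D"], ["q"], genes, backbone)
        i = {l: t for t, l in enumerate(um.labels)}
        assert um.values[i["A"], i["q"]] == 2.0

    def test_uncovered_pair_raises(self, backbone):
        src = {"q": {"A": 1.0, "B": 1.0, "C": 1.0}}  # D missing
        with pytest.raises(ValueError, match="D"):
            build_update_matrix(["A", "B", "C", "D"], ["q"], [src], backbone)

    def test_saturated_distances_capped(self, backbone):
        src = {"q": {"A": float("inf"), "B": 1.0, "C": 2.0, "D": 3.0}}
        um = build_update_matrix(["A", "B", "C", "D"], ["q"], [src], backbone)
        assert np.all(np.isfinite(um.values))


class TestInference:
    def test_nj_and_bme_recover_additive_topology(self):
        tree = simulate_species_tree(6, seed=3)
        pat = patristic_distances(tree)
        um = UpdateMatrix(pat.labels, pat.values,
                          np.zeros_like(pat.values, dtype=bool))
        for method in ("nj", "bme"):
            rec = infer_subtree(um, method=method)
            assert rf_distance(tree, rec) == 0

    def test_four_leaf_branch_lengths(self):
        tree = parse_newick("((A:1,B:2):0.5,(C:3,D:4):0.5);")
        pat = patristic_distances(tree)
        um = UpdateMatrix(pat.labels, pat.values,
                          np.zeros_like(pat.values, dtype=bool))
        rec = infer_subtree(um, method="bme")
        assert rf_distance(tree, rec) == 0
        rpat = patristic_distances(rec, list(pat.labels))
        assert np.allclose(rpat.values, pat.values, atol=1e-6)

    def test_small_perturbation_keeps_topology(self):
        tree = simulate_species_tree(8, seed=4)
        pat = patristic_distances(tree)
        internal = [n.length for n in tree.postorder()
                    if n is not tree.root and not n.is_leaf()]
        eps = min(internal) / 4
        V = pat.values.copy()
        V[0, 1] += eps
        V[1, 0] += eps
        um = UpdateMatrix(pat.labels, V, np.zeros_like(V, dtype=bool))
        rec = infer_subtree(um, method="bme")
        assert rf_distance(tree, rec) == 0

    def test_too_few_labels(self):
        um = UpdateMatrix(("A", "B"), np.array([[0, 1.0], [1.0, 0]]),
                          np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            infer_subtree(um)


def _exact_update(sp, backbone, queries, m=16):
    """Run assign -> matrix -> bme -> merge from exact distances."""
    pat = patristic_distances(sp)
    ps = build_partition(backbone, m=m, m_prime=8)
    scores = {
        q: {i: 1.0 / (1e-9 + min(pat.get(q, l) for l in ps.first_level[i]))
            for i in range(ps.n_clusters)}
        for q in queries
    }
    assign = assign_queries_for_update([scores])
    updated = {}
    for cid in sorted(set(assign.values())):
        qs = [q for q, c in assign.items() if c == cid]
        members = sorted(ps.augmented[cid])
        src = {a: {b: pat.get(a, b) for b in members + qs if b != a} for a in qs}
        um = build_update_matrix(members, qs, [src], backbone)
        updated[cid] = infer_subtree(um, method="bme")
    return merge_updated_subtrees(backbone, updated, assign), assign, updated


class TestMerge:
    def test_zero_queries_identity(self, random_tree):
        backbone = random_tree(10, seed=5)
        merged = merge_updated_subtrees(backbone, {}, {})
        assert rf_distance(merged, backbone) == 0

    def test_single_leaf_round_trip(self):
        sp = simulate_species_tree(24, seed=6)
        leaf = sorted(sp.leaf_labels())[3]
        from cdepp.trees import prune_with_attachments

        backbone, _ = prune_with_attachments(sp, [leaf])
        merged, _a, _u = _exact_update(sp, backbone, [leaf], m=24)
        assert rf_distance(merged, sp) == 0

    def test_cherry_queries_stay_adjacent(self):
        sp = simulate_species_tree(32, seed=7)
        # find a cherry (two-leaf clade)
        cherry = None
        below = sp.leafset_below()
        for node in sp.postorder():
            if node is not sp.root and len(below[node]) == 2:
                cherry = sorted(below[node])
                break
        from cdepp.trees import prune_with_attachments

        backbone, _ = prune_with_attachments(sp, cherry)
        merged, _a, _u = _exact_update(sp, backbone, cherry, m=32)
        mb = merged.leafset_below()
        assert any(mb[n] == frozenset(cherry) for n in merged.postorder()
                   if n is not merged.root)

    @pytest.mark.parametrize("seed", range(3))
    def test_backbone_always_preserved_multicluster(self, seed):
        """Even with small clusters and discordant inputs the backbone
        restriction of the merged tree is unchanged."""
        sp = simulate_species_tree(48, seed=seed)
        gene = perturb_to_discordance(sp, 0.3, seed=seed)
        backbone, queries, _att = make_queries(sp, fraction=0.1, seed=seed)
        gpat = patristic_distances(gene)  # deliberately conflicting distances
        ps = build_partition(backbone, m=12, m_prime=6)
        scores = {
            q: {i: 1.0 / (1e-9 + min(gpat.get(q, l) for l in ps.first_level[i]))
                for i in range(ps.n_clusters)}
            for q in queries
        }
        assign = assign_queries_for_update([scores])
        updated = {}
        for cid in sorted(set(assign.values())):
            qs = [q for q, c in assign.items() if c == cid]
            members = sorted(ps.augmented[cid])
            src = {a: {b: gpat.get(a, b) for b in members + qs if b != a}
                   for a in qs}
            um = build_update_matrix(members, qs, [src], backbone)
            updated[cid] = infer_subtree(um, method="bme")
        merged = merge_updated_subtrees(backbone, updated, assign)
        assert set(merged.leaf_labels()) == set(backbone.leaf_labels()) | set(queries)
        rest = restrict_to_taxa(merged, backbone.leaf_labels())
        assert rf_distance(rest, backbone) == 0

    def test_unassigned_query_raises(self, random_tree):
        backbone = random_tree(10, seed=9)
        with pytest.raises(ValueError, match="no updated subtree"):
            merge_updated_subtrees(backbone, {}, {"ghost": 0})

    def test_export_multitree_newick(self, random_tree):
        backbone = random_tree(8, seed=10)
        sub = random_tree(5, seed=11)
        text = export_supertree_inputs(backbone, {0: sub})
        lines = text.strip().splitlines()
        assert len(lines) == 2
        assert all(ln.endswith(";") for ln in lines)


class TestMultiGene:
    def test_median_combination_not_worse_than_single_gene(self):
        """With several discordant genes, the median-combined update is at
        least as good (quartet distance) as the median single-gene update."""
        rng_seeds = range(4)
        combined_better_or_equal = 0
        for seed in rng_seeds:
            sp = simulate_species_tree(40, seed=seed)
            backbone, queries, _att = make_queries(sp, fraction=0.1, seed=seed)
            genes = [perturb_to_discordance(sp, 0.25, seed=seed * 10 + g)
                     for g in range(4)]
            gpats = [patristic_distances(g) for g in genes]
            ps = build_partition(backbone, m=40, m_prime=8)
            spat = patristic_distances(sp)
            scores = {
                q: {i: 1.0 / (1e-9 + min(spat.get(q, l)
                                         for l in ps.first_level[i]))
                    for i in range(ps.n_clusters)}
                for q in queries
            }
            assign = assign_queries_for_update([scores])

            def run(sources):
                updated = {}
                for cid in sorted(set(assign.values())):
                    qs = [q for q, c in assign.items() if c == cid]
                    members = sorted(ps.augmented[cid])
                    um = build_update_matrix(members, qs, sources, backbone)
                    updated[cid] = infer_subtree(um, method="bme")
                merged = merge_updated_subtrees(backbone, updated, assign)
                return quartet_distance(sp, merged, sample_size=20000, seed=1)

            def as_source(gpat):
                return {q: {l: gpat.get(q, l)
                            for l in gpat.labels if l != q}
                        for q in queries}

            single = [run([as_source(gp)]) for gp in gpats]
            multi = run([as_source(gp) for gp in gpats])
            if multi <= float(np.median(single)) + 1e-9:
                combined_better_or_equal += 1
        assert combined_better_or_equal >= 3
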