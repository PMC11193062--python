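"""Distance merging, JC distances, constrained-LS placement, jplace I/O."""

import json
import math

import numpy as np
import pytest

from cdepp.placement import (
    DistanceProfile,
    Placement,
    jc_distance,
    merge_distance_profiles,
    place_query,
    read_jplace,
    write_jplace,
)
from cdepp.trees import (
    parse_edge_numbered_newick,
    patristic_distances,
    placement_edge_error,
    prune_with_attachments,
)


class TestMergeProfiles:
    def test_median_rules(self):
        labels = ("L1", "L2", "L3")
        partials = [{"L1": 1.0, "L2": 1.0}, {"L1": 2.0, "L2": 3.0}, {"L1": 9.0}]
        prof = merge_distance_profiles("q", labels, partials)
        assert prof.observed() == {"L1": 2.0, "L2": 2.0}
        assert prof.provenance.tolist() == [3, 2, 0]
        assert not prof.mask[2]

    def test_negative_input_raises(self):
        with pytest.raises(ValueError, match="negative"):
            merge_distance_profiles("q", ("L1",), [{"L1": -0.5}])

    def test_permutation_invariance(self):
        labels = tuple(f"L{i}" for i in range(5))
        rng = np.random.default_rng(0)
        partials = [{lab: float(rng.random()) for lab in labels[:4]}
                    for _ in range(3)]
        a = merge_distance_profiles("q", labels, partials)
        b = merge_distance_profiles("q", labels, list(reversed(partials)))
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.provenance, b.provenance)


class TestJC:
    def test_identical_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_p_tenth_closed_form(self):
        d = jc_distance("A" * 9 + "C", "A" * 10)
        assert d == pytest.approx(0.10733, abs=1e-5)

    def test_saturation_sentinel(self):
        assert math.isinf(jc_distance("AAAA", "CCCC"))

    def test_gaps_ignored(self):
        # only the two mutually non-gap sites count
        assert jc_distance("AC--", "A-G-") == 0.0

    def test_no_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            jc_distance("AC--", "--GT")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jc_distance("ACG", "AC")


class TestPlaceQuery:
    def test_quartet_internal_edge_optimum(self, quartet_tree):
        """The verified optimum sits on the internal edge with zero residual,
        0.5 from the AB junction (pendant absorbed)."""
        prof = DistanceProfile.from_dict(
            "q", sorted(quartet_tree.leaf_labels()),
            {"A": 1.5, "B": 1.5, "C": 2.5, "D": 2.5})
        pl = place_query(prof, quartet_tree, weighting="ols")
        node = quartet_tree.node_for_edge(pl.edge_id)
        assert not node.is_leaf()
        assert pl.residual == pytest.approx(0.0, abs=1e-12)
        # distance of the attachment point from the AB junction along the
        # internal path: the point is 0.5 above the AB node
        labels = {c.label for c in node.children}
        if labels == {"A", "B"}:
            assert node.length - pl.distal == pytest.approx(0.5)
        else:
            assert pl.distal + node.length == pytest.approx(1.5)

    def test_two_observed_distances_suffice(self, quartet_tree):
        prof = DistanceProfile.from_dict(
            "q", sorted(quartet_tree.leaf_labels()), {"A": 1.5, "B": 1.5})
        pl = place_query(prof, quartet_tree)
        assert pl.n_used == 2

    def test_too_few_distances_raise(self, quartet_tree):
        prof = DistanceProfile.from_dict(
            "q", sorted(quartet_tree.leaf_labels()), {"A": 1.0})
        with pytest.raises(ValueError, match="at least 2"):
            place_query(prof, quartet_tree)

    @pytest.mark.parametrize("weighting", ["ols", "be", "fm"])
    def test_exact_distance_recovery(self, random_tree, weighting):
        tree = random_tree(20, seed=3, death=0.2)
        pat = patristic_distances(tree)
        for leaf in tree.leaf_labels()[:6]:
            backbone, att = prune_with_attachments(tree, [leaf])
            true_edge, _x, true_p = att[leaf]
            dists = {l: pat.get(leaf, l) for l in backbone.leaf_labels()}
            prof = DistanceProfile.from_dict(leaf, sorted(dists), dists)
            pl = place_query(prof, backbone, weighting=weighting)
            assert placement_edge_error(backbone, true_edge, pl.edge_id) == 0
            assert pl.pendant == pytest.approx(true_p, abs=1e-6)
            assert pl.residual == pytest.approx(0.0, abs=1e-9)

    def test_monotone_degradation_with_noise(self, random_tree):
        """Mean edge error never decreases as distance noise grows."""
        tree = random_tree(24, seed=5, death=0.2)
        pat = patristic_distances(tree)
        rng = np.random.default_rng(0)
        sigmas = [0.0, 0.3, 1.2]
        means = []
        for sigma in sigmas:
            errs = []
            for rep in range(60):
                leaf = tree.leaf_labels()[rep % tree.n_leaves]
                backbone, att = prune_with_attachments(tree, [leaf])
                dists = {
                    l: max(1e-3, pat.get(leaf, l) + rng.normal(0, sigma))
                    for l in backbone.leaf_labels()
                }
                prof = DistanceProfile.from_dict(leaf, sorted(dists), dists)
                pl = place_query(prof, backbone)
                errs.append(placement_edge_error(backbone, att[leaf][0], pl.edge_id))
            means.append(np.mean(errs))
        assert means[0] <= means[1] + 1e-9 <= means[2] + 0.5


class TestEnsemblePlacement:
    def test_single_model_composition_identity(self, tiny_placer, small_dataset):
        """With one selected model the ensemble equals that model's vector."""
        from cdepp.neural import ModelSelection

        ds = small_dataset
        qlab, qseq = next(iter(ds.query_seqs(0).items()))
        from cdepp.encoding import one_hot_encode

        row = one_hot_encode({qlab: qseq}).row(qlab)
        cid = sorted(tiny_placer.embedders_)[0]
        sel = ModelSelection([(cid, 1.0)])
        prof = tiny_placer.distance_profile(qlab, row, sel)
        direct = tiny_placer.cluster_distance_source(cid, {qlab: qseq})[qlab]
        for lab, cnt in zip(prof.labels, prof.provenance):
            if cnt:
                assert prof.observed()[lab] == pytest.approx(direct[lab], abs=1e-6)
        # leaves outside the cluster stay missing
        outside = set(prof.labels) - set(tiny_placer.embedders_[cid].labels_)
        obs = prof.observed()
        assert all(lab not in obs for lab in outside)

    def test_disjoint_models_union_coverage(self, tiny_placer, small_dataset):
        from cdepp.neural import ModelSelection
        from cdepp.encoding import one_hot_encode

        ds = small_dataset
        qlab, qseq = next(iter(ds.query_seqs(0).items()))
        row = one_hot_encode({qlab: qseq}).row(qlab)
        cids = sorted(tiny_placer.embedders_)[:2]
        sel = ModelSelection([(cids[0], 1.0), (cids[1], 0.9)])
        prof = tiny_placer.distance_profile(qlab, row, sel)
        covered = {lab for e in cids for lab in tiny_placer.embedders_[e].labels_}
        assert {l for l, m in zip(prof.labels, prof.mask) if m} == covered

    def test_backbone_self_placement(self, tiny_placer, small_dataset):
        """A backbone sequence replayed as query lands on its own edge."""
        ds = small_dataset
        seqs = ds.backbone_seqs(0)
        lab = sorted(seqs)[0]
        pl = tiny_placer.predict({lab + "_replay": seqs[lab]})[0]
        true_edge = ds.backbone.node_for_leaf(lab).edge_id
        err = placement_edge_error(ds.backbone, true_edge, pl.edge_id)
        assert err <= 1  # its own pendant edge or the adjacent one


class TestJplace:
    def test_round_trip(self, quartet_tree):
        pls = [Placement("q1", 2, 0.4, 0.1, 0.02, 4)]
        text = write_jplace(pls, quartet_tree)
        doc = json.loads(text)
        assert doc["version"] == 3
        back = read_jplace(text)
        assert back[0].query_id == "q1"
        assert back[0].edge_id == 2
        assert back[0].pendant == pytest.approx(0.4)
        assert back[0].distal == pytest.approx(0.1)

    def test_tree_edge_numbering_round_trips(self, quartet_tree):
        text = write_jplace([], quartet_tree)
        doc = json.loads(text)
        t2 = parse_edge_numbered_newick(doc["tree"])
        assert t2.edge_ids() == quartet_tree.edge_ids()

    def test_empty_placements_valid(self, quartet_tree):
        doc = json.loads(write_jplace([], quartet_tree))
        assert doc["placements"] == []
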