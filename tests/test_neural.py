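"""Encoding, metric-learning loss, embedder/classifier training, routing."""

import math

import numpy as np
import pytest

from cdepp.encoding import one_hot_encode
from cdepp.neural import (
    SequenceEmbedder,
    SubtreeClassifier,
    depp_loss,
    embed_distances,
    first_level_scores,
    select_models,
)
from cdepp.simulate import evolve_sequences, simulate_species_tree
from cdepp.trees import patristic_distances


class TestOneHot:
    def test_acgt_identity_pattern(self):
        enc = one_hot_encode({"x": "ACGT"})
        assert np.array_equal(enc.row("x"), np.eye(4))

    def test_gap_and_ambiguity_are_zero(self):
        enc = one_hot_encode({"x": "A-N"})
        row = enc.row("x")
        assert np.array_equal(row[0], [1, 0, 0, 0])
        assert np.array_equal(row[1], [0, 0, 0, 0])
        assert np.array_equal(row[2], [0, 0, 0, 0])

    def test_case_and_u_folding(self):
        assert np.array_equal(one_hot_encode({"x": "acgu"}).data,
                              one_hot_encode({"x": "ACGT"}).data)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="unequal"):
            one_hot_encode({"a": "ACG", "b": "AC"})

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            one_hot_encode({})


class TestDeppLoss:
    def test_exact_fit_is_zero(self):
        rng = np.random.default_rng(0)
        E = rng.random((5, 3))
        D = np.sqrt(((E[:, None] - E[None]) ** 2).sum(-1))
        assert depp_loss(E, D) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("target,expected", [(1.0, 1.0), (4.0, 1.0)])
    def test_two_point_hand_values(self, target, expected):
        E = np.array([[0.0, 0.0], [2.0, 0.0]])
        D = np.array([[0.0, target], [target, 0.0]])
        assert depp_loss(E, D) == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        E = rng.random((6, 3))
        D = np.abs(rng.random((6, 6)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1]])
        moved = E @ R.T + np.array([5.0, -2.0, 1.0])
        assert depp_loss(moved, D) == pytest.approx(depp_loss(E, D), rel=1e-9)

    def test_zero_distance_pairs_excluded_and_counted(self):
        E = np.array([[0.0], [1.0], [2.0]])
        D = np.array([[0, 0, 2.0], [0, 0, 1.0], [2.0, 1.0, 0]])
        loss, excluded = depp_loss(E, D, return_excluded=True)
        assert excluded == 1
        assert loss == pytest.approx(0.5 * 0 + 0, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            depp_loss(np.zeros((3, 2)), np.zeros((4, 4)))


@pytest.fixture(scope="module")
def eight_leaf_training_data():
    tree = simulate_species_tree(8, seed=4)
    seqs = evolve_sequences(tree, 200, "jc", seed=4)
    enc = one_hot_encode(seqs)
    pat = patristic_distances(tree, enc.labels)
    return enc, pat


class TestEmbedder:
    def test_training_reduces_loss(self, eight_leaf_training_data):
        enc, pat = eight_leaf_training_data
        emb = SequenceEmbedder(embedding_dim=8, channels=16, epochs=50,
                               lr=1e-3, seed=0).fit(enc, pat)
        assert emb.final_loss_ < emb.initial_loss_

    def test_distance_fit_improves_substantially(self, eight_leaf_training_data):
        """RMS gap between embedding and patristic distances shrinks."""
        enc, pat = eight_leaf_training_data

        def rms(emb):
            E = emb.transform(enc)
            d = np.sqrt(((E[:, None] - E[None]) ** 2).sum(-1))
            iu = np.triu_indices(len(enc.labels), 1)
            return float(np.sqrt(((d[iu] - pat.values[iu]) ** 2).mean()))

        short = SequenceEmbedder(embedding_dim=8, channels=16, epochs=1,
                                 lr=1e-3, seed=0, eval_every=1).fit(enc, pat)
        long = SequenceEmbedder(embedding_dim=8, channels=16, epochs=120,
                                lr=1e-3, seed=0).fit(enc, pat)
        assert rms(long) < 0.5 * rms(short)

    def test_determinism(self, eight_leaf_training_data):
        enc, pat = eight_leaf_training_data
        a = SequenceEmbedder(epochs=20, seed=7).fit(enc, pat)
        b = SequenceEmbedder(epochs=20, seed=7).fit(enc, pat)
        for k in a.net_.params:
            assert np.array_equal(a.net_.params[k], b.net_.params[k])

    def test_single_sequence_raises(self):
        enc = one_hot_encode({"only": "ACGT"})
        with pytest.raises(ValueError, match="merge"):
            SequenceEmbedder().fit(enc, np.zeros((1, 1)))

    def test_identical_sequences_raise(self):
        enc = one_hot_encode({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError, match="zero"):
            SequenceEmbedder().fit(enc, np.zeros((2, 2)))

    def test_length_mismatch_on_transform(self, eight_leaf_training_data):
        enc, pat = eight_leaf_training_data
        emb = SequenceEmbedder(epochs=5, seed=0).fit(enc, pat)
        with pytest.raises(ValueError, match="length"):
            emb.transform(one_hot_encode({"q": "ACGT"}))

    def test_embed_distances_contract(self, eight_leaf_training_data):
        enc, pat = eight_leaf_training_data
        emb = SequenceEmbedder(epochs=10, seed=0).fit(enc, pat)
        lab0 = enc.labels[0]
        d = embed_distances(emb, enc.row(lab0), enc)
        assert set(d) == set(enc.labels)
        # single-row vs batched forward passes differ by float32 rounding
        assert d[lab0] == pytest.approx(0.0, abs=1e-5)
        assert all(v >= 0 for v in d.values())


class TestClassifier:
    def test_uniform_prediction_cross_entropy(self):
        from cdepp._nn import softmax_cross_entropy

        logits = np.zeros((5, 4))
        assert softmax_cross_entropy(logits, np.zeros(5, int)) == pytest.approx(
            math.log(4))

    def test_separable_toy_reaches_full_accuracy(self):
        # two well-separated sequence families, 10 taxa each
        rng = np.random.default_rng(0)
        base_a = "".join(rng.choice(list("ACGT"), 80))
        base_b = "".join(rng.choice(list("ACGT"), 80))

        def mutate(s, k):
            s = list(s)
            for pos in rng.choice(len(s), k, replace=False):
                s[pos] = rng.choice(list("ACGT"))
            return "".join(s)

        seqs = {f"a{i}": mutate(base_a, 4) for i in range(10)}
        seqs.update({f"b{i}": mutate(base_b, 4) for i in range(10)})
        enc = one_hot_encode(seqs)
        y = np.array([0 if lab.startswith("a") else 1 for lab in enc.labels])
        clf = SubtreeClassifier(channels=16, epochs=80, lr=1e-3, seed=0).fit(enc, y)
        assert np.mean(clf.predict(enc) == y) == 1.0

    def test_probabilities_sum_to_one(self, eight_leaf_training_data):
        enc, _ = eight_leaf_training_data
        y = np.arange(len(enc.labels)) % 2
        clf = SubtreeClassifier(channels=8, epochs=10, seed=1).fit(enc, y)
        probs = clf.predict_proba(enc)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_empty_class_raises(self, eight_leaf_training_data):
        enc, _ = eight_leaf_training_data
        y = np.full(len(enc.labels), 2)  # classes 0 and 1 empty
        with pytest.raises(ValueError, match="zero members"):
            SubtreeClassifier(epochs=2).fit(enc, y)


class TestRouting:
    def test_first_level_max_pooling(self):
        probs = np.array([0.1, 0.4, 0.3, 0.2])
        label_map = [(0, 0), (0, 1), (1, 0), (1, 1)]
        scores = first_level_scores(probs, label_map)
        assert scores == {0: pytest.approx(0.4), 1: pytest.approx(0.3)}

    def test_single_cluster_degenerate(self):
        scores = first_level_scores(np.array([0.2, 0.8]), [(0, 0), (0, 1)])
        assert scores == {0: pytest.approx(0.8)}

    def test_bounds(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(12))
        label_map = [(i % 4, i // 4) for i in range(12)]
        scores = first_level_scores(probs, label_map)
        assert sum(scores.values()) >= probs.max() - 1e-12
        assert all(0 <= s <= 1 for s in scores.values())

    def test_ratio_cutoff(self):
        sel = select_models({1: 0.9, 2: 0.5, 3: 0.001})
        assert sel.cluster_ids == [1, 2]

    def test_cap_at_four(self):
        sel = select_models({i: 0.4 for i in range(1, 6)})
        assert sel.cluster_ids == [1, 2, 3, 4]

    def test_singleton(self):
        assert select_models({9: 0.1}).cluster_ids == [9]

    def test_order_independent(self):
        scores = {3: 0.5, 1: 0.9, 7: 0.02, 2: 0.004}
        rev = dict(reversed(list(scores.items())))
        assert select_models(scores).cluster_ids == select_models(rev).cluster_ids
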