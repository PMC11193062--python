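"""End-to-end training and placement: the :class:`ClusteredPlacer` estimator.

``fit`` decomposes the backbone tree, trains one metric-learning embedder per
(augmented) first-level cluster and one softmax classifier over the
second-level clusters; ``predict`` routes each query through the classifier,
selects up to four cluster models, merges their distance estimates by the
median, and places the query by constrained least squares.  Ablation
strategies (full-data model, subsample, random partition, tree partition
without routing) are available through the ``strategy`` and
``classifier_mode`` parameters so the whole accuracy ladder can be run with
one class.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
from sklearn.base import BaseEstimator

from .encoding import EncodedAlignment, one_hot_encode
from .neural import (
    ModelSelection,
    SequenceEmbedder,
    SubtreeClassifier,
    first_level_scores,
    select_models,
)
from .partition import (
    DEFAULT_M,
    DEFAULT_M_PRIME,
    PartitionSet,
    baseline_partition,
    build_partition,
    compute_k,
)
from .placement import Placement, merge_distance_profiles, place_query
from .trees import PhyloTree, parse_edge_numbered_newick, patristic_distances

__all__ = ["ClusteredPlacer", "TEST_PROFILE", "PAPER_PROFILE"]

# Scaled-down schedule used throughout the test-suite-sized experiments.
TEST_PROFILE = dict(m=64, m_prime=8, embedding_dim=16, channels=32,
                    epochs=150, classifier_epochs=400, lr=1e-3, batch_size=32)
# Reference-scale defaults (dataset sizes of the original studies).
PAPER_PROFILE = dict(m=DEFAULT_M, m_prime=DEFAULT_M_PRIME, embedding_dim=128,
                     channels=64, epochs=2000, classifier_epochs=2000,
                     lr=1e-4, batch_size=32)

_STRATEGIES = ("cdepp", "treepart", "random", "subsample", "full")
_CLASSIFIER_MODES = ("2level", "multi", "top", "off")


class ClusteredPlacer(BaseEstimator):
    """Divide-and-conquer ensemble placement on a backbone tree.

    Parameters mirror the method's knobs: ``m`` / ``m_prime`` are the
    first/second-level maximum cluster sizes, ``k`` the number of
    representatives per cluster (default ceil(m*ln(c)/3)), ``max_models`` and
    ``ratio`` the routing rule, ``weighting`` the least-squares weights.
    ``strategy`` selects the ablation arm; ``classifier_mode`` chooses
    routing: '2level' (second-level classes, max-pooled scores), 'multi'
    (first-level classes, top-4/ratio), 'top' (first-level argmax only) or
    'off' (use every model).
    """

    def __init__(self, m: int = DEFAULT_M, m_prime: int = DEFAULT_M_PRIME,
                 k: int | None = None, embedding_dim: int = 128,
                 channels: int = 64, epochs: int = 2000,
                 classifier_epochs: int = 2000, lr: float = 1e-4,
                 batch_size: int = 32, seed: int = 0,
                 strategy: str = "cdepp", classifier_mode: str = "2level",
                 use_representatives: bool = True, subsample_size: int | None = None,
                 max_models: int = 4, ratio: float = 1.0 / 200.0,
                 weighting: str = "fm"):
        self.m = m
        self.m_prime = m_prime
        self.k = k
        self.embedding_dim = embedding_dim
        self.channels = channels
        self.epochs = epochs
        self.classifier_epochs = classifier_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.strategy = strategy
        self.classifier_mode = classifier_mode
        self.use_representatives = use_representatives
        self.subsample_size = subsample_size
        self.max_models = max_models
        self.ratio = ratio
        self.weighting = weighting

    # ------------------------------------------------------------------
    def fit(self, tree: PhyloTree, seqs: dict[str, str]):
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")
        if self.classifier_mode not in _CLASSIFIER_MODES:
            raise ValueError(f"classifier_mode must be one of {_CLASSIFIER_MODES}")
        leaves = set(tree.leaf_labels())
        extra = sorted(set(seqs) - leaves)
        if extra:
            raise ValueError(f"sequences not in the backbone tree: {extra}")
        taxa = sorted(set(seqs) & leaves)
        if len(taxa) < 4:
            raise ValueError("need at least 4 backbone sequences")
        enc = one_hot_encode({t: seqs[t] for t in taxa})
        pat = patristic_distances(tree, taxa)
        rng = np.random.default_rng(self.seed)

        partition = None
        classifier = None
        label_map = None
        if self.strategy == "full":
            clusters = {0: frozenset(taxa)}
        elif self.strategy == "subsample":
            size = self.subsample_size or min(len(taxa), self.m)
            sub = baseline_partition(taxa, "subsample", size,
                                     seed=int(rng.integers(2**31)))
            clusters = {0: sub[0]}
        elif self.strategy == "random":
            sets = baseline_partition(taxa, "random", self.m,
                                      seed=int(rng.integers(2**31)))
            clusters = dict(enumerate(sets))
        else:  # treepart / cdepp: phylogenetic decomposition
            partition = build_partition(
                tree, m=self.m, m_prime=self.m_prime, k=self.k,
                use_representatives=self.use_representatives,
            )
            clusters = {
                i: frozenset(th & set(taxa))
                for i, th in enumerate(partition.augmented)
            }

        embedders: dict[int, SequenceEmbedder] = {}
        cluster_enc: dict[int, EncodedAlignment] = {}
        for cid in sorted(clusters):
            members = sorted(clusters[cid])
            if len(members) < 2:
                raise ValueError(
                    f"cluster {cid} has fewer than 2 sequenced members; "
                    f"reduce the cluster count or merge clusters"
                )
            sub_enc = enc.subset(members)
            emb = SequenceEmbedder(
                embedding_dim=self.embedding_dim, channels=self.channels,
                epochs=self.epochs, lr=self.lr, batch_size=self.batch_size,
                seed=int(rng.integers(2**31)), cluster_id=cid,
            ).fit(sub_enc, pat.submatrix(members))
            embedders[cid] = emb
            cluster_enc[cid] = sub_enc

        use_classifier = (
            self.strategy == "cdepp" and self.classifier_mode != "off"
            and partition is not None and partition.n_clusters > 1
        )
        if use_classifier:
            if self.classifier_mode == "2level":
                lab2 = partition.second_level_labels()
                pairs = sorted({lab2[t] for t in taxa})
                pair_index = {p: i for i, p in enumerate(pairs)}
                y = np.array([pair_index[lab2[t]] for t in taxa])
                label_map = pairs
            else:  # single-level classes = first-level clusters
                home = partition.home_cluster()
                firsts = sorted({home[t] for t in taxa})
                fi = {f: i for i, f in enumerate(firsts)}
                y = np.array([fi[home[t]] for t in taxa])
                label_map = [(f, 0) for f in firsts]
            classifier = SubtreeClassifier(
                channels=self.channels, epochs=self.classifier_epochs,
                lr=self.lr, batch_size=self.batch_size,
                seed=int(rng.integers(2**31)), label_map=label_map,
            ).fit(enc, y)

        self.tree_ = tree
        self.taxa_ = taxa
        self.seq_len_ = enc.length
        self.partition_ = partition
        self.clusters_ = clusters
        self.embedders_ = embedders
        self.cluster_encodings_ = cluster_enc
        self.classifier_ = classifier
        self.label_map_ = label_map
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "embedders_"):
            raise ValueError("ClusteredPlacer is not fitted")

    def query_scores(self, row: np.ndarray) -> dict[int, float]:
        """First-level scores for one encoded query (uniform if no classifier)."""
        self._check_fitted()
        if self.classifier_ is None:
            return {cid: 1.0 for cid in self.embedders_}
        probs = self.classifier_.predict_proba_one(row)
        return first_level_scores(probs, self.classifier_.label_map)

    def select_for_query(self, row: np.ndarray) -> ModelSelection:
        scores = self.query_scores(row)
        if self.classifier_ is None:
            return ModelSelection([(cid, 1.0) for cid in sorted(scores)],
                                  max_models=max(len(scores), 1), ratio=0.0)
        if self.classifier_mode == "top":
            return select_models(scores, max_models=1, ratio=self.ratio)
        return select_models(scores, max_models=self.max_models, ratio=self.ratio)

    def distance_profile(self, query_id: str, row: np.ndarray,
                         selection: ModelSelection):
        partials = []
        for cid in selection.cluster_ids:
            emb = self.embedders_[cid]
            q = emb.embed_one(row)
            E = emb.training_embeddings_
            dvec = np.sqrt(((E - q[None]) ** 2).sum(axis=1))
            partials.append({lab: float(v) for lab, v in zip(emb.labels_, dvec)})
        labels = sorted(self.tree_.leaf_labels())
        return merge_distance_profiles(query_id, labels, partials)

    def predict(self, queries: dict[str, str]) -> list[Placement]:
        """Place every query; returns one :class:`Placement` per query."""
        self._check_fitted()
        if not queries:
            return []
        enc = one_hot_encode(queries)
        if enc.length != self.seq_len_:
            raise ValueError(
                f"query length {enc.length} != trained length {self.seq_len_}"
            )
        out = []
        for lab in enc.labels:
            row = enc.row(lab)
            selection = self.select_for_query(row)
            profile = self.distance_profile(lab, row, selection)
            out.append(place_query(profile, self.tree_, weighting=self.weighting))
        return out

    # -- update support -------------------------------------------------
    def scores_for_queries(self, queries: dict[str, str]) -> dict[str, dict[int, float]]:
        self._check_fitted()
        enc = one_hot_encode(queries)
        return {lab: self.query_scores(enc.row(lab)) for lab in enc.labels}

    def cluster_distance_source(self, cid: int, queries: dict[str, str]
                                ) -> dict[str, dict[str, float]]:
        """Model-estimated distances query->(cluster members + other queries).

        Used to assemble update matrices: embeds the queries under cluster
        ``cid``'s model and measures Euclidean distances to the cluster's
        training embeddings and among the queries themselves.
        """
        self._check_fitted()
        emb = self.embedders_[cid]
        enc = one_hot_encode(queries)
        Q = emb.transform(enc)
        E = emb.training_embeddings_
        src: dict[str, dict[str, float]] = {}
        for qi, qlab in enumerate(enc.labels):
            row = {}
            dvec = np.sqrt(((E - Q[qi][None]) ** 2).sum(axis=1))
            for lab, v in zip(emb.labels_, dvec):
                row[lab] = float(v)
            for qj, qlab2 in enumerate(enc.labels):
                if qj != qi:
                    row[qlab2] = float(np.sqrt(((Q[qi] - Q[qj]) ** 2).sum()))
            src[qlab] = row
        return src

    # -- bundle persistence ---------------------------------------------
    def save_bundle(self, path) -> None:
        """Write the fitted model bundle (manifest, partition TSV, weights)."""
        self._check_fitted()
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.get_params(),
            "seq_len": self.seq_len_,
            "taxa": self.taxa_,
            "tree": self.tree_.to_newick(edge_numbers=True),
            "clusters": {str(c): sorted(s) for c, s in self.clusters_.items()},
            "label_map": self.label_map_,
            "final_losses": {str(c): e.final_loss_ for c, e in self.embedders_.items()},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if self.partition_ is not None:
            (path / "partition.tsv").write_text(self.partition_.to_tsv())
        for cid, emb in self.embedders_.items():
            np.savez(path / f"embedder_{cid}.npz",
                     labels=np.array(emb.labels_),
                     embeddings=emb.training_embeddings_,
                     **{f"p_{k}": v for k, v in emb.net_.params.items()},
                     meta=np.array([emb.net_.seq_len, emb.net_.out_dim,
                                    emb.net_.channels, emb.net_.seed]))
        if self.classifier_ is not None:
            np.savez(path / "classifier.npz",
                     labels=np.array(self.classifier_.labels_),
                     **{f"p_{k}": v for k, v in self.classifier_.net_.params.items()},
                     meta=np.array([self.classifier_.net_.seq_len,
                                    self.classifier_.net_.out_dim,
                                    self.classifier_.net_.channels,
                                    self.classifier_.net_.seed]))

    @classmethod
    def load_bundle(cls, path) -> "ClusteredPlacer":
        from ._nn import TrunkNet

        path = pathlib.Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        est = cls(**manifest["config"])
        est.tree_ = parse_edge_numbered_newick(manifest["tree"])
        est.taxa_ = manifest["taxa"]
        est.seq_len_ = manifest["seq_len"]
        est.clusters_ = {int(c): frozenset(s)
                         for c, s in manifest["clusters"].items()}
        est.label_map_ = (None if manifest["label_map"] is None else
                          [tuple(p) for p in manifest["label_map"]])
        est.partition_ = None
        ptsv = path / "partition.tsv"
        if ptsv.exists():
            k = compute_k(est.m, len(est.clusters_)) if est.k is None else est.k
            est.partition_ = PartitionSet.from_tsv(
                ptsv.read_text(), m=est.m, m_prime=est.m_prime, k=k)
        est.embedders_ = {}
        for f in sorted(path.glob("embedder_*.npz")):
            cid = int(f.stem.split("_")[1])
            z = np.load(f, allow_pickle=False)
            L, d, C, s = (int(v) for v in z["meta"])
            net = TrunkNet(L, d, C, seed=s)
            net.params = {k[2:]: z[k] for k in z.files if k.startswith("p_")}
            emb = SequenceEmbedder(embedding_dim=d, channels=C, cluster_id=cid)
            emb.net_ = net
            emb.labels_ = tuple(str(x) for x in z["labels"])
            emb.seq_len_ = L
            emb.training_embeddings_ = z["embeddings"]
            emb.initial_loss_ = emb.final_loss_ = float(
                manifest["final_losses"][str(cid)])
            emb.n_excluded_pairs_ = 0
            est.embedders_[cid] = emb
        est.classifier_ = None
        cf = path / "classifier.npz"
        if cf.exists():
            z = np.load(cf, allow_pickle=False)
            L, K, C, s = (int(v) for v in z["meta"])
            net = TrunkNet(L, K, C, seed=s)
            net.params = {k[2:]: z[k] for k in z.files if k.startswith("p_")}
            clf = SubtreeClassifier(channels=C, label_map=est.label_map_)
            clf.net_ = net
            clf.labels_ = tuple(str(x) for x in z["labels"])
            clf.seq_len_ = L
            clf.n_classes_ = K
            clf.initial_loss_ = clf.final_loss_ = 0.0
            est.classifier_ = clf
        est.cluster_encodings_ = {}
        return est


def run_update(placers: list[ClusteredPlacer],
               per_gene_queries: list[dict[str, str]],
               method: str = "bme") -> PhyloTree:
    """Multi-gene tree update: average scores, median distances, re-infer, merge.

    ``placers`` holds one fitted model per gene (all sharing one backbone
    tree); ``per_gene_queries`` the aligned query sequences per gene.
    """
    from .update import (
        assign_queries_for_update,
        build_update_matrix,
        infer_subtree,
        merge_updated_subtrees,
    )

    if not placers or len(placers) != len(per_gene_queries):
        raise ValueError("one query set per fitted gene model required")
    backbone = placers[0].tree_
    per_gene_scores = [p.scores_for_queries(q)
                       for p, q in zip(placers, per_gene_queries)]
    assign = assign_queries_for_update(per_gene_scores)
    updated = {}
    for cid in sorted(set(assign.values())):
        qs = sorted(q for q, c in assign.items() if c == cid)
        members = sorted(placers[0].clusters_[cid])
        sources = []
        for placer, queries in zip(placers, per_gene_queries):
            sub = {q: s for q, s in queries.items() if q in qs}
            if sub:
                sources.append(placer.cluster_distance_source(cid, sub))
        um = build_update_matrix(members, qs, sources, backbone)
        updated[cid] = infer_subtree(um, method=method)
    return merge_updated_subtrees(backbone, updated, assign)
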