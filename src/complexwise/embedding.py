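"""Stage 2: random-walk node embeddings and random-forest classification.

Node vectors are learned from second-order biased random walks (the
node2vec scheme: return probability ∝ 1/p, staying within the previous
node's neighborhood ∝ 1, moving outward ∝ 1/q) fed to a skip-gram model
with negative sampling.  Walk generation and the SGNS update loop are
implemented here directly — the inner loop is numba-compiled and
deterministic under a fixed seed.  A complex's vector is the
coordinate-wise mean of its members' vectors; a random forest trained on
known complexes versus random node sets gives each stage-1 candidate a
final probability, and candidates above the decision threshold are the
predicted complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
from numba import njit
from sklearn.ensemble import RandomForestClassifier

from .core import ComplexSet, Network, ProteinComplex, ValidationError


@dataclass
class WalkConfig:
    """Walk and skip-gram hyperparameters.

    p/q are the node2vec return and in-out biases (p = 8 keeps walks
    moving away from the previous node, favouring exploration); walk
    length 80 and 10 walks per node give the corpus; 64-dimensional
    vectors with a context window of 10, 5 epochs and 5 negative samples
    per positive pair.
    """

    p: float = 8.0
    q: float = 1.0
    walk_length: int = 80
    num_walks: int = 10
    dimensions: int = 64
    window: int = 10
    epochs: int = 5
    negatives: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    use_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValidationError("p and q must be > 0")
        if self.walk_length < 2:
            raise ValidationError("walk_length must be >= 2")
        if self.dimensions < 1:
            raise ValidationError("dimensions must be >= 1")


@dataclass
class NodeEmbedding:
    """One vector per network node, all of the same dimension."""

    vectors: Dict[str, np.ndarray]

    @property
    def dimensions(self) -> int:
        return len(next(iter(self.vectors.values())))

    def __contains__(self, node: str) -> bool:
        return node in self.vectors

    def __getitem__(self, node: str) -> np.ndarray:
        return self.vectors[node]


def _step_distribution(
    net: Network, prev: Optional[str], cur: str, cfg: WalkConfig
):
    """Neighbors of ``cur`` with their unnormalised transition weights."""
    nbrs = sorted(net[cur])
    if not nbrs:
        return nbrs, None
    weights = np.empty(len(nbrs))
    for i, x in enumerate(nbrs):
        w = net.edges[cur, x].get("weight", 1.0) if cfg.use_weights else 1.0
        if prev is not None:
            if x == prev:
                w /= cfg.p
            elif not net.has_edge(x, prev):
                w /= cfg.q
        weights[i] = w
    return nbrs, weights / weights.sum()


def generate_walks(net: Network, cfg: WalkConfig) -> List[List[str]]:
    """num_walks biased walks per node, truncated at dead ends; seeded."""
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot walk an empty network")
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(net.nodes)
    walks: List[List[str]] = []
    for _ in range(cfg.num_walks):
        for start_i in rng.permutation(len(nodes)):
            start = nodes[start_i]
            walk = [start]
            prev: Optional[str] = None
            while len(walk) < cfg.walk_length:
                nbrs, probs = _step_distribution(net, prev, walk[-1], cfg)
                if not nbrs:
                    break
                nxt = nbrs[rng.choice(len(nbrs), p=probs)]
                prev = walk[-1]
                walk.append(nxt)
            walks.append(walk)
    return walks


@njit(cache=True)
def _sgns_train(
    W, C, centers, contexts, neg_table, epochs, n_negative, lr0, lr_min, seed
):  # pragma: no cover - exercised via embed_nodes
    n_pairs = centers.shape[0]
    dim = W.shape[1]
    table_size = neg_table.shape[0]
    state = np.uint64(seed * 2 + 1)
    total = epochs * n_pairs
    step = 0
    grad = np.empty(dim)
    for _ in range(epochs):
        for i in range(n_pairs):
            lr = lr0 - (lr0 - lr_min) * (step / total)
            step += 1
            c = centers[i]
            for d in range(dim):
                grad[d] = 0.0
            for s in range(n_negative + 1):
                if s == 0:
                    target = contexts[i]
                    label = 1.0
                else:
                    # xorshift64* generator
                    state ^= state >> np.uint64(12)
                    state ^= state << np.uint64(25)
                    state ^= state >> np.uint64(27)
                    target = neg_table[
                        (state * np.uint64(2685821657736338717))
                        % np.uint64(table_size)
                    ]
                    if target == contexts[i]:
                        continue
                    label = 0.0
                dot = 0.0
                for d in range(dim):
                    dot += W[c, d] * C[target, d]
                if dot > 6.0:
                    pred = 1.0
                elif dot < -6.0:
                    pred = 0.0
                else:
                    pred = 1.0 / (1.0 + np.exp(-dot))
                g = (label - pred) * lr
                for d in range(dim):
                    grad[d] += g * C[target, d]
                    C[target, d] += g * W[c, d]
            for d in range(dim):
                W[c, d] += grad[d]


def embed_nodes(walks: List[List[str]], cfg: WalkConfig) -> NodeEmbedding:
    """Skip-gram-with-negative-sampling over the walk corpus.

    Every token in the corpus gets a vector; nodes appearing only as
    length-1 walks (isolated nodes) keep their small random
    initialisation.  Deterministic under ``cfg.seed``.
    """
    if not walks:
        raise ValidationError("empty walk corpus")
    vocab = sorted({node for walk in walks for node in walk})
    index = {node: i for i, node in enumerate(vocab)}
    rng = np.random.default_rng(cfg.seed)

    counts = np.zeros(len(vocab))
    encoded = []
    for walk in walks:
        arr = np.array([index[n] for n in walk], dtype=np.int32)
        encoded.append(arr)
        np.add.at(counts, arr, 1)

    centers_parts, contexts_parts = [], []
    for arr in encoded:
        for off in range(1, min(cfg.window, len(arr) - 1) + 1):
            a, b = arr[:-off], arr[off:]
            centers_parts.append(a)
            contexts_parts.append(b)
            centers_parts.append(b)
            contexts_parts.append(a)
    dim = cfg.dimensions
    W = (rng.random((len(vocab), dim)) - 0.5) / dim
    C = np.zeros((len(vocab), dim))
    if centers_parts:
        centers = np.concatenate(centers_parts)
        contexts = np.concatenate(contexts_parts)
        order = rng.permutation(centers.shape[0])
        centers, contexts = centers[order], contexts[order]

        # unigram^0.75 negative-sampling table
        probs = counts**0.75
        probs /= probs.sum()
        table_size = max(100_000, 10 * len(vocab))
        neg_table = np.repeat(
            np.arange(len(vocab), dtype=np.int32),
            np.maximum(1, np.round(probs * table_size).astype(np.int64)),
        )
        _sgns_train(
            W,
            C,
            centers,
            contexts,
            neg_table,
            cfg.epochs,
            cfg.negatives,
            cfg.learning_rate,
            cfg.min_learning_rate,
            cfg.seed + 1,
        )
    return NodeEmbedding({node: W[i].copy() for node, i in index.items()})


def embed_network(net: Network, cfg: WalkConfig) -> NodeEmbedding:
    """Walks + skip-gram in one call; guarantees a vector per node."""
    emb = embed_nodes(generate_walks(net, cfg), cfg)
    assert all(n in emb for n in net.nodes)
    return emb


def complex_vector(cx: ProteinComplex, emb: NodeEmbedding) -> np.ndarray:
    """Coordinate-wise mean of the member vectors."""
    try:
        vecs = [emb[m] for m in sorted(cx.members)]
    except KeyError as exc:
        raise KeyError(f"complex member {exc} has no embedding") from exc
    return np.mean(vecs, axis=0)


@dataclass
class ComplexClassifier:
    """Random forest over complex vectors with a decision threshold."""

    model: RandomForestClassifier
    threshold: float = 0.5
    _positive_col: int = 0

    def prob(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.atleast_2d(X))[:, self._positive_col]


def train_stage2(
    positives: ComplexSet,
    negatives: ComplexSet,
    emb: NodeEmbedding,
    seed: int = 0,
    n_estimators: int = 1000,
    threshold: float = 0.5,
) -> ComplexClassifier:
    """Fit the random forest on positive/negative complex vectors."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValidationError("both classes are required")
    X = np.vstack(
        [complex_vector(c, emb) for c in positives]
        + [complex_vector(c, emb) for c in negatives]
    )
    y = np.array([1] * len(positives) + [0] * len(negatives))
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return ComplexClassifier(model, threshold=threshold, _positive_col=pos_col)


def classify_candidates(
    cands: ComplexSet,
    clf: ComplexClassifier,
    emb: NodeEmbedding,
    threshold: Optional[float] = None,
) -> ComplexSet:
    """Keep candidates whose positive-class probability clears the bar."""
    thr = clf.threshold if threshold is None else threshold
    if len(cands) == 0:
        return ComplexSet([], provenance="classified candidates")
    X = np.vstack([complex_vector(c, emb) for c in cands])
    probs = clf.prob(X)
    kept = [
        ProteinComplex(c.members, probability=float(p))
        for c, p in zip(cands, probs)
        if p > thr
    ]
    return ComplexSet(kept, provenance="classified candidates")
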