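"""Stage 1: SVM-guided clique seeding, expansion and overlap filtration.

The candidate-detection stage trains a probabilistic support-vector
classifier on the 16 subgraph features of known complexes (positives) and
size-matched random node sets (negatives), then:

1. enumerates maximal cliques (>= 3 nodes) as seeds;
2. *selection* — scans seeds by descending classifier probability and
   drops any seed sharing more than ``alpha`` proteins with an
   already-kept one (the overlap-count rule; "exceeds" is strict, so a
   shared pair survives at the default alpha = 2);
3. *expansion* — greedily adds the external neighbor giving the largest
   strict probability increase until none does;
4. *filtration* — scans candidates by descending probability; a
   lower-ranked candidate whose member overlap ratio with the current one
   reaches ``beta`` is merged (union, rescored, re-ranked), one with a
   smaller but nonzero overlap is removed, and disjoint candidates are
   left alone.  Applying the removal rule to zero-overlap pairs would
   delete every disjoint candidate, so the rule is restricted to pairs
   that actually overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ComplexSet, Network, ProteinComplex, ValidationError, fanout_seed
from .evaluation import overlap_ratio
from .features import N_FEATURES, extract_features


@dataclass
class SvccConfig:
    """Stage-1 thresholds: overlap count alpha, overlap ratio beta."""

    alpha: int = 2
    beta: float = 0.8
    min_clique: int = 3

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValidationError("alpha must be >= 1")
        if not 0.0 < self.beta <= 1.0:
            raise ValidationError("beta must be in (0, 1]")
        if self.min_clique < 3:
            raise ValidationError("min_clique must be >= 3")


@dataclass
class TrainingSet:
    features: np.ndarray
    labels: np.ndarray
    complex_refs: list

    def __post_init__(self) -> None:
        if not (
            self.features.shape[0]
            == self.labels.shape[0]
            == len(self.complex_refs)
        ):
            raise ValidationError("training-set rows/labels/refs mismatch")
        if len(set(self.labels.tolist())) < 2:
            raise ValidationError("training set needs both classes")


class SubgraphScorer:
    """Probability-calibrated SVC over the 16 subgraph features.

    Hyperparameters: C=3, polynomial kernel of degree 4, gamma='scale',
    coef0=0, tol=1e-3, cache_size=200, probability calibration on.
    Features are standardised before the kernel: the degree/weight
    statistics span very different scales, and the homogeneous degree-4
    polynomial is otherwise dominated by vector magnitude (small but
    perfectly dense subgraphs would sit near the origin and inherit the
    majority bias).  Scores are cached per member set — expansion
    re-evaluates the same subgraphs many times.
    """

    def __init__(self, unet: Network, wnet: Network, seed: int = 0):
        self.unet = unet
        self.wnet = wnet
        self.model = make_pipeline(
            StandardScaler(),
            SVC(
                C=3,
                kernel="poly",
                degree=4,
                gamma="scale",
                coef0=0,
                probability=True,
                tol=1e-3,
                cache_size=200,
                random_state=seed,
            ),
        )
        self._cache: dict = {}

    def fit(self, ts: TrainingSet) -> "SubgraphScorer":
        import warnings

        with warnings.catch_warnings():
            # sklearn >= 1.9 deprecates SVC(probability=True); the built-in
            # Platt calibration is exactly the behaviour wanted here.
            warnings.filterwarnings("ignore", category=FutureWarning)
            self.model.fit(ts.features, ts.labels)
        self._positive_col = int(np.where(self.model.classes_ == 1)[0][0])
        self._cache.clear()
        return self

    def prob_features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return self.model.predict_proba(X)[:, self._positive_col]

    def prob_sets(self, member_sets: Sequence[frozenset]) -> np.ndarray:
        """Probability that each node set is a real complex."""
        out = np.empty(len(member_sets))
        todo, idx = [], []
        for i, m in enumerate(member_sets):
            key = frozenset(m)
            if key in self._cache:
                out[i] = self._cache[key]
            else:
                todo.append(key)
                idx.append(i)
        if todo:
            X = np.vstack(
                [extract_features(m, self.unet, self.wnet) for m in todo]
            )
            probs = self.prob_features(X)
            for key, i, p in zip(todo, idx, probs):
                self._cache[key] = float(p)
                out[i] = p
        return out

    def prob(self, members: Iterable[str]) -> float:
        return float(self.prob_sets([frozenset(members)])[0])


def sample_negatives(
    net: Network,
    positives: ComplexSet,
    seed: int,
    max_tries: int = 1000,
) -> ComplexSet:
    """Draw one random node set per positive, size-matched.

    Members are drawn uniformly without replacement from the network's
    nodes; a draw identical to any positive member set is rejected and
    redrawn (bounded by ``max_tries``).
    """
    nodes = sorted(net.nodes)
    rng = np.random.default_rng(seed)
    forbidden = {frozenset(p.members) for p in positives}
    negatives = []
    for pos in positives:
        k = len(pos.members)
        if k > len(nodes):
            raise ValidationError(
                f"cannot sample {k} nodes from a {len(nodes)}-node network"
            )
        for _ in range(max_tries):
            draw = frozenset(rng.choice(nodes, size=k, replace=False).tolist())
            if draw not in forbidden:
                negatives.append(ProteinComplex(draw, label=0))
                break
        else:
            raise ValidationError(
                f"could not draw a size-{k} negative in {max_tries} tries"
            )
    return ComplexSet(negatives, provenance=f"random negatives (seed={seed})")


def build_training_set(
    positives: ComplexSet,
    negatives: ComplexSet,
    unet: Network,
    wnet: Network,
) -> TrainingSet:
    """Stack the 16-feature rows of positives (label 1) then negatives (0)."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValidationError("both classes are required")
    refs, labels = [], []
    for cx, lab in [(c, 1) for c in positives] + [(c, 0) for c in negatives]:
        if len(cx.members) < 3:
            raise ValidationError(
                f"training complex of size {len(cx.members)} (< 3)"
            )
        refs.append(ProteinComplex(cx.members, label=lab))
        labels.append(lab)
    X = np.vstack([extract_features(c.members, unet, wnet) for c in refs])
    return TrainingSet(X, np.asarray(labels), refs)


def train_stage1(
    ts: TrainingSet, unet: Network, wnet: Network, seed: int = 0
) -> SubgraphScorer:
    return SubgraphScorer(unet, wnet, seed=seed).fit(ts)


def enumerate_initial_subgraphs(net: Network, min_clique: int = 3) -> ComplexSet:
    """All maximal cliques with >= ``min_clique`` nodes, canonically ordered."""
    cliques = [
        frozenset(c) for c in nx.find_cliques(net) if len(c) >= min_clique
    ]
    cliques = sorted(set(cliques), key=lambda m: tuple(sorted(m)))
    return ComplexSet(
        [ProteinComplex(m) for m in cliques], provenance="maximal cliques"
    )


def _rank_key(cx: ProteinComplex):
    # descending probability, larger size first, then lexicographic members
    return (-(cx.probability or 0.0), -len(cx.members), cx.canonical)


def _scored(cands: Iterable[ProteinComplex], scorer: SubgraphScorer) -> list:
    cands = list(cands)
    if not cands:
        return []
    probs = scorer.prob_sets([c.members for c in cands])
    return [c.with_probability(float(p)) for c, p in zip(cands, probs)]


def select_subgraphs(
    initial: ComplexSet,
    scorer: SubgraphScorer,
    alpha: int = 2,
) -> ComplexSet:
    """Greedy overlap-count pruning of the clique seeds.

    Seeds are scored, ranked by descending probability, and a seed
    sharing strictly more than ``alpha`` proteins with any kept seed is
    dropped.
    """
    ranked = sorted(_scored(initial, scorer), key=_rank_key)
    kept: List[ProteinComplex] = []
    for cand in ranked:
        if all(len(cand.members & k.members) <= alpha for k in kept):
            kept.append(cand)
    return ComplexSet(kept, provenance="selected seeds")


def expand_subgraph(
    seed: ProteinComplex,
    net: Network,
    scorer: SubgraphScorer,
) -> ProteinComplex:
    """Greedily absorb the neighbor that most increases the probability.

    Expansion candidates are external nodes adjacent (in ``net``) to at
    least one member; the best strict improvement is taken each round,
    ties broken lexicographically by node id.
    """
    members = set(seed.members)
    current_p = scorer.prob(members)
    while True:
        frontier = sorted(
            {u for v in members for u in net[v]} - members
        )
        if not frontier:
            break
        trials = [frozenset(members | {u}) for u in frontier]
        probs = scorer.prob_sets(trials)
        best = int(np.argmax(probs))  # argmax takes first max: lexicographic tie-break
        if probs[best] > current_p:
            members.add(frontier[best])
            current_p = float(probs[best])
        else:
            break
    return ProteinComplex(frozenset(members), probability=current_p)


def filter_candidates(
    cands: ComplexSet,
    scorer: SubgraphScorer,
    beta: float = 0.8,
) -> ComplexSet:
    """Ranked-scan overlap filtration of expanded candidates.

    Repeatedly take the highest-probability candidate C; among the rest,
    merge every candidate with overlap ratio >= ``beta`` into C (union,
    rescored and pushed back into the ranked pool) and remove every
    candidate with a smaller nonzero overlap.  Disjoint candidates are
    untouched; exact duplicates collapse (their union is C itself).
    """
    pool = sorted(_scored(cands, scorer), key=_rank_key)
    kept: List[ProteinComplex] = []
    while pool:
        top = pool.pop(0)
        merged = set(top.members)
        survivors = []
        for other in pool:
            ov = overlap_ratio(top, other)
            if ov >= beta:
                merged |= other.members
            elif ov == 0.0:
                survivors.append(other)
            # 0 < ov < beta: removed
        pool = survivors
        if merged != set(top.members):
            rescored = ProteinComplex(
                frozenset(merged), probability=scorer.prob(merged)
            )
            pool = sorted(pool + [rescored], key=_rank_key)
        else:
            kept.append(top)
    return ComplexSet(kept, provenance="filtered candidates")


def run_svcc(
    net: Network,
    scorer: SubgraphScorer,
    cfg: Optional[SvccConfig] = None,
) -> ComplexSet:
    """Full stage 1: cliques -> selection -> expansion -> filtration.

    ``net`` is the network used for seeding and expansion topology
    (normally the confidence-weighted, filtered network); the scorer
    carries the raw and weighted graphs used for feature extraction.
    Every output complex has >= 3 members and a classifier probability.
    """
    cfg = cfg or SvccConfig()
    seeds = enumerate_initial_subgraphs(net, cfg.min_clique)
    selected = select_subgraphs(seeds, scorer, alpha=cfg.alpha)
    expanded = []
    seen = set()
    for s in selected:
        e = expand_subgraph(s, net, scorer)
        if e.members not in seen:
            seen.add(e.members)
            expanded.append(e)
    return filter_candidates(ComplexSet(expanded), scorer, beta=cfg.beta)
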