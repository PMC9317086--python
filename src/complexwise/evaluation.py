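"""Matching, scoring and cross-validation of predicted complexes.

A predicted complex p matches a reference complex b when their
neighborhood affinity NA(b, p) = |Vb ∩ Vp|^2 / (|Vb| |Vp|) exceeds 0.25.
Precision is the fraction of predictions matching at least one reference
complex, recall the fraction of reference complexes matched at least
once, and the F-score their harmonic mean.  Biological coherence of a
prediction is scored by the upper-tail hypergeometric probability of its
GO-term annotation counts.

The five-fold protocol mirrors supervised practice: the reference
catalog is shuffled into five folds; each round trains both stages on
four folds, predicts complexes from the whole network, and discards
predictions overlapping the *training* complexes at ratio >= 0.9 (they
are rediscoveries, not predictions).  The five rounds' survivors are
pooled, deduplicated at overlap ratio > 0.6 (keeping the higher
classifier probability), and scored against the full catalog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional

from .core import (
    ASPECTS,
    AnnotationIndex,
    ComplexSet,
    Network,
    ProteinComplex,
    ValidationError,
    fanout_seed,
)


def overlap_ratio(c1: ProteinComplex, c2: ProteinComplex) -> float:
    """Jaccard overlap |C1 ∩ C2| / |C1 ∪ C2| of two member sets."""
    a, b = c1.members, c2.members
    if not a or not b:
        raise ValidationError("overlap_ratio needs non-empty complexes")
    return len(a & b) / len(a | b)


def neighborhood_affinity(b: ProteinComplex, p: ProteinComplex) -> float:
    """|Vb ∩ Vp|^2 / (|Vb| * |Vp|)."""
    vb, vp = b.members, p.members
    if not vb or not vp:
        raise ValidationError("neighborhood_affinity needs non-empty complexes")
    return len(vb & vp) ** 2 / (len(vb) * len(vp))


def fscore(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class EvalResult:
    n_predicted: int
    n_reference: int
    ncp: int
    ncb: int
    precision: float
    recall: float
    fscore: float

    def as_dict(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_reference": self.n_reference,
            "ncp": self.ncp,
            "ncb": self.ncb,
            "precision": self.precision,
            "recall": self.recall,
            "fscore": self.fscore,
        }


def precision_recall_fscore(
    predicted: ComplexSet,
    reference: ComplexSet,
    na_threshold: float = 0.25,
) -> EvalResult:
    """Match predictions to references at NA > ``na_threshold`` (strict)."""
    if len(reference) == 0:
        raise ValidationError("reference set must be non-empty")
    matched_p = [False] * len(predicted)
    matched_b = [False] * len(reference)
    for i, p in enumerate(predicted):
        for j, b in enumerate(reference):
            if neighborhood_affinity(b, p) > na_threshold:
                matched_p[i] = True
                matched_b[j] = True
    ncp = sum(matched_p)
    ncb = sum(matched_b)
    prec = ncp / len(predicted) if len(predicted) else 0.0
    rec = ncb / len(reference)
    return EvalResult(
        n_predicted=len(predicted),
        n_reference=len(reference),
        ncp=ncp,
        ncb=ncb,
        precision=prec,
        recall=rec,
        fscore=fscore(prec, rec),
    )


def hypergeometric_tail(
    k: int, universe_size: int, annotated_size: int, complex_size: int
) -> float:
    """P(X >= k) for X ~ hypergeometric(|V|, |F|, |C|).

    Exact integer-binomial tail sum — equivalent to 1 minus the CDF at
    k-1 but free of floating-point cancellation.  k <= 0 returns 1.
    """
    if k <= 0:
        return 1.0
    total = math.comb(universe_size, complex_size)
    tail = sum(
        math.comb(annotated_size, i)
        * math.comb(universe_size - annotated_size, complex_size - i)
        for i in range(k, min(annotated_size, complex_size) + 1)
    )
    return tail / total


def enrichment_pvalue(
    cx: ProteinComplex,
    ann: AnnotationIndex,
    term: str,
    universe_size: int,
) -> float:
    """Hypergeometric upper-tail probability of the observed annotation count.

    With |V| proteins in the universe, |F| of them annotated by ``term``
    and a complex of |C| members of which k are annotated, returns
    P(X >= k).  k = 0 returns 1 by convention.
    """
    members = cx.members
    c_size = len(members)
    if universe_size < c_size:
        raise ValidationError(
            f"universe ({universe_size}) smaller than complex ({c_size})"
        )
    annotated = ann.term_proteins.get(term, set())
    f_size = len(annotated)
    if f_size > universe_size:
        raise ValidationError("term annotates more proteins than the universe")
    k = len(members & annotated)
    return hypergeometric_tail(k, universe_size, f_size, c_size)


@dataclass(frozen=True)
class EnrichmentResult:
    """Best (lowest-p) term per GO aspect for one complex."""

    complex: ProteinComplex
    best: dict  # aspect -> (term or None, p-value)


def best_enrichment(
    cx: ProteinComplex,
    ann: AnnotationIndex,
    universe_size: int,
    bonferroni: bool = False,
) -> EnrichmentResult:
    """Per aspect, the minimum enrichment p over terms hitting the complex.

    Aspects with no candidate term report (None, 1.0).  The optional
    Bonferroni correction multiplies by the per-aspect candidate count
    (off by default; reported values are raw per-complex p-values).
    """
    best = {aspect: (None, 1.0) for aspect in ASPECTS}
    candidates: dict = {aspect: [] for aspect in ASPECTS}
    terms = set()
    for m in cx.members:
        terms |= ann.terms_of(m)
    for t in sorted(terms):
        candidates[ann.term_aspect[t]].append(t)
    for aspect in ASPECTS:
        for t in candidates[aspect]:
            p = enrichment_pvalue(cx, ann, t, universe_size)
            if bonferroni:
                p = min(1.0, p * len(candidates[aspect]))
            if p < best[aspect][1]:
                best[aspect] = (t, p)
    return EnrichmentResult(complex=cx, best=best)


@dataclass
class CvConfig:
    folds: int = 5
    train_overlap: float = 0.9
    merge_overlap: float = 0.6
    na_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        for name in ("train_overlap", "merge_overlap", "na_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1]")


def dedupe_predictions(
    predictions: Iterable[ProteinComplex], merge_overlap: float = 0.6
) -> List[ProteinComplex]:
    """Ranked-scan dedup: drop any prediction overlapping a kept one
    at ratio strictly above ``merge_overlap`` (keep higher probability)."""
    ranked = sorted(
        predictions,
        key=lambda c: (-(c.probability or 0.0), -len(c.members), c.canonical),
    )
    kept: List[ProteinComplex] = []
    seen = set()
    for cand in ranked:
        if cand.members in seen:  # exact duplicates always collapse
            continue
        if all(overlap_ratio(cand, k) <= merge_overlap for k in kept):
            kept.append(cand)
            seen.add(cand.members)
    return kept


@dataclass
class CvResult:
    """Outcome of the five-fold protocol.

    ``complexes``/``evaluation`` are the final two-stage predictions and
    their scores; when the SVCC-only baseline is requested it shares the
    same folds, negatives and stage-1 candidates.
    """

    complexes: ComplexSet
    evaluation: EvalResult
    svcc_only: Optional[ComplexSet] = None
    svcc_only_evaluation: Optional[EvalResult] = None

    def __iter__(self):  # allow (complexes, result) unpacking
        return iter((self.complexes, self.evaluation))


def cross_validate(
    net: Network,
    unet: Network,
    wnet: Network,
    standard: ComplexSet,
    seed: int,
    cfg: Optional[CvConfig] = None,
    svcc_cfg=None,
    walk_cfg=None,
    with_baseline: bool = False,
    rf_estimators: int = 1000,
    threshold: float = 0.5,
) -> CvResult:
    """Run the full five-fold supervised protocol on one network.

    ``net`` is the detection network (cliques/expansion; normally the
    weighted-filtered graph), ``unet``/``wnet`` the raw and weighted
    graphs behind feature extraction.  The node embedding is trained once
    on the raw network and shared across folds (it uses no complex
    labels).  Returns final predictions plus their evaluation against the
    *full* standard set; ``with_baseline`` additionally evaluates the
    stage-1 candidates put through the same pruning/dedup protocol.
    """
    # local imports: svcc/embedding also import from this module
    from . import embedding as emb_mod
    from . import svcc as svcc_mod

    import numpy as np

    cfg = cfg or CvConfig()
    svcc_cfg = svcc_cfg or svcc_mod.SvccConfig()
    walk_cfg = walk_cfg or emb_mod.WalkConfig(seed=fanout_seed(seed, "walks"))

    usable = [
        c for c in standard
        if len(c.members & set(net.nodes)) >= 3
    ]
    usable = [ProteinComplex(c.members & set(net.nodes)) for c in usable]
    if len(usable) < cfg.folds:
        raise ValidationError(
            f"{len(usable)} usable standard complexes for {cfg.folds} folds"
        )

    rng = np.random.default_rng(fanout_seed(seed, "folds"))
    order = rng.permutation(len(usable))
    folds = [sorted(order[i :: cfg.folds].tolist()) for i in range(cfg.folds)]

    # Walks run on the detection network (confidence-filtered): removing
    # low-confidence edges keeps walks inside functional modules, which is
    # what makes the complex vectors generalise across folds.
    embedding = emb_mod.embed_network(net, walk_cfg)

    final: List[ProteinComplex] = []
    baseline: List[ProteinComplex] = []
    for f, test_idx in enumerate(folds):
        train_idx = [i for i in range(len(usable)) if i not in set(test_idx)]
        train = ComplexSet([usable[i] for i in train_idx])
        negatives = svcc_mod.sample_negatives(
            net, train, seed=fanout_seed(seed, f"negatives-{f}")
        )
        ts = svcc_mod.build_training_set(train, negatives, unet, wnet)
        scorer = svcc_mod.train_stage1(
            ts, unet, wnet, seed=fanout_seed(seed, f"svc-{f}")
        )
        candidates = svcc_mod.run_svcc(net, scorer, svcc_cfg)

        clf = emb_mod.train_stage2(
            train,
            negatives,
            embedding,
            seed=fanout_seed(seed, f"rf-{f}"),
            n_estimators=rf_estimators,
        )
        predicted = emb_mod.classify_candidates(
            candidates, clf, embedding, threshold=threshold
        )

        def _novel(p: ProteinComplex) -> bool:
            return all(
                overlap_ratio(p, t) < cfg.train_overlap for t in train
            )

        final.extend(p for p in predicted if _novel(p))
        if with_baseline:
            baseline.extend(c for c in candidates if _novel(c))

    final_set = ComplexSet(
        dedupe_predictions(final, cfg.merge_overlap),
        provenance=f"{cfg.folds}-fold CV predictions (seed={seed})",
    )
    reference = ComplexSet(usable, provenance=standard.provenance)
    result = precision_recall_fscore(final_set, reference, cfg.na_threshold)

    if not with_baseline:
        return CvResult(final_set, result)
    base_set = ComplexSet(
        dedupe_predictions(baseline, cfg.merge_overlap),
        provenance="SVCC-only baseline",
    )
    base_eval = precision_recall_fscore(base_set, reference, cfg.na_threshold)
    return CvResult(final_set, result, base_set, base_eval)
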