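"""Edge confidence scores combining topology and GO annotation overlap.

Each interaction edge gets a topological score (a Jaccard coefficient
augmented with the connectivity of the shared neighborhood — the
"high-order common neighbor" similarity) and a biological score driven by
how many GO terms the endpoints share and how specific those terms are.
The two are summed and square-rooted into the final edge weight; edges
whose weight falls at or below a confidence floor are removed, which is
how low-confidence (likely false-positive) interactions are filtered out
before complex detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .core import AnnotationIndex, Network, ValidationError


def _check_node(net: Network, v: str) -> None:
    if v not in net:
        raise KeyError(f"node {v!r} not in network")


def jaccard_similarity(net: Network, v: str, u: str) -> float:
    """|N(v) ∩ N(u)| / |N(v) ∪ N(u)| — 0 when the union is empty."""
    _check_node(net, v)
    _check_node(net, u)
    nv, nu = set(net[v]), set(net[u])
    union = nv | nu
    if not union:
        return 0.0
    return len(nv & nu) / len(union)


def cns(net: Network, v: str, u: str) -> float:
    """Connectivity of the common neighborhood of v and u.

    Sums, over every common neighbor w, the product
    JCS(v, w) * JCS(w, u): a common neighbor contributes strongly only
    when it is tightly tied to *both* endpoints.
    """
    _check_node(net, v)
    _check_node(net, u)
    common = set(net[v]) & set(net[u])
    return sum(
        jaccard_similarity(net, v, w) * jaccard_similarity(net, w, u)
        for w in common
    )


def hocn(net: Network, v: str, u: str) -> float:
    """High-order common-neighbor similarity of an edge.

    (JCS + CNS + |CN|) / (|CN| + 1); 0 for an isolated edge.
    """
    _check_node(net, v)
    _check_node(net, u)
    n_common = len(set(net[v]) & set(net[u]))
    return (
        jaccard_similarity(net, v, u) + cns(net, v, u) + n_common
    ) / (n_common + 1)


def go_similarity(
    ann: AnnotationIndex, v: str, u: str, log_base: float = 10.0
) -> float:
    """Biological similarity from shared GO annotations.

    |C(v,u)| * log(min_i |S_i| / Smax)^2, where C(v,u) is the set of
    terms annotating both proteins, S_i the annotated-protein set of each
    shared term and Smax the largest annotated-protein count over all
    terms.  Sharing many *specific* (small-|S|) terms scores high; an
    empty shared set short-circuits to 0.  The log base only rescales the
    score by a constant and defaults to 10.
    """
    if ann.smax < 1:
        raise ValidationError("annotation index is empty (Smax = 0)")
    shared = ann.shared_terms(v, u)
    if not shared:
        return 0.0
    s_min = min(len(ann.term_proteins[t]) for t in shared)
    return len(shared) * math.log(s_min / ann.smax, log_base) ** 2


@dataclass(frozen=True)
class EdgeScore:
    """All per-edge score components; weight = sqrt(go_sim + hocn)."""

    edge: frozenset
    jcs: float
    cns: float
    hocn: float
    go_sim: float

    @property
    def merge(self) -> float:
        return self.go_sim + self.hocn

    @property
    def weight(self) -> float:
        return math.sqrt(self.merge)


def score_edge(
    net: Network,
    v: str,
    u: str,
    ann: Optional[AnnotationIndex] = None,
    log_base: float = 10.0,
) -> EdgeScore:
    sim = 0.0 if ann is None else go_similarity(ann, v, u, log_base=log_base)
    return EdgeScore(
        edge=frozenset((v, u)),
        jcs=jaccard_similarity(net, v, u),
        cns=cns(net, v, u),
        hocn=hocn(net, v, u),
        go_sim=sim,
    )


def weight_network(
    net: Network,
    ann: Optional[AnnotationIndex] = None,
    min_weight: float = 0.0,
    log_base: float = 10.0,
) -> Network:
    """Produce the confidence-weighted network.

    Every existing edge (scores are defined between interacting proteins
    only; no link prediction) is weighted sqrt(go_sim + hocn).  Edges with
    weight <= ``min_weight`` are dropped — the default 0 removes exactly
    the zero-confidence edges (no shared neighborhood, no shared GO
    terms).  The node set is left unchanged.  With ``ann=None`` the
    biological term is 0 and weights reduce to sqrt(HOCN).
    """
    if min_weight < 0:
        raise ValidationError(f"min_weight must be >= 0, got {min_weight}")
    weighted: Network = nx.Graph()
    weighted.add_nodes_from(net.nodes)
    for v, u in net.edges:
        score = score_edge(net, v, u, ann=ann, log_base=log_base)
        if score.weight > min_weight:
            weighted.add_edge(v, u, weight=score.weight)
    return weighted
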