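"""The 16 topological features describing a candidate complex subgraph.

Five features come from the unweighted interaction graph, nine from the
confidence-weighted graph and two from degree-related attributes
(average neighbor degree).  All statistics except modularity are computed
on the *induced* subgraph; modularity is the one feature that looks
outward, comparing internal edge weight against the weight crossing the
subgraph boundary.  Conventions, stated once here and relied on
everywhere:

* weighted density sums over ordered node pairs (each internal edge
  twice) and divides by |V|(|V|-1), so a unit-weight clique scores 1;
* modularity's internal sum counts each unordered edge once (otherwise
  internal weight would double-count against the boundary);
* the weighted clustering coefficient sums w(v,j)+w(v,h) over *adjacent*
  neighbor pairs (j,h) — pairs closing a triangle — each unordered pair
  once, normalised by w(v)(k_v - 1);
* variances are population variances; medians midpoint-of-two for even n;
* degenerate cases (singleton subgraphs, zero-degree nodes) map to 0,
  never NaN.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import Network, ValidationError

#: Fixed feature order; frozen at 16 entries.
FEATURE_NAMES = (
    "density_u",
    "degree_max_u",
    "degree_avg_u",
    "degree_med_u",
    "clustcoef_var_u",
    "density_w",
    "degree_max_w",
    "degree_avg_w",
    "degree_med_w",
    "edgeweight_mean",
    "edgeweight_var",
    "modularity",
    "ccw_mean",
    "ccw_max",
    "avg_nbr_degree_mean",
    "avg_nbr_degree_var",
)

N_FEATURES = len(FEATURE_NAMES)


def _edge_weight(net: Network, u: str, v: str) -> float:
    return net.edges[u, v].get("weight", 1.0)


def weighted_density(sub: Iterable[str], wnet: Network) -> float:
    """Sum of w(v,u) over ordered pairs / (|V|(|V|-1)); 0 if |V| < 2."""
    nodes = set(sub)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = sum(
        _edge_weight(wnet, u, v)
        for u, v in wnet.subgraph(nodes).edges
    )
    return 2.0 * total / (n * (n - 1))


def modularity(sub: Iterable[str], wnet: Network) -> float:
    """d_in / (d_in + d_out) of the subgraph within its host network.

    d_in sums each internal edge weight once; d_out sums edges with
    exactly one endpoint inside.  Returns 0 when the subgraph touches no
    edges at all.
    """
    nodes = set(sub)
    missing = nodes - set(wnet.nodes)
    if missing:
        raise ValidationError(f"nodes {sorted(missing)} not in network")
    d_in = 0.0
    d_out = 0.0
    seen = set()
    for v in nodes:
        for u in wnet[v]:
            if u in nodes:
                if (u, v) not in seen:
                    seen.add((v, u))
                    d_in += _edge_weight(wnet, v, u)
            else:
                d_out += _edge_weight(wnet, v, u)
    if d_in + d_out == 0:
        return 0.0
    return d_in / (d_in + d_out)


def unweighted_clustering(v: str, sub_net: Network) -> float:
    """2 T(v) / (k(k-1)) with T(v) = triangles through v; 0 when k < 2."""
    neighbors = list(sub_net[v])
    k = len(neighbors)
    if k < 2:
        return 0.0
    triangles = 0
    for i in range(k):
        for j in range(i + 1, k):
            if sub_net.has_edge(neighbors[i], neighbors[j]):
                triangles += 1
    return 2.0 * triangles / (k * (k - 1))


def weighted_clustering(v: str, sub_net: Network) -> float:
    """Weighted clustering of v: triangle-pair weight over w(v)(k_v - 1).

    Sums w(v,j) + w(v,h) over unordered neighbor pairs (j,h) that are
    themselves adjacent; 0 when v has fewer than two neighbors or zero
    total incident weight.
    """
    neighbors = list(sub_net[v])
    k = len(neighbors)
    if k < 2:
        return 0.0
    wv = sum(_edge_weight(sub_net, v, j) for j in neighbors)
    if wv == 0:
        return 0.0
    num = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            a, b = neighbors[i], neighbors[j]
            if sub_net.has_edge(a, b):
                num += _edge_weight(sub_net, v, a) + _edge_weight(sub_net, v, b)
    return num / (wv * (k - 1))


def _pop_var(x: Sequence[float]) -> float:
    if len(x) == 0:
        return 0.0
    return float(np.var(np.asarray(x, dtype=float)))


def _median(x: Sequence[float]) -> float:
    if len(x) == 0:
        return 0.0
    return float(np.median(np.asarray(x, dtype=float)))


def extract_features(
    sub: Iterable[str],
    unet: Network,
    wnet: Network,
    weighted_annd: bool = False,
) -> np.ndarray:
    """Compute the 16-feature vector of a node set, ordered as
    :data:`FEATURE_NAMES`.

    ``unet`` is the raw interaction graph, ``wnet`` the confidence-
    weighted graph (its edges may be a subset after filtering).  The
    subgraph must be contained in both node sets and have >= 2 members.
    ``weighted_annd`` switches the average-neighbor-degree features to
    weighted degrees.
    """
    nodes = sorted(set(sub))
    n = len(nodes)
    if n < 2:
        raise ValidationError("feature extraction needs >= 2 nodes")
    missing = set(nodes) - (set(unet.nodes) & set(wnet.nodes))
    if missing:
        raise ValidationError(f"nodes {sorted(missing)} not in both networks")

    su = unet.subgraph(nodes)
    sw = wnet.subgraph(nodes)

    # unweighted view
    deg_u = [su.degree(v) for v in nodes]
    density_u = 2.0 * su.number_of_edges() / (n * (n - 1))
    cc_u = [unweighted_clustering(v, su) for v in nodes]

    # weighted view
    deg_w = [
        sum(_edge_weight(sw, v, u) for u in sw[v]) for v in nodes
    ]
    weights = [_edge_weight(sw, u, v) for u, v in sw.edges]
    density_w = weighted_density(nodes, wnet)
    ccw = [weighted_clustering(v, sw) for v in nodes]

    # degree-related attributes: per-node mean of induced neighbors' degrees
    if weighted_annd:
        deg_map = dict(zip(nodes, deg_w))
        nbr_graph = sw
    else:
        deg_map = dict(zip(nodes, deg_u))
        nbr_graph = su
    annd = []
    for v in nodes:
        nbrs = list(nbr_graph[v])
        annd.append(
            sum(deg_map[u] for u in nbrs) / len(nbrs) if nbrs else 0.0
        )

    vec = np.array(
        [
            density_u,
            float(max(deg_u)),
            float(np.mean(deg_u)),
            _median(deg_u),
            _pop_var(cc_u),
            density_w,
            float(max(deg_w)) if deg_w else 0.0,
            float(np.mean(deg_w)) if deg_w else 0.0,
            _median(deg_w),
            float(np.mean(weights)) if weights else 0.0,
            _pop_var(weights),
            modularity(nodes, wnet),
            float(np.mean(ccw)),
            float(max(ccw)),
            float(np.mean(annd)),
            _pop_var(annd),
        ],
        dtype=float,
    )
    assert vec.shape == (N_FEATURES,)
    if not np.all(np.isfinite(vec)):  # pragma: no cover - contract guard
        raise AssertionError("non-finite feature value")
    return vec


def feature_matrix(
    subs: Iterable[Iterable[str]], unet: Network, wnet: Network
) -> np.ndarray:
    """Stack :func:`extract_features` rows for many subgraphs."""
    rows = [extract_features(s, unet, wnet) for s in subs]
    if not rows:
        return np.empty((0, N_FEATURES))
    return np.vstack(rows)
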