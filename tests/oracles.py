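"""Naive, definition-level reference implementations used as oracles.

Everything here is written directly from the mathematical definitions
over plain adjacency dicts — deliberately independent of the package's
networkx-based code paths.
"""

from itertools import combinations
from statistics import median


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def naive_jcs(adj, v, u):
    union = adj[v] | adj[u]
    if not union:
        return 0.0
    return len(adj[v] & adj[u]) / len(union)


def naive_cns(adj, v, u):
    return sum(
        naive_jcs(adj, v, w) * naive_jcs(adj, w, u) for w in adj[v] & adj[u]
    )


def naive_hocn(adj, v, u):
    cn = len(adj[v] & adj[u])
    return (naive_jcs(adj, v, u) + naive_cns(adj, v, u) + cn) / (cn + 1)


def _var(xs):
    if not xs:
        return 0.0
    m = sum(xs) / len(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def naive_features(sub, uedges, wedges):
    """The 16 subgraph features from first principles.

    ``uedges``: set of frozenset pairs of the raw graph.
    ``wedges``: dict frozenset pair -> weight of the weighted host graph.
    Returns a dict keyed like FEATURE_NAMES.
    """
    nodes = sorted(sub)
    n = len(nodes)
    in_u = [e for e in uedges if e <= set(nodes)]
    in_w = {e: w for e, w in wedges.items() if e <= set(nodes)}

    def u_nbrs(v):
        return {next(iter(e - {v})) for e in in_u if v in e}

    def w_nbrs(v):
        return {next(iter(e - {v})) for e in in_w if v in e}

    deg_u = {v: len(u_nbrs(v)) for v in nodes}
    deg_w = {
        v: sum(w for e, w in in_w.items() if v in e) for v in nodes
    }

    def cc_u(v):
        nb = u_nbrs(v)
        k = len(nb)
        if k < 2:
            return 0.0
        t = sum(
            1 for a, b in combinations(sorted(nb), 2)
            if frozenset((a, b)) in in_u
        )
        return 2 * t / (k * (k - 1))

    def ccw(v):
        nb = sorted(w_nbrs(v))
        k = len(nb)
        if k < 2 or deg_w[v] == 0:
            return 0.0
        num = sum(
            in_w[frozenset((v, a))] + in_w[frozenset((v, b))]
            for a, b in combinations(nb, 2)
            if frozenset((a, b)) in in_w
        )
        return num / (deg_w[v] * (k - 1))

    d_in = sum(in_w.values())
    d_out = sum(
        w for e, w in wedges.items() if len(e & set(nodes)) == 1
    )

    def annd(v):
        nb = u_nbrs(v)
        if not nb:
            return 0.0
        return sum(deg_u[u] for u in nb) / len(nb)

    annds = [annd(v) for v in nodes]
    weights = list(in_w.values())
    return {
        "density_u": 2 * len(in_u) / (n * (n - 1)),
        "degree_max_u": max(deg_u.values()),
        "degree_avg_u": sum(deg_u.values()) / n,
        "degree_med_u": float(median(sorted(deg_u.values()))),
        "clustcoef_var_u": _var([cc_u(v) for v in nodes]),
        "density_w": 2 * d_in / (n * (n - 1)),
        "degree_max_w": max(deg_w.values()),
        "degree_avg_w": sum(deg_w.values()) / n,
        "degree_med_w": float(median(sorted(deg_w.values()))),
        "edgeweight_mean": sum(weights) / len(weights) if weights else 0.0,
        "edgeweight_var": _var(weights),
        "modularity": d_in / (d_in + d_out) if d_in + d_out else 0.0,
        "ccw_mean": sum(ccw(v) for v in nodes) / n,
        "ccw_max": max(ccw(v) for v in nodes),
        "avg_nbr_degree_mean": sum(annds) / n,
        "avg_nbr_degree_var": _var(annds),
    }
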