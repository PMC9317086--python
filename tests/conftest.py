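import networkx as nx
import pytest

from complexwise import synthetic, weighting
from complexwise.core import AnnotationIndex


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def four_clique():
    g = nx.Graph()
    g.add_edges_from(
        (u, v)
        for i, u in enumerate("abcd")
        for v in "abcd"[i + 1 :]
    )
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


def unit_weights(g: nx.Graph) -> nx.Graph:
    w = g.copy()
    nx.set_edge_attributes(w, 1.0, "weight")
    return w


@pytest.fixture(scope="session")
def bench():
    """Default synthetic benchmark plus its confidence-weighted network."""
    cfg = synthetic.SynthConfig(seed=1)
    net, truth, ann = synthetic.generate(cfg)
    wnet = weighting.weight_network(net, ann)
    return {"cfg": cfg, "net": net, "truth": truth, "ann": ann, "wnet": wnet}


@pytest.fixture
def small_ann():
    """Terms t1 (|S|=10), t2 (|S|=100) shared by x/y, big term sets Smax=1000."""
    ann = AnnotationIndex()
    for i in range(1000):
        ann.add(f"b{i}", "t_max", "BP")
    for i in range(8):
        ann.add(f"s{i}", "t1", "BP")
    for i in range(98):
        ann.add(f"m{i}", "t2", "CC")
    for p in ("x", "y"):
        ann.add(p, "t1", "BP")
        ann.add(p, "t2", "CC")
    return ann
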