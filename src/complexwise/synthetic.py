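"""Synthetic PPI benchmarks with planted complexes and coherent GO terms.

The generator emulates the statistical structure the method assumes: a
sparse Erdős–Rényi interactome in which protein complexes appear as
dense planted subgraphs whose members tend to share specific GO terms.
Disjoint node sets are planted and internally wired at ``p_in``; most of
them ("coherent" complexes) receive a dedicated GO term annotating all
members, and per-protein noise annotations are sprinkled on top so the
annotation index is never trivially separable.  The ground-truth complex
set is returned for scoring.  Everything is deterministic under the
config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .core import (
    AnnotationIndex,
    ComplexSet,
    Network,
    ProteinComplex,
    ValidationError,
    fanout_seed,
)
from . import io as cwio

#: GAF aspect letters cycled across synthetic terms (exercises filtering).
_ASPECT_CYCLE = ("P", "F", "C")


@dataclass
class SynthConfig:
    n_background_nodes: int = 300
    p_background: float = 0.01
    n_complexes: int = 20
    size_min: int = 3
    size_max: int = 8
    p_in: float = 0.9
    n_go_terms: int = 50
    p_term_coherent: float = 0.9
    annotation_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_background", "p_in", "p_term_coherent",
                     "annotation_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.size_min < 3:
            raise ValidationError("size_min must be >= 3")
        if self.size_max < self.size_min:
            raise ValidationError("size_max < size_min")
        if self.size_max > self.n_background_nodes:
            raise ValidationError("size_max exceeds the node count")


def generate(cfg: SynthConfig):
    """Return (network, truth complexes, annotation index).

    The network is unweighted; planted complexes are disjoint node sets
    drawn from the background population, internally wired at ``p_in``
    on top of the background edges.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes = [f"P{i:04d}" for i in range(cfg.n_background_nodes)]

    net: Network = nx.Graph()
    net.add_nodes_from(nodes)
    bg = nx.fast_gnp_random_graph(
        cfg.n_background_nodes,
        cfg.p_background,
        seed=fanout_seed(cfg.seed, "background"),
    )
    for i, j in bg.edges:
        net.add_edge(nodes[i], nodes[j])

    sizes = rng.integers(cfg.size_min, cfg.size_max + 1, size=cfg.n_complexes)
    if sizes.sum() > cfg.n_background_nodes:
        raise ValidationError(
            "planted complexes need more nodes than the network has"
        )
    pool = rng.permutation(cfg.n_background_nodes)
    truth = []
    cursor = 0
    for size in sizes:
        members = [nodes[i] for i in pool[cursor : cursor + size]]
        cursor += size
        for a in range(size):
            for b in range(a + 1, size):
                if rng.random() < cfg.p_in:
                    net.add_edge(members[a], members[b])
        truth.append(ProteinComplex(frozenset(members)))

    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    aspect_of = {
        t: _ASPECT_CYCLE[i % len(_ASPECT_CYCLE)] for i, t in enumerate(terms)
    }
    ann = AnnotationIndex()
    from .core import GAF_ASPECT

    term_cursor = 0
    for cx in truth:
        if term_cursor < len(terms) and rng.random() < cfg.p_term_coherent:
            t = terms[term_cursor]
            term_cursor += 1
            for m in sorted(cx.members):
                ann.add(m, t, GAF_ASPECT[aspect_of[t]])
    for node in nodes:
        if rng.random() < cfg.annotation_noise:
            t = terms[rng.integers(len(terms))]
            ann.add(node, t, GAF_ASPECT[aspect_of[t]])

    return net, ComplexSet(truth, provenance="planted truth"), ann


def _gaf_row(protein: str, term: str, aspect_letter: str) -> str:
    cols = [
        "SYNTH",            # DB
        protein,            # DB Object ID
        protein,            # DB Object Symbol
        "involved_in",      # Qualifier
        term,               # GO ID
        "SYNTH_REF:0000001",  # DB:Reference
        "IEA",              # Evidence Code
        "",                 # With/From
        aspect_letter,      # Aspect
        "",                 # DB Object Name
        "",                 # Synonym
        "protein",          # DB Object Type
        "taxon:0",          # Taxon
        "20260101",         # Date
        "SYNTH",            # Assigned By
        "",                 # Annotation Extension
        "",                 # Gene Product Form ID
    ]
    return "\t".join(cols)


def make_benchmark(cfg: SynthConfig, out_dir) -> dict:
    """Write edges.tsv / truth.txt / ann.gaf (+ manifest.json) to a dir.

    All three files round-trip through the io module; the manifest
    records the full config so the fixture can be regenerated.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth, ann = generate(cfg)

    edges_path = out / "edges.tsv"
    truth_path = out / "truth.txt"
    gaf_path = out / "ann.gaf"
    cwio.write_edge_list(net, edges_path)
    cwio.write_complexes(truth, truth_path)

    aspect_letter = {"BP": "P", "MF": "F", "CC": "C"}
    with open(gaf_path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in sorted(ann.term_proteins):
            letter = aspect_letter[ann.term_aspect[term]]
            for protein in sorted(ann.term_proteins[term]):
                fh.write(_gaf_row(protein, term, letter) + "\n")

    manifest = {"config": asdict(cfg), "files": ["edges.tsv", "truth.txt",
                                                 "ann.gaf"]}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
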