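"""Readers and writers for edge lists, complex catalogs and GAF annotations.

Edge lists are two- or three-column whitespace/tab-separated text
(``u  v  [weight]``) with ``#`` comments.  Complex catalogs are
MIPS/SGD-style: one complex per line, whitespace-separated protein IDs.
GO annotations come in as GAF 2.x.  All outputs are UTF-8 text.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .core import (
    GAF_ASPECT,
    AnnotationIndex,
    ComplexSet,
    Network,
    ParseError,
    ProteinComplex,
    ValidationError,
)

logger = logging.getLogger(__name__)

_FLOAT_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+[eE][+-]?\d+|\d+\.?\d*)$")


def read_edge_list(path, dedupe: bool = True) -> Network:
    """Read an interaction edge list into an undirected simple graph.

    Self-loops are dropped and duplicate pairs collapsed (first-seen
    weight kept, conflicting later weights logged and ignored).  The node
    set is exactly the union of endpoint identifiers, so an endpoint seen
    only in a self-loop still becomes a node.
    """
    net: Network = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2-3 fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            weight = None
            if len(fields) == 3:
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad weight {fields[2]!r}"
                    ) from exc
                if weight < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative weight {weight}"
                    )
            net.add_node(u)
            net.add_node(v)
            if u == v:
                continue
            if net.has_edge(u, v):
                if not dedupe:
                    raise ParseError(f"{path}:{lineno}: duplicate edge {u}-{v}")
                old = net.edges[u, v].get("weight")
                if weight is not None and old is not None and weight != old:
                    logger.warning(
                        "%s:%d: duplicate edge %s-%s with conflicting weight "
                        "%s (keeping first %s)", path, lineno, u, v, weight, old
                    )
                continue
            if weight is None:
                net.add_edge(u, v)
            else:
                net.add_edge(u, v, weight=weight)
    return net


def write_edge_list(net: Network, path, decimals: int = 6) -> None:
    """Write ``u<TAB>v[<TAB>weight]`` lines in canonical sorted order."""
    with open(path, "w", encoding="utf-8") as fh:
        isolated = [n for n in sorted(net.nodes) if net.degree(n) == 0]
        for n in isolated:
            # Self-referential placeholder keeps isolated nodes round-trippable.
            fh.write(f"{n}\t{n}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            w = net.edges[u, v].get("weight")
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:.{decimals}f}\n")


def network_summary(net: Network) -> dict:
    """Node/edge counts and the mean neighbor count 2|E|/|V|."""
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    avg = 2.0 * n_edges / n_nodes if n_nodes else 0.0
    return {"n_nodes": n_nodes, "n_edges": n_edges, "avg_neighbors": avg}


def read_complexes(
    path,
    min_size: int = 3,
    restrict_to: Optional[Network] = None,
    provenance: str = "",
) -> ComplexSet:
    """Read a one-complex-per-line catalog.

    When ``restrict_to`` is given, members absent from that network are
    dropped before the size filter — catalog complexes routinely contain
    proteins the interaction screen never observed, and such members can
    never be recovered from the network.  Complexes left with fewer than
    ``min_size`` members are discarded.  A trailing tab-separated numeric
    field (as written by :func:`write_complexes`) is read back as the
    complex probability.
    """
    complexes = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            prob = None
            tab_fields = line.split("\t")
            if len(tab_fields) > 1 and _FLOAT_RE.match(tab_fields[-1].strip()):
                prob = float(tab_fields[-1])
                line = "\t".join(tab_fields[:-1])
            members = set(line.split())
            if restrict_to is not None:
                members &= set(restrict_to.nodes)
            if len(members) < min_size:
                continue
            complexes.append(ProteinComplex(frozenset(members), probability=prob))
    return ComplexSet(complexes, provenance=provenance or str(path))


def write_complexes(cs: ComplexSet, path) -> None:
    """One complex per line, members sorted, optional 4-dp probability."""
    with open(path, "w", encoding="utf-8") as fh:
        for cx in cs:
            line = " ".join(cx.canonical)
            if cx.probability is not None:
                line += f"\t{cx.probability:.4f}"
            fh.write(line + "\n")


def read_gaf(
    path,
    aspects: Iterable[str] = ("BP", "CC", "MF"),
    exclude_evidence: Iterable[str] = (),
    id_column: int = 1,
) -> AnnotationIndex:
    """Parse a GAF 2.x annotation file into an :class:`AnnotationIndex`.

    Rows whose qualifier contains ``NOT`` are skipped (they assert the
    *absence* of a function).  ``aspects`` restricts which of BP/CC/MF are
    retained; all evidence codes are accepted unless listed in
    ``exclude_evidence``.  ``id_column`` selects the protein identifier
    column (1 = DB Object ID, 2 = DB Object Symbol).
    """
    wanted = set(aspects)
    unknown = wanted - set(GAF_ASPECT.values())
    if unknown:
        raise ValidationError(f"unknown aspects {sorted(unknown)}")
    excluded = set(exclude_evidence)
    idx = AnnotationIndex()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ParseError(
                    f"{path}:{lineno}: GAF row has {len(cols)} columns (< 15)"
                )
            qualifier, go_id, evidence, aspect_code = (
                cols[3], cols[4], cols[6], cols[8],
            )
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in excluded:
                continue
            aspect = GAF_ASPECT.get(aspect_code)
            if aspect is None:
                raise ParseError(
                    f"{path}:{lineno}: bad aspect code {aspect_code!r}"
                )
            if aspect not in wanted:
                continue
            protein = cols[id_column]
            if not protein:
                raise ParseError(f"{path}:{lineno}: empty protein identifier")
            idx.add(protein, go_id, aspect)
    return idx
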