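"""Shared domain types and helpers.

A PPI network is held as an undirected :class:`networkx.Graph` whose nodes
are protein identifier strings; edge weights, when present, live in the
``"weight"`` edge attribute.  Complexes are immutable member sets with an
optional classifier probability, and GO annotations are kept in a small
bidirectional index (protein -> terms, term -> proteins).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import networkx as nx

#: Alias for the canonical network container.
Network = nx.Graph

ASPECTS = ("BP", "CC", "MF")

#: GAF single-letter aspect codes -> canonical aspect names.
GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


class ParseError(ValueError):
    """Malformed input file (message carries the offending line number)."""


class ValidationError(ValueError):
    """A contract violation on arguments or data."""


@dataclass(frozen=True)
class ProteinComplex:
    """A set of proteins hypothesised (or known) to form a complex."""

    members: frozenset
    probability: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError("a complex must have at least one member")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"probability {self.probability!r} outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    @property
    def canonical(self) -> tuple:
        """Members as a sorted tuple (total order for tie-breaking)."""
        return tuple(sorted(self.members))

    def with_probability(self, p: float) -> "ProteinComplex":
        return ProteinComplex(self.members, probability=p, label=self.label)


@dataclass
class ComplexSet:
    """An ordered collection of complexes with free-text provenance."""

    complexes: list = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[ProteinComplex]:
        return iter(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]

    def member_sets(self) -> list:
        return [c.members for c in self.complexes]


@dataclass
class AnnotationIndex:
    """Bidirectional protein <-> GO-term maps with per-term counts.

    ``protein_terms`` and ``term_proteins`` are mutually consistent
    inverses; ``term_aspect`` assigns each term exactly one of BP/CC/MF.
    """

    protein_terms: dict = field(default_factory=dict)
    term_proteins: dict = field(default_factory=dict)
    term_aspect: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "AnnotationIndex":
        """Build from an iterable of (protein, term, aspect) triples."""
        idx = cls()
        for protein, term, aspect in records:
            idx.add(protein, term, aspect)
        return idx

    def add(self, protein: str, term: str, aspect: str) -> None:
        if aspect not in ASPECTS:
            raise ValidationError(f"unknown GO aspect {aspect!r}")
        prev = self.term_aspect.setdefault(term, aspect)
        if prev != aspect:
            raise ValidationError(
                f"term {term} assigned two aspects ({prev}, {aspect})"
            )
        self.protein_terms.setdefault(protein, set()).add(term)
        self.term_proteins.setdefault(term, set()).add(protein)

    @property
    def smax(self) -> int:
        """Largest annotated-protein count over all terms (0 if empty)."""
        if not self.term_proteins:
            return 0
        return max(len(p) for p in self.term_proteins.values())

    def terms_of(self, protein: str) -> frozenset:
        return frozenset(self.protein_terms.get(protein, ()))

    def shared_terms(self, v: str, u: str) -> frozenset:
        return self.terms_of(v) & self.terms_of(u)

    def n_terms(self) -> int:
        return len(self.term_proteins)


def fanout_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from one global seed.

    Stage names salt the hash so independent sources of randomness never
    share a stream even when the global seed is reused.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
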