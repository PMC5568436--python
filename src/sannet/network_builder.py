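"""Conflating annotated utterances into a Syntactically Analyzed Network (SAN).

A SAN is a directed labeled graph: each unique canonical word form is a node,
and each governor → dependent dependency observed in the corpus is an edge
carrying the multiset of relation labels with which that pair occurred.  Edge
direction follows the analysis convention (under the DP-hypothesis the
determiner points at the noun).  Root attachments never become edges — the
network connects words to words only — and self-loops (which can arise when
unification collapses two forms of one utterance) are dropped with a warning.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .annotation import (
    AnnotatedUtterance,
    AnnotationError,
    LabelScheme,
    NormalizationMap,
    normalize,
    validate,
)

logger = logging.getLogger(__name__)

__all__ = ["NodeData", "EdgeData", "SAN", "ComponentView", "add_utterance", "build_san", "components"]


@dataclass
class NodeData:
    """Attributes of one word node.

    ``occurrence_count`` is how many times the word was produced (token
    occurrences, not edges).  The category is resolved by majority vote over
    all annotations of the form; ties break lexicographically so bilingual
    node coloring is deterministic.
    """

    occurrence_count: int = 0
    category_votes: Counter = field(default_factory=Counter)

    @property
    def category(self) -> Optional[str]:
        if not self.category_votes:
            return None
        best = max(self.category_votes.values())
        return min(c for c, v in self.category_votes.items() if v == best)


@dataclass
class EdgeData:
    """Attributes of one governor → dependent edge: a relation-label multiset."""

    labels: Counter = field(default_factory=Counter)

    @property
    def count(self) -> int:
        return sum(self.labels.values())

    @property
    def distinct_labels(self) -> list[str]:
        return sorted(self.labels)


class SAN:
    """The accumulated network. Nodes keyed by canonical form, edges by pair.

    Two edge-counting conventions coexist because network programs differ:
    ``pair`` counts each connected (governor, dependent) pair once however many
    labels it carries; ``labeled`` counts each distinct
    (governor, dependent, relation) triple.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, NodeData] = {}
        self.edges: dict[tuple[str, str], EdgeData] = {}

    # -- counting -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self, mode: str = "pair") -> int:
        if mode == "pair":
            return len(self.edges)
        if mode == "labeled":
            return sum(len(set(e.labels)) for e in self.edges.values())
        raise ValueError(f"unknown edge mode {mode!r} (use 'pair' or 'labeled')")

    def total_arc_count(self) -> int:
        """Total non-root, non-self-loop arcs consumed (sum of edge counts)."""
        return sum(e.count for e in self.edges.values())

    # -- mutation -----------------------------------------------------------
    def upsert_node(self, form: str, category: Optional[str] = None, occurrences: int = 1) -> None:
        node = self.nodes.setdefault(form, NodeData())
        node.occurrence_count += occurrences
        if category:
            if node.category_votes and category not in node.category_votes:
                logger.info("category conflict on %r: %s vs %s", form, category, dict(node.category_votes))
            node.category_votes[category] += 1

    def upsert_edge(self, governor: str, dependent: str, relation: str, count: int = 1) -> None:
        if governor == dependent:
            raise AnnotationError(f"self-loop edge on {governor!r}")
        if governor not in self.nodes:
            self.upsert_node(governor, occurrences=0)
        if dependent not in self.nodes:
            self.upsert_node(dependent, occurrences=0)
        self.edges.setdefault((governor, dependent), EdgeData()).labels[relation] += count

    # -- projections --------------------------------------------------------
    def to_networkx(self, label_join: str = "|") -> nx.DiGraph:
        """Directed graph with node/edge attributes, nodes and edges sorted."""
        g = nx.DiGraph()
        for form in sorted(self.nodes):
            data = self.nodes[form]
            attrs = {"occurrence_count": data.occurrence_count}
            if data.category is not None:
                attrs["category"] = data.category
            g.add_node(form, **attrs)
        for (gov, dep) in sorted(self.edges):
            edge = self.edges[(gov, dep)]
            g.add_edge(
                gov,
                dep,
                relations=label_join.join(edge.distinct_labels),
                relation_counts=label_join.join(
                    f"{l}:{edge.labels[l]}" for l in edge.distinct_labels
                ),
                count=edge.count,
            )
        return g

    def undirected(self) -> nx.Graph:
        """Undirected simple projection used by all distance/clustering metrics."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def directed_degree(self, form: str, mode: str = "labeled") -> int:
        """In-degree + out-degree of a node.

        ``labeled`` counts each distinct relation label on an incident edge
        separately (a pair linked by both "subject" and "object" contributes
        2); ``simple`` counts distinct neighbors per direction.
        """
        deg = 0
        for (gov, dep), edge in self.edges.items():
            if form in (gov, dep):
                deg += len(set(edge.labels)) if mode == "labeled" else 1
        return deg

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SAN):
            return NotImplemented
        return (
            {f: (n.occurrence_count, n.category) for f, n in self.nodes.items()}
            == {f: (n.occurrence_count, n.category) for f, n in other.nodes.items()}
            and {k: e.labels for k, e in self.edges.items()}
            == {k: e.labels for k, e in other.edges.items()}
        )


@dataclass(frozen=True)
class ComponentView:
    """A weakly connected component of a SAN (direction ignored for membership)."""

    san: SAN
    member_nodes: frozenset[str]
    is_giant: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.member_nodes)

    def induced_edges(self) -> dict[tuple[str, str], EdgeData]:
        return {
            (g, d): e
            for (g, d), e in self.san.edges.items()
            if g in self.member_nodes and d in self.member_nodes
        }

    def n_edges(self, mode: str = "pair") -> int:
        edges = self.induced_edges()
        if mode == "pair":
            return len(edges)
        return sum(len(set(e.labels)) for e in edges.values())

    def undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.member_nodes))
        g.add_edges_from(sorted(self.induced_edges()))
        return g


def add_utterance(
    san: SAN,
    annotated: AnnotatedUtterance,
    normalization: Optional[NormalizationMap] = None,
    scheme: Optional[LabelScheme] = None,
) -> SAN:
    """Fold one annotated utterance into the network, in place.

    The insertion is atomic: the annotation is validated first and an invalid
    one is rejected whole.  Every token occurrence increments its node's
    occurrence count; every non-root arc adds its relation to the edge's label
    multiset.  Arcs whose normalized endpoints coincide are dropped with a
    logged warning.
    """
    if scheme is not None:
        problems = validate(annotated, scheme)
        if problems:
            raise AnnotationError(
                f"utterance {annotated.utterance.index}: invalid annotation: "
                + "; ".join(problems)
            )
    canon = [
        normalize(t.canonical, normalization) for t in annotated.utterance.tokens
    ]
    for token, form in zip(annotated.utterance.tokens, canon):
        san.upsert_node(form, category=token.category)
    for arc in annotated.non_root_arcs:
        gov, dep = canon[arc.governor_pos - 1], canon[arc.dependent_pos - 1]
        if gov == dep:
            logger.warning(
                "utterance %d: dropping arc with same canonical form %r at both "
                "ends (repeated word or unification collision)",
                annotated.utterance.index,
                gov,
            )
            continue
        san.upsert_edge(gov, dep, arc.relation)
    return san


def build_san(
    annotations: Iterable[AnnotatedUtterance],
    normalization: Optional[NormalizationMap] = None,
    scheme: Optional[LabelScheme] = None,
) -> SAN:
    """Build a SAN by folding :func:`add_utterance` over the annotation list.

    The result is independent of list order: same nodes, same edges, same
    counts for any permutation.
    """
    san = SAN()
    for i, annotated in enumerate(annotations):
        try:
            add_utterance(san, annotated, normalization=normalization, scheme=scheme)
        except AnnotationError as exc:
            raise AnnotationError(f"annotation {i}: {exc}") from exc
    return san


def components(san: SAN) -> list[ComponentView]:
    """Weakly connected components, largest first; the first is the giant one.

    Size ties break by lexicographically smallest member form, for
    deterministic giant-component selection.
    """
    if not san.nodes:
        return []
    undirected = san.undirected()
    member_sets = [frozenset(c) for c in nx.connected_components(undirected)]
    member_sets.sort(key=lambda c: (-len(c), min(c)))
    return [
        ComponentView(san=san, member_nodes=members, is_giant=(i == 0))
        for i, members in enumerate(member_sets)
    ]
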