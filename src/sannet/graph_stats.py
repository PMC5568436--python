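"""Network statistics for SANs: summary metrics, relation frequencies, hubs.

All distance and clustering metrics are computed on the undirected simple
projection of the directed labeled network, with unit edge lengths.  Path
length and diameter are defined only on a connected graph, so they are always
taken on the giant connected component; asking for them on a disconnected
graph is an error, never a silent fallback.

The summary carries an advisory small-world flag: high clustering relative to
the Erdős–Rényi expectation <k>/N combined with a characteristic path length
close to the random-graph scale ln N / ln <k>.  The thresholds are
configurable and the flag is descriptive, not a hypothesis test.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .annotation import AnnotatedUtterance
from .network_builder import SAN, ComponentView, components

__all__ = [
    "NetworkStats",
    "RelationFrequencyTable",
    "HubTable",
    "LongitudinalReport",
    "clustering_coefficient",
    "characteristic_path_length",
    "diameter",
    "average_degree",
    "node_edge_ratio",
    "summarize",
    "relation_frequencies",
    "hubs",
    "track_longitudinal",
]

GraphLike = Union[SAN, ComponentView, nx.Graph]


def _as_undirected(view: GraphLike) -> nx.Graph:
    if isinstance(view, (SAN, ComponentView)):
        return view.undirected()
    return nx.Graph(view)


@dataclass(frozen=True)
class NetworkStats:
    """One row of a network-summary table.

    ``path_length_L`` and ``diameter`` are always giant-component quantities;
    they are ``None`` when the (sub)graph has fewer than two nodes.
    ``avg_degree_k`` is 2E/N on the undirected simple projection and
    ``node_edge_ratio`` is N/E (``None`` when E = 0).
    """

    n_nodes: int
    n_edges: int
    clustering_C: float
    path_length_L: Optional[float]
    diameter: Optional[int]
    avg_degree_k: float
    node_edge_ratio: Optional[float]
    component_scope: str  # "giant" | "whole"
    small_world: bool = False


def clustering_coefficient(view: GraphLike) -> float:
    """Mean local clustering over all nodes; degree-<2 nodes contribute 0.

    Equals 0 on any tree and 1 on any complete graph.
    """
    g = _as_undirected(view)
    if g.number_of_nodes() == 0:
        raise ValueError("clustering coefficient undefined on an empty graph")
    return nx.average_clustering(g)


def characteristic_path_length(view: GraphLike) -> float:
    """Mean shortest-path length over all unordered node pairs (unit lengths)."""
    g = _as_undirected(view)
    if g.number_of_nodes() < 2:
        raise ValueError("path length needs at least 2 nodes")
    if not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected: compute path length on the giant connected "
            "component (components(san)[0])"
        )
    return nx.average_shortest_path_length(g)


def diameter(view: GraphLike) -> int:
    """Maximum shortest-path length on the undirected projection."""
    g = _as_undirected(view)
    if g.number_of_nodes() < 2:
        raise ValueError("diameter needs at least 2 nodes")
    if not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected: compute the diameter on the giant connected "
            "component (components(san)[0])"
        )
    return nx.diameter(g)


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Average number of edges per node, <k> = 2E/N (undirected projection)."""
    if n_nodes < 1:
        raise ValueError("average degree needs at least one node")
    return 2.0 * n_edges / n_nodes


def node_edge_ratio(n_nodes: int, n_edges: int) -> float:
    """Ratio of nodes vs. edges, N/E; undefined (error) when E = 0."""
    if n_edges < 1:
        raise ValueError("node/edge ratio undefined with zero edges")
    return n_nodes / n_edges


def summarize(
    san: SAN,
    scope: str = "giant",
    edge_mode: str = "pair",
    sw_clustering_factor: float = 4.0,
    sw_path_factor: float = 2.0,
) -> NetworkStats:
    """Populate a :class:`NetworkStats` row for the whole graph or its giant part.

    Node/edge counts, clustering, <k> and N/E honour ``scope``; path length and
    diameter are giant-component quantities regardless.  ``edge_mode`` selects
    the edge-counting convention (connected pairs vs. labeled links).  Values
    are kept at full precision; rounding happens only at presentation time.
    """
    if scope not in ("giant", "whole"):
        raise ValueError(f"unknown scope {scope!r} (use 'giant' or 'whole')")
    if not san.nodes:
        raise ValueError("cannot summarize an empty network")

    comps = components(san)
    giant = comps[0]
    counted: Union[SAN, ComponentView] = giant if scope == "giant" else san
    n = counted.n_nodes if scope == "giant" else san.n_nodes
    e = counted.n_edges(edge_mode)

    clustering = clustering_coefficient(counted)
    length = characteristic_path_length(giant) if giant.n_nodes >= 2 else None
    diam = diameter(giant) if giant.n_nodes >= 2 else None
    k = average_degree(n, e)
    ratio = node_edge_ratio(n, e) if e else None

    small_world = False
    if length is not None and k > 1.0 and n >= 3:
        random_c = k / n
        random_l = math.log(n) / math.log(k)
        small_world = (
            clustering > sw_clustering_factor * random_c
            and length <= sw_path_factor * random_l
        )
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        clustering_C=clustering,
        path_length_L=length,
        diameter=diam,
        avg_degree_k=k,
        node_edge_ratio=ratio,
        component_scope=scope,
        small_world=small_world,
    )


@dataclass(frozen=True)
class RelationFrequencyTable:
    """Counts of syntactic relations over the whole graph.

    ``token`` mode counts every produced arc (requires the annotation list);
    ``type`` mode counts distinct (governor, dependent, relation) triples in
    the network.
    """

    rows: dict[str, int]
    mode: str

    def total(self) -> int:
        return sum(self.rows.values())


def relation_frequencies(
    san: Optional[SAN] = None,
    annotations: Optional[Sequence[AnnotatedUtterance]] = None,
    mode: str = "type",
) -> RelationFrequencyTable:
    if mode == "token":
        if annotations is None:
            raise ValueError("token mode needs the annotation list")
        counts: Counter = Counter(
            arc.relation for ann in annotations for arc in ann.non_root_arcs
        )
    elif mode == "type":
        if san is None:
            raise ValueError("type mode needs the network")
        counts = Counter()
        for edge in san.edges.values():
            for label in set(edge.labels):
                counts[label] += 1
    else:
        raise ValueError(f"unknown mode {mode!r} (use 'token' or 'type')")
    return RelationFrequencyTable(rows=dict(sorted(counts.items())), mode=mode)


@dataclass(frozen=True)
class HubTable:
    """Highly connected words, ranked by directed degree (in + out).

    Rows are sorted by degree descending, ties alphabetical; every row's
    degree is at least ``cutoff``.
    """

    rows: tuple[tuple[str, int], ...]
    cutoff: int


def hubs(san: SAN, min_degree: int = 1, mode: str = "labeled") -> HubTable:
    """Rank words by directed degree and keep those at or above ``min_degree``.

    ``labeled`` degree counts each distinct relation label on an incident edge
    as its own directed edge; ``simple`` counts distinct neighbor pairs.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    rows = [
        (form, deg)
        for form in san.nodes
        if (deg := san.directed_degree(form, mode=mode)) >= min_degree
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return HubTable(rows=tuple(rows), cutoff=min_degree)


@dataclass(frozen=True)
class LongitudinalReport:
    """Development across chronologically ordered sessions.

    ``degrees`` holds each word's directed degree per session (0 when the word
    is absent); ``stats`` and ``relations`` give per-session summary rows;
    ``appeared_labels`` lists relation labels absent in at least one session
    and produced in a later one — in a clinical record a candidate sign of
    recovery.
    """

    session_ids: tuple[str, ...]
    degrees: pd.DataFrame
    stats: dict[str, NetworkStats]
    relations: pd.DataFrame
    appeared_labels: tuple[str, ...]


def track_longitudinal(
    sans: Sequence[tuple[str, SAN]],
    degree_mode: str = "labeled",
    scope: str = "giant",
) -> LongitudinalReport:
    """Compare two or more session networks word by word and label by label."""
    if len(sans) < 2:
        raise ValueError("longitudinal tracking needs at least 2 sessions")
    ids = tuple(sid for sid, _ in sans)
    if len(set(ids)) != len(ids):
        raise ValueError("session ids must be unique")

    forms = sorted({form for _, san in sans for form in san.nodes})
    degrees = pd.DataFrame(
        {
            sid: [
                san.directed_degree(f, mode=degree_mode) if f in san.nodes else 0
                for f in forms
            ]
            for sid, san in sans
        },
        index=forms,
    )

    stats = {sid: summarize(san, scope=scope) for sid, san in sans}

    tables = {sid: relation_frequencies(san=san, mode="type") for sid, san in sans}
    labels = sorted({label for t in tables.values() for label in t.rows})
    relations = pd.DataFrame(
        {sid: [tables[sid].rows.get(l, 0) for l in labels] for sid, _ in sans},
        index=labels,
    )

    appeared = []
    for label in labels:
        series = [tables[sid].rows.get(label, 0) for sid, _ in sans]
        for i in range(len(series) - 1):
            if series[i] == 0 and any(v > 0 for v in series[i + 1 :]):
                appeared.append(label)
                break
    return LongitudinalReport(
        session_ids=ids,
        degrees=degrees,
        stats=stats,
        relations=relations,
        appeared_labels=tuple(appeared),
    )
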