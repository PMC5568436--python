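"""Serialize SANs and result tables for network programs and spreadsheets.

GraphML is the interchange format both Gephi and Cytoscape import; SIF is
Cytoscape's simple interaction format; the edge CSV opens directly in a
spreadsheet.  All outputs are UTF-8 and preserve special characters (ñ,
accents) byte-exactly.  Readers for GraphML, the edge CSV and the pairs
format are provided so exports round-trip.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import networkx as nx

from .annotation import AnnotatedUtterance, ROOT_RELATION
from .graph_stats import HubTable, NetworkStats, RelationFrequencyTable
from .network_builder import SAN

__all__ = [
    "ExportOptions",
    "write_graphml",
    "read_graphml",
    "write_sif",
    "write_edge_csv",
    "read_edge_csv",
    "write_pairs",
    "write_stats_csv",
]


@dataclass(frozen=True)
class ExportOptions:
    """Serialization switches shared by the writers."""

    include_counts: bool = True
    include_categories: bool = True
    label_join: str = "|"

    def __post_init__(self) -> None:
        if self.label_join in ("\t", ","):
            raise ValueError("label_join may not be a tab or comma (tabular formats)")


DEFAULT_OPTIONS = ExportOptions()


def write_graphml(san: SAN, options: ExportOptions = DEFAULT_OPTIONS) -> str:
    """Serialize to GraphML: directed edges, attributes on nodes and edges.

    Node attributes: ``category`` and ``occurrence_count``; edge attributes:
    ``relations`` (labels joined with ``options.label_join``) and ``count``.
    Node and edge order is sorted, so equal networks serialize identically.
    """
    if not san.nodes:
        raise ValueError("refusing to export an empty network")
    g = san.to_networkx(label_join=options.label_join)
    if not options.include_counts:
        for _, data in g.nodes(data=True):
            data.pop("occurrence_count", None)
        for _, _, data in g.edges(data=True):
            data.pop("count", None)
    if not options.include_categories:
        for _, data in g.nodes(data=True):
            data.pop("category", None)
    buffer = io.BytesIO()
    nx.write_graphml(g, buffer, encoding="utf-8", prettyprint=True)
    return buffer.getvalue().decode("utf-8")


def read_graphml(
    source: str, options: ExportOptions = DEFAULT_OPTIONS
) -> SAN:
    """Rebuild a SAN from a GraphML document produced by :func:`write_graphml`."""
    g = nx.parse_graphml(source)
    san = SAN()
    for node, data in g.nodes(data=True):
        san.upsert_node(
            str(node),
            category=data.get("category"),
            occurrences=int(data.get("occurrence_count", 0)),
        )
    for gov, dep, data in g.edges(data=True):
        if data.get("relation_counts"):
            for item in str(data["relation_counts"]).split(options.label_join):
                label, _, times = item.rpartition(":")
                san.upsert_edge(str(gov), str(dep), label, count=int(times))
            continue
        labels = [l for l in str(data.get("relations", "")).split(options.label_join) if l]
        count = int(data.get("count", len(labels) or 1))
        if not labels:
            san.upsert_edge(str(gov), str(dep), ROOT_RELATION, count=count)
            continue
        # no per-label counts recorded: spread the total evenly
        base, extra = divmod(count, len(labels))
        for i, label in enumerate(labels):
            san.upsert_edge(str(gov), str(dep), label, count=base + (1 if i < extra else 0))
    return san


def write_sif(san: SAN, options: ExportOptions = DEFAULT_OPTIONS) -> str:
    """One line per labeled edge, ``governor<TAB>relation<TAB>dependent``.

    Isolated nodes are emitted as bare-name lines so they survive the import.
    Forms containing a tab cannot be encoded and raise.
    """
    if not san.nodes:
        raise ValueError("refusing to export an empty network")
    for form in san.nodes:
        if "\t" in form:
            raise ValueError(f"form {form!r} contains a tab: unencodable in SIF")
    lines = []
    connected = set()
    for (gov, dep) in sorted(san.edges):
        connected.update((gov, dep))
        for label in san.edges[(gov, dep)].distinct_labels:
            lines.append(f"{gov}\t{label}\t{dep}")
    for form in sorted(san.nodes):
        if form not in connected:
            lines.append(form)
    return "\n".join(lines) + "\n"


_CSV_HEADER = [
    "governor",
    "relation",
    "dependent",
    "count",
    "governor_category",
    "dependent_category",
]


def write_edge_csv(san: SAN, options: ExportOptions = DEFAULT_OPTIONS) -> str:
    """RFC-4180 CSV, one row per (governor, relation, dependent) with its count."""
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for (gov, dep) in sorted(san.edges):
        edge = san.edges[(gov, dep)]
        for label in sorted(edge.labels):
            writer.writerow(
                [
                    gov,
                    label,
                    dep,
                    edge.labels[label] if options.include_counts else "",
                    (san.nodes[gov].category or "") if options.include_categories else "",
                    (san.nodes[dep].category or "") if options.include_categories else "",
                ]
            )
    return out.getvalue()


def read_edge_csv(source: str) -> SAN:
    """Rebuild a SAN's edge map (and categories) from :func:`write_edge_csv` output."""
    san = SAN()
    reader = csv.DictReader(io.StringIO(source))
    for row in reader:
        gov, dep = row["governor"], row["dependent"]
        san.upsert_node(gov, category=row.get("governor_category") or None, occurrences=0)
        san.upsert_node(dep, category=row.get("dependent_category") or None, occurrences=0)
        san.upsert_edge(gov, dep, row["relation"], count=int(row.get("count") or 1))
    return san


def write_pairs(annotations: Sequence[AnnotatedUtterance]) -> str:
    """Write annotations in the columnar pairs format (blank-line blocks).

    Repeated canonical forms within one utterance receive the ``#k``
    occurrence suffix so the block remains unambiguous.
    """
    blocks = []
    for ann in annotations:
        seen: Counter = Counter()
        keys: dict[int, str] = {}
        for token in ann.utterance.tokens:
            seen[token.canonical] += 1
            keys[token.position] = (
                token.canonical
                if seen[token.canonical] == 1
                else f"{token.canonical}#{seen[token.canonical]}"
            )
        lines = []
        for arc in ann.non_root_arcs:
            gov_tok = ann.token_at(arc.governor_pos)
            dep_tok = ann.token_at(arc.dependent_pos)
            cols = [keys[arc.governor_pos], arc.relation, keys[arc.dependent_pos]]
            if gov_tok.category or dep_tok.category:
                cols += [gov_tok.category or "", dep_tok.category or ""]
            lines.append("\t".join(cols))
        if not lines:  # single-word utterance: a bare-form line so it round-trips
            for pos in sorted(keys):
                tok = ann.token_at(pos)
                lines.append(
                    f"{keys[pos]}\t{tok.category}" if tok.category else keys[pos]
                )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def write_stats_csv(
    result: Union[NetworkStats, RelationFrequencyTable, HubTable, Sequence[NetworkStats]],
) -> str:
    """Tabular CSV for any of the three result objects.

    Presentation rounding mirrors the usual network-summary layout: clustering
    to 3 decimals, node/edge ratio to 6, <k> and L to 3.  Internal objects
    keep full precision.
    """
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    if isinstance(result, NetworkStats):
        result = [result]
    if isinstance(result, RelationFrequencyTable):
        writer.writerow(["relation", "count"])
        for label, count in result.rows.items():
            writer.writerow([label, count])
    elif isinstance(result, HubTable):
        writer.writerow(["hub", "directed_edges"])
        for form, degree in result.rows:
            writer.writerow([form, degree])
    else:
        writer.writerow(
            ["scope", "C", "nodes", "edges", "ratio_n_e", "k", "L", "diameter"]
        )
        for stats in result:
            writer.writerow(
                [
                    stats.component_scope,
                    round(stats.clustering_C, 3),
                    stats.n_nodes,
                    stats.n_edges,
                    "" if stats.node_edge_ratio is None else round(stats.node_edge_ratio, 6),
                    round(stats.avg_degree_k, 3),
                    "" if stats.path_length_L is None else round(stats.path_length_L, 3),
                    "" if stats.diameter is None else stats.diameter,
                ]
            )
    return out.getvalue()
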