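"""File-backed gene/protein interaction store and neighbourhood assembly.

Interactions are undirected edges with an evidence class — ``biochemical``
(Y2H, pull-down, co-IP, ...; the assay is carried as a free-text method
string) or ``computational`` — loaded from a 3–4 column tab-delimited file.
Around any gene of interest a breadth-first interactor neighbourhood is
assembled (deterministic, lexicographic order) and exported as SIF or
GraphML for downstream network tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "EVIDENCE_CLASSES",
    "InteractionError",
    "InteractionStore",
    "Neighborhood",
    "load_interactions",
    "neighborhood",
    "export_sif",
    "export_graphml",
]

EVIDENCE_CLASSES = ("biochemical", "computational")


class InteractionError(ValueError):
    """Malformed interaction input."""


@dataclass
class InteractionStore:
    """Deduplicated undirected interaction graph.

    Edge attributes: ``evidence`` (biochemical wins when sources disagree)
    and ``methods`` (sorted, ';'-joined free-text assay labels).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add(
        self, gene_a: str, gene_b: str, evidence: str, method: str = ""
    ) -> None:
        if evidence not in EVIDENCE_CLASSES:
            raise InteractionError(
                f"unknown evidence class {evidence!r}; "
                f"expected one of {EVIDENCE_CLASSES}"
            )
        if self.graph.has_edge(gene_a, gene_b):
            data = self.graph.edges[gene_a, gene_b]
            methods = set(data["methods"].split(";")) if data["methods"] else set()
            if method:
                methods.add(method)
            data["methods"] = ";".join(sorted(methods))
            if evidence == "biochemical":
                data["evidence"] = "biochemical"
        else:
            self.graph.add_edge(
                gene_a, gene_b, evidence=evidence, methods=method
            )

    def edges(self) -> list[tuple[str, str, dict]]:
        return sorted(
            (tuple(sorted((a, b))) + ({**d},) for a, b, d in self.graph.edges(data=True)),
            key=lambda e: (e[0], e[1]),
        )

    def __len__(self) -> int:
        return self.graph.number_of_edges()


def load_interactions(tsv_path: str | Path) -> InteractionStore:
    """Read a 3–4 column TSV (gene_a, gene_b, evidence, [method]).

    The same pair in either orientation merges into one undirected edge with
    its method labels pooled.
    """
    store = InteractionStore()
    with open(tsv_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if line_no == 1 and len(parts) >= 3 and parts[2].lower() == "evidence":
                continue  # header row
            if len(parts) < 3:
                raise InteractionError(
                    f"line {line_no}: expected 3-4 tab-delimited columns"
                )
            gene_a, gene_b, evidence = parts[0], parts[1], parts[2]
            method = parts[3] if len(parts) > 3 else ""
            try:
                store.add(gene_a, gene_b, evidence, method)
            except InteractionError as exc:
                raise InteractionError(f"line {line_no}: {exc}") from None
    return store


@dataclass
class Neighborhood:
    """Interactors of a root gene out to a BFS depth.

    ``layers`` maps each depth d ≥ 1 to the edges whose farther endpoint
    first appears at that distance from the root (edges of the induced ball,
    annotated by radius); ordering is deterministic (lexicographic).
    """

    root: str
    depth: int
    layers: list[tuple[int, list[tuple[str, str, dict]]]]
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [e for _, layer in self.layers for e in layer]

    @property
    def nodes(self) -> list[str]:
        names = {self.root}
        for a, b, _ in self.edges:
            names.update((a, b))
        return sorted(names)


def neighborhood(
    store: InteractionStore,
    root: str,
    depth: int = 1,
    evidence_filter: str | None = None,
    annotations: Mapping[str, str] | None = None,
) -> Neighborhood:
    """Breadth-first interactor tree of ``root`` to the given depth,
    optionally restricted to one evidence class. An absent root yields an
    empty neighbourhood."""
    if depth < 1:
        raise InteractionError("depth must be >= 1")
    if evidence_filter is not None and evidence_filter not in EVIDENCE_CLASSES:
        raise InteractionError(f"unknown evidence class {evidence_filter!r}")
    g = store.graph
    if evidence_filter is not None:
        g = g.edge_subgraph(
            [
                (a, b)
                for a, b, d in g.edges(data=True)
                if d["evidence"] == evidence_filter
            ]
        ).copy()
    if root not in g:
        return Neighborhood(root, depth, [], dict(annotations or {}))
    dist = nx.single_source_shortest_path_length(g, root, cutoff=depth)
    layers: list[tuple[int, list[tuple[str, str, dict]]]] = []
    for d in range(1, depth + 1):
        layer = []
        for a, b, data in g.edges(data=True):
            if a not in dist or b not in dist:
                continue
            if max(dist[a], dist[b]) == d:
                x, y = sorted((a, b))
                layer.append((x, y, {**data}))
        layer.sort(key=lambda e: (e[0], e[1]))
        layers.append((d, layer))
    keep = {n for n in dist}
    notes = {k: v for k, v in (annotations or {}).items() if k in keep}
    return Neighborhood(root, depth, layers, notes)


def export_sif(nbhd: Neighborhood, path: str | Path) -> None:
    """Write the neighbourhood as SIF (node <evidence> node per line); an
    empty neighbourhood still writes its (isolated) root node."""
    lines = [f"{a}\t{d['evidence']}\t{b}" for a, b, d in nbhd.edges]
    if not lines:
        lines = [nbhd.root]
    Path(path).write_text("\n".join(lines) + "\n")


def export_graphml(nbhd: Neighborhood, path: str | Path) -> None:
    """Write the neighbourhood as GraphML with annotation node attributes."""
    g = nx.Graph()
    for node in nbhd.nodes:
        g.add_node(node, annotation=nbhd.annotations.get(node, ""))
    for a, b, data in nbhd.edges:
        g.add_edge(a, b, evidence=data["evidence"], methods=data.get("methods", ""))
    nx.write_graphml(g, str(path))
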