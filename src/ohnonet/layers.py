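"""The three regulatory layers: TF→gene, protein–protein, miRNA→gene.

Each layer is an immutable simple graph over string identifiers.  Node
identity across layers is by shared gene identifier; no fuzzy matching.
The transcriptional layer is a digraph in which self-loops (a TF binding its
own promoter) are permitted and contribute one unit to both the in- and
out-degree of the node.  The protein interaction layer is an undirected
simple graph without self-edges.  The miRNA layer is bipartite with edges
always running miRNA → gene; the miRNA and gene identifier namespaces must
be disjoint.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .catalog import SSD, WGD, GenePairCatalog

EdgeTuple = tuple[str, str]

LAYER_KINDS = ("directed", "undirected", "bipartite")


@dataclass(frozen=True)
class DirectedLayer:
    """Simple digraph of transcriptional regulations; self-loops allowed."""

    edges: frozenset[EdgeTuple]

    @classmethod
    def from_edges(cls, edges: Iterable[Sequence[str]]) -> "DirectedLayer":
        dedup = {(str(e[0]), str(e[1])) for e in edges}
        return cls(frozenset(dedup))

    @cached_property
    def nodes(self) -> frozenset[str]:
        return frozenset(x for e in self.edges for x in e)

    @cached_property
    def out_adj(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for u, v in self.edges:
            adj.setdefault(u, set()).add(v)
        return {u: frozenset(vs) for u, vs in adj.items()}

    @cached_property
    def in_adj(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for u, v in self.edges:
            adj.setdefault(v, set()).add(u)
        return {v: frozenset(us) for v, us in adj.items()}

    @property
    def regulators(self) -> frozenset[str]:
        """Nodes with out-degree >= 1."""
        return frozenset(self.out_adj)

    def out_neighbors(self, node: str) -> frozenset[str]:
        return self.out_adj.get(node, frozenset())

    def in_neighbors(self, node: str) -> frozenset[str]:
        return self.in_adj.get(node, frozenset())

    def out_degree(self, node: str) -> int:
        return len(self.out_adj.get(node, ()))

    def in_degree(self, node: str) -> int:
        return len(self.in_adj.get(node, ()))

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class UndirectedLayer:
    """Simple undirected PPI graph; self-edges are rejected.

    Edges are stored as canonically ordered tuples (smaller identifier
    first).
    """

    edges: frozenset[EdgeTuple]

    @classmethod
    def from_edges(cls, edges: Iterable[Sequence[str]]) -> "UndirectedLayer":
        dedup: set[EdgeTuple] = set()
        for e in edges:
            u, v = str(e[0]), str(e[1])
            if u == v:
                raise ValueError(f"self-edge not allowed in undirected layer: {u!r}")
            dedup.add((u, v) if u < v else (v, u))
        return cls(frozenset(dedup))

    @cached_property
    def nodes(self) -> frozenset[str]:
        return frozenset(x for e in self.edges for x in e)

    @cached_property
    def adj(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for u, v in self.edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        return {u: frozenset(vs) for u, vs in adj.items()}

    def neighbors(self, node: str) -> frozenset[str]:
        return self.adj.get(node, frozenset())

    def degree(self, node: str) -> int:
        return len(self.adj.get(node, ()))

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class BipartiteLayer:
    """Simple bipartite miRNA→gene graph.

    All edges run from a miRNA identifier to a gene identifier; an
    identifier appearing on both sides is a namespace collision and is
    rejected at construction.
    """

    edges: frozenset[EdgeTuple]

    @classmethod
    def from_edges(cls, edges: Iterable[Sequence[str]]) -> "BipartiteLayer":
        dedup = {(str(e[0]), str(e[1])) for e in edges}
        sources = {u for u, _ in dedup}
        targets = {v for _, v in dedup}
        clash = sources & targets
        if clash:
            raise ValueError(
                f"identifier(s) appear on both sides of the bipartite layer: "
                f"{sorted(clash)[:5]}")
        return cls(frozenset(dedup))

    @cached_property
    def mirnas(self) -> frozenset[str]:
        return frozenset(u for u, _ in self.edges)

    @cached_property
    def genes(self) -> frozenset[str]:
        return frozenset(v for _, v in self.edges)

    @cached_property
    def nodes(self) -> frozenset[str]:
        return self.mirnas | self.genes

    @cached_property
    def out_adj(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for m, g in self.edges:
            adj.setdefault(m, set()).add(g)
        return {m: frozenset(gs) for m, gs in adj.items()}

    @cached_property
    def in_adj(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for m, g in self.edges:
            adj.setdefault(g, set()).add(m)
        return {g: frozenset(ms) for g, ms in adj.items()}

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self.out_adj.get(mirna, frozenset())

    def regulators_of(self, gene: str) -> frozenset[str]:
        return self.in_adj.get(gene, frozenset())

    def has_edge(self, m: str, g: str) -> bool:
        return (m, g) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.mirnas, bipartite=0)
        g.add_nodes_from(self.genes, bipartite=1)
        g.add_edges_from(self.edges)
        return g


Layer = DirectedLayer | UndirectedLayer | BipartiteLayer


@dataclass(frozen=True)
class Multilayer:
    """The co-registered triple of regulatory layers."""

    tf: DirectedLayer
    ppi: UndirectedLayer
    mirna: BipartiteLayer

    def replace(self, **kwargs) -> "Multilayer":
        parts = {"tf": self.tf, "ppi": self.ppi, "mirna": self.mirna}
        parts.update(kwargs)
        return Multilayer(**parts)

    def genes(self) -> frozenset[str]:
        """Gene identifiers across layers (miRNAs excluded)."""
        return self.tf.nodes | self.ppi.nodes | self.mirna.genes


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_layer(path, layer_kind: str) -> Layer:
    """Load a TSV edge list (two identifier columns, header line, ``#``
    comments, optional gzip) as a validated layer."""
    if layer_kind not in LAYER_KINDS:
        raise ValueError(f"unknown layer kind {layer_kind!r}; expected one of {LAYER_KINDS}")
    rows: list[EdgeTuple] = []
    with _open_text(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed edge row at line {lineno}: {line!r}")
            rows.append((parts[0], parts[1]))
    if layer_kind == "directed":
        return DirectedLayer.from_edges(rows)
    if layer_kind == "undirected":
        return UndirectedLayer.from_edges(rows)
    return BipartiteLayer.from_edges(rows)


def write_layer(layer: Layer, path, columns: tuple[str, str] = ("source", "target")) -> None:
    """Write a layer back as a two-column TSV edge list."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for u, v in sorted(layer.edges):
            fh.write(f"{u}\t{v}\n")


@dataclass
class DegreeSummary:
    """Per-gene-class empirical degree distributions of one layer.

    ``distributions`` maps (class_label, degree_type) to a Counter of
    degree → number of nodes; degree_type is ``k_in``/``k_out`` for
    directed and bipartite layers, ``k`` for the undirected layer.
    """

    layer_kind: str
    distributions: dict[tuple[str, str], Counter] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"class": cls, "degree_type": dtype, "degree": deg, "count": cnt}
            for (cls, dtype), counter in sorted(self.distributions.items())
            for deg, cnt in sorted(counter.items())
        ]
        return pd.DataFrame(rows, columns=["class", "degree_type", "degree", "count"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def degree_summary(layer: Layer, catalog: GenePairCatalog) -> DegreeSummary:
    """Degree distributions of the whole layer and of WGD / SSD member genes.

    The ALL class covers every node of the layer (for the bipartite layer,
    miRNA out-degrees and gene in-degrees are reported separately); the WGD
    and SSD classes cover the genes participating in at least one pair of
    that class that are present in the layer.  Gene-level classes may
    overlap — pair classes are disjoint, gene membership is not.
    """
    classes: dict[str, set[str] | None] = {
        "ALL": None,
        WGD: catalog.genes_in_class(WGD),
        SSD: catalog.genes_in_class(SSD),
    }
    out = DegreeSummary(layer_kind=type(layer).__name__)

    def collect(nodes: Iterable[str], dtype: str, degfun) -> Counter:
        return Counter(degfun(n) for n in nodes)

    if isinstance(layer, DirectedLayer):
        for cls, members in classes.items():
            nodes = layer.nodes if members is None else layer.nodes & members
            out.distributions[(cls, "k_in")] = collect(nodes, "k_in", layer.in_degree)
            out.distributions[(cls, "k_out")] = collect(nodes, "k_out", layer.out_degree)
    elif isinstance(layer, UndirectedLayer):
        for cls, members in classes.items():
            nodes = layer.nodes if members is None else layer.nodes & members
            out.distributions[(cls, "k")] = collect(nodes, "k", layer.degree)
    elif isinstance(layer, BipartiteLayer):
        # miRNAs are not genes: only the ALL class sees their out-degrees
        out.distributions[("ALL", "k_out")] = collect(
            layer.mirnas, "k_out", lambda m: len(layer.targets_of(m)))
        for cls, members in classes.items():
            genes = layer.genes if members is None else layer.genes & members
            out.distributions[(cls, "k_in")] = collect(
                genes, "k_in", lambda g: len(layer.regulators_of(g)))
    else:  # pragma: no cover
        raise TypeError(f"unknown layer type {type(layer)!r}")
    return out
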