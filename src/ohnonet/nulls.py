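"""Degree-preserving randomization of the network layers.

The null model for motif enrichment is the classic double-edge-swap Markov
chain: two edges are drawn at random and their endpoints exchanged, which
destroys local topology while keeping every node's (in/out, or per-side
bipartite) degree exactly fixed.  Swaps that would create a parallel edge or
a new self-loop are rejected and count toward the attempt budget, the
uniform-sampling convention of the swap-chain algorithm.  Existing directed
self-loops are frozen: they are never selected for swapping and survive
untouched, so self-regulation is neither inflated nor destroyed by the
randomization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .layers import BipartiteLayer, DirectedLayer, Layer, Multilayer, UndirectedLayer, write_layer

logger = logging.getLogger(__name__)

DEFAULT_N_REALIZATIONS = 100
DEFAULT_SWAPS_PER_EDGE = 10.0

RANDOMIZABLE = ("tf", "ppi", "mirna")


def _n_attempts(n_swaps_per_edge: float, n_edges: int) -> int:
    return math.ceil(n_swaps_per_edge * n_edges)


def rewire_directed(layer: DirectedLayer, n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
                    seed: int | np.random.Generator = 0) -> DirectedLayer:
    """Degree-preserving rewiring of a digraph.

    Picks two swappable (non-self-loop) edges (a,b), (c,d) and proposes
    (a,d), (c,b); the proposal is rejected when it would introduce a
    self-loop or an edge already present.  In- and out-degrees of every node
    are preserved exactly.
    """
    if n_swaps_per_edge <= 0:
        raise ValueError("n_swaps_per_edge must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edge_set = set(layer.edges)
    swappable = sorted(e for e in edge_set if e[0] != e[1])
    m = len(swappable)
    if m < 2:
        logger.warning("directed layer has %d swappable edges; returned unchanged", m)
        return layer
    attempts = _n_attempts(n_swaps_per_edge, len(layer.edges))
    idx = rng.integers(0, m, size=(attempts, 2))
    for i, j in idx:
        if i == j:
            continue
        a, b = swappable[i]
        c, d = swappable[j]
        if a == d or c == b:
            continue
        new1, new2 = (a, d), (c, b)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add(new1)
        edge_set.add(new2)
        swappable[i] = new1
        swappable[j] = new2
    return DirectedLayer(frozenset(edge_set))


def rewire_undirected(layer: UndirectedLayer, n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
                      seed: int | np.random.Generator = 0) -> UndirectedLayer:
    """Degree-preserving rewiring of an undirected simple graph.

    For edges {a,b}, {c,d} on four distinct nodes, one of the two swap
    orientations {a,c}+{b,d} or {a,d}+{b,c} is chosen uniformly; proposals
    creating multi-edges are rejected.
    """
    if n_swaps_per_edge <= 0:
        raise ValueError("n_swaps_per_edge must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edge_set = set(layer.edges)  # canonical (u < v) tuples
    edges = sorted(edge_set)
    m = len(edges)
    if m < 2:
        logger.warning("undirected layer has %d edges; returned unchanged", m)
        return layer
    attempts = _n_attempts(n_swaps_per_edge, m)
    idx = rng.integers(0, m, size=(attempts, 2))
    orient = rng.integers(0, 2, size=attempts)
    for (i, j), o in zip(idx, orient):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if o == 0:
            p1, p2 = (a, c), (b, d)
        else:
            p1, p2 = (a, d), (b, c)
        p1 = p1 if p1[0] < p1[1] else (p1[1], p1[0])
        p2 = p2 if p2[0] < p2[1] else (p2[1], p2[0])
        if p1 in edge_set or p2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(p1)
        edge_set.add(p2)
        edges[i] = p1
        edges[j] = p2
    return UndirectedLayer(frozenset(edge_set))


def rewire_bipartite(layer: BipartiteLayer, n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
                     seed: int | np.random.Generator = 0) -> BipartiteLayer:
    """Degree-preserving rewiring of the miRNA→gene layer.

    The gene ends of two edges are exchanged: (m1,g1), (m2,g2) becomes
    (m1,g2), (m2,g1).  miRNA out-degrees and gene in-degrees are preserved;
    bipartiteness holds by construction.
    """
    if n_swaps_per_edge <= 0:
        raise ValueError("n_swaps_per_edge must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edge_set = set(layer.edges)
    edges = sorted(edge_set)
    m = len(edges)
    if m < 2:
        logger.warning("bipartite layer has %d edges; returned unchanged", m)
        return layer
    attempts = _n_attempts(n_swaps_per_edge, m)
    idx = rng.integers(0, m, size=(attempts, 2))
    for i, j in idx:
        if i == j:
            continue
        m1, g1 = edges[i]
        m2, g2 = edges[j]
        new1, new2 = (m1, g2), (m2, g1)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = new1
        edges[j] = new2
    return BipartiteLayer(frozenset(edge_set))


def rewire_layer(layer: Layer, n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
                 seed: int | np.random.Generator = 0) -> Layer:
    """Dispatch to the rewiring routine matching the layer type."""
    if isinstance(layer, DirectedLayer):
        return rewire_directed(layer, n_swaps_per_edge, seed)
    if isinstance(layer, UndirectedLayer):
        return rewire_undirected(layer, n_swaps_per_edge, seed)
    if isinstance(layer, BipartiteLayer):
        return rewire_bipartite(layer, n_swaps_per_edge, seed)
    raise TypeError(f"cannot rewire object of type {type(layer)!r}")


@dataclass
class NullEnsemble:
    """An ordered ensemble of degree-preserving layer randomizations.

    Each realization is a full :class:`Multilayer` in which exactly one
    layer (``randomized_layer_kind``) has been rewired with its own seed
    (``base_seed + i``) while the other layers are passed through untouched.
    """

    realizations: list[Multilayer]
    randomized_layer_kind: str
    base_seed: int
    n_swaps_per_edge: float

    def __len__(self) -> int:
        return len(self.realizations)

    def __iter__(self) -> Iterator[Multilayer]:
        return iter(self.realizations)

    def randomized_layers(self) -> Iterator[Layer]:
        for r in self.realizations:
            yield getattr(r, self.randomized_layer_kind)

    def dump(self, directory) -> list[Path]:
        """Write each randomized realization as an edge-list TSV for audit."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, layer in enumerate(self.randomized_layers()):
            p = directory / f"{self.randomized_layer_kind}_realization_{i:03d}.tsv"
            write_layer(layer, p)
            paths.append(p)
        return paths


def build_ensemble(layers: Multilayer, randomize: str,
                   n_realizations: int = DEFAULT_N_REALIZATIONS,
                   base_seed: int = 0,
                   n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE) -> NullEnsemble:
    """Build the null ensemble with one layer randomized per realization.

    Realization ``i`` is rewired with seed ``base_seed + i``; the same base
    seed therefore reproduces the ensemble bit-for-bit.
    """
    if randomize not in RANDOMIZABLE:
        raise ValueError(f"randomize must be one of {RANDOMIZABLE}, got {randomize!r}")
    source = getattr(layers, randomize)
    realizations = []
    for i in range(n_realizations):
        rewired = rewire_layer(source, n_swaps_per_edge, seed=base_seed + i)
        realizations.append(layers.replace(**{randomize: rewired}))
    return NullEnsemble(realizations, randomize, base_seed, n_swaps_per_edge)
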