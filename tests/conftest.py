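import numpy as np
import pytest

from ohnonet import (BipartiteLayer, DirectedLayer, GenePairCatalog, GenePair,
                     Multilayer, UndirectedLayer)


@pytest.fixture
def star_tf():
    """One TF regulating five targets."""
    return DirectedLayer.from_edges([("T", f"G{i}") for i in range(1, 6)])


@pytest.fixture
def small_multilayer():
    tf = DirectedLayer.from_edges([
        ("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B"), ("T1", "T1"),
        ("A", "C"), ("B", "C"), ("A", "B"),
    ])
    ppi = UndirectedLayer.from_edges([("A", "B"), ("A", "W"), ("B", "W"), ("C", "W")])
    mirna = BipartiteLayer.from_edges([("m1", "A"), ("m1", "B"), ("m2", "A")])
    return Multilayer(tf, ppi, mirna)


@pytest.fixture
def ab_catalog():
    cat = GenePairCatalog()
    cat.add(GenePair.make("A", "B", "WGD"))
    return cat


def random_multilayer(rng: np.random.Generator, n_genes: int = 12, n_mirnas: int = 3,
                      p: float = 0.25):
    """A dense-ish random multilayer on a small gene set, for oracle tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    tf_edges = [(genes[i], genes[j]) for i in range(n_genes) for j in range(n_genes)
                if rng.random() < p]
    ppi_edges = [(genes[i], genes[j]) for i in range(n_genes) for j in range(i + 1, n_genes)
                 if rng.random() < p]
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    mi_edges = [(m, g) for m in mirnas for g in genes if rng.random() < p]
    return Multilayer(DirectedLayer.from_edges(tf_edges),
                      UndirectedLayer.from_edges(ppi_edges),
                      BipartiteLayer.from_edges(mi_edges))


def random_pairs(rng: np.random.Generator, n_genes: int = 12, n_pairs: int = 6):
    genes = [f"g{i}" for i in range(n_genes)]
    pairs = set()
    while len(pairs) < n_pairs:
        i, j = rng.choice(n_genes, size=2, replace=False)
        a, b = genes[i], genes[j]
        pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)
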