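"""Synthetic three-layer networks with planted WGD and SSD pairs.

A duplication–divergence generator produces co-registered transcriptional,
protein-interaction and miRNA layers with known ground truth, so that every
pipeline stage (classification, motif census, null models, enrichment,
similarity) can be exercised and validated without any external download.

The model: an ancestral genome of ``n_ancestral_genes`` genes (the first
``n_tfs`` of which are transcription factors, optionally self-regulating)
and ``n_mirnas`` miRNAs receives

1. one whole-genome duplication: every gene g gains a copy g′; every
   ancestral edge is copied to all duplicate endpoint combinations and each
   copy is retained independently with the per-layer ``wgd_retention``
   probability.  A TF self-loop g→g therefore spawns the 2×2 edge set
   {g→g, g→g′, g′→g, g′→g′} before retention — the seed of FFL+Bifan
   structures between the duplicated TF pair and any duplicated target
   pair.  Each (g, g′) pair additionally gains a direct protein interaction
   with probability ``wgd_interaction_gain`` and is labelled WGD;
2. ``n_ssd_events`` small-scale duplications: single genes picked uniformly
   are copied with the per-layer ``ssd_retention``; the resulting
   (parent, copy) pairs are labelled SSD, except for a recent tail of
   events (``ssd_young_fraction``) applied after the divergence noise and
   labelled SSD_YOUNG — recency is modelled purely as having experienced
   fewer rewiring rounds;
3. divergence noise: each edge is independently rewired (one endpoint
   resampled uniformly, preserving simplicity) with probability
   ``post_duplication_rewiring``.

miRNAs are never duplicated; their edges participate only through target
duplication.  Every stochastic decision is recorded in an event log that
replays deterministically to the emitted layers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .catalog import SSD, SSD_YOUNG, WGD, GenePair, GenePairCatalog
from .layers import BipartiteLayer, DirectedLayer, Multilayer, UndirectedLayer, write_layer

LAYER_KEYS = ("tf", "ppi", "mirna")


def _per_layer(value: float | Mapping[str, float], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {k: float(value.get(k, 0.0)) for k in LAYER_KEYS}
    else:
        out = {k: float(value) for k in LAYER_KEYS}
    for k, v in out.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}[{k}] must be a probability, got {v}")
    return out


@dataclass
class SimulationParams:
    """Tunable knobs of the duplication–divergence generator.

    Defaults describe a small synthetic genome: 1000 ancestral genes of
    which 50 are TFs, 30 miRNAs, mean TF out-degree ≈ 20, mean PPI degree
    ≈ 5, mean miRNA out-degree ≈ 20; a strongly-retained WGD (r = 0.8) and
    100 weakly-retained SSD events (r = 0.5) followed by 5% rewiring noise.
    """

    n_ancestral_genes: int = 1000
    n_tfs: int = 50
    n_mirnas: int = 30
    tf_density: float = 0.02       # P(TF → gene) ancestral edge
    ppi_density: float = 0.005     # P(gene – gene) ancestral interaction
    mirna_density: float = 0.02    # P(miRNA → gene) ancestral edge
    p_self_loop: float = 0.3       # P(a TF self-regulates)
    wgd_retention: float | Mapping[str, float] = 0.8
    wgd_interaction_gain: float = 0.2
    n_ssd_events: int = 100
    ssd_retention: float | Mapping[str, float] = 0.5
    ssd_interaction_gain: float = 0.05
    ssd_young_fraction: float = 0.15
    post_duplication_rewiring: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes <= 0 or self.n_mirnas < 0 or self.n_tfs < 0:
            raise ValueError("counts must be positive")
        if self.n_tfs > self.n_ancestral_genes:
            raise ValueError("n_tfs cannot exceed n_ancestral_genes")
        for name in ("tf_density", "ppi_density", "mirna_density", "p_self_loop",
                     "wgd_interaction_gain", "ssd_interaction_gain",
                     "ssd_young_fraction", "post_duplication_rewiring"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_ssd_events < 0:
            raise ValueError("n_ssd_events must be non-negative")
        self.wgd_retention = _per_layer(self.wgd_retention, "wgd_retention")
        self.ssd_retention = _per_layer(self.ssd_retention, "ssd_retention")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wgd_retention"] = dict(self.wgd_retention)
        d["ssd_retention"] = dict(self.ssd_retention)
        return d


@dataclass
class SyntheticTruth:
    """A generated multilayer network with its planted ground truth."""

    layers: Multilayer
    catalog: GenePairCatalog
    event_log: list[dict]
    params: SimulationParams
    ancestral: Multilayer

    def write(self, outdir) -> dict[str, str]:
        """Write layers, catalog and event log as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        for key, cols in (("tf", ("tf", "target")), ("ppi", ("gene_a", "gene_b")),
                          ("mirna", ("mirna", "target"))):
            p = outdir / f"{key}_layer.tsv"
            write_layer(getattr(self.layers, key), p, cols)
            files[key] = str(p)
        cat_path = outdir / "catalog.tsv"
        self.catalog.to_tsv(cat_path)
        files["catalog"] = str(cat_path)
        ev_path = outdir / "events.jsonl"
        with open(ev_path, "w") as fh:
            for ev in self.event_log:
                fh.write(json.dumps(ev) + "\n")
        files["events"] = str(ev_path)
        return files


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _mirna_names(n: int) -> list[str]:
    return [f"mir{i:04d}" for i in range(n)]


def generate_ancestral(params: SimulationParams,
                       rng: np.random.Generator | None = None) -> Multilayer:
    """Random simple layers at the requested densities.

    TF→gene and miRNA→gene edges are independent Bernoulli draws at the
    layer density; TF self-loops are placed separately with ``p_self_loop``.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genes = _gene_names(params.n_ancestral_genes)
    tfs = genes[:params.n_tfs]
    mirnas = _mirna_names(params.n_mirnas)
    n = len(genes)

    tf_edges: set[tuple[str, str]] = set()
    for i, tf in enumerate(tfs):
        mask = rng.random(n) < params.tf_density
        mask[i] = False  # self-loops handled separately
        tf_edges.update((tf, genes[j]) for j in np.flatnonzero(mask))
        if rng.random() < params.p_self_loop:
            tf_edges.add((tf, tf))

    ppi_edges: set[tuple[str, str]] = set()
    for i in range(n - 1):
        mask = rng.random(n - i - 1) < params.ppi_density
        ppi_edges.update((genes[i], genes[i + 1 + j]) for j in np.flatnonzero(mask))

    mirna_edges: set[tuple[str, str]] = set()
    for m in mirnas:
        mask = rng.random(n) < params.mirna_density
        mirna_edges.update((m, genes[j]) for j in np.flatnonzero(mask))

    return Multilayer(DirectedLayer(frozenset(tf_edges)),
                      UndirectedLayer(frozenset(ppi_edges)),
                      BipartiteLayer(frozenset(mirna_edges)))


def _wgd_copy(g: str) -> str:
    return g + "w"


def _und(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


def apply_wgd(layers: Multilayer, params: SimulationParams,
              rng: np.random.Generator) -> tuple[Multilayer, list[GenePair], list[dict]]:
    """Duplicate every gene and retain edge copies per layer.

    Returns the post-WGD layers, the planted WGD pair annotations and the
    event-log entries recording exactly which edge copies were retained.
    """
    genes = sorted(layers.genes())
    r = params.wgd_retention

    def keep(p: float) -> bool:
        return rng.random() < p

    tf_edges: set[tuple[str, str]] = set()
    for u, v in sorted(layers.tf.edges):
        for cand in ((u, v), (u, _wgd_copy(v)), (_wgd_copy(u), v),
                     (_wgd_copy(u), _wgd_copy(v))):
            if keep(r["tf"]):
                tf_edges.add(cand)

    ppi_edges: set[tuple[str, str]] = set()
    for u, v in sorted(layers.ppi.edges):
        for cand in ((u, v), (u, _wgd_copy(v)), (_wgd_copy(u), v),
                     (_wgd_copy(u), _wgd_copy(v))):
            if keep(r["ppi"]):
                ppi_edges.add(_und(*cand))

    mirna_edges: set[tuple[str, str]] = set()
    for m, g in sorted(layers.mirna.edges):
        for cand in ((m, g), (m, _wgd_copy(g))):
            if keep(r["mirna"]):
                mirna_edges.add(cand)

    gained: list[tuple[str, str]] = []
    for g in genes:
        if rng.random() < params.wgd_interaction_gain:
            e = _und(g, _wgd_copy(g))
            ppi_edges.add(e)
            gained.append(e)

    pairs = [GenePair.make(g, _wgd_copy(g), WGD, source="wgd_event") for g in genes]
    event = {
        "type": "wgd",
        "retained": {"tf": sorted(tf_edges), "ppi": sorted(ppi_edges - set(gained)),
                     "mirna": sorted(mirna_edges)},
        "ppi_gain": sorted(gained),
    }
    new_layers = Multilayer(DirectedLayer(frozenset(tf_edges)),
                            UndirectedLayer(frozenset(ppi_edges)),
                            BipartiteLayer(frozenset(mirna_edges)))
    return new_layers, pairs, [event]


def apply_ssd_events(layers: Multilayer, params: SimulationParams,
                     rng: np.random.Generator, n_events: int | None = None,
                     label: str = SSD, copy_suffix: str = "s",
                     ) -> tuple[Multilayer, list[GenePair], list[dict]]:
    """Duplicate ``n_events`` single genes with per-layer retention.

    Each event copies one gene's incident edges to the new copy, retaining
    each independently with ``ssd_retention``; a self-loop g→g spawns the
    g′→g′, g→g′ and g′→g candidates.  A single-gene duplication never
    duplicates the gene's regulator or targets, so one SSD event cannot
    create a bifan between two duplicate pairs by itself.
    """
    if n_events is None:
        n_events = params.n_ssd_events
    genes = sorted(layers.genes())
    r = params.ssd_retention
    tf_edges = set(layers.tf.edges)
    ppi_edges = set(layers.ppi.edges)
    mirna_edges = set(layers.mirna.edges)
    pairs: list[GenePair] = []
    events: list[dict] = []

    chosen_idx = rng.choice(len(genes), size=min(n_events, len(genes)), replace=False)
    for k, gi in enumerate(chosen_idx):
        parent = genes[gi]
        copy = f"{parent}{copy_suffix}{k}"
        retained: dict[str, list] = {"tf": [], "ppi": [], "mirna": []}
        # transcriptional in/out edges, self-loop expanded to all cross copies
        for u, v in sorted(tf_edges):
            if u == parent and v == parent:
                cands = [(copy, copy), (parent, copy), (copy, parent)]
            elif u == parent:
                cands = [(copy, v)]
            elif v == parent:
                cands = [(u, copy)]
            else:
                continue
            for cand in cands:
                if rng.random() < r["tf"]:
                    retained["tf"].append(cand)
        for u, v in sorted(ppi_edges):
            if parent not in (u, v):
                continue
            other = v if u == parent else u
            if rng.random() < r["ppi"]:
                retained["ppi"].append(_und(copy, other))
        for m, g in sorted(mirna_edges):
            if g == parent and rng.random() < r["mirna"]:
                retained["mirna"].append((m, copy))
        gain = rng.random() < params.ssd_interaction_gain
        tf_edges.update(tuple(e) for e in retained["tf"])
        ppi_edges.update(tuple(e) for e in retained["ppi"])
        mirna_edges.update(tuple(e) for e in retained["mirna"])
        if gain:
            ppi_edges.add(_und(parent, copy))
        pairs.append(GenePair.make(parent, copy, label, source="ssd_event"))
        events.append({"type": "ssd", "parent": parent, "copy": copy,
                       "label": label, "retained": {k2: sorted(v2) for k2, v2 in retained.items()},
                       "ppi_gain": gain})

    new_layers = Multilayer(DirectedLayer(frozenset(tf_edges)),
                            UndirectedLayer(frozenset(ppi_edges)),
                            BipartiteLayer(frozenset(mirna_edges)))
    return new_layers, pairs, events


def apply_rewiring(layers: Multilayer, params: SimulationParams,
                   rng: np.random.Generator) -> tuple[Multilayer, list[dict]]:
    """Divergence noise: each edge independently loses one endpoint.

    With probability ``post_duplication_rewiring`` an edge has one endpoint
    resampled uniformly among valid endpoints (layer constraints and
    simplicity respected); a proposal colliding with an existing edge is
    retried a few times and otherwise abandoned.
    """
    q = params.post_duplication_rewiring
    genes = sorted(layers.genes())
    moves: list[dict] = []
    if q == 0.0 or not genes:
        return layers, moves

    def resample(pool, forbidden):
        for _ in range(10):
            cand = pool[rng.integers(0, len(pool))]
            if cand not in forbidden:
                return cand
        return None

    tf_edges = set(layers.tf.edges)
    for u, v in sorted(layers.tf.edges):
        if rng.random() >= q:
            continue
        new_v = resample(genes, {u})
        if new_v is None or (u, new_v) in tf_edges:
            continue
        tf_edges.discard((u, v))
        tf_edges.add((u, new_v))
        moves.append({"type": "rewire", "layer": "tf", "old": [u, v], "new": [u, new_v]})

    ppi_edges = set(layers.ppi.edges)
    for e in sorted(layers.ppi.edges):
        if e not in ppi_edges:  # may have been displaced by an earlier move
            continue
        if rng.random() >= q:
            continue
        keep_idx = rng.integers(0, 2)
        kept, dropped = e[keep_idx], e[1 - keep_idx]
        new_other = resample(genes, {kept})
        if new_other is None:
            continue
        new_e = _und(kept, new_other)
        if new_e in ppi_edges:
            continue
        ppi_edges.discard(e)
        ppi_edges.add(new_e)
        moves.append({"type": "rewire", "layer": "ppi", "old": list(e), "new": list(new_e)})

    mirna_edges = set(layers.mirna.edges)
    for m, g in sorted(layers.mirna.edges):
        if rng.random() >= q:
            continue
        new_g = resample(genes, set())
        if new_g is None or (m, new_g) in mirna_edges:
            continue
        mirna_edges.discard((m, g))
        mirna_edges.add((m, new_g))
        moves.append({"type": "rewire", "layer": "mirna", "old": [m, g], "new": [m, new_g]})

    new_layers = Multilayer(DirectedLayer(frozenset(tf_edges)),
                            UndirectedLayer(frozenset(ppi_edges)),
                            BipartiteLayer(frozenset(mirna_edges)))
    return new_layers, moves


def generate(params: SimulationParams) -> SyntheticTruth:
    """Run the full generator: ancestral → WGD → SSD → rewiring → young SSD.

    Young SSD events are applied after the divergence noise, so their pairs
    have experienced no rewiring — recency as reduced divergence.
    Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    ancestral = generate_ancestral(params, rng)
    n_young = round(params.ssd_young_fraction * params.n_ssd_events)
    n_ancient = params.n_ssd_events - n_young

    layers, wgd_pairs, log = apply_wgd(ancestral, params, rng)
    layers, ssd_pairs, ev = apply_ssd_events(layers, params, rng, n_ancient, SSD, "s")
    log.extend(ev)
    layers, moves = apply_rewiring(layers, params, rng)
    log.extend(moves)
    layers, young_pairs, ev = apply_ssd_events(layers, params, rng, n_young, SSD_YOUNG, "y")
    log.extend(ev)

    catalog = GenePairCatalog(gene_universe=set(layers.genes()))
    for p in wgd_pairs + ssd_pairs + young_pairs:
        catalog.add(p)
    return SyntheticTruth(layers, catalog, log, params, ancestral)


def replay_event_log(ancestral: Multilayer, event_log: Iterable[dict]) -> Multilayer:
    """Reconstruct the emitted layers from the ancestral layers and the log."""
    tf = set(ancestral.tf.edges)
    ppi = set(ancestral.ppi.edges)
    mirna = set(ancestral.mirna.edges)
    for ev in event_log:
        if ev["type"] == "wgd":
            tf = {tuple(e) for e in ev["retained"]["tf"]}
            ppi = {tuple(e) for e in ev["retained"]["ppi"]}
            ppi.update(tuple(e) for e in ev["ppi_gain"])
            mirna = {tuple(e) for e in ev["retained"]["mirna"]}
        elif ev["type"] == "ssd":
            tf.update(tuple(e) for e in ev["retained"]["tf"])
            ppi.update(tuple(e) for e in ev["retained"]["ppi"])
            mirna.update(tuple(e) for e in ev["retained"]["mirna"])
            if ev["ppi_gain"]:
                ppi.add(_und(ev["parent"], ev["copy"]))
        elif ev["type"] == "rewire":
            target = {"tf": tf, "ppi": ppi, "mirna": mirna}[ev["layer"]]
            target.discard(tuple(ev["old"]))
            target.add(tuple(ev["new"]))
        else:  # pragma: no cover
            raise ValueError(f"unknown event type {ev['type']!r}")
    return Multilayer(DirectedLayer(frozenset(tf)),
                      UndirectedLayer(frozenset(ppi)),
                      BipartiteLayer(frozenset(mirna)))
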