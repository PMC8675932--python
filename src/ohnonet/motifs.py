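"""Census of duplication-related network motifs over annotated gene pairs.

Motifs are counted per distinct node-tuple instance (pair × third node ×
…), the convention under which edge-swap null-model Z-scores are computed;
per-pair indicator counting (does this pair participate at all?) is exposed
through the ``denominator``/fraction bookkeeping of ``count_pair_ppi``.

Taxonomy (a, b denote the two genes of a duplicate pair):

========================  =====================================================
pair_ppi                  direct protein interaction a–b
co_interaction            third protein w with a–w and b–w
V                         duplicate TFs a, b sharing a target g (a→g, b→g)
lambda_tf / lambda_mirna  common regulator r with r→a and r→b
delta_tf / delta_mirna    lambda instance whose pair also interacts: a–b ∈ PPI
ffl                       a→b plus common target g (a→g, b→g); both orientations
bifan                     duplicate TF pair regulating a duplicate target pair
                          (all four cross edges), no TF–TF regulation
ffl_bifan                 bifan edge set plus at least one TF–TF regulation
mixed_bifan               common TF and common miRNA regulating the pair
mixed_bifan_ppi           mixed_bifan whose pair also interacts at PPI level
========================  =====================================================

Self-loops never count as motif edges in three-or-more-node motifs; they are
consumed only by :func:`classify_fbl_selfloops`, the small-topology
categorization of TF pairs (self-regulation and mutual/feedback regulation).

Monotonicity caveat: adding an edge never decreases the count of motifs with
monotone predicates (V, Λ, Δ, FFL, co-interaction, mixed bifans), but the
plain bifan is *non-monotone* — adding a regulation between the two TFs
migrates the instance into the ffl_bifan class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import PairTuple, canonical_pair, canonicalize_pairs
from .layers import BipartiteLayer, DirectedLayer, Multilayer, UndirectedLayer

MOTIF_NAMES = (
    "pair_ppi", "co_interaction", "V", "lambda_tf", "lambda_mirna",
    "delta_tf", "delta_mirna", "ffl", "bifan", "ffl_bifan",
    "mixed_bifan", "mixed_bifan_ppi",
)

FBL_CATEGORIES = (
    "none", "one_self", "both_self",
    "one_way", "one_way_self_regulator", "one_way_self_target", "one_way_both_self",
    "fbl", "fbl_one_self", "fbl_both_self",
)


@dataclass
class MotifCount:
    """Observed motif statistics for one pair class on one layer set."""

    motif_name: str
    pair_class: str
    count: int
    denominator: int
    instance_log: list[tuple] | None = field(default=None, repr=False)

    @property
    def fraction(self) -> float | None:
        if self.denominator <= 0:
            return None
        return self.count / self.denominator


def _pairs(pairs: Iterable[Sequence[str]]) -> list[PairTuple]:
    return sorted(canonicalize_pairs(pairs))


def count_pair_ppi(ppi: UndirectedLayer, pairs: Iterable[Sequence[str]],
                   pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Pairs with a direct protein–protein interaction.

    The count is per pair (an indicator, not an instance count); the
    denominator is the number of pairs with both genes present in the PPI
    network, so ``fraction`` is the percentage-style statistic reported for
    pair-level interaction rates.
    """
    plist = _pairs(pairs)
    nodes = ppi.nodes
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in plist:
        if a in nodes and b in nodes:
            denom += 1
            if ppi.has_edge(a, b):
                count += 1
                if log is not None:
                    log.append((a, b))
    return MotifCount("pair_ppi", pair_class, count, denom, log)


def count_co_interaction(ppi: UndirectedLayer, pairs: Iterable[Sequence[str]],
                         pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Instances (pair, w) with a–w and b–w in the PPI layer, w ∉ {a, b}.

    A direct a–b interaction is neither required nor forbidden.
    """
    plist = _pairs(pairs)
    nodes = ppi.nodes
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in plist:
        if a in nodes and b in nodes:
            denom += 1
            third = (ppi.neighbors(a) & ppi.neighbors(b)) - {a, b}
            count += len(third)
            if log is not None:
                log.extend((a, b, w) for w in sorted(third))
    return MotifCount("co_interaction", pair_class, count, denom, log)


def count_v_motifs(tf_layer: DirectedLayer, tf_pairs: Iterable[Sequence[str]],
                   pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Instances (pair, g) where both duplicate TFs regulate g: a→g, b→g.

    Eligibility (the denominator) is restricted to pairs whose two members
    are both regulators in the layer; shared targets equal to either pair
    member are excluded, so self-loops and within-pair regulations never
    count.
    """
    plist = _pairs(pairs=tf_pairs)
    regs = tf_layer.regulators
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in plist:
        if a in regs and b in regs:
            denom += 1
            shared = (tf_layer.out_neighbors(a) & tf_layer.out_neighbors(b)) - {a, b}
            count += len(shared)
            if log is not None:
                log.extend((a, b, g) for g in sorted(shared))
    return MotifCount("V", pair_class, count, denom, log)


def count_lambda_motifs(reg_layer: DirectedLayer | BipartiteLayer,
                        target_pairs: Iterable[Sequence[str]],
                        pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Instances (pair, r) where a common regulator targets both genes.

    ``reg_layer`` may be the transcriptional digraph (r is a TF) or the
    bipartite miRNA layer (r is a miRNA).  The regulator must differ from
    both pair members.  Eligible pairs have both genes present in the layer.
    """
    plist = _pairs(target_pairs)
    if isinstance(reg_layer, DirectedLayer):
        present = reg_layer.nodes
        in_of = reg_layer.in_neighbors
        name = "lambda_tf"
    elif isinstance(reg_layer, BipartiteLayer):
        present = reg_layer.genes
        in_of = reg_layer.regulators_of
        name = "lambda_mirna"
    else:
        raise TypeError("lambda motifs need a directed or bipartite layer")
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in plist:
        if a in present and b in present:
            denom += 1
            common = (in_of(a) & in_of(b)) - {a, b}
            count += len(common)
            if log is not None:
                log.extend((a, b, r) for r in sorted(common))
    return MotifCount(name, pair_class, count, denom, log)


def count_delta_motifs(reg_layer: DirectedLayer | BipartiteLayer,
                       ppi: UndirectedLayer,
                       target_pairs: Iterable[Sequence[str]],
                       pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Λ instances whose target pair also shares a PPI edge (Δ motif).

    Eligible pairs have both genes in the regulatory layer and in the PPI
    network.
    """
    plist = _pairs(target_pairs)
    if isinstance(reg_layer, DirectedLayer):
        present = reg_layer.nodes
        in_of = reg_layer.in_neighbors
        name = "delta_tf"
    elif isinstance(reg_layer, BipartiteLayer):
        present = reg_layer.genes
        in_of = reg_layer.regulators_of
        name = "delta_mirna"
    else:
        raise TypeError("delta motifs need a directed or bipartite layer")
    pnodes = ppi.nodes
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in plist:
        if a in present and b in present and a in pnodes and b in pnodes:
            denom += 1
            if not ppi.has_edge(a, b):
                continue
            common = (in_of(a) & in_of(b)) - {a, b}
            count += len(common)
            if log is not None:
                log.extend((a, b, r) for r in sorted(common))
    return MotifCount(name, pair_class, count, denom, log)


def classify_fbl_selfloops(tf_layer: DirectedLayer,
                           tf_pairs: Iterable[Sequence[str]]) -> dict[str, list[PairTuple]]:
    """Categorize TF pairs by their self-loop / mutual-regulation topology.

    Every pair lands in exactly one category.  ``fbl`` means mutual
    regulation a↔b (a two-node feedback loop), refined by how many of the
    two genes also self-regulate; ``one_way`` variants distinguish whether
    the self-loop sits on the regulating or the regulated gene.
    """
    out: dict[str, list[PairTuple]] = {c: [] for c in FBL_CATEGORIES}
    for a, b in _pairs(tf_pairs):
        sa = tf_layer.has_edge(a, a)
        sb = tf_layer.has_edge(b, b)
        ab = tf_layer.has_edge(a, b)
        ba = tf_layer.has_edge(b, a)
        nself = int(sa) + int(sb)
        if ab and ba:
            cat = ("fbl", "fbl_one_self", "fbl_both_self")[nself]
        elif ab or ba:
            if nself == 0:
                cat = "one_way"
            elif nself == 2:
                cat = "one_way_both_self"
            else:
                self_on_regulator = (ab and sa) or (ba and sb)
                cat = "one_way_self_regulator" if self_on_regulator else "one_way_self_target"
        else:
            cat = ("none", "one_self", "both_self")[nself]
        out[cat].append((a, b))
    return out


def count_ffl(tf_layer: DirectedLayer, tf_pairs: Iterable[Sequence[str]],
              pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Feed-forward loops within a duplicate TF pair: a→b, a→g, b→g.

    Counted per ordered instance (regulating orientation × common target);
    if both a→b and b→a are present, both orientations are tested.  The
    common target g must differ from both pair members, so self-loops play
    no role.  Eligibility mirrors V motifs: both members must be regulators.
    """
    plist = _pairs(tf_pairs)
    regs = tf_layer.regulators
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in plist:
        if a in regs and b in regs:
            denom += 1
            shared = (tf_layer.out_neighbors(a) & tf_layer.out_neighbors(b)) - {a, b}
            for src, dst in ((a, b), (b, a)):
                if tf_layer.has_edge(src, dst):
                    count += len(shared)
                    if log is not None:
                        log.extend((src, dst, g) for g in sorted(shared))
    return MotifCount("ffl", pair_class, count, denom, log)


def _same_class_pair_sets(regulator_pairs, target_pairs):
    return _pairs(regulator_pairs), set(_pairs(target_pairs))


def _bifan_like(tf_layer: DirectedLayer, regulator_pairs, target_pairs,
                want_tf_tf_edge: bool, name: str, pair_class: str,
                log_instances: bool) -> MotifCount:
    reg_list, target_set = _same_class_pair_sets(regulator_pairs, target_pairs)
    regs = tf_layer.regulators
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    for a, b in reg_list:
        if not (a in regs and b in regs):
            continue
        denom += 1
        has_internal = tf_layer.has_edge(a, b) or tf_layer.has_edge(b, a)
        if has_internal != want_tf_tf_edge:
            continue
        common = (tf_layer.out_neighbors(a) & tf_layer.out_neighbors(b)) - {a, b}
        if len(common) < 2:
            continue
        for c, d in itertools.combinations(sorted(common), 2):
            if (c, d) not in target_set:
                continue
            if (c, d) == (a, b):  # cannot happen (targets exclude a, b) but explicit
                continue
            count += 1
            if log is not None:
                log.append((a, b, c, d))
    return MotifCount(name, pair_class, count, denom, log)


def count_bifan(tf_layer: DirectedLayer, regulator_pairs: Iterable[Sequence[str]],
                target_pairs: Iterable[Sequence[str]],
                pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Bifans built from two duplicate pairs of the same class.

    An instance is a regulator pair (a,b) and a *different* target pair
    (c,d), all four cross regulations a→c, a→d, b→c, b→d present, no
    regulation in either direction between a and b, and the two pairs
    sharing no gene.  Adding a TF–TF regulation migrates the instance to the
    ffl_bifan class, which makes this count non-monotone in the edge set.
    """
    return _bifan_like(tf_layer, regulator_pairs, target_pairs, False,
                       "bifan", pair_class, log_instances)


def count_ffl_bifan(tf_layer: DirectedLayer, regulator_pairs: Iterable[Sequence[str]],
                    target_pairs: Iterable[Sequence[str]],
                    pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Bifan edge set plus at least one TF–TF regulation (multi-output FFL).

    Counted once per (regulator pair, target pair) combination regardless of
    whether one or both internal regulations are present.
    """
    return _bifan_like(tf_layer, regulator_pairs, target_pairs, True,
                       "ffl_bifan", pair_class, log_instances)


def count_mixed_bifan(tf_layer: DirectedLayer, mirna_layer: BipartiteLayer,
                      target_pairs: Iterable[Sequence[str]],
                      require_ppi: bool = False, ppi: UndirectedLayer | None = None,
                      pair_class: str = "ALL", log_instances: bool = False) -> MotifCount:
    """Instances (pair, t, m): TF t and miRNA m each regulate both genes.

    With ``require_ppi`` the pair must additionally interact at the protein
    level.  The instance count for a pair is the product of its common-TF
    and common-miRNA counts.
    """
    if require_ppi and ppi is None:
        raise ValueError("require_ppi=True needs the ppi layer")
    plist = _pairs(target_pairs)
    tf_nodes = tf_layer.nodes
    mi_genes = mirna_layer.genes
    count = 0
    denom = 0
    log: list[tuple] | None = [] if log_instances else None
    name = "mixed_bifan_ppi" if require_ppi else "mixed_bifan"
    for a, b in plist:
        if not (a in tf_nodes and b in tf_nodes and a in mi_genes and b in mi_genes):
            continue
        if require_ppi and not (a in ppi.nodes and b in ppi.nodes):
            continue
        denom += 1
        if require_ppi and not ppi.has_edge(a, b):
            continue
        tfs = (tf_layer.in_neighbors(a) & tf_layer.in_neighbors(b)) - {a, b}
        mirs = mirna_layer.regulators_of(a) & mirna_layer.regulators_of(b)
        count += len(tfs) * len(mirs)
        if log is not None:
            log.extend((a, b, t, m) for t in sorted(tfs) for m in sorted(mirs))
    return MotifCount(name, pair_class, count, denom, log)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_BRUTE_GUARD = 500


def brute_force_census(layers: Multilayer, pairs: Iterable[Sequence[str]],
                       motif_name: str, pair_class: str = "ALL",
                       target_pairs: Iterable[Sequence[str]] | None = None) -> MotifCount:
    """Count a motif by exhaustive enumeration over node tuples.

    A deliberately naive, independent code path used as a testing oracle for
    the optimized counting functions: membership tests go straight against
    the raw edge sets, candidate third nodes / regulators / targets are
    enumerated over entire node sets, and bifan-style motifs loop over all
    combinations of pair couples.  Guarded to 500 total nodes.

    For ``bifan``/``ffl_bifan``, ``pairs`` is the regulator pair list and
    ``target_pairs`` the target pair list (defaults to the same list).
    """
    n_nodes = len(layers.tf.nodes | layers.ppi.nodes | layers.mirna.nodes)
    if n_nodes > _BRUTE_GUARD:
        raise ValueError(f"brute-force census guarded to {_BRUTE_GUARD} nodes, got {n_nodes}")
    plist = _pairs(pairs)
    tset = set(_pairs(target_pairs)) if target_pairs is not None else set(plist)
    tf_edges = layers.tf.edges
    ppi_edges = layers.ppi.edges
    mi_edges = layers.mirna.edges
    tf_nodes = sorted(layers.tf.nodes)
    ppi_nodes = sorted(layers.ppi.nodes)
    mirnas = sorted(layers.mirna.mirnas)
    mi_genes = layers.mirna.genes

    def und(u, v):
        return ((u, v) if u < v else (v, u)) in ppi_edges

    count = 0
    denom = 0

    if motif_name == "pair_ppi":
        for a, b in plist:
            if a in layers.ppi.nodes and b in layers.ppi.nodes:
                denom += 1
                count += int(und(a, b))
    elif motif_name == "co_interaction":
        for a, b in plist:
            if a in layers.ppi.nodes and b in layers.ppi.nodes:
                denom += 1
                for w in ppi_nodes:
                    if w not in (a, b) and und(a, w) and und(b, w):
                        count += 1
    elif motif_name == "V":
        regulators = {u for u, _ in tf_edges}
        for a, b in plist:
            if a in regulators and b in regulators:
                denom += 1
                for g in tf_nodes:
                    if g not in (a, b) and (a, g) in tf_edges and (b, g) in tf_edges:
                        count += 1
    elif motif_name in ("lambda_tf", "delta_tf"):
        for a, b in plist:
            if a in layers.tf.nodes and b in layers.tf.nodes:
                if motif_name == "delta_tf":
                    if not (a in layers.ppi.nodes and b in layers.ppi.nodes):
                        continue
                    denom += 1
                    if not und(a, b):
                        continue
                else:
                    denom += 1
                for r in tf_nodes:
                    if r not in (a, b) and (r, a) in tf_edges and (r, b) in tf_edges:
                        count += 1
    elif motif_name in ("lambda_mirna", "delta_mirna"):
        for a, b in plist:
            if a in mi_genes and b in mi_genes:
                if motif_name == "delta_mirna":
                    if not (a in layers.ppi.nodes and b in layers.ppi.nodes):
                        continue
                    denom += 1
                    if not und(a, b):
                        continue
                else:
                    denom += 1
                for m in mirnas:
                    if (m, a) in mi_edges and (m, b) in mi_edges:
                        count += 1
    elif motif_name == "ffl":
        regulators = {u for u, _ in tf_edges}
        for a, b in plist:
            if a in regulators and b in regulators:
                denom += 1
                for src, dst in ((a, b), (b, a)):
                    if (src, dst) in tf_edges:
                        for g in tf_nodes:
                            if g not in (a, b) and (src, g) in tf_edges and (dst, g) in tf_edges:
                                count += 1
    elif motif_name in ("bifan", "ffl_bifan"):
        regulators = {u for u, _ in tf_edges}
        want_internal = motif_name == "ffl_bifan"
        for a, b in plist:
            if not (a in regulators and b in regulators):
                continue
            denom += 1
            internal = (a, b) in tf_edges or (b, a) in tf_edges
            if internal != want_internal:
                continue
            for c, d in sorted(tset):
                if {c, d} & {a, b}:
                    continue
                if all(e in tf_edges for e in ((a, c), (a, d), (b, c), (b, d))):
                    count += 1
    elif motif_name in ("mixed_bifan", "mixed_bifan_ppi"):
        need_ppi = motif_name == "mixed_bifan_ppi"
        for a, b in plist:
            if not (a in layers.tf.nodes and b in layers.tf.nodes
                    and a in mi_genes and b in mi_genes):
                continue
            if need_ppi and not (a in layers.ppi.nodes and b in layers.ppi.nodes):
                continue
            denom += 1
            if need_ppi and not und(a, b):
                continue
            for t in tf_nodes:
                if t in (a, b) or (t, a) not in tf_edges or (t, b) not in tf_edges:
                    continue
                for m in mirnas:
                    if (m, a) in mi_edges and (m, b) in mi_edges:
                        count += 1
    else:
        raise ValueError(f"unknown motif {motif_name!r}")
    return MotifCount(motif_name, pair_class, count, denom)


def count_motif(motif_name: str, layers: Multilayer, pairs: Iterable[Sequence[str]],
                pair_class: str = "ALL",
                target_pairs: Iterable[Sequence[str]] | None = None) -> MotifCount:
    """Uniform dispatcher over the optimized counting functions."""
    if motif_name == "pair_ppi":
        return count_pair_ppi(layers.ppi, pairs, pair_class)
    if motif_name == "co_interaction":
        return count_co_interaction(layers.ppi, pairs, pair_class)
    if motif_name == "V":
        return count_v_motifs(layers.tf, pairs, pair_class)
    if motif_name == "lambda_tf":
        return count_lambda_motifs(layers.tf, pairs, pair_class)
    if motif_name == "lambda_mirna":
        return count_lambda_motifs(layers.mirna, pairs, pair_class)
    if motif_name == "delta_tf":
        return count_delta_motifs(layers.tf, layers.ppi, pairs, pair_class)
    if motif_name == "delta_mirna":
        return count_delta_motifs(layers.mirna, layers.ppi, pairs, pair_class)
    if motif_name == "ffl":
        return count_ffl(layers.tf, pairs, pair_class)
    if motif_name == "bifan":
        return count_bifan(layers.tf, pairs,
                           pairs if target_pairs is None else target_pairs, pair_class)
    if motif_name == "ffl_bifan":
        return count_ffl_bifan(layers.tf, pairs,
                               pairs if target_pairs is None else target_pairs, pair_class)
    if motif_name == "mixed_bifan":
        return count_mixed_bifan(layers.tf, layers.mirna, pairs, False, None, pair_class)
    if motif_name == "mixed_bifan_ppi":
        return count_mixed_bifan(layers.tf, layers.mirna, pairs, True, layers.ppi, pair_class)
    raise ValueError(f"unknown motif {motif_name!r}")
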