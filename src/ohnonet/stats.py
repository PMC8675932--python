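"""Enrichment Z-scores, Sørensen–Dice similarity, and distribution tests.

Motif enrichment follows the standard null-ensemble convention:
``Z = (n − n̄_null) / σ_null`` where n is the observed motif count and the
null mean/SD are taken over the degree-preserving randomized ensemble
(population SD, 1/N — the ensemble is the entire null sample of interest).
|Z| ≳ 5 is conventionally treated as significant.

Interaction similarity between the two genes of a pair uses the
Sørensen–Dice coefficient S(A,B) = 2|A∩B| / (|A|+|B|) over their neighbor
sets (regulators, targets or PPI partners).  The partner gene is removed
from both sets before scoring, so a direct a→b regulation or a–b
interaction is never counted as a "shared" neighbor.  Pairs whose two
effective sets are both empty carry no similarity information and are
excluded, with the exclusion count surfaced, because zero-inflation drives
these distributions.

Distribution comparisons use the two-tailed Mann–Whitney U test at the
P < 0.01 level, with plot symbols ``*`` (SSD vs WGD), ``■`` (WGD vs
non-duplicated) and ``▲`` (SSD vs non-duplicated).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .catalog import NOT_DUP, SSD, WGD, PairTuple, canonicalize_pairs
from .layers import BipartiteLayer, DirectedLayer, Layer, UndirectedLayer
from .nulls import NullEnsemble

Z_SIGNIFICANCE = 5.0
P_THRESHOLD = 0.01

INTERACTION_ROLES = ("ppi-partners", "targets", "regulators-TF", "regulators-miRNA")

#: class-pairing → figure symbol for significant comparisons
COMPARISON_SYMBOLS: dict[frozenset, str] = {
    frozenset({SSD, WGD}): "*",
    frozenset({WGD, NOT_DUP}): "■",   # ■
    frozenset({SSD, NOT_DUP}): "▲",   # ▲
}


@dataclass
class EnrichmentResult:
    """Observed count against its null ensemble for one motif and class."""

    motif_name: str
    pair_class: str
    observed: float
    null_counts: list[float] = field(repr=False)
    null_mean: float
    null_sd: float
    z: float | None
    randomized_layer: str = ""
    is_headline: bool = True

    @property
    def significant(self) -> bool:
        return self.z is not None and abs(self.z) >= Z_SIGNIFICANCE


def z_score(observed: float, null_counts: Sequence[float], *,
            motif_name: str = "", pair_class: str = "ALL",
            randomized_layer: str = "", is_headline: bool = True) -> EnrichmentResult:
    """Z-score of an observed count against the null-count sample.

    The null SD uses the population (1/N) convention.  A degenerate null
    (σ = 0) never enters infinite arithmetic: when the constant null equals
    the observation there is no deviation and z = 0; otherwise the z-score
    is undefined and reported as the ``None`` sentinel.
    """
    counts = np.asarray(list(null_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("null_counts must be nonempty")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    z: float | None
    if sd > 0.0:
        z = (float(observed) - mean) / sd
    elif float(observed) == mean:
        z = 0.0
    else:
        z = None
    return EnrichmentResult(motif_name, pair_class, float(observed), counts.tolist(),
                            mean, sd, z, randomized_layer, is_headline)


def dice_similarity(set_a: Iterable, set_b: Iterable) -> float | None:
    """Sørensen–Dice coefficient 2|A∩B|/(|A|+|B|); None when both sets empty."""
    a = set(set_a)
    b = set(set_b)
    tot = len(a) + len(b)
    if tot == 0:
        return None
    return 2.0 * len(a & b) / tot


@dataclass
class SimilarityDistribution:
    """Per-pair Dice scores for one pair class and interaction role."""

    pair_class: str
    interaction_role: str
    values: list[float]
    n_excluded_empty: int = 0

    def __len__(self) -> int:
        return len(self.values)

    def median(self) -> float:
        return float(np.median(self.values)) if self.values else math.nan

    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else math.nan


def _neighbor_fn(layer: Layer, interaction_role: str):
    if interaction_role == "targets":
        if not isinstance(layer, DirectedLayer):
            raise TypeError("role 'targets' requires the directed layer")
        return layer.nodes, layer.out_neighbors
    if interaction_role == "regulators-TF":
        if not isinstance(layer, DirectedLayer):
            raise TypeError("role 'regulators-TF' requires the directed layer")
        return layer.nodes, layer.in_neighbors
    if interaction_role == "regulators-miRNA":
        if not isinstance(layer, BipartiteLayer):
            raise TypeError("role 'regulators-miRNA' requires the bipartite layer")
        return layer.genes, layer.regulators_of
    if interaction_role == "ppi-partners":
        if not isinstance(layer, UndirectedLayer):
            raise TypeError("role 'ppi-partners' requires the undirected layer")
        return layer.nodes, layer.neighbors
    raise ValueError(f"unknown interaction role {interaction_role!r}; "
                     f"expected one of {INTERACTION_ROLES}")


def similarity_distribution(layer: Layer, pairs: Iterable[Sequence[str]],
                            interaction_role: str,
                            pair_class: str = "ALL") -> SimilarityDistribution:
    """Dice similarity of each eligible pair's neighbor sets in one layer.

    Eligible pairs have both genes present in the layer (gene side, for the
    bipartite layer).  The partner gene is removed from both neighbor sets
    before scoring; pairs left with two empty sets are excluded and counted
    in ``n_excluded_empty``.
    """
    present, neigh = _neighbor_fn(layer, interaction_role)
    values: list[float] = []
    n_excluded = 0
    for a, b in sorted(canonicalize_pairs(pairs)):
        if a not in present or b not in present:
            continue
        sa = set(neigh(a)) - {a, b}
        sb = set(neigh(b)) - {a, b}
        s = dice_similarity(sa, sb)
        if s is None:
            n_excluded += 1
        else:
            values.append(s)
    return SimilarityDistribution(pair_class, interaction_role, values, n_excluded)


_ROLE_LAYER_ATTR = {
    "targets": "tf",
    "regulators-TF": "tf",
    "regulators-miRNA": "mirna",
    "ppi-partners": "ppi",
}


def null_similarity_distribution(ensemble: NullEnsemble,
                                 pairs: Iterable[Sequence[str]],
                                 interaction_role: str,
                                 pair_class: str = "ALL") -> SimilarityDistribution:
    """Similarity distribution pooled over every null realization.

    Scores from all realizations are concatenated into a single
    distribution (pooling, not per-realization summaries).
    """
    plist = sorted(canonicalize_pairs(pairs))
    attr = _ROLE_LAYER_ATTR[interaction_role]
    values: list[float] = []
    n_excluded = 0
    for realization in ensemble:
        d = similarity_distribution(getattr(realization, attr), plist,
                                    interaction_role, pair_class)
        values.extend(d.values)
        n_excluded += d.n_excluded_empty
    return SimilarityDistribution(pair_class, interaction_role, values, n_excluded)


@dataclass
class ComparisonResult:
    """Two-tailed Mann–Whitney comparison of two similarity distributions."""

    class_a: str
    class_b: str
    u_statistic: float
    p_value: float
    significant: bool
    symbol: str
    method: str = ""


_EXACT_ENUMERATION_CAP = 200_000


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample, with 0.5 credit for ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_two_tailed_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-tailed Mann–Whitney p by enumeration of all group splits.

    Handles ties through midranks: the permutation distribution of U over
    all C(n1+n2, n1) assignments of the pooled values is symmetric about
    n1·n2/2, and the two-tailed p is the probability of a deviation at
    least as large as observed.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    dev_obs = abs(u_obs - mu)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_two_tailed(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-tailed Mann–Whitney U test; returns (U of first sample, p, method).

    Small samples (all C(n1+n2, n1) splits enumerable) get the tie-aware
    exact permutation p-value; moderate tie-free samples use the exact
    distribution; large or tie-heavy samples use the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if math.comb(n1 + n2, n1) <= _EXACT_ENUMERATION_CAP:
        return u, _exact_two_tailed_p(x, y), "exact-enumeration"
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    if n1 <= 20 and n2 <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return u, float(res.pvalue), "exact-scipy"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return u, float(res.pvalue), "asymptotic"


def compare_distributions(d1: SimilarityDistribution,
                          d2: SimilarityDistribution) -> ComparisonResult:
    """Compare two similarity distributions; symbol per the class pairing."""
    if not d1.values or not d2.values:
        raise ValueError("cannot compare an empty similarity distribution")
    u, p, method = mann_whitney_two_tailed(d1.values, d2.values)
    significant = p < P_THRESHOLD
    symbol = COMPARISON_SYMBOLS.get(frozenset({d1.pair_class, d2.pair_class}), "")
    if not significant:
        symbol = ""
    return ComparisonResult(d1.pair_class, d2.pair_class, u, p, significant, symbol, method)


def enrich_mixed(observed: "MotifCount | float",
                 null_counts_by_layer: Mapping[str, Sequence[float]],
                 headline_layer: str = "tf", *,
                 motif_name: str = "", pair_class: str = "ALL") -> list[EnrichmentResult]:
    """One enrichment result per randomized layer for a mixed-type motif.

    Motifs spanning several layers get a Z-score against each per-layer
    null ensemble; the transcriptional-layer randomization is flagged as
    the headline result.
    """
    from .motifs import MotifCount  # local import to avoid a cycle

    if isinstance(observed, MotifCount):
        motif_name = motif_name or observed.motif_name
        pair_class = observed.pair_class
        obs_value = observed.count
    else:
        obs_value = float(observed)
    results = []
    for layer_kind, counts in null_counts_by_layer.items():
        results.append(z_score(obs_value, counts, motif_name=motif_name,
                               pair_class=pair_class, randomized_layer=layer_kind,
                               is_headline=(layer_kind == headline_layer)))
    return results
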