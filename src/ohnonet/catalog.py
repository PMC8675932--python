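"""Classification of duplicate gene pairs into WGD / SSD / young-SSD classes.

Human gene pairs surviving from the two rounds of whole-genome duplication
(WGD, "ohnologs") are compared throughout this package against pairs created
by small-scale duplications (SSD).  The WGD list is built by merging two
curated sources and filtering against the currently recognized paralogue set;
the SSD list is everything paralogous that is not WGD, split by duplication
age so that only SSD pairs roughly contemporary to the WGD event enter the
comparisons.  Non-duplicated pairs — all remaining pairs constructible from
the genes of a network — serve as the background class.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PairTuple = tuple[str, str]

WGD = "WGD"
SSD = "SSD"
SSD_YOUNG = "SSD_YOUNG"
NOT_DUP = "NOT_DUP"

CLASS_LABELS = (WGD, SSD, SSD_YOUNG)

#: Taxon names ordered oldest-first, following the NCBI taxonomy lineage of
#: Homo sapiens.  Used to rank the most-recent-common-ancestor label of a
#: paralog pair; pairs whose ancestor is strictly older than Sarcopterygii
#: are treated as contemporaries of the vertebrate WGD events.
DEFAULT_AGE_ORDER: tuple[str, ...] = (
    "Opisthokonta",
    "Bilateria",
    "Chordata",
    "Vertebrata",
    "Gnathostomata",
    "Euteleostomi",
    "Sarcopterygii",
    "Tetrapoda",
    "Amniota",
    "Mammalia",
    "Theria",
    "Eutheria",
    "Boreoeutheria",
    "Euarchontoglires",
    "Primates",
    "Simiiformes",
    "Catarrhini",
    "Hominoidea",
    "Hominidae",
    "Homininae",
    "Homo sapiens",
)

DEFAULT_AGE_RANK: dict[str, int] = {t: i for i, t in enumerate(DEFAULT_AGE_ORDER)}

DEFAULT_AGE_THRESHOLD = "Sarcopterygii"


def canonical_pair(gene_a: str, gene_b: str) -> PairTuple:
    """Return the pair in canonical (lexicographically sorted) order."""
    if gene_a == gene_b:
        raise ValueError(f"self-pair is not a valid gene pair: {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def canonicalize_pairs(pairs: Iterable[Sequence[str]]) -> set[PairTuple]:
    """Deduplicate an iterable of 2-sequences under unordered comparison."""
    return {canonical_pair(p[0], p[1]) for p in pairs}


@dataclass(frozen=True)
class GenePair:
    """An unordered pair of paralogous genes with its duplication class.

    ``gene_a < gene_b`` lexicographically; ``class_label`` is one of
    ``WGD``, ``SSD`` (ancient small-scale duplicates) or ``SSD_YOUNG``
    (duplicated more recently than the WGD epoch); ``age_label`` is the
    taxon name of the pair's most recent common ancestor, when known.
    """

    gene_a: str
    gene_b: str
    class_label: str
    source: str = ""
    age_label: str | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair: {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            raise ValueError("GenePair fields must be in canonical order; use GenePair.make")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @classmethod
    def make(cls, gene_a: str, gene_b: str, class_label: str,
             source: str = "", age_label: str | None = None) -> "GenePair":
        a, b = canonical_pair(gene_a, gene_b)
        return cls(a, b, class_label, source, age_label)

    @property
    def key(self) -> PairTuple:
        return (self.gene_a, self.gene_b)


@dataclass
class GenePairCatalog:
    """The disjoint partition of duplicate pairs into WGD / SSD / SSD_YOUNG.

    ``pairs`` maps the canonical pair tuple to its :class:`GenePair`; a pair
    appears in exactly one class.  ``gene_universe`` is the set of gene
    identifiers considered valid (protein-coding) — every catalogued pair's
    genes belong to it.
    """

    pairs: dict[PairTuple, GenePair] = field(default_factory=dict)
    gene_universe: set[str] = field(default_factory=set)

    def add(self, pair: GenePair, *, replace: bool = False) -> None:
        if not replace and pair.key in self.pairs and self.pairs[pair.key].class_label != pair.class_label:
            raise ValueError(f"pair {pair.key} already catalogued as "
                             f"{self.pairs[pair.key].class_label}")
        self.pairs[pair.key] = pair
        self.gene_universe.update(pair.key)

    def pairs_in_class(self, class_label: str) -> set[PairTuple]:
        return {k for k, p in self.pairs.items() if p.class_label == class_label}

    @property
    def wgd_pairs(self) -> set[PairTuple]:
        return self.pairs_in_class(WGD)

    @property
    def ssd_pairs(self) -> set[PairTuple]:
        return self.pairs_in_class(SSD)

    @property
    def young_ssd_pairs(self) -> set[PairTuple]:
        return self.pairs_in_class(SSD_YOUNG)

    def genes_in_class(self, class_label: str) -> set[str]:
        out: set[str] = set()
        for k, p in self.pairs.items():
            if p.class_label == class_label:
                out.update(k)
        return out

    def __contains__(self, pair: Sequence[str]) -> bool:
        return canonical_pair(pair[0], pair[1]) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "class_label": p.class_label,
             "source": p.source, "age_label": p.age_label or ""}
            for p in self.pairs.values()
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "class_label", "source", "age_label"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().sort_values(["class_label", "gene_a", "gene_b"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenePairCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        cat = cls()
        for row in df.itertuples(index=False):
            cat.add(GenePair.make(row.gene_a, row.gene_b, row.class_label,
                                  getattr(row, "source", ""),
                                  getattr(row, "age_label", "") or None))
        return cat


def read_pair_tsv(path) -> list[tuple[str, str, str, str]]:
    """Read a pair-list TSV: gene_a, gene_b, optional source, optional age_label.

    Header line required; ``#`` comment lines ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected at least two columns, got {cols}")
    out = []
    for row in df.itertuples(index=False):
        vals = tuple(row)
        out.append((vals[0], vals[1],
                    vals[2] if len(vals) > 2 else "",
                    vals[3] if len(vals) > 3 else ""))
    return out


def _normalize_case(pair_lists: Sequence[Iterable[Sequence[str]]],
                    gene_sets: Sequence[Iterable[str]]):
    """Detect identifiers that differ only by case and fold them to one form.

    Returns a mapping applied to every identifier; identifiers with a single
    observed spelling map to themselves.
    """
    spellings: dict[str, set[str]] = {}
    for genes in gene_sets:
        for g in genes:
            spellings.setdefault(g.casefold(), set()).add(g)
    for plist in pair_lists:
        for p in plist:
            for g in (p[0], p[1]):
                spellings.setdefault(g.casefold(), set()).add(g)
    mapping: dict[str, str] = {}
    for folded, seen in spellings.items():
        if len(seen) > 1:
            canonical = sorted(seen)[0]
            logger.warning("identifier case inconsistency %s -> normalized to %r",
                           sorted(seen), canonical)
            for s in seen:
                mapping[s] = canonical
        else:
            (only,) = seen
            mapping[only] = only
    return mapping


def merge_wgd_sources(source_a: Iterable[Sequence[str]],
                      source_b: Iterable[Sequence[str]],
                      valid_pairs: Iterable[Sequence[str]],
                      valid_genes: Iterable[str],
                      *,
                      alias_table: Mapping[str, str] | None = None) -> GenePairCatalog:
    """Build the WGD class by merging two ohnolog sources.

    The union of the two sources is intersected with ``valid_pairs`` (the
    currently recognized paralogue list) and restricted to pairs whose genes
    both belong to ``valid_genes`` (the protein-coding filter).  Comparison is
    unordered.  Identifier normalization is case-folding plus the optional
    ``alias_table``; an empty result raises, signalling mismatched identifier
    namespaces between the inputs.
    """
    source_a = list(source_a)
    source_b = list(source_b)
    valid_pairs = list(valid_pairs)
    valid_genes = list(valid_genes)

    norm = _normalize_case([source_a, source_b, valid_pairs], [valid_genes])
    if alias_table:
        norm = {k: alias_table.get(v, v) for k, v in norm.items()}

    def npair(p: Sequence[str]) -> PairTuple:
        return canonical_pair(norm[p[0]], norm[p[1]])

    genes = {norm[g] for g in valid_genes}
    valid = {npair(p) for p in valid_pairs}
    merged = {npair(p) for p in itertools.chain(source_a, source_b)}
    kept = {p for p in merged & valid if p[0] in genes and p[1] in genes}
    if not kept:
        raise ValueError(
            "merging WGD sources produced an empty pair list; the identifier "
            "namespaces of the inputs probably do not match")
    cat = GenePairCatalog(gene_universe=set(genes))
    for a, b in kept:
        cat.add(GenePair(a, b, WGD, source="merged"))
    return cat


def classify_ssd(all_paralogs: Iterable[Sequence[str]],
                 wgd: GenePairCatalog | Iterable[Sequence[str]],
                 age_rank: Mapping[str, int] = DEFAULT_AGE_RANK,
                 age_threshold_taxon: str = DEFAULT_AGE_THRESHOLD,
                 ) -> tuple[set[PairTuple], set[PairTuple]]:
    """Split the non-WGD paralogs into ancient and young SSD pair sets.

    ``all_paralogs`` yields (gene_a, gene_b, age_label) or longer rows with
    the age label in the last position used; SSD is everything not catalogued
    as WGD.  Pairs whose most recent common ancestor is *strictly older* than
    ``age_threshold_taxon`` under ``age_rank`` (oldest = smallest rank) are
    ancient; the remainder — including pairs with an unknown age label, which
    are conservatively excluded from comparisons — are young.
    """
    if age_threshold_taxon not in age_rank:
        raise ValueError(f"age threshold {age_threshold_taxon!r} not in age_rank")
    threshold = age_rank[age_threshold_taxon]
    if isinstance(wgd, GenePairCatalog):
        wgd_keys = set(wgd.pairs)
    else:
        wgd_keys = canonicalize_pairs(wgd)

    # resolve duplicate rows to the oldest (smallest-rank) age label observed
    best_rank: dict[PairTuple, int | None] = {}
    for row in all_paralogs:
        a, b = row[0], row[1]
        age = row[2] if len(row) > 2 else ""
        key = canonical_pair(a, b)
        if key in wgd_keys:
            continue
        if age in age_rank:
            rank = age_rank[age]
            prev = best_rank.get(key)
            best_rank[key] = rank if prev is None else min(prev, rank)
        else:
            if age:
                logger.warning("age label %r not in age ranking; pair %s routed "
                               "to the young class", age, key)
            else:
                logger.warning("missing age label; pair %s routed to the young class", key)
            best_rank.setdefault(key, None)

    ancient: set[PairTuple] = set()
    young: set[PairTuple] = set()
    for key, rank in best_rank.items():
        if rank is not None and rank < threshold:
            ancient.add(key)
        else:
            young.add(key)
    return ancient, young


def build_catalog(wgd_pairs: Iterable[Sequence[str]],
                  ancient_ssd: Iterable[Sequence[str]],
                  young_ssd: Iterable[Sequence[str]] = (),
                  gene_universe: Iterable[str] = ()) -> GenePairCatalog:
    """Assemble a catalog from already-classified pair sets."""
    cat = GenePairCatalog(gene_universe=set(gene_universe))
    for pairs, label in ((wgd_pairs, WGD), (ancient_ssd, SSD), (young_ssd, SSD_YOUNG)):
        for p in pairs:
            cat.add(GenePair.make(p[0], p[1], label))
    return cat


class NonDuplicatedPairUniverse:
    """All unordered pairs over a gene set that are in no duplicate class.

    The quadratic pair set is never materialized: membership, counting and
    uniform seeded sampling are supported directly.  Excluded pairs are every
    catalogued pair (WGD, ancient SSD and young SSD alike) with both genes in
    the network gene set.
    """

    def __init__(self, network_genes: Iterable[str], catalog: GenePairCatalog):
        self._genes = sorted(set(network_genes))
        if not self._genes:
            raise ValueError("network_genes must be nonempty")
        self._gene_set = set(self._genes)
        self._excluded = {k for k in catalog.pairs
                          if k[0] in self._gene_set and k[1] in self._gene_set}

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    def __contains__(self, pair: Sequence[str]) -> bool:
        try:
            key = canonical_pair(pair[0], pair[1])
        except ValueError:
            return False
        return (key[0] in self._gene_set and key[1] in self._gene_set
                and key not in self._excluded)

    def __len__(self) -> int:
        n = len(self._genes)
        return n * (n - 1) // 2 - len(self._excluded)

    def sample(self, n_pairs: int, seed: int | np.random.Generator = 0) -> list[PairTuple]:
        """Uniformly sample ``n_pairs`` distinct non-duplicated pairs."""
        if n_pairs > len(self):
            raise ValueError(f"requested {n_pairs} pairs from a universe of size {len(self)}")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = len(self._genes)
        if n * (n - 1) // 2 <= 20000:
            # small universe: enumerate and choose without replacement
            members = list(self)
            idx = rng.choice(len(members), size=n_pairs, replace=False)
            return sorted(members[i] for i in idx)
        chosen: set[PairTuple] = set()
        # rejection sampling over uniformly random index pairs; the excluded
        # set is small relative to n(n-1)/2 in any realistic input
        while len(chosen) < n_pairs:
            k = max(16, 2 * (n_pairs - len(chosen)))
            ii = rng.integers(0, n, size=k)
            jj = rng.integers(0, n, size=k)
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                key = canonical_pair(self._genes[i], self._genes[j])
                if key in self._excluded or key in chosen:
                    continue
                chosen.add(key)
                if len(chosen) == n_pairs:
                    break
        return sorted(chosen)

    def __iter__(self) -> Iterator[PairTuple]:
        """Iterate the full universe (only sensible for small gene sets)."""
        for a, b in itertools.combinations(self._genes, 2):
            key = (a, b)
            if key not in self._excluded:
                yield key


def non_duplicated_pairs(network_genes: Iterable[str],
                         catalog: GenePairCatalog) -> NonDuplicatedPairUniverse:
    """Background pair universe: every pair over ``network_genes`` not catalogued."""
    return NonDuplicatedPairUniverse(network_genes, catalog)
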