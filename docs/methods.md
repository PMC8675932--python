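# Methods

## Scientific setting

Two rounds of whole-genome duplication (WGD) at the origin of the
vertebrate lineage left the human genome with thousands of surviving
duplicate pairs ("ohnologs"), alongside pairs continuously produced by
small-scale duplications (SSD).  This package quantifies how the two kinds
of duplicate pairs are distributed in local regulatory circuits — network
motifs — across three co-registered interaction layers: a directed TF→gene
transcriptional network, an undirected protein–protein interaction (PPI)
network, and a bipartite miRNA→gene network.  Two complementary statistics
are computed per pair class (WGD, ancient SSD, and a sampled background of
non-duplicated pairs):

* **motif enrichment**, the Z-score of the observed motif-instance count
  against a degree-preserving randomized ensemble,
  `Z = (n − n̄_null) / σ_null`, with |Z| ≳ 5 treated as significant;
* **interaction similarity**, the per-pair Sørensen–Dice overlap
  `S(A, B) = 2|A∩B| / (|A| + |B|)` of the two genes' neighbor sets
  (regulators, targets or PPI partners), compared between classes with a
  two-tailed Mann–Whitney U test at P < 0.01.

## Pair classification

The WGD class is the union of two curated ohnolog sources intersected with
the currently recognized paralogue list and restricted to protein-coding
genes; pairs are unordered and deduplicated, and an empty merge result is
treated as an error because it indicates mismatched identifier namespaces.
The SSD class is every remaining paralog pair, split by the age of the
pair's most recent common ancestor: pairs strictly older than
*Sarcopterygii* are "ancient" and enter comparisons as contemporaries of
the WGD epoch; younger pairs (including pairs with unrecognized age labels,
which are routed conservatively to this class) are kept separate so that
duplication-age confounds do not masquerade as mechanism differences.  The
taxon order is supplied as an explicit oldest-first rank table (the NCBI
taxonomy lineage of *Homo sapiens*) rather than inferred from data, keeping
the rule testable and data-version independent.  When the same pair appears
with several age labels, the oldest one wins.  Classes are disjoint at the
pair level; a gene may well appear in pairs of different classes, and
gene-level summaries (degree distributions) therefore use overlapping gene
sets.

Non-duplicated pairs are all pairs constructible from a network's genes
that are in no duplicate class (young SSD included).  The quadratic pair
set is never materialized: the universe object supports membership tests,
exact counting, and uniform seeded sampling by rejection (with full
enumeration as the fallback for small gene sets).

## Motif census conventions

Motifs are counted per distinct node-tuple instance — (pair, third node),
(pair, regulator), (regulator pair, target pair) — which is the granularity
at which edge-swap null Z-scores are conventionally computed.  The direct
pair-PPI statistic is the exception: it is a per-pair indicator, reported as
a percentage of the pairs with both genes present in the PPI network.
Eligibility rules (what enters a denominator) follow the layer semantics:
V-motif and FFL pairs need both members to be regulators; Λ/Δ pairs need
both genes present in the regulatory layer (and the PPI layer for Δ); mixed
bifans need presence in every participating layer.

Specific choices worth stating:

* Self-loops never count as motif edges in three-or-more-node motifs; they
  are consumed only by the feedback-loop/self-loop categorization, which
  assigns every TF pair to exactly one of ten topological categories
  (none / one-self / both-self; one-way regulation with four self-loop
  placements; mutual regulation with 0, 1 or 2 self-loops).
* FFLs are counted per ordered orientation: if both a→b and b→a exist,
  both orientations contribute.  This scales counts (and hence Z-scores) by
  a constant relative to an unordered convention without affecting signs or
  rankings.
* Bifans and FFL+Bifans require the regulator pair and target pair to be
  distinct same-class pairs sharing no gene, with all four cross
  regulations present; the plain bifan additionally requires *no*
  TF–TF regulation, so it is deliberately non-monotone — adding an internal
  edge migrates the instance to the FFL+Bifan class.
* Every optimized counter is mirrored by a brute-force enumerator (guarded
  to 500 nodes) used as an independent oracle in the tests; equality is
  exact, not approximate.

## Null models

Randomized layers are produced by the double-edge-swap chain: repeatedly
draw two edges and exchange endpoints, rejecting any proposal that would
create a parallel edge or a new self-loop.  Rejected proposals count toward
the attempt budget (uniform-sampling convention), and the budget is
`ceil(10 × |E|)` attempted swaps by default — the standard order of
magnitude for edge-swap mixing; on a 200-node Erdős–Rényi digraph this
leaves under 30% edge overlap with the original network.  Per-node in- and
out-degrees (or per-side bipartite degrees) are preserved exactly, which is
asserted in the tests as integer equality for every realization.

Existing directed self-loops are frozen rather than destroyed or swapped:
the self-loop census must see the real network's self-regulation, and
freezing keeps null three-node motif statistics comparable without
inflating or deflating self-loops.  The alternative (deleting them before
rewiring) would change degree sequences and was rejected.

Ensembles default to 100 realizations; realization *i* uses seed
`base_seed + i`, making every ensemble bit-reproducible.  For motifs that
span several layers, one ensemble per participating layer is built and one
Z-score reported per randomized layer, with the transcriptional-layer
randomization flagged as the headline number.

## Statistics

* **Z-scores** use the population (1/N) SD convention, since the ensemble
  *is* the entire null sample of interest; at N = 100 the difference from
  1/(N−1) is below reporting precision.  A degenerate null (σ = 0) yields
  z = 0 when the observation equals the constant null and an undefined
  sentinel otherwise — never ±∞ arithmetic.
* **Dice similarity** removes the partner gene from both neighbor sets
  before scoring, so a direct a→b regulation or a–b interaction is not
  itself counted as a "shared" neighbor.  Pairs whose two effective sets
  are both empty are excluded from the distribution but counted and
  surfaced (`n_excluded_empty`), because zero-inflation is a real feature
  of these distributions and silent dropping would hide it.  Pairs with a
  gene absent from the layer are skipped outright (the real-data analyses
  restrict to pairs inside each network).
* **Null similarity distributions** pool the per-pair scores of all
  realizations into one distribution rather than summarizing
  per-realization medians; pooling keeps the zero-mass structure visible to
  the rank test.
* **Mann–Whitney U** is two-tailed with midrank tie handling.  The p-value
  route depends on feasibility: when all C(n1+n2, n1) group splits can be
  enumerated (cap 200,000, which covers every case with n1+n2 ≤ 10 and
  balanced samples up to 20 total) an exact tie-aware permutation p is
  computed by direct enumeration; tie-free samples with both groups ≤ 20
  use the exact distribution; everything else uses the normal approximation
  with tie and continuity corrections.  Full enumeration at 20-per-group
  (≈ 1.4 × 10¹¹ splits) is computationally impossible, which is why the
  exact route is bounded by enumerability rather than by group size alone.
  Significance symbols follow the figure convention: `*` SSD–WGD,
  `■` WGD–non-duplicated, `▲` SSD–non-duplicated, shown only at p < 0.01.

## Synthetic data generator

The generator exists so that every claim the pipeline makes can be checked
against planted ground truth.  It emulates: one genome-wide duplication
with per-layer, per-copy edge retention (each ancestral edge spawns all
duplicate endpoint combinations — four for gene–gene layers, two for
miRNA→gene — each kept with probability r); direct PPI gain between WGD
partners; independent single-gene SSD duplications with their own
retention; and divergence noise that re-targets each edge with a small
probability.  A self-regulating TF duplicates into a mutually regulating TF
pair sharing its duplicated targets — exactly the mechanism that seeds
FFL+Bifan arrays, and without the self-loop, plain bifans; the tests assert
this routing exhaustively at full retention.

Defaults are the conditions used throughout the validation: 1000 ancestral
genes, 50 TFs (mean ancestral out-degree ≈ 20), 30 miRNAs, WGD retention
0.8, 100 SSD events at retention 0.5, 5% rewiring, PPI gain 0.2 (WGD) /
0.05 (SSD) — the last two chosen so the direct-interaction rates of the two
classes sit in the qualitative ratio observed in real PPI data (roughly
one in five WGD pairs versus one in twenty-five SSD pairs).  Young SSD
pairs are modelled purely as recency: a configurable tail of events
(default 15%) is applied after the rewiring stage, so those pairs have
experienced no divergence noise.  miRNAs are never duplicated.  Every
stochastic decision is recorded in an event log that replays exactly to the
emitted layers, and `generate` is deterministic under its seed.

For a WGD TF pair at retention r with ancestral out-degree k, each of the
2k candidate targets enters each copy's target set independently with
probability r, so E|A∩B| = 2k·r² and E|A| = E|B| = 2k·r; the mean Dice
approaches r from below with an O(1/k) finite-size bias.  The parameter-
recovery test therefore uses k ≈ 18 and compares the across-seed mean to r
within three between-seed standard deviations, and checks monotonicity in
r directly.

### What the generator does not emulate

Scale-free degree distributions (ancestral layers are Erdős–Rényi-like),
sequence evolution, expression/dosage constraints, fitness-coupled
retention, correlated retention between layers, and gene loss.  Passing
tests therefore demonstrate that the pipeline *detects planted structure
and rejects its absence* under controlled conditions — not that any
particular real-data enrichment value is reproduced.  Real-data headline
numbers depend on specific database releases and are outside desk-scale
scope.

## Problem sizes and numerical choices

The validation suite runs the full pipeline at the default synthetic-genome
scale (≈ 2100 genes after duplication, ≈ 3–9 × 10³ edges per layer) with
100-realization ensembles; oracle equivalence uses 200 random ≤ 15-node
graphs per motif; degree conservation uses 500-node layers of each kind.
These sizes were chosen so the whole suite completes in well under a minute
per heavy test while leaving the statistical assertions comfortable
margins (3-SD bands, p ≪ 0.01 separations).

Degenerate inputs are handled explicitly: layers with fewer than two
swappable edges are returned unchanged with a warning; empty null-count
vectors and empty similarity distributions raise; undirected self-edges
and bipartite namespace collisions are rejected at load time with the
offending line or identifier named.

## Known limitations

* The Λ/Δ eligibility rule ("both genes present in the layer") makes
  denominators depend on the layer's node set; pairs invisible to a layer
  are silently out of scope for that layer's statistics.
* The exact Mann–Whitney route switches to the asymptotic approximation
  for large tie-heavy samples; at the sample sizes where this happens the
  approximation error is far below the 0.01 decision threshold.
* Edge-swap sampling is the standard practical null; it is not a perfectly
  uniform sampler of the degree-constrained graph space, and connectivity
  is not preserved.
* The generator's event log records retained edges per event, so logs are
  proportional to network size; they are intended for audit and replay,
  not as a compact serialization.
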