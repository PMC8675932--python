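# ohnonet

Motif enrichment and interaction-similarity analysis of duplicated gene
pairs in multilayer regulatory networks.

## The problem

The vertebrate genome carries two kinds of duplicate gene pairs: ohnologs,
survivors of the whole-genome duplications (WGD) at the origin of the
lineage, and pairs produced by ongoing small-scale duplications (SSD).
The two mechanisms leave different fingerprints in the local wiring of
regulatory networks — WGD duplicates a regulator *together with* its
targets and its self-regulation, so a single event can mint feed-forward
loops, bifans and mutually regulating TF pairs wholesale, while an SSD
event copies one gene at a time.  `ohnonet` is a toolkit for quantifying
those fingerprints across three interaction layers — a directed TF→gene
transcriptional network, an undirected protein–protein interaction (PPI)
network, and a bipartite miRNA→gene network — for anyone studying gene
duplication, regulatory-network evolution, or motif statistics in
multilayer biological networks.

Two statistics are computed per pair class (WGD, ancient SSD, and a
sampled non-duplicated background):

* **Motif enrichment.** For each motif (direct pair PPI, co-interaction
  with a third protein, V, Λ, Δ, FFL, Bifan, FFL+Bifan, mixed TF+miRNA
  bifans, and the self-loop/feedback-loop taxonomy of TF pairs) the
  observed instance count *n* is compared against an ensemble of
  degree-preserving edge-swap randomizations:

      Z = (n − n̄_null) / σ_null ,

  with 100 realizations per ensemble and |Z| ≳ 5 read as significant.
* **Interaction similarity.** Each pair's regulator/target/partner sets A
  and B are scored with the Sørensen–Dice coefficient
  S(A,B) = 2|A∩B|/(|A|+|B|) (partner gene removed first), and class
  distributions are compared with a two-tailed Mann–Whitney U test at
  P < 0.01 (symbols: `*` SSD–WGD, `■` WGD–not-duplicated, `▲`
  SSD–not-duplicated).

Because the real input networks and ohnolog lists are release-dependent
downloads, the package ships a duplication–divergence simulator that
generates co-registered three-layer networks with planted WGD/SSD pairs
and full ground truth, so the entire pipeline is testable at desk scale.

## Worked example

Simulate a small genome (300 ancestral genes, 30 TFs, one WGD at retention
0.8, 100 SSD events at retention 0.5, 5% divergence noise) and test two
motif families against 100-realization nulls:

```python
import pandas as pd
from ohnonet import RunConfig, run_pipeline

config = RunConfig(
    output_dir="demo",
    simulate=dict(n_ancestral_genes=300, n_tfs=30, n_mirnas=10, seed=42),
    motifs=["pair_ppi", "lambda_tf"],
    n_realizations=100,
    base_seed=42,
)
run_pipeline(config)
enr = pd.read_csv("demo/enrichment.tsv", sep="\t")
print(enr[["motif_name", "pair_class", "observed", "null_mean", "null_sd", "z"]]
      .to_string(index=False))
```

which prints:

```
motif_name pair_class  observed  null_mean  null_sd         z
  pair_ppi        WGD      56.0       2.07 1.328571 40.592497
  pair_ppi        SSD       2.0       0.27 0.526403  3.286456
  pair_ppi    NOT_DUP      10.0      12.15 2.920188 -0.736254
 lambda_tf        WGD     193.0      12.43 3.418348 52.823769
 lambda_tf        SSD      39.0       1.92 1.293677 28.662488
 lambda_tf    NOT_DUP     119.0     109.70 9.247162  1.005714
```

Reading the output: 56 of the planted WGD pairs share a direct protein
interaction where the degree-preserving null expects about 2 (Z ≈ 41), and
WGD pairs sit under a common TF (Λ motif) 193 times against a null mean of
12 (Z ≈ 53) — the planted duplication structure is strongly enriched.  The
non-duplicated background is statistically indistinguishable from its null
(|Z| ≈ 1), as it should be.  The run directory also contains per-pair Dice
similarity distributions (`similarity.tsv`), Mann–Whitney class comparisons
with their significance symbols (`comparisons.tsv`), tidy degree
distributions, the raw per-realization census, and a `manifest.json`
recording seeds and files; `ohnonet report --run-dir demo` renders
boxplot + Z-bar panels per motif.

The same pipeline runs on real edge lists by replacing the `simulate`
block with `tf_path` / `ppi_path` / `mirna_path` / `catalog_path` (TSV edge
lists and a pair catalog built with `ohnonet classify`).

A command-line interface mirrors the library:
`ohnonet simulate | classify | census | rewire | enrich | similarity |
report | run`.

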