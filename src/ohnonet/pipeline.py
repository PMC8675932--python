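"""End-to-end orchestration: classify → census → null ensembles → statistics.

A run is described by a :class:`RunConfig` (a YAML-serializable set of input
paths or a simulate block, the motif list and the ensemble settings).  All
randomness descends from ``base_seed``, so a run is reproducible bit-for-bit
from config + seed; the manifest written alongside the outputs records every
file, seed and default so the run is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import NOT_DUP, SSD, WGD, GenePairCatalog, non_duplicated_pairs
from .layers import Multilayer, degree_summary, load_layer
from .motifs import MOTIF_NAMES, classify_fbl_selfloops, count_motif
from .nulls import build_ensemble
from .simulate import SimulationParams, generate
from .stats import (compare_distributions, enrich_mixed, null_similarity_distribution,
                    similarity_distribution, z_score)

logger = logging.getLogger(__name__)

#: which layers each motif touches (first = headline randomization) and the
#: interaction-similarity role that accompanies it, if meaningful
MOTIF_SPEC: dict[str, dict] = {
    "pair_ppi":        {"layers": ("ppi",), "role": "ppi-partners", "pair_domain": "ppi"},
    "co_interaction":  {"layers": ("ppi",), "role": "ppi-partners", "pair_domain": "ppi"},
    "V":               {"layers": ("tf",), "role": "targets", "pair_domain": "tf_regulators"},
    "lambda_tf":       {"layers": ("tf",), "role": "regulators-TF", "pair_domain": "tf"},
    "lambda_mirna":    {"layers": ("mirna",), "role": "regulators-miRNA", "pair_domain": "mirna"},
    "delta_tf":        {"layers": ("tf", "ppi"), "role": None, "pair_domain": "tf_ppi"},
    "delta_mirna":     {"layers": ("mirna", "ppi"), "role": None, "pair_domain": "mirna_ppi"},
    "ffl":             {"layers": ("tf",), "role": None, "pair_domain": "tf_regulators"},
    "bifan":           {"layers": ("tf",), "role": None, "pair_domain": "tf_regulators"},
    "ffl_bifan":       {"layers": ("tf",), "role": None, "pair_domain": "tf_regulators"},
    "mixed_bifan":     {"layers": ("tf", "mirna"), "role": None, "pair_domain": "tf_mirna"},
    "mixed_bifan_ppi": {"layers": ("tf", "mirna", "ppi"), "role": None, "pair_domain": "tf_mirna_ppi"},
}

DEFAULT_MOTIFS = ("pair_ppi", "co_interaction", "V", "lambda_tf", "lambda_mirna", "ffl")


@dataclass
class RunConfig:
    """Validated description of a pipeline run."""

    output_dir: str
    simulate: dict | None = None
    tf_path: str | None = None
    ppi_path: str | None = None
    mirna_path: str | None = None
    catalog_path: str | None = None
    motifs: list[str] = field(default_factory=lambda: list(DEFAULT_MOTIFS))
    n_realizations: int = 100
    n_swaps_per_edge: float = 10.0
    base_seed: int = 0
    n_not_dup: int = 2000
    classify_fbl: bool = True

    def validate(self) -> None:
        for m in self.motifs:
            if m not in MOTIF_NAMES:
                raise ValueError(f"unknown motif {m!r}; choose from {MOTIF_NAMES}")
        if self.simulate is None:
            for name in ("tf_path", "ppi_path", "mirna_path", "catalog_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config must set either a simulate block or {name}")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")
        if self.n_realizations <= 0:
            raise ValueError("n_realizations must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: RunConfig) -> tuple[Multilayer, GenePairCatalog]:
    if config.simulate is not None:
        params = SimulationParams(**{**config.simulate, "seed": config.simulate.get("seed", config.base_seed)})
        truth = generate(params)
        return truth.layers, truth.catalog
    layers = Multilayer(
        load_layer(config.tf_path, "directed"),
        load_layer(config.ppi_path, "undirected"),
        load_layer(config.mirna_path, "bipartite"),
    )
    return layers, GenePairCatalog.from_tsv(config.catalog_path)


def _pair_domain_genes(domain: str, layers: Multilayer) -> set[str]:
    parts = {
        "ppi": layers.ppi.nodes,
        "tf": layers.tf.nodes,
        "tf_regulators": layers.tf.regulators,
        "mirna": layers.mirna.genes,
        "tf_ppi": layers.tf.nodes & layers.ppi.nodes,
        "mirna_ppi": layers.mirna.genes & layers.ppi.nodes,
        "tf_mirna": layers.tf.nodes & layers.mirna.genes,
        "tf_mirna_ppi": layers.tf.nodes & layers.mirna.genes & layers.ppi.nodes,
    }
    return set(parts[domain])


def _pairs_by_class(motif: str, layers: Multilayer, catalog: GenePairCatalog,
                    n_not_dup: int, seed: int) -> dict[str, list]:
    """WGD / ancient-SSD / sampled non-duplicated pairs for one motif domain."""
    domain_genes = _pair_domain_genes(MOTIF_SPEC[motif]["pair_domain"], layers)
    out = {WGD: sorted(catalog.wgd_pairs), SSD: sorted(catalog.ssd_pairs)}
    if domain_genes and len(domain_genes) > 1:
        universe = non_duplicated_pairs(domain_genes, catalog)
        out[NOT_DUP] = universe.sample(min(n_not_dup, len(universe)), seed=seed)
    else:
        out[NOT_DUP] = []
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write tidy TSV outputs + manifest."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("loading inputs")
    layers, catalog = _load_inputs(config)

    # degree summaries per layer
    degree_rows = []
    for kind in ("tf", "ppi", "mirna"):
        ds = degree_summary(getattr(layers, kind), catalog)
        df = ds.to_dataframe()
        df.insert(0, "layer", kind)
        degree_rows.append(df)
    degrees_df = pd.concat(degree_rows, ignore_index=True)

    # which layer kinds need a null ensemble
    needed_kinds: list[str] = []
    for m in config.motifs:
        for k in MOTIF_SPEC[m]["layers"]:
            if k not in needed_kinds:
                needed_kinds.append(k)
    ensembles = {}
    for i, kind in enumerate(needed_kinds):
        logger.info("building %d-realization null ensemble for %s layer",
                    config.n_realizations, kind)
        ensembles[kind] = build_ensemble(
            layers, kind, config.n_realizations,
            base_seed=config.base_seed + 1000 * (i + 1),
            n_swaps_per_edge=config.n_swaps_per_edge)

    census_rows = []
    enrich_rows = []
    sim_rows = []
    cmp_rows = []

    for mi, motif in enumerate(config.motifs):
        spec = MOTIF_SPEC[motif]
        pairs_by_class = _pairs_by_class(motif, layers, catalog,
                                         config.n_not_dup, seed=config.base_seed + 7 * mi + 13)
        sims = {}
        for cls, pairs in pairs_by_class.items():
            observed = count_motif(motif, layers, pairs, pair_class=cls)
            census_rows.append({"motif_name": motif, "pair_class": cls,
                                "layer_set": "+".join(spec["layers"]),
                                "count": observed.count, "denominator": observed.denominator,
                                "realization_id": "NA"})
            null_counts_by_layer = {}
            for kind in spec["layers"]:
                counts = []
                for ri, realization in enumerate(ensembles[kind]):
                    nc = count_motif(motif, realization, pairs, pair_class=cls)
                    counts.append(nc.count)
                    census_rows.append({"motif_name": motif, "pair_class": cls,
                                        "layer_set": "+".join(spec["layers"]),
                                        "count": nc.count, "denominator": nc.denominator,
                                        "realization_id": f"{kind}:{ri}"})
                null_counts_by_layer[kind] = counts
            headline = spec["layers"][0] if "tf" not in spec["layers"] else "tf"
            for res in enrich_mixed(observed, null_counts_by_layer, headline_layer=headline,
                                    motif_name=motif):
                enrich_rows.append({"motif_name": motif, "pair_class": cls,
                                    "observed": res.observed, "null_mean": res.null_mean,
                                    "null_sd": res.null_sd,
                                    "z": "" if res.z is None else res.z,
                                    "randomized_layer": res.randomized_layer,
                                    "is_headline": res.is_headline})

            role = spec["role"]
            if role is not None:
                attr = {"targets": "tf", "regulators-TF": "tf",
                        "regulators-miRNA": "mirna", "ppi-partners": "ppi"}[role]
                d = similarity_distribution(getattr(layers, attr), pairs, role, cls)
                sims[cls] = d
                for v in d.values:
                    sim_rows.append({"motif_name": motif, "pair_class": cls,
                                     "interaction_role": role, "value": v, "null": False})
                nd = null_similarity_distribution(ensembles[attr], pairs, role, cls)
                if d.values and nd.values:
                    c = compare_distributions(d, nd)
                    cmp_rows.append({"motif_name": motif, "class_a": f"{cls}",
                                     "class_b": f"{cls}:null", "U": c.u_statistic,
                                     "p": c.p_value, "significant": c.significant,
                                     "symbol": "", "method": c.method})

        # pairwise class comparisons of the real similarity distributions
        classes = [c for c in (WGD, SSD, NOT_DUP) if c in sims and sims[c].values]
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                c = compare_distributions(sims[classes[i]], sims[classes[j]])
                cmp_rows.append({"motif_name": motif, "class_a": c.class_a,
                                 "class_b": c.class_b, "U": c.u_statistic,
                                 "p": c.p_value, "significant": c.significant,
                                 "symbol": c.symbol, "method": c.method})

    files: dict[str, str] = {}

    def write_df(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        files[name] = str(p)

    write_df("degrees.tsv", degrees_df)
    write_df("census.tsv", pd.DataFrame(census_rows))
    write_df("enrichment.tsv", pd.DataFrame(enrich_rows))
    write_df("similarity.tsv", pd.DataFrame(sim_rows))
    write_df("comparisons.tsv", pd.DataFrame(cmp_rows))

    if config.classify_fbl:
        tf_pairs_by_cls = {WGD: sorted(catalog.wgd_pairs), SSD: sorted(catalog.ssd_pairs)}
        fbl_rows = []
        for cls, pairs in tf_pairs_by_cls.items():
            regs = layers.tf.regulators
            tf_pairs = [p for p in pairs if p[0] in regs and p[1] in regs]
            for cat, members in classify_fbl_selfloops(layers.tf, tf_pairs).items():
                for a, b in members:
                    fbl_rows.append({"pair_class": cls, "category": cat,
                                     "gene_a": a, "gene_b": b})
        write_df("fbl_selfloops.tsv", pd.DataFrame(
            fbl_rows, columns=["pair_class", "category", "gene_a", "gene_b"]))

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "base_seed": config.base_seed,
        "ensemble_seeds": {k: ensembles[k].base_seed for k in ensembles},
        "files": files,
        "wall_clock_s": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"]["manifest.json"] = str(outdir / "manifest.json")
    return manifest


def report(run_dir, fmt: str = "png") -> list[Path]:
    """Render similarity boxplots with significance symbols and Z-score bars.

    One panel pair per motif that has both similarity and enrichment
    outputs; missing stage outputs are listed in a warning and skipped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    written: list[Path] = []
    missing = [n for n in ("enrichment.tsv", "similarity.tsv", "comparisons.tsv")
               if not (run_dir / n).exists()]
    if missing:
        logger.warning("missing outputs %s; report proceeds with available panels", missing)
    if "enrichment.tsv" in missing:
        return written
    enr = pd.read_csv(run_dir / "enrichment.tsv", sep="\t")
    sim = (pd.read_csv(run_dir / "similarity.tsv", sep="\t")
           if (run_dir / "similarity.tsv").exists() else pd.DataFrame())
    cmps = (pd.read_csv(run_dir / "comparisons.tsv", sep="\t")
            if (run_dir / "comparisons.tsv").exists() else pd.DataFrame())

    for motif in enr["motif_name"].unique():
        e = enr[(enr["motif_name"] == motif) & enr["is_headline"]]
        s = sim[sim["motif_name"] == motif] if not sim.empty else pd.DataFrame()
        fig, axes = plt.subplots(1, 2 if s.empty else 3, figsize=(10, 3.2))
        axes = list(axes) if hasattr(axes, "__len__") else [axes]
        ax_i = 0
        if not s.empty:
            ax = axes[ax_i]; ax_i += 1
            classes = [c for c in ("WGD", "SSD", "NOT_DUP") if (s["pair_class"] == c).any()]
            data = [s.loc[s["pair_class"] == c, "value"].to_numpy() for c in classes]
            ax.boxplot(data, tick_labels=classes, showfliers=False)
            ax.set_ylabel("Dice similarity S")
            ax.set_title(f"{motif}: similarity")
            if not cmps.empty:
                syms = cmps[(cmps["motif_name"] == motif) & cmps["significant"]
                            & (cmps["symbol"].fillna("") != "")]["symbol"]
                if len(syms):
                    ax.text(0.02, 0.95, " ".join(syms), transform=ax.transAxes,
                            va="top", fontsize=12)
        ax = axes[ax_i]; ax_i += 1
        zvals = pd.to_numeric(e["z"], errors="coerce")
        ax.bar(e["pair_class"], zvals)
        ax.axhline(5, ls="--", c="gray", lw=0.8)
        ax.axhline(-5, ls="--", c="gray", lw=0.8)
        ax.set_ylabel("Z-score")
        ax.set_title(f"{motif}: enrichment")
        ax = axes[ax_i]
        ax.axis("off")
        if not cmps.empty:
            rows = cmps[cmps["motif_name"] == motif]
            txt = "\n".join(f"{r.class_a} vs {r.class_b}: p={r.p:.2e} {r.symbol or ''}"
                            for r in rows.itertuples())
            ax.text(0, 1, txt or "no comparisons", va="top", fontsize=8, family="monospace")
        fig.tight_layout()
        p = run_dir / f"report_{motif}.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if not written:
        logger.warning("empty run directory %s; nothing to report", run_dir)
    return written
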