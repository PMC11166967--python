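"""Configuration-driven pipeline driver.

A run is described by a YAML config with exactly one of an ``inputs`` block
(paths to counts/samples/gene sets/knowledge base) or a ``simulation``
block (design preset and generator parameters), plus stage toggles and
per-stage parameters. Stages execute in dependency order
dge → consensus → {enrichment, modules, pairs, regulators}; each writes TSV
outputs into the bundle directory and the run manifest records versions,
seeds, parameters and input checksums. Identical config + seed reproduce
byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, consensus, dge, enrichment, gene_modules, io, \
    pair_models, regulators, simdata
from ._utils import ValidationError

logger = logging.getLogger(__name__)

_STAGES = ("dge", "consensus", "enrichment", "modules", "pairs", "regulators")
_STAGE_DEPS = {"consensus": ("dge",), "enrichment": ("dge",),
               "modules": ("dge",), "pairs": ("dge", "consensus"),
               "regulators": ("dge",)}

_DEFAULT_PARAMS = {
    "fdr_threshold": 0.1,
    "min_subsets": 2,
    "min_missions": 2,
    "n_perm": 1000,
    "gsea_min_size": 15,
    "gsea_weight": 1.0,
    "ora_min_size": 15,
    "z_threshold": 1.0,
    "regulator_adj_p": 0.05,
    "min_variance": 1.7,
    "max_identical_fraction": 0.25,
    "embed_method": "umap",
    "umap_n_neighbors": 15,
    "min_cluster_size": 10,
    "pair_top_k": 10,
    "pair_cv_top": 50,
    "mrmr_k": 2,
    "dispersion_shrinkage": 0.5,
}

_DEFAULT_SIMULATION = {
    "preset": "paper-like",
    "replicates_per_group": 6,
    "n_genes": 2000,
    "n_subset_de": 10,
    "n_cross_mission": 20,
    "lfc": 2.0,
    "n_modules": 3,
    "module_size": 60,
    "module_loading": 1.5,
    "n_synergy_pairs": 1,
    "synergy_coeff": 3.0,
    "n_sets": 50,
    "set_size": 30,
    "enrichment_fraction": 0.8,
    "n_enriched": 5,
}

_INPUT_KEYS = {"counts", "samples", "gmt", "kb", "orthologs"}


@dataclass
class PipelineConfig:
    seed: int = 0
    inputs: dict | None = None
    simulation: dict | None = None
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.inputs is None) == (self.simulation is None):
            raise ValidationError(
                "config needs exactly one of 'inputs' or 'simulation'"
            )
        if self.inputs is not None:
            unknown = set(self.inputs) - _INPUT_KEYS
            if unknown:
                raise ValidationError(
                    f"unknown input key {sorted(unknown)[0]!r}")
        if self.simulation is not None:
            unknown = set(self.simulation) - set(_DEFAULT_SIMULATION)
            if unknown:
                raise ValidationError(
                    f"unknown simulation key {sorted(unknown)[0]!r}")
            self.simulation = {**_DEFAULT_SIMULATION, **self.simulation}
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage {sorted(unknown)[0]!r}")
        self.stages = {s: bool(self.stages.get(s, s in ("dge", "consensus")))
                       for s in _STAGES}
        unknown = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown:
            raise ValidationError(f"unknown parameter {sorted(unknown)[0]!r}")
        self.params = {**_DEFAULT_PARAMS, **self.params}
        for stage, deps in _STAGE_DEPS.items():
            if self.stages[stage]:
                for dep in deps:
                    if not self.stages[dep]:
                        raise ValidationError(
                            f"stage {stage!r} requires stage {dep!r}")


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected
    by name and defaults are filled in."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    unknown = set(raw) - {"seed", "inputs", "simulation", "stages", "params"}
    if unknown:
        raise ValidationError(f"unknown config key {sorted(unknown)[0]!r}")
    return PipelineConfig(seed=int(raw.get("seed", 0)),
                          inputs=raw.get("inputs"),
                          simulation=raw.get("simulation"),
                          stages=raw.get("stages", {}),
                          params=raw.get("params", {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "params": p, "stages": config.stages, "inputs": {},
                      "records": {}}

    gene_sets = None
    kb = None
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        design = simdata.make_design(
            sim["preset"], replicates_per_group=sim["replicates_per_group"])
        sparams = simdata.SimulationParams(n_genes=sim["n_genes"],
                                           seed=config.seed)
        effects = simdata.sample_effects(
            design, sparams, n_subset_de=sim["n_subset_de"],
            n_cross_mission=sim["n_cross_mission"], lfc=sim["lfc"],
            n_modules=sim["n_modules"], module_size=sim["module_size"],
            module_loading=sim["module_loading"],
            n_synergy_pairs=sim["n_synergy_pairs"],
            synergy_coeff=sim["synergy_coeff"], seed=config.seed)
        counts, samples, truth = simdata.simulate_counts(design, sparams,
                                                         effects)
        gene_sets = simdata.plant_genesets(
            truth, n_sets=sim["n_sets"], set_size=sim["set_size"],
            enrichment_fraction=sim["enrichment_fraction"],
            n_enriched=sim["n_enriched"], seed=config.seed)
        first_subset = design.subsets[0].subset_id
        n_de_first = sum(e.subset_id == first_subset for e in truth.de)
        if n_de_first >= 4:
            kb = simdata.plant_regulator_kb(
                truth, first_subset, n_targets=min(20, n_de_first),
                seed=config.seed)
            io.write_kb(kb, out / "knowledge_base.tsv")
        io.write_counts(counts, out / "counts.tsv")
        io.write_samples(samples, out / "samples.tsv")
        truth.write_tsv(out / "truth.tsv")
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
        manifest["simulation"] = sim
    else:
        paths = config.inputs
        counts = io.read_counts(paths["counts"])
        samples = io.read_samples(paths["samples"], counts)
        if "gmt" in paths:
            gene_sets = io.read_gmt(paths["gmt"])
        if "kb" in paths:
            kb = io.read_kb(paths["kb"])
        for key, path in paths.items():
            manifest["inputs"][key] = _sha256(Path(path))

    manifest["records"]["genes_in"] = int(len(counts))
    manifest["records"]["samples"] = int(counts.shape[1])

    # ---- dge ------------------------------------------------------------
    results = []
    for subset_id in sorted(samples["subset_id"].unique()):
        res = dge.run_subset_dge(counts, samples, subset_id,
                                 shrinkage_weight=p["dispersion_shrinkage"])
        res.write_tsv(out / f"dge_{subset_id}.tsv")
        manifest["records"][f"genes_tested_{subset_id}"] = len(res.table)
        results.append(res)
    collection = consensus.ResultCollection(results)

    # ---- consensus ------------------------------------------------------
    consensus_genes: list[str] = []
    if config.stages["consensus"]:
        multi = consensus.multi_subset_degs(collection, p["fdr_threshold"],
                                            p["min_subsets"])
        multi.to_csv(out / "consensus_multi_subset.tsv", sep="\t",
                     index=False)
        cross = consensus.cross_mission_degs(collection, p["fdr_threshold"],
                                             p["min_missions"])
        pd.Series(cross, name="gene").to_csv(out / "consensus_cross_mission.tsv",
                                             sep="\t", index=False)
        upset = consensus.upset_counts(collection, p["fdr_threshold"])
        upset[upset["count"] > 0].to_csv(out / "upset_counts.tsv", sep="\t",
                                         index=False)
        consensus_genes = list(multi["gene"])
        manifest["records"]["multi_subset_degs"] = len(multi)
        manifest["records"]["cross_mission_degs"] = len(cross)
        if consensus_genes:
            values, mask = consensus.effect_matrix(collection,
                                                   consensus_genes, "log2FC",
                                                   p["fdr_threshold"])
            values.to_csv(out / "effect_matrix.tsv", sep="\t")
            mask.to_csv(out / "effect_matrix_mask.tsv", sep="\t")

    # ---- enrichment -----------------------------------------------------
    if config.stages["enrichment"] and gene_sets:
        tables = []
        for res in results:
            tab = res.table.dropna(subset=["stat"])
            ranked = pd.Series(tab["stat"].to_numpy(),
                               index=tab["gene"].to_numpy())
            g = enrichment.gsea(ranked, gene_sets,
                                min_size=p["gsea_min_size"],
                                n_perm=p["n_perm"],
                                weight=p["gsea_weight"], seed=config.seed)
            g.insert(0, "subset_id", res.subset_id)
            tables.append(g)
        pd.concat(tables, ignore_index=True).to_csv(
            out / "gsea.tsv", sep="\t", index=False)
        if consensus_genes:
            universe = collection.gene_universe()
            o = enrichment.ora(consensus_genes, universe, gene_sets,
                               min_size=p["ora_min_size"])
            o.to_csv(out / "ora_consensus.tsv", sep="\t", index=False)

    # ---- gene modules ---------------------------------------------------
    if config.stages["modules"]:
        factors = dge.estimate_size_factors(counts, pseudo_reference=True)
        logmat = gene_modules.log_normalize(counts, factors)
        emb, labels = gene_modules.module_pipeline(
            logmat, max_identical_fraction=p["max_identical_fraction"],
            min_variance=p["min_variance"], method=p["embed_method"],
            seed=config.seed, n_neighbors=p["umap_n_neighbors"],
            min_cluster_size=p["min_cluster_size"])
        emb.to_csv(out / "gene_embedding.tsv", sep="\t")
        labels.to_csv(out / "gene_clusters.tsv", sep="\t")
        manifest["records"]["genes_embedded"] = len(emb)
        manifest["records"]["gene_clusters"] = int(labels.max() + 1)
        if gene_sets and (labels >= 0).any():
            ann = gene_modules.annotate_clusters(labels, [gene_sets],
                                                 list(counts.index))
            for c, tab in ann.items():
                tab.to_csv(out / f"cluster_{c}_annotation.tsv", sep="\t",
                           index=False)

    # ---- pair models ----------------------------------------------------
    if config.stages["pairs"]:
        factors = dge.estimate_size_factors(counts, pseudo_reference=True)
        logmat = gene_modules.log_normalize(counts, factors)
        labels01 = (samples.set_index("sample_id")
                    .loc[logmat.columns, "condition"] == "flight").astype(int)
        pool = consensus_genes if consensus_genes else None
        if pool is not None and len(pool) < 2:
            pool = None
        models = pair_models.search_pairs(logmat, labels01.to_numpy(),
                                          gene_pool=pool,
                                          top_k=p["pair_top_k"],
                                          seed=config.seed,
                                          cv_top=p["pair_cv_top"])
        pair_models.models_table(models).to_csv(out / "pair_models.tsv",
                                                sep="\t", index=False)
        chosen = pair_models.select_mrmr(models, k=p["mrmr_k"])
        for i, m in enumerate(chosen):
            if m.gene_b is None:
                continue
            raster = pair_models.decision_boundary(
                m, logmat.loc[m.gene_a], logmat.loc[m.gene_b],
                grid_resolution=51)
            raster.to_csv(out / f"boundary_{i}_{m.gene_a}_{m.gene_b}.tsv",
                          sep="\t", index=False)
        manifest["records"]["pair_models"] = len(models)

    # ---- regulators ------------------------------------------------------
    if config.stages["regulators"] and kb is not None:
        tables = [regulators.activation_z(kb, res, p["fdr_threshold"])
                  for res in results]
        acts = pd.concat([t for t in tables if len(t)], ignore_index=True) \
            if any(len(t) for t in tables) else pd.DataFrame(
                columns=["regulator", "subset_id", "n_overlap",
                         "n_consistent", "n_inconsistent", "z", "pvalue",
                         "padj"])
        acts = regulators.classify_regulators(acts, p["z_threshold"],
                                              p["regulator_adj_p"])
        acts.to_csv(out / "regulator_activation.tsv", sep="\t", index=False)
        if len(acts):
            z = acts.pivot_table(index="regulator", columns="subset_id",
                                 values="z")
            order = regulators.cluster_zmatrix(z)
            z.loc[order["row_order"], order["col_order"]].to_csv(
                out / "regulator_zmatrix.tsv", sep="\t")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest
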