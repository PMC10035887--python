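"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis in stage order — annotation
transfer, orthogroup QC, per-site metrics, class-comparison statistics,
lineage-specific scans, enrichment — on either a synthetic dataset
generated from the run seed or user-supplied input files, and writes all
stage outputs plus a run manifest (configuration, seed, per-stage row
counts, warning count) to the output directory.  Identical configuration
and seed give identical outputs.

All thresholds default to the study values: binding frequency 0.10,
cross-validation precision 0.50 (0.75 for ions), pairwise similarity
80%, gaps 10%, minimum orthogroup size 10, allele-frequency cutoff 0.01,
fold-enrichment cutoff 2, FDR 0.05.  Any override is recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import annotation, enrichment, qc, scan, stats
from ._version import __version__
from .ortho import Orthogroup, read_orthogroup_fasta
from .phylo import PrimatePhylogeny, load_reference_tree
from .sitemetrics import SiteRateModel
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds in one place."""

    # input paths (ignored when synthetic is set)
    msa_dir: str | None = None
    tree_path: str | None = None
    profiles_path: str | None = None
    matches_path: str | None = None
    variants_path: str | None = None
    go_path: str | None = None
    # synthetic mode
    synthetic: SimulationConfig | None = None
    # thresholds (study defaults)
    binding_freq_cutoff: float = 0.10
    precision_cutoff: float = 0.50
    precision_cutoff_ion: float = 0.75
    similarity_threshold: float = 80.0
    gap_threshold: float = 10.0
    min_orthogroup_size: int = 10
    maf_threshold: float = 0.01
    fold_threshold: float = 2.0
    fdr_threshold: float = 0.05
    subst_model: str = "JTT"
    seed: int = 0
    outdir: str | None = None

    def overridden_thresholds(self) -> dict:
        defaults = PipelineConfig()
        keys = [
            "binding_freq_cutoff", "precision_cutoff", "precision_cutoff_ion",
            "similarity_threshold", "gap_threshold", "min_orthogroup_size",
            "maf_threshold", "fold_threshold", "fdr_threshold",
        ]
        return {
            k: getattr(self, k)
            for k in keys
            if getattr(self, k) != getattr(defaults, k)
        }


@dataclass
class PipelineResults:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    site_table: pd.DataFrame
    qc_table: pd.DataFrame
    conservation: pd.DataFrame
    class_tests: pd.DataFrame
    ligand_pairwise: pd.DataFrame
    human_calls: pd.DataFrame
    ape_strict_calls: pd.DataFrame
    ape_relaxed_calls: pd.DataFrame
    variable_genes: set[str]
    fold_table: pd.DataFrame
    go_results: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def summary(self) -> str:
        m = self.manifest["counts"]
        lines = [
            "Ligand-binding interface evolution pipeline",
            "=" * 62,
            f"Orthogroups analysed / input:  {m['orthogroups_retained']} / {m['orthogroups_input']}",
            f"Columns scored:                {m['columns_scored']}",
            f"Ligand-binding sites:          {m['binding_sites']}"
            f" ({m['binding_sites_conserved']} conserved)",
            f"Human-specific calls (pass):   {m['human_strict_pass']} / {m['human_strict_candidates']}",
            f"Great-ape relaxed calls:       {m['ape_relaxed_candidates']}",
            f"Variable-interface genes:      {m['variable_interface_genes']}",
            f"Fold >= 2 qualifying genes:    {m['fold_qualifying_genes']}",
            f"Enriched terms (FDR < {self.config.fdr_threshold:g}):   {m['enriched_terms']}",
            "=" * 62,
        ]
        return "\n".join(lines)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        ds = generate_dataset(config.synthetic)
        return ds.tree, ds.orthogroups, ds.profiles, ds.matches, ds.variants, ds.go_annotations
    if not config.msa_dir or not config.tree_path:
        raise ValueError("either synthetic config or msa_dir + tree_path are required")
    for path in [config.tree_path, config.profiles_path, config.matches_path]:
        if path and not os.path.exists(path):
            raise FileNotFoundError(path)
    tree = PrimatePhylogeny.from_file(config.tree_path)
    orthogroups = [
        read_orthogroup_fasta(os.path.join(config.msa_dir, f))
        for f in sorted(os.listdir(config.msa_dir))
        if f.endswith((".fa", ".fasta"))
    ]
    read = lambda p: pd.read_csv(p, sep="\t", comment="#") if p else pd.DataFrame()
    return (
        tree,
        orthogroups,
        read(config.profiles_path),
        read(config.matches_path),
        read(config.variants_path),
        read(config.go_path),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Run every stage in order and return a results bundle."""
    t_start = time.time()
    tree, orthogroups, profiles, matches, variants, go_ann = _load_inputs(config)
    thresholds = dict(
        freq_cutoff=config.binding_freq_cutoff,
        precision_cutoff=config.precision_cutoff,
        precision_cutoff_ion=config.precision_cutoff_ion,
    )
    stage_times: dict[str, float] = {}

    # ---- QC ----------------------------------------------------------
    t0 = time.time()
    retained: list[Orthogroup] = []
    qc_frames = []
    for og in orthogroups:
        report = qc.qc_orthogroup(
            og,
            matches,
            similarity_threshold=config.similarity_threshold,
            gap_threshold=config.gap_threshold,
            min_size=config.min_orthogroup_size,
        )
        filtered, report = qc.filter_orthogroup(og, report)
        qc_frames.append(report.table)
        if filtered is not None:
            retained.append(filtered)
    qc_table = pd.concat(qc_frames, ignore_index=True) if qc_frames else pd.DataFrame()
    stage_times["qc"] = time.time() - t0

    # ---- annotation + per-site metrics -------------------------------
    t0 = time.time()
    site_frames = []
    annotations: dict[str, pd.DataFrame] = {}
    for og in retained:
        ann = annotation.annotate_orthogroup(og, matches, profiles, **thresholds)
        annotations[og.orthogroup_id] = ann
        results = SiteRateModel(og, tree, config.subst_model).fit()
        merged = ann.merge(
            results.frame.drop(columns=["human_position"]),
            on=["orthogroup", "column"],
        )
        merged.insert(0, "gene", og.gene)
        site_frames.append(merged)
    site_table = (
        pd.concat(site_frames, ignore_index=True) if site_frames else pd.DataFrame()
    )
    stage_times["metrics"] = time.time() - t0

    # ---- class comparison stats --------------------------------------
    t0 = time.time()
    conservation = stats.conservation_table(site_table) if len(site_table) else pd.DataFrame()
    test_rows = []
    if len(site_table):
        for cls in ("other", "other_within_domain"):
            if conservation.loc[cls, "n_sites"] and conservation.loc["ligand_binding", "n_sites"]:
                table = stats.conserved_variable_2x2(conservation, "ligand_binding", cls)
                test_rows.append(
                    {
                        "test": f"fisher_conserved_binding_vs_{cls}",
                        "statistic": float("nan"),
                        "p": stats.fisher_exact_2x2(table),
                    }
                )
        scored = site_table.dropna(subset=["variable"])
        binding = scored[scored["class"] == annotation.CLASS_BINDING]
        other_dom = scored[scored["class"] == annotation.CLASS_OTHER_DOMAIN]
        if len(binding) and len(other_dom):
            for value in ("normalized_rate", "ml_rate", "entropy"):
                test_rows.append(
                    {
                        "test": f"mwu_{value}_binding_vs_other_within_domain",
                        "statistic": float("nan"),
                        "p": stats.mann_whitney_u(
                            binding[value].dropna(), other_dom[value].dropna()
                        ),
                    }
                )
    class_tests = pd.DataFrame(test_rows, columns=["test", "statistic", "p"])

    ligand_groups = stats.ligand_rate_groups(site_table) if len(site_table) else {}
    if len(ligand_groups) >= 2:
        h, p = stats.kruskal_wallis(list(ligand_groups.values()))
        class_tests.loc[len(class_tests)] = ["kruskal_wallis_ligand_rates", h, p]
        ligand_pairwise = stats.conover_posthoc(ligand_groups)
    else:
        ligand_pairwise = pd.DataFrame()
    stage_times["stats"] = time.time() - t0

    # ---- lineage-specific scans --------------------------------------
    t0 = time.time()
    human_taxa = tree.clade_sets.get("human", {"Homo_sapiens"})
    ape_taxa = tree.clade_sets.get("great_apes", set())
    human_calls, ape_strict, ape_relaxed = [], [], []
    for og in retained:
        ann = annotations[og.orthogroup_id]
        human_calls += scan.scan_lineage_specific(og, ann, human_taxa, "strict")
        if ape_taxa:
            ape_strict += scan.scan_lineage_specific(og, ann, ape_taxa, "strict")
            ape_relaxed += scan.scan_lineage_specific(og, ann, ape_taxa, "relaxed")
    human_calls = scan.apply_population_filter(human_calls, variants, config.maf_threshold)
    ape_strict = scan.apply_population_filter(ape_strict, variants, config.maf_threshold)
    ape_relaxed = scan.apply_population_filter(ape_relaxed, variants, config.maf_threshold)
    human_frame = scan.calls_to_frame(human_calls)
    ape_strict_frame = scan.calls_to_frame(ape_strict)
    ape_relaxed_frame = scan.calls_to_frame(ape_relaxed)
    stage_times["scan"] = time.time() - t0

    # ---- enrichment ---------------------------------------------------
    t0 = time.time()
    if len(site_table):
        background = set(
            site_table.loc[site_table["class"] == annotation.CLASS_BINDING, "gene"]
        )
        variable_genes = enrichment.variable_interface_genes(
            site_table, variants, config.maf_threshold
        ) & background
        fold_table = enrichment.fold_enrichment_table(
            site_table,
            fold_threshold=config.fold_threshold,
        )
        go_results = (
            enrichment.go_overrepresentation(
                variable_genes, background, go_ann, config.fdr_threshold
            )
            if len(go_ann) and variable_genes
            else pd.DataFrame(columns=["term_id", "study_k", "study_n", "bg_k", "bg_n", "p", "fdr", "significant"])
        )
    else:
        variable_genes, fold_table = set(), pd.DataFrame()
        go_results = pd.DataFrame()
    stage_times["enrichment"] = time.time() - t0

    # ---- manifest -----------------------------------------------------
    scored = site_table.dropna(subset=["variable"]) if len(site_table) else site_table
    binding_sites = (
        scored[scored["class"] == annotation.CLASS_BINDING] if len(scored) else scored
    )
    counts = {
        "orthogroups_input": len(orthogroups),
        "orthogroups_retained": len(retained),
        "columns_scored": int(len(scored)),
        "binding_sites": int(len(binding_sites)),
        "binding_sites_conserved": int((~binding_sites["variable"].astype(bool)).sum())
        if len(binding_sites)
        else 0,
        "human_strict_candidates": len(human_frame),
        "human_strict_pass": int(human_frame["population_pass"].sum())
        if len(human_frame)
        else 0,
        "ape_strict_candidates": len(ape_strict_frame),
        "ape_relaxed_candidates": len(ape_relaxed_frame),
        "variable_interface_genes": len(variable_genes),
        "fold_qualifying_genes": int(fold_table["qualifies"].sum())
        if len(fold_table)
        else 0,
        "enriched_terms": int(go_results["significant"].sum()) if len(go_results) else 0,
    }
    cfg_dict = dataclasses.asdict(config)
    if config.synthetic is not None:
        cfg_dict["synthetic"] = dataclasses.asdict(config.synthetic)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    for name, seconds in stage_times.items():
        logger.info("stage %s finished in %.2fs", name, seconds)
    logger.info("pipeline finished in %.2fs", time.time() - t_start)
    # timings stay out of the manifest so identical runs are byte-identical
    manifest = {
        "ligevo_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "threshold_overrides": config.overridden_thresholds(),
        "counts": counts,
    }

    results = PipelineResults(
        config=config,
        site_table=site_table,
        qc_table=qc_table,
        conservation=conservation,
        class_tests=class_tests,
        ligand_pairwise=ligand_pairwise,
        human_calls=human_frame,
        ape_strict_calls=ape_strict_frame,
        ape_relaxed_calls=ape_relaxed_frame,
        variable_genes=variable_genes,
        fold_table=fold_table,
        go_results=go_results,
        manifest=manifest,
    )
    if config.outdir:
        write_results(results, config.outdir)
    return results


def write_results(results: PipelineResults, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    kw = dict(sep="\t", index=False)
    results.site_table.to_csv(os.path.join(outdir, "site_metrics.tsv"), **kw)
    results.qc_table.to_csv(os.path.join(outdir, "qc_report.tsv"), **kw)
    results.conservation.to_csv(os.path.join(outdir, "conservation_summary.tsv"), sep="\t")
    results.class_tests.to_csv(os.path.join(outdir, "class_tests.tsv"), **kw)
    results.ligand_pairwise.to_csv(os.path.join(outdir, "ligand_pairwise.tsv"), **kw)
    results.human_calls.to_csv(os.path.join(outdir, "human_specific_calls.tsv"), **kw)
    results.ape_strict_calls.to_csv(os.path.join(outdir, "ape_strict_calls.tsv"), **kw)
    results.ape_relaxed_calls.to_csv(os.path.join(outdir, "ape_relaxed_calls.tsv"), **kw)
    results.fold_table.to_csv(os.path.join(outdir, "fold_enrichment.tsv"), **kw)
    results.go_results.to_csv(os.path.join(outdir, "go_enrichment.tsv"), **kw)
    pd.Series(sorted(results.variable_genes), name="gene").to_csv(
        os.path.join(outdir, "variable_interface_genes.tsv"), **kw
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as handle:
        json.dump(results.manifest, handle, indent=2, sort_keys=True)
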