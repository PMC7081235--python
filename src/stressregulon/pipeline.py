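"""End-to-end orchestration: preprocess → DE → regulons → response → enrichment → report.

`run_all` drives the whole pipeline from a :class:`PipelineConfig` (paths +
thresholds); `run_pipeline` is the in-memory core used by tests and the
acceptance machinery.  Contrasts are enumerated from the design
automatically: per genotype × stress, early-vs-control and late-vs-control;
per stress × timepoint, each mutant vs wild type.  Every stage is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    AnnotationMap,
    CountExperiment,
    GeneSet,
    ValidationError,
    read_counts,
    read_family_map,
    read_gmt,
    read_module_map,
    write_results,
)
from .diffexp import Contrast, call_degs, estimate_dispersions, nb_wald
from .enrichment import (
    enrich_annotation,
    module_enrichment,
    permutation_enrich,
    summarize_families,
    wave_groups,
)
from .preprocess import filter_detected, pca, size_factors, vst, zscore_rows
from .regulons import RegulonSet, build_regulons, cluster_fc_summary, hcluster_expression
from .response import antagonism_overlap, response_calls


@dataclass
class PipelineConfig:
    """All paths and thresholds of a pipeline run."""

    counts: str | None = None
    design: str | None = None
    gmt: str | None = None
    family: str | None = None
    modules: str | None = None
    lengths: str | None = None
    out_dir: str = "results"
    wild_type: str = "col0"
    alpha: float = 0.01          # BH-adjusted DEG threshold
    lfc: float = 0.5             # |log2FC| DEG threshold
    tfbs_alpha: float = 0.01     # raw threshold, genome-background TFBS screen
    perm_alpha: float = 0.05     # permutation threshold, regulon background
    n_perm: int = 10_000
    module_p_cut: float = 1e-5
    module_min_size: int = 50
    k_clusters: int = 5
    min_count: int = 2
    min_samples: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "tfbs_alpha", "perm_alpha", "module_p_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name}={v} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class ResultBundle:
    """Everything the pipeline computed, for report assembly and inspection."""

    experiment: CountExperiment
    sf: pd.Series
    dispersions: pd.Series
    regulons: RegulonSet
    wt_tables: dict[str, pd.DataFrame]
    mutant_early_tables: dict[tuple[str, str], pd.DataFrame]
    control_tables: dict[tuple[str, str], pd.DataFrame]
    control_sets: dict[tuple[str, str], tuple[GeneSet, GeneSet]]
    response: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_varfrac: np.ndarray
    clusters: pd.Series | None = None
    cluster_summary: pd.DataFrame | None = None
    tfbs: dict[str, pd.DataFrame] = field(default_factory=dict)
    tfbs_families: dict[str, pd.DataFrame] = field(default_factory=dict)
    waves: pd.DataFrame | None = None
    nonresp_enrichment: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    module_tests: pd.DataFrame | None = None
    antagonism: pd.DataFrame | None = None


def _mutants(experiment: CountExperiment, wild_type: str) -> list[str]:
    genotypes = list(dict.fromkeys(experiment.design["genotype"]))
    if wild_type not in genotypes:
        raise ValidationError(f"wild type {wild_type!r} absent from design")
    return [g for g in genotypes if g != wild_type]


def run_pipeline(experiment: CountExperiment,
                 config: PipelineConfig,
                 binding_map: AnnotationMap | None = None,
                 modules: AnnotationMap | None = None) -> ResultBundle:
    """Run every stage on an in-memory experiment."""
    config.validate()
    stresses = tuple(dict.fromkeys(experiment.design["stress"]))
    if len(stresses) != 3:
        raise ValidationError(f"expected 3 stresses, found {stresses}")
    mutants = _mutants(experiment, config.wild_type)

    experiment = filter_detected(experiment, config.min_count, config.min_samples)
    sf = size_factors(experiment)
    vst_matrix = vst(experiment, sf)
    scores, varfrac = pca(vst_matrix, n_components=3)
    dispersions = estimate_dispersions(experiment, sf)

    regulons, wt_tables = build_regulons(
        experiment, config.wild_type, stresses, dispersions, sf,
        alpha=config.alpha, lfc=config.lfc)

    # mutant early-vs-control per stress
    mutant_early: dict[tuple[str, str], pd.DataFrame] = {}
    for mutant in mutants:
        for stress in stresses:
            contrast = Contrast((mutant, stress, "control"),
                                (mutant, stress, "early"),
                                label=f"{mutant}_{stress}_early_vs_control")
            table = nb_wald(experiment, contrast, dispersions, sf)
            table, _, _ = call_degs(table, alpha=config.alpha, lfc=config.lfc)
            mutant_early[(mutant, stress)] = table

    # mutant vs wild type at control, per stress experiment (growth systems
    # are kept separate by conditioning on the stress experiment)
    control_tables: dict[tuple[str, str], pd.DataFrame] = {}
    control_sets: dict[tuple[str, str], tuple[GeneSet, GeneSet]] = {}
    for mutant in mutants:
        for stress in stresses:
            contrast = Contrast((config.wild_type, stress, "control"),
                                (mutant, stress, "control"),
                                label=f"{mutant}_vs_{config.wild_type}_{stress}_control")
            table = nb_wald(experiment, contrast, dispersions, sf)
            table, up, down = call_degs(table, alpha=config.alpha,
                                        lfc=config.lfc,
                                        label=f"{mutant}_{stress}_control")
            control_tables[(mutant, stress)] = table
            control_sets[(mutant, stress)] = (up, down)

    # response calls for both EARLY regulons
    frames = []
    for mutant in mutants:
        for stress in stresses:
            for regulon in (regulons.early_up, regulons.early_down):
                frames.append(response_calls(
                    regulon, mutant, stress, "early",
                    mutant_early[(mutant, stress)],
                    control_tables[(mutant, stress)],
                    alpha=config.alpha, lfc=config.lfc))
    response = pd.concat(frames, ignore_index=True)

    # co-expression clustering of the wild-type response (DEG union per run)
    deg_union = sorted(set().union(*(gs.genes for gs in regulons.inputs.values())))
    clusters = None
    cluster_summary = None
    if len(deg_union) >= config.k_clusters:
        wt_mask = experiment.sample_mask(genotype=config.wild_type)
        sub = vst_matrix.values[[experiment.genes.index(g) for g in deg_union]]
        from .preprocess import NormalizedMatrix
        z = zscore_rows(NormalizedMatrix(deg_union,
                                         [s for s, m in zip(experiment.samples, wt_mask) if m],
                                         sub[:, wt_mask], "vst"))
        clusters = hcluster_expression(z, k=config.k_clusters)
        cluster_summary = cluster_fc_summary(clusters, wt_tables)

    bundle = ResultBundle(
        experiment=experiment, sf=sf, dispersions=dispersions,
        regulons=regulons, wt_tables=wt_tables,
        mutant_early_tables=mutant_early, control_tables=control_tables,
        control_sets=control_sets, response=response,
        pca_scores=scores, pca_varfrac=varfrac,
        clusters=clusters, cluster_summary=cluster_summary,
    )

    # ---- enrichment stages (optional inputs) -----------------------------
    if binding_map is not None and len(binding_map):
        background = GeneSet("detected", frozenset(experiment.genes))
        summaries = {}
        for name in ("early_up", "early_down", "late_up", "late_down"):
            regulon = regulons.get(name)
            if not regulon.genes:
                continue
            res = enrich_annotation(
                GeneSet(name, regulon.genes), background, binding_map,
                alpha=config.tfbs_alpha, correction="none")
            bundle.tfbs[name] = res
            fam = summarize_families(res, allow_unassigned=True)
            bundle.tfbs_families[name] = fam
            summaries[name] = fam
        if summaries:
            bundle.waves = wave_groups(summaries)

        # non-responsive sets against the EARLY UP background (permutation
        # null corrects for the small background population)
        eu = regulons.early_up
        if eu.genes:
            nonresp_by = response[(response["regulon"] == "early_up")
                                  & (response["status"] == "non_responsive")]
            for (mutant, stress), sub in nonresp_by.groupby(["mutant", "stress"]):
                query = GeneSet(f"{mutant}_{stress}_nonresponsive",
                                frozenset(sub["gene"]), direction="up")
                if not query.genes:
                    continue
                bundle.nonresp_enrichment[(mutant, stress)] = permutation_enrich(
                    query, GeneSet("early_up", eu.genes), binding_map,
                    n_perm=config.n_perm, alpha=config.perm_alpha,
                    seed=config.seed)

    if modules is not None and len(modules):
        eu = regulons.early_up
        if eu.genes:
            population = GeneSet("early_up", eu.genes)
            queries = {}
            nonresp_by = response[(response["regulon"] == "early_up")
                                  & (response["status"] == "non_responsive")]
            for (mutant, stress), sub in nonresp_by.groupby(["mutant", "stress"]):
                queries[f"{mutant}_{stress}"] = GeneSet(
                    f"{mutant}_{stress}", frozenset(sub["gene"]))
            m_tests = max(1, len(queries) * len(modules))
            rows = []
            for name, query in queries.items():
                res = module_enrichment(query, modules, population, m_tests)
                res.insert(0, "gene_set", name)
                rows.append(res)
            if rows:
                bundle.module_tests = pd.concat(rows, ignore_index=True)

    # cross-genotype antagonism at control: each mutant's control down-set vs
    # the other mutants' control up-sets (pooled across stress experiments)
    antag_rows = []
    for mutant in mutants:
        down_genes = frozenset().union(
            *(control_sets[(mutant, s)][1].genes for s in stresses))
        reference = GeneSet(f"{mutant}_control_down", down_genes, "down")
        comparisons = {
            other: GeneSet(f"{other}_control_up", frozenset().union(
                *(control_sets[(other, s)][0].genes for s in stresses)), "up")
            for other in mutants if other != mutant}
        table = antagonism_overlap(reference, comparisons)
        table.insert(0, "reference", mutant)
        antag_rows.append(table)
    bundle.antagonism = pd.concat(antag_rows, ignore_index=True)
    return bundle


def report(bundle: ResultBundle) -> dict[str, pd.DataFrame]:
    """Assemble machine-readable summary tables from a result bundle."""
    tables: dict[str, pd.DataFrame] = {}

    tables["regulon_sizes"] = pd.DataFrame(
        [{"regulon": name, "size": len(bundle.regulons.get(name).genes)}
         for name in ("early_up", "early_down", "late_up", "late_down")])

    venn_rows = []
    for name, regions in bundle.regulons.venn.items():
        for pattern, count in regions.items():
            venn_rows.append({"regulon": name, "pattern": pattern, "count": count})
    tables["venn_regions"] = pd.DataFrame(venn_rows)

    resp = bundle.response
    nonresp = resp[resp["status"] == "non_responsive"]
    counts = (nonresp.groupby(["mutant", "stress", "regulon"])
              .size().rename("n_non_responsive").reset_index())
    tables["nonresponsive_counts"] = counts

    mech = (nonresp.groupby(["mutant", "regulon", "mechanism"])
            .size().rename("n_genes").reset_index())
    tables["mechanism_counts"] = mech

    lr_frac_rows = []
    for mutant, sub in nonresp[nonresp["regulon"] == "early_up"].groupby("mutant"):
        genes = sub.drop_duplicates("gene")
        n_lr = int((genes["mechanism"] == "LR").sum())
        lr_frac_rows.append({"mutant": mutant, "n_non_responsive": len(genes),
                             "n_lr": n_lr,
                             "lr_fraction": n_lr / len(genes) if len(genes) else np.nan})
    tables["lr_fractions"] = pd.DataFrame(lr_frac_rows)

    tables["response_calls"] = resp
    tables["pca_scores"] = bundle.pca_scores.reset_index(names="sample")
    tables["pca_variance"] = pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(bundle.pca_varfrac))],
         "variance_fraction": bundle.pca_varfrac})
    if bundle.antagonism is not None:
        tables["antagonism"] = bundle.antagonism
    if bundle.cluster_summary is not None:
        tables["cluster_fc_summary"] = bundle.cluster_summary
    if bundle.clusters is not None:
        tables["clusters"] = bundle.clusters.rename_axis("gene").reset_index()
    for name, fam in bundle.tfbs_families.items():
        tables[f"tfbs_families_{name}"] = fam
    if bundle.waves is not None:
        tables["wave_groups"] = bundle.waves
    if bundle.module_tests is not None:
        tables["module_enrichment"] = bundle.module_tests
    return tables


def run_all(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """File-driven entry point: read inputs, run the pipeline, write results."""
    if not config.counts or not config.design:
        raise ValidationError("config must provide counts and design paths")
    experiment = read_counts(config.counts, config.design)
    binding_map = None
    if config.gmt:
        family = read_family_map(config.family) if config.family else None
        binding_map = read_gmt(config.gmt, family=family)
    modules = read_module_map(config.modules) if config.modules else None
    bundle = run_pipeline(experiment, config, binding_map=binding_map,
                          modules=modules)
    tables = report(bundle)
    write_results(tables, config.out_dir, seed=config.seed,
                  config=asdict(config))
    return tables
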