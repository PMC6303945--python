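"""End-to-end orchestration: simulate/load -> networks -> reports.

The pipeline chains every stage of the methodology: cohort simulation
(or user data), eQTL scan, causal inference test, structural priors,
MCMC consensus network with de-loop, key driver analysis, seed-centric
consensus correlation networks, knockout DEG signatures, enrichment and
projection.  Every stage persists its artifacts under the output
directory as plain text, and a machine-readable JSON summary captures
the headline results (top key drivers, regulator rank, CGCCS sizes,
enrichment table, projection counts) together with the seed and a
configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .bayesnet import (
    McmcConfig,
    consensus_average,
    deloop,
    extract_neighborhood,
    mcmc_structure_search,
)
from .consensus_corr import cgccs, directional_vote, seed_correlations
from .datatypes import Cohort, CohortCollection, ExpressionMatrix, TraitTable
from .eqtl_cit import build_priors, enumerate_trios, eqtl_scan, run_cit_for_trios
from .keydriver import key_driver_analysis, write_keydriver_tsv
from .signatures import (
    SignatureSet,
    call_degs,
    deg_sets,
    enrichment_table,
    fisher_enrichment,
    project_signatures,
)
from .simulate import (
    SimulationConfig,
    TrueNetwork,
    generate_true_dag,
    simulate_cohorts,
    simulate_knockout,
    simulate_traits,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run settings for the full pipeline.

    ``mode`` is ``simulate`` (generate cohorts with ground truth) or
    ``user-data`` (read expression/genotype/trait files).  Thresholds
    cover every stage; paths are only consulted in user-data mode.
    """

    mode: str = "simulate"
    out_dir: str = "drivernet_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    eqtl_fdr: float = 0.05
    cit_alpha: float = 0.05
    cit_permutations: int = 500
    trio_p_threshold: float = 0.01
    max_pairs_per_locus: int = 200
    deg_fc_threshold: float = 1.2
    deg_q_threshold: float = 0.05
    corr_fdr: float = 0.05
    kda_h: int = 6
    kda_m: float = 2.0
    neighborhood_depth: int = 3
    neighborhood_trim: bool = True
    seed_gene: str | None = None  # defaults to the planted regulator
    expression_paths: list[str] = field(default_factory=list)
    genotype_path: str | None = None
    traits_paths: list[str] = field(default_factory=list)
    tf_edges_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "user-data"):
            raise ValueError("mode must be 'simulate' or 'user-data'")
        for name in ("eqtl_fdr", "cit_alpha", "deg_q_threshold", "corr_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.deg_fc_threshold < 1.0:
            raise ValueError("fold-change threshold is on the linear scale (>= 1)")
        if self.mode == "user-data":
            missing = [p for p in self.expression_paths if not Path(p).exists()]
            if not self.expression_paths:
                raise ValueError("user-data mode needs expression_paths")
            if missing:
                raise FileNotFoundError(f"missing expression files: {missing}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if "beta_range" in sim:
                sim["beta_range"] = tuple(sim["beta_range"])
            if "sigma_range" in sim:
                sim["sigma_range"] = tuple(sim["sigma_range"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            d["simulation"] = SimulationConfig(**sim)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = McmcConfig(**d["mcmc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = dataclasses.replace(self.simulation, seed=seed)
        mc = dataclasses.replace(self.mcmc, seed=seed)
        return dataclasses.replace(self, seed=seed, simulation=sim, mcmc=mc)


# ---------------------------------------------------------------------------
# reusable inference block
# ---------------------------------------------------------------------------

def infer_network(
    expr: ExpressionMatrix,
    geno=None,
    tf_edges=None,
    mcmc: McmcConfig | None = None,
    cit_alpha: float = 0.05,
    cit_permutations: int = 500,
    trio_p_threshold: float = 0.01,
    max_pairs_per_locus: int = 200,
    eqtl_fdr: float = 0.05,
    seed: int = 0,
):
    """eQTL -> CIT -> priors -> MCMC consensus -> de-loop, in one call.

    Returns a dict with the eQTL table, CIT results, prior edges, the
    raw consensus network, the de-looped DAG and the removed edges.
    """
    mcmc = mcmc or McmcConfig(seed=seed)
    hits = pd.DataFrame(columns=["gene", "locus", "slope", "F", "p", "q", "significant"])
    cit_results: list = []
    if geno is not None and len(geno.loci):
        hits = eqtl_scan(expr, geno, fdr_threshold=eqtl_fdr)
        trios = enumerate_trios(
            hits, max_pairs_per_locus=max_pairs_per_locus, p_threshold=trio_p_threshold
        )
        cit_results = run_cit_for_trios(
            expr, geno, trios, B=cit_permutations, alpha=cit_alpha, seed=seed
        )
    priors = build_priors(cit_results, tf_edges=tf_edges, alpha=cit_alpha)
    dags = mcmc_structure_search(expr, priors, mcmc)
    consensus = consensus_average(dags, mcmc.consensus_threshold)
    result = deloop(consensus)
    return {
        "eqtl": hits,
        "cit": cit_results,
        "priors": priors,
        "consensus": consensus,
        "dag": result.network,
        "removed_edges": result.removed,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: PipelineConfig):
    """Generate truth + cohorts + traits + knockouts; persist everything."""
    out = _outdir(config)
    sim = config.simulation
    truth = generate_true_dag(sim)
    cohorts = simulate_cohorts(truth, sim)
    simulate_traits(cohorts, truth, sim)
    truth.edge_frame().to_csv(out / "truth_edges.tsv", sep="\t", index=False)
    dio.write_gmt(
        {"module": truth.module, "regulator": {truth.regulator}},
        out / "truth_module.gmt",
    )
    for cohort in cohorts:
        dio.write_expression_tsv(cohort.expression, out / f"{cohort.dataset}_expression.tsv")
        if cohort.genotypes is not None:
            dio.write_genotype_tsv(cohort.genotypes, out / f"{cohort.dataset}_genotypes.tsv")
            dio.write_minimal_vcf(cohort.genotypes, out / f"{cohort.dataset}_genotypes.vcf")
        if cohort.traits is not None:
            dio.write_traits_csv(cohort.traits, out / f"{cohort.dataset}_traits.csv")
    knockouts = {
        "AST": simulate_knockout(truth, sim, contrast="AST", seed_offset=0),
        "AST+NEU": simulate_knockout(truth, sim, contrast="AST_NEU", seed_offset=1),
    }
    for name, ko in knockouts.items():
        tag = name.replace("+", "_")
        dio.write_expression_tsv(ko.wildtype, out / f"knockout_{tag}_wildtype.tsv")
        dio.write_expression_tsv(ko.knockout, out / f"knockout_{tag}_knockout.tsv")
    dio.write_gmt(
        {
            "true_degs_up": knockouts["AST"].true_degs.up,
            "true_degs_dn": knockouts["AST"].true_degs.down,
        },
        out / "true_degs.gmt",
    )
    return truth, cohorts, knockouts


def stage_network(config: PipelineConfig, expr, geno, tf_edges=None):
    """Infer the consensus DAG and run key driver analysis; persist."""
    out = _outdir(config)
    res = infer_network(
        expr,
        geno,
        tf_edges=tf_edges,
        mcmc=config.mcmc,
        cit_alpha=config.cit_alpha,
        cit_permutations=config.cit_permutations,
        trio_p_threshold=config.trio_p_threshold,
        max_pairs_per_locus=config.max_pairs_per_locus,
        eqtl_fdr=config.eqtl_fdr,
        seed=config.seed,
    )
    res["eqtl"].to_csv(out / "eqtl_hits.tsv", sep="\t", index=False)
    pd.DataFrame([c.as_row() for c in res["cit"]]).to_csv(
        out / "cit_results.tsv", sep="\t", index=False
    )
    dio.write_prior_tsv(res["priors"], out / "prior_edges.tsv")
    dio.write_edge_tsv(res["consensus"], out / "consensus_network.tsv")
    dio.write_edge_tsv(res["dag"], out / "consensus_dag.tsv")
    dio.write_sif(res["dag"], out / "consensus_dag.sif")
    pd.DataFrame(
        res["removed_edges"], columns=["source", "target", "weight"]
    ).to_csv(out / "deloop_removed.tsv", sep="\t", index=False)
    kda = key_driver_analysis(res["dag"], h=config.kda_h, m=config.kda_m)
    write_keydriver_tsv(kda, out / "key_drivers.tsv")
    res["kda"] = kda
    return res


def stage_cgccs(config: PipelineConfig, cohorts: CohortCollection, seed_gene: str):
    """Per-cohort seed correlations (disease samples), voting, CGCCS family."""
    out = _outdir(config)
    records = []
    for cohort in cohorts:
        try:
            samples = cohort.ad_samples
        except ValueError:
            samples = cohort.expression.samples
        if not samples:
            samples = cohort.expression.samples
        records.append(
            seed_correlations(
                cohort.expression, seed_gene, samples, fdr_threshold=config.corr_fdr
            )
        )
    stacked = pd.concat(records, ignore_index=True)
    stacked.to_csv(out / "seed_correlations.tsv", sep="\t", index=False)
    tallies = directional_vote(stacked)
    tallies.to_csv(out / "vote_tallies.tsv", sep="\t", index=False)
    n_datasets = len(cohorts)
    family = {}
    for n in range(1, n_datasets + 1):
        net = cgccs(tallies, n, n_datasets, seed_gene=seed_gene)
        family[n] = net
        net.members.to_csv(out / f"cgccs_{n}.tsv", sep="\t", index=False)
    return tallies, family


def stage_degs(config: PipelineConfig, knockouts: dict):
    """Knockout DEG calling for each contrast; returns tables and sets."""
    out = _outdir(config)
    tables = {}
    sets: dict[str, set] = {}
    for name, ko in knockouts.items():
        degs = call_degs(
            ko.knockout,
            ko.wildtype,
            fc_threshold=config.deg_fc_threshold,
            q_threshold=config.deg_q_threshold,
            contrast=name,
        )
        tag = name.replace("+", "_")
        degs.to_csv(out / f"degs_{tag}.tsv", sep="\t", index=False)
        tables[name] = degs
        sets.update(deg_sets(degs, name))
    universe = set(next(iter(knockouts.values())).wildtype.genes)
    signatures = SignatureSet(sets=sets, universe=universe)
    dio.write_gmt({k: v for k, v in sets.items()}, out / "deg_signatures.gmt")
    return tables, signatures


def stage_enrich(
    config: PipelineConfig,
    signatures: SignatureSet,
    module: set[str],
    cgccs_family: dict,
):
    """DEG-signature enrichment in the module and in each CGCCS(n)."""
    out = _outdir(config)
    results = []
    universe = signatures.universe
    for name, members in signatures.sets.items():
        if not members:
            continue
        if module:
            results.append(
                fisher_enrichment(members, module, universe, name, "module")
            )
        for n, net in cgccs_family.items():
            ref = net.genes & universe
            if ref:
                results.append(
                    fisher_enrichment(members, ref, universe, name, f"CGCCS({n})")
                )
    table = enrichment_table(results)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dictionary."""
    out = _outdir(config)
    summary: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    stage = "simulate"
    try:
        if config.mode == "simulate":
            truth, cohorts, knockouts = stage_simulate(config)
            seed_gene = config.seed_gene or truth.regulator
            module = truth.module
            expr = ExpressionMatrix(
                cohorts[0].expression.values.loc[:, cohorts[0].control_samples]
                if cohorts[0].traits is not None and config.simulation.n_control
                else cohorts[0].expression.values,
                value_kind="residual",
                dataset=cohorts[0].dataset,
            )
            geno = None
            if cohorts[0].genotypes is not None:
                geno = cohorts[0].genotypes.aligned_to(expr)
            tf_edges = None
        else:
            truth = None
            knockouts = {}
            module = set()
            cohort_list = []
            for i, path in enumerate(config.expression_paths):
                e = dio.read_expression_tsv(path, value_kind="residual")
                traits = None
                if i < len(config.traits_paths):
                    traits = dio.read_traits_csv(config.traits_paths[i])
                cohort_list.append(Cohort(e.dataset, e, None, traits))
            cohorts = CohortCollection(cohort_list)
            expr = cohorts[0].expression
            geno = None
            if config.genotype_path:
                gp = config.genotype_path
                geno = (
                    dio.read_minimal_vcf(gp)
                    if gp.endswith(".vcf")
                    else dio.read_genotype_tsv(gp)
                )
                geno = geno.aligned_to(expr)
            if config.seed_gene is None:
                raise ValueError("user-data mode requires seed_gene")
            seed_gene = config.seed_gene
            tf_edges = (
                dio.read_tf_edges(config.tf_edges_path)
                if config.tf_edges_path
                else None
            )

        stage = "network"
        net = stage_network(config, expr, geno, tf_edges)
        kda = net["kda"]
        summary["n_consensus_edges"] = int(net["consensus"].number_of_edges())
        summary["n_dag_edges"] = int(net["dag"].number_of_edges())
        summary["n_prior_edges"] = int(len(net["priors"]))
        summary["top_key_drivers"] = kda.head(10)[
            ["node", "downstream", "rank"]
        ].to_dict("records")
        summary["key_drivers"] = list(kda.loc[kda["is_key_driver"], "node"])
        if seed_gene in set(kda["node"]):
            summary["seed_gene_rank"] = int(
                kda.loc[kda["node"] == seed_gene, "rank"].iloc[0]
            )

        stage = "neighborhood"
        hood = extract_neighborhood(
            net["dag"],
            seed_gene,
            depth=config.neighborhood_depth,
            trim=config.neighborhood_trim,
        )
        dio.write_sif(hood, out / "seed_neighborhood.sif")
        summary["neighborhood_size"] = int(hood.number_of_nodes())

        stage = "cgccs"
        tallies, family = stage_cgccs(config, cohorts, seed_gene)
        summary["cgccs_sizes"] = {
            int(n): int(len(net_.genes)) for n, net_ in family.items()
        }

        if knockouts:
            stage = "degs"
            deg_tables, signatures = stage_degs(config, knockouts)
            summary["deg_counts"] = {
                f"{name}({d})": int(
                    (
                        (t["direction"] == d) & t["significant"]
                    ).sum()
                )
                for name, t in deg_tables.items()
                for d in ("up", "dn")
            }

            stage = "enrich"
            enr = stage_enrich(config, signatures, module, family)
            summary["enrichment"] = enr.to_dict("records")

            stage = "project"
            sig4 = SignatureSet(
                sets={
                    "AST(up)": signatures.sets.get("AST(up)", set()),
                    "AST(dn)": signatures.sets.get("AST(dn)", set()),
                    "AST+NEU(up)": signatures.sets.get("AST+NEU(up)", set()),
                    "AST+NEU(dn)": signatures.sets.get("AST+NEU(dn)", set()),
                },
                universe=signatures.universe,
            )
            labels, counts = project_signatures(net["dag"].nodes, sig4)
            labels.rename_axis("gene").reset_index().to_csv(
                out / "projection_labels.tsv", sep="\t", index=False
            )
            summary["projection_counts"] = {k: int(v) for k, v in counts.items()}
    except Exception as err:
        summary["failed_stage"] = stage
        summary["error"] = str(err)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
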