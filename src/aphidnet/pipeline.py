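"""Configuration-driven orchestration of the full analysis pipeline.

Stages run in a fixed order -- normalize, expression filter, differential
expression, network + TOM, module detection, target-TF selection,
subnetworks, enrichment, occupancy, report -- and every stage's output is
written as a TSV into the output directory.  Identical configuration and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression, io, network, report, simulate, targets
from . import enrichment as enrich
from .containers import (
    ConfigError,
    ExpressionMatrix,
    GeneAnnotation,
    MetaboliteTable,
    PipelineError,
    SampleDesign,
)

__all__ = ["SimulationConfig", "PipelineConfig", "run_pipeline", "simulate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator."""

    n_genes_per_module: int = 150
    n_background: int = 1100
    n_reps: int = 3
    effect_size: float = 3.0
    noise_sd: float = 0.3
    dispersion: float = 0.02
    n_hubs_per_module: int = 3
    n_pathways: int = 40
    pathway_size: int = 50
    enrichment_fraction: float = 0.9
    n_background_tfs: int = 30
    metabolites_per_set: int = 25
    null_metabolites: int = 100
    metabolite_effect: float = 1.0
    metabolite_noise_sd: float = 0.3

    def validate(self) -> None:
        if self.n_genes_per_module <= 0:
            raise ConfigError("n_genes_per_module must be positive")
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2")
        if not 0 < self.enrichment_fraction <= 1:
            raise ConfigError("enrichment_fraction must be in (0, 1]")


@dataclass
class PipelineConfig:
    """Thresholds, network parameters, and the single pipeline seed."""

    seed: int = 1
    fdr_alpha: float = 0.05
    min_fold: float = 2.0
    min_mean: float = 1.0
    q_kme: float = 0.10
    peak_pct: float = 0.75
    q_subnet: float = 0.01
    fisher_alpha: float = 0.05
    anova_alpha: float = 0.05
    beta: float | None = None
    candidate_betas: list[float] = field(
        default_factory=lambda: list(network.DEFAULT_BETAS)
    )
    min_module_size: int = 30
    cut_height: float = 0.78
    merge_threshold: float = 0.9
    activity_fraction: float = 0.5
    top_n_genes: int = 200
    save_tom: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        for name in ("fdr_alpha", "fisher_alpha", "anova_alpha"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {value}")
        for name in ("q_kme", "peak_pct", "q_subnet", "activity_fraction"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {value}")
        if self.min_fold < 1:
            raise ConfigError("min_fold must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ConfigError("cut_height must be in (0, 1]")
        if not 0 < self.merge_threshold <= 1:
            raise ConfigError("merge_threshold must be in (0, 1]")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        if not self.candidate_betas:
            raise ConfigError("candidate_betas must be non-empty")
        self.simulation.validate()

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        sim = payload.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
        config = cls(**payload, simulation=SimulationConfig(**sim))
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


@dataclass
class ReportBundle:
    """Key result tables of a pipeline run."""

    deg_table: pd.DataFrame
    assignment: network.ModuleAssignment
    target_tfs: pd.DataFrame
    enrichment: pd.DataFrame
    occupancy_transcript: pd.DataFrame
    occupancy_metabolite: pd.DataFrame
    grid: pd.DataFrame
    zscores: pd.DataFrame
    profile_summary: pd.DataFrame
    beta: float


def simulate_inputs(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write a full set of simulated input tables to ``out_dir``."""
    config.validate()
    sim = config.simulation
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = simulate.generate_design(n_reps=sim.n_reps)
    counts, truth = simulate.generate_expression(
        design=design,
        n_genes_per_module=sim.n_genes_per_module,
        n_background=sim.n_background,
        effect_size=sim.effect_size,
        noise_sd=sim.noise_sd,
        dispersion=sim.dispersion,
        n_hubs_per_module=sim.n_hubs_per_module,
        seed=config.seed,
    )
    annotation = simulate.generate_annotations(
        truth,
        n_pathways=sim.n_pathways,
        pathway_size=sim.pathway_size,
        enrichment_fraction=sim.enrichment_fraction,
        n_background_tfs=sim.n_background_tfs,
        seed=config.seed + 1,
    )
    metabolites = simulate.generate_metabolites(
        design=design,
        n_per_set=sim.metabolites_per_set,
        n_null=sim.null_metabolites,
        effect_size=sim.metabolite_effect,
        noise_sd=sim.metabolite_noise_sd,
        pathway_ids=sorted(annotation.pathways),
        truth=truth,
        seed=config.seed + 2,
    )
    io.write_counts(counts, out / "counts.tsv")
    io.write_design(design, out / "design.tsv")
    io.write_annotations(annotation, out / "annotations.tsv")
    io.write_metabolites(
        metabolites, out / "metabolites.tsv", out / "metabolite_pathways.tsv"
    )
    (out / "truth.json").write_text(truth.to_json())
    logger.info("simulated inputs written to %s", out)
    return out


def _load_inputs(
    input_dir: Path,
) -> tuple[ExpressionMatrix, SampleDesign, GeneAnnotation, MetaboliteTable]:
    counts = io.read_counts(input_dir / "counts.tsv")
    design = io.read_design(input_dir / "design.tsv")
    annotation = io.read_annotations(input_dir / "annotations.tsv")
    metabolites = io.read_metabolites(
        input_dir / "metabolites.tsv", input_dir / "metabolite_pathways.tsv"
    )
    design.check_matches(counts)
    return counts, design, annotation, metabolites


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, out_dir: str | Path
) -> ReportBundle:
    """Execute every stage on the tables in ``input_dir``."""
    config.validate()
    input_dir = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        counts, design, annotation, metabolites = _load_inputs(input_dir)

        stage = "normalize"
        logger.info("normalizing %d x %d counts", counts.n_genes, counts.n_samples)
        norm = expression.normalize(counts)
        io.write_counts(norm, out / "normalized.tsv")

        stage = "filter_expressed"
        expressed = expression.filter_expressed(norm, min_mean=config.min_mean)
        (out / "expressed_genes.txt").write_text("\n".join(expressed) + "\n")
        logger.info("%d expressed genes", len(expressed))

        stage = "call_degs"
        deg_table = expression.call_degs(
            norm, design, fdr_alpha=config.fdr_alpha, min_fold=config.min_fold
        )
        io.write_table(deg_table, out / "deg.tsv")

        stage = "network"
        net_data = norm.data.loc[expressed]
        net = network.build_network(
            net_data,
            beta=config.beta,
            candidate_betas=tuple(config.candidate_betas),
        )
        logger.info("soft power beta = %g", net.beta)
        (out / "soft_threshold.txt").write_text(f"{net.beta:g}\n")
        if config.save_tom:
            io.write_table(
                pd.DataFrame(net.tom, index=net.genes, columns=net.genes)
                .reset_index(names="gene"),
                out / "tom.tsv",
            )

        stage = "detect_modules"
        net_data = net_data.loc[net.genes]
        assignment = network.detect_modules(
            net.tom,
            net_data,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_threshold=config.merge_threshold,
        )
        own = assignment.own_kme()
        modules_frame = pd.DataFrame(
            {
                "gene": assignment.modules.index,
                "module": assignment.modules.to_numpy(),
                "kme_own_module": [
                    own.get(g, float("nan")) for g in assignment.modules.index
                ],
            }
        )
        io.write_table(modules_frame, out / "modules.tsv")
        eigen_out = assignment.eigengenes.T.reset_index(names="module")
        io.write_table(eigen_out, out / "eigengenes.tsv")
        logger.info(
            "%d modules (%d genes unassigned)",
            len(assignment.labels),
            int((assignment.modules == network.UNASSIGNED).sum()),
        )

        stage = "target_tfs"
        tf_table = targets.select_target_tfs(
            annotation,
            assignment,
            norm,
            design,
            deg_table,
            expressed=expressed,
            q_kme=config.q_kme,
            peak_pct=config.peak_pct,
            activity_fraction=config.activity_fraction,
            keep_all=True,
        )
        io.write_table(tf_table, out / "target_tfs.tsv")
        selected = tf_table[tf_table["selected"]]

        stage = "subnetworks"
        subnet_rows = []
        subnets: dict[str, targets.Subnetwork] = {}
        for tf in selected["gene"]:
            subnet = targets.tf_subnetwork(net, tf, q=config.q_subnet)
            subnets[tf] = subnet
            for gene, score in subnet.members.items():
                subnet_rows.append(
                    {"tf": tf, "member": gene, "tom_score": float(score)}
                )
        io.write_table(
            pd.DataFrame(subnet_rows, columns=["tf", "member", "tom_score"]),
            out / "subnetworks.tsv",
        )

        stage = "top_module_genes"
        top_sets = targets.module_top_kme(assignment, q=config.q_kme)
        top_genes = targets.top_module_genes(assignment, n=config.top_n_genes)
        top_rows = []
        for label, frame in top_genes.items():
            frame = frame.assign(module=label)
            top_rows.append(frame[["module", "gene", "kme", "rank"]])
        if top_rows:
            io.write_table(pd.concat(top_rows), out / "top_module_genes.tsv")
        composition = targets.tf_family_composition(annotation, top_sets)
        io.write_table(composition, out / "tf_family_composition.tsv")

        stage = "enrichment"
        background = list(expressed)
        frames = []
        for label in assignment.labels:
            frame = enrich.fisher_enrichment(
                assignment.members(label),
                background,
                annotation.pathways,
                alpha=config.fisher_alpha,
            )
            frame.insert(0, "unit", f"module_{label}")
            frames.append(frame)
        for tf, subnet in subnets.items():
            frame = enrich.fisher_enrichment(
                subnet.genes,
                background,
                annotation.pathways,
                alpha=config.fisher_alpha,
            )
            frame.insert(0, "unit", tf)
            frames.append(frame)
        enrichment_table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["unit"] + enrich.ENRICHMENT_COLUMNS)
        )
        io.write_table(enrichment_table, out / "enrichment.tsv")

        stage = "metabolite_da"
        da_table = enrich.metabolite_da(
            metabolites, design, alpha=config.anova_alpha
        )
        io.write_table(da_table, out / "metabolite_da.tsv")

        stage = "occupancy"
        occ_t = enrich.transcript_occupancy(
            deg_table, annotation.pathways, expressed
        )
        occ_m = enrich.metabolite_occupancy(da_table, metabolites.pathways)
        io.write_table(occ_t, out / "occupancy_transcript.tsv")
        io.write_table(occ_m, out / "occupancy_metabolite.tsv")

        stage = "report"
        subnet_enrichment = enrichment_table[
            ~enrichment_table["unit"].astype(str).str.startswith("module_")
        ]
        grid = report.tf_pathway_grid(subnet_enrichment, selected)
        io.write_table(grid, out / "tf_pathway_grid.tsv")
        deg_genes = sorted(set(deg_table.loc[deg_table["is_deg"], "gene"]))
        if deg_genes:
            zscores, _ = report.zscore_table(norm, deg_genes)
        else:
            zscores = pd.DataFrame(columns=norm.samples)
        io.write_table(
            zscores.reset_index(names="gene"), out / "deg_zscores.tsv"
        )
        summary = report.module_profile_summary(assignment.eigengenes, design)
        io.write_table(summary, out / "module_profile_summary.tsv")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return ReportBundle(
        deg_table=deg_table,
        assignment=assignment,
        target_tfs=tf_table,
        enrichment=enrichment_table,
        occupancy_transcript=occ_t,
        occupancy_metabolite=occ_m,
        grid=grid,
        zscores=zscores,
        profile_summary=summary,
        beta=net.beta,
    )
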