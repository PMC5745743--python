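"""End-to-end orchestration: screen -> enrich -> build the three networks ->
compute metrics -> write Pajek files and reports, from one declarative
configuration.

A run is deterministic given config + seed. Stage record counts are logged
and collected in the :class:`RunReport`, whose funnel mirrors the screening
cascade (compounds identified -> drug-like -> with targets).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .exceptions import ConfigurationError
from .io_formats import (
    read_compound_table,
    read_gmt,
    read_interaction_table,
    render_metrics_report,
    write_metrics_report,
    write_pajek,
)
from .metrics import (
    MetricsReport,
    centrality_outliers,
    compute_metrics,
    rank_nodes,
)
from .networks import (
    build_tripartite,
    extract_core_subnetwork,
    max_degree_pathway,
    project_protein_association,
)
from .enrichment import enrich_pathways
from .screening import screen
from .synthetic_data import (
    DatasetBundle,
    SimulationConfig,
    simulate_bundle,
    study_shaped_bundle,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Exactly one input source must be set: the three input paths, a
    simulation config, or ``use_study_bundle=True`` (the packaged
    deterministic study-shaped dataset).
    """

    compounds_path: str | None = None
    interactions_path: str | None = None
    pathways_path: str | None = None
    simulation: SimulationConfig | None = None
    use_study_bundle: bool = False

    # screening
    min_support: int = 5
    apply_lipinski: bool = True

    # enrichment
    alpha: float = 0.01
    correction: str = "none"
    background_path: str | None = None  # protein ids, one per line; default
    # background is the union of pathway members and the query

    # networks
    key_pathway: str | None = None  # None -> maximal-degree pathway

    # metrics
    smallworld_replicates: int = 0
    seed: int = 0

    out_dir: str | None = None

    def __post_init__(self) -> None:
        paths = all(p is not None for p in
                    (self.compounds_path, self.interactions_path, self.pathways_path))
        some_paths = any(p is not None for p in
                         (self.compounds_path, self.interactions_path, self.pathways_path))
        sources = sum([paths, self.simulation is not None, self.use_study_bundle])
        if some_paths and not paths:
            raise ConfigurationError(
                "compounds_path, interactions_path and pathways_path must be "
                "given together")
        if sources != 1:
            raise ConfigurationError(
                "exactly one input source required: the three input paths, a "
                "simulation block, or use_study_bundle")
        if self.min_support < 1:
            raise ConfigurationError(f"min_support must be >= 1, got {self.min_support}")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.smallworld_replicates < 0:
            raise ConfigurationError("smallworld_replicates must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(simulation=sim, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class RunReport:
    """Stage-by-stage accounting plus the three metric reports."""

    config: dict
    version: str
    funnel: dict
    enrichment: list
    n_pathways_annotated: int
    n_pathways_significant: int
    key_pathway: str
    tripartite: MetricsReport
    core: MetricsReport
    projection: MetricsReport
    hub_ingredients: list
    key_proteins: list
    outliers: list[str]

    def summary_quantities(self) -> dict:
        """The headline numbers of the run (full precision)."""
        return {
            "compounds_identified": self.funnel["compounds_identified"],
            "compounds_druglike": self.funnel["compounds_druglike"],
            "compounds_with_targets": self.funnel["compounds_with_targets"],
            "targets_kept": self.funnel["targets_kept"],
            "pathways_annotated": self.n_pathways_annotated,
            "pathways_significant": self.n_pathways_significant,
            "tripartite_nodes": self.tripartite.n_nodes,
            "tripartite_edges": self.tripartite.n_edges,
            "tripartite_mean_degree": self.tripartite.mean_degree,
            "core_nodes": self.core.n_nodes,
            "core_edges": self.core.n_edges,
            "core_mean_degree": self.core.mean_degree,
            "projection_nodes": self.projection.n_nodes,
            "projection_edges": self.projection.n_edges,
            "projection_mean_degree": self.projection.mean_degree,
        }


def _load_bundle(config: PipelineConfig) -> DatasetBundle:
    if config.use_study_bundle:
        return study_shaped_bundle()
    if config.simulation is not None:
        return simulate_bundle(config.simulation)
    return DatasetBundle(
        compounds=read_compound_table(config.compounds_path),
        interactions=read_interaction_table(config.interactions_path),
        pathways=read_gmt(config.pathways_path),
        description="loaded from input files",
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and (optionally) write outputs.

    Stages: load/simulate -> screening cascade -> pathway
    over-representation -> tripartite network -> core subnetwork of the key
    pathway -> protein association projection -> metrics on all three
    graphs -> hub ranking and centrality outliers. When ``out_dir`` is set,
    Pajek files, metric reports and the run report are written there.
    """
    bundle = _load_bundle(config)
    logger.info("stage input: %d compounds, %d interaction rows, %d pathways",
                len(bundle.compounds), len(bundle.interactions), len(bundle.pathways))

    screened = screen(bundle.compounds, bundle.interactions,
                      min_support=config.min_support,
                      apply_lipinski=config.apply_lipinski)
    compounds = screened["compounds"]
    interactions = screened["interactions"]
    kept_targets = sorted(set(interactions["target_id"]))
    funnel = {
        "compounds_identified": len(bundle.compounds),
        "compounds_druglike": screened["lipinski"].n_kept,
        "compounds_with_targets": len(compounds),
        "targets_in": int(bundle.interactions["target_id"].nunique())
        if len(bundle.interactions) else 0,
        "targets_kept": len(kept_targets),
        "interaction_rows_kept": len(interactions),
    }
    logger.info("stage screening: funnel %s", funnel)

    background = None
    if config.background_path is not None:
        background = {line.strip() for line
                      in Path(config.background_path).read_text().splitlines()
                      if line.strip()}
        background |= set(kept_targets)
    enrichment = enrich_pathways(set(kept_targets), bundle.pathways,
                                 background=background,
                                 alpha=config.alpha,
                                 correction=config.correction)
    n_significant = sum(r.significant for r in enrichment)
    logger.info("stage enrichment: %d pathways tested, %d significant at "
                "alpha=%g", len(enrichment), n_significant, config.alpha)

    memberships = bundle.pathways.restrict(kept_targets)
    tripartite = build_tripartite(interactions, memberships)
    key_pathway = config.key_pathway or max_degree_pathway(tripartite)
    core = extract_core_subnetwork(tripartite, key_pathway)
    projection = project_protein_association(memberships)
    logger.info("stage networks: tripartite %d/%d, core %d/%d (pathway %s), "
                "projection %d/%d",
                tripartite.number_of_nodes(), tripartite.number_of_edges(),
                core.number_of_nodes(), core.number_of_edges(), key_pathway,
                projection.number_of_nodes(), projection.number_of_edges())

    tri_report = compute_metrics(tripartite, seed=config.seed)
    core_report = compute_metrics(core, seed=config.seed)
    proj_report = compute_metrics(
        projection, smallworld_replicates=config.smallworld_replicates,
        seed=config.seed)

    hub_ingredients = []
    if tri_report.per_node is not None:
        ingredient_ids = {str(n) for n, d in tripartite.nodes(data=True)
                          if d.get("role") == "ingredient"}
        tri_table = tri_report.per_node
        ing_rows = tri_table[tri_table["node"].isin(ingredient_ids)]
        hub_ingredients = rank_nodes(ing_rows, by="k", top_n=10)[
            ["node", "k"]].to_dict("records")

    key_proteins, outliers = [], []
    if proj_report.per_node is not None and len(proj_report.per_node) >= 3:
        key_proteins = rank_nodes(proj_report.per_node, by="Cd", top_n=10)[
            ["node", "k", "Cd", "Cb", "Cc"]].to_dict("records")
        outliers = centrality_outliers(proj_report.per_node)

    report = RunReport(
        config=config.echo(), version=__version__, funnel=funnel,
        enrichment=[r.as_dict() for r in enrichment],
        n_pathways_annotated=len(enrichment),
        n_pathways_significant=n_significant,
        key_pathway=str(key_pathway),
        tripartite=tri_report, core=core_report, projection=proj_report,
        hub_ingredients=hub_ingredients, key_proteins=key_proteins,
        outliers=outliers,
    )

    if config.out_dir is not None:
        _write_outputs(report, tripartite, core, projection, Path(config.out_dir))
    return report


def _write_outputs(report: RunReport, tripartite, core, projection,
                   out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pajek(tripartite, out_dir / "tripartite.net", out_dir / "tripartite.clu")
    write_pajek(core, out_dir / "core.net", out_dir / "core.clu")
    write_pajek(projection, out_dir / "projection.net", out_dir / "projection.clu")
    for name, rep in (("tripartite", report.tripartite), ("core", report.core),
                      ("projection", report.projection)):
        write_metrics_report(rep, out_dir / f"metrics_{name}.json", format="json")
        write_metrics_report(rep, out_dir / f"metrics_{name}.tsv", format="tsv")
    payload = {
        "version": report.version,
        "config": report.config,
        "funnel": report.funnel,
        "key_pathway": report.key_pathway,
        "n_pathways_annotated": report.n_pathways_annotated,
        "n_pathways_significant": report.n_pathways_significant,
        "enrichment": report.enrichment,
        "hub_ingredients": report.hub_ingredients,
        "key_proteins": report.key_proteins,
        "outliers": report.outliers,
        "metrics": {
            "tripartite": render_metrics_report(report.tripartite)["global"],
            "core": render_metrics_report(report.core)["global"],
            "projection": render_metrics_report(report.projection)["global"],
        },
    }
    (out_dir / "run_report.json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")
    (out_dir / "funnel.txt").write_text(summarize_counts(report) + "\n",
                                        encoding="utf-8")


def summarize_counts(report: RunReport) -> str:
    """One-line-per-stage text funnel of the run."""
    f = report.funnel
    lines = [
        f"compounds identified   {f['compounds_identified']:>6d}",
        f"compounds drug-like    {f['compounds_druglike']:>6d}",
        f"compounds with targets {f['compounds_with_targets']:>6d}",
        f"targets collected      {f['targets_in']:>6d}",
        f"targets kept           {f['targets_kept']:>6d}",
        f"pathways annotated     {report.n_pathways_annotated:>6d}",
        f"pathways significant   {report.n_pathways_significant:>6d}",
        f"tripartite network     {report.tripartite.n_nodes:>6d} nodes / "
        f"{report.tripartite.n_edges} edges",
        f"core subnetwork        {report.core.n_nodes:>6d} nodes / "
        f"{report.core.n_edges} edges (pathway {report.key_pathway})",
        f"protein projection     {report.projection.n_nodes:>6d} nodes / "
        f"{report.projection.n_edges} edges",
    ]
    return "\n".join(lines)
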