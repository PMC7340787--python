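"""End-to-end orchestration: preprocess -> network -> PPI mapping ->
candidate validation -> enrichment, from files or from a synthetic design.

Every intermediate is persisted as plain TSV when an output directory is
given, so any stage can be rerun standalone; a fixed seed yields an
identical report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from coexppi import enrichment, ppi, preprocessing, synthetic, validation
from coexppi.coexpression import CoexpressionNetwork
from coexppi.utils import ConfigError, StageError

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "demo"]


@dataclass
class PipelineConfig:
    """Flat configuration for a full run.

    Exactly one of the input routes must be supplied: file paths
    (``expression`` at minimum) or a synthetic ``design``.
    """

    # real inputs
    expression: str | None = None
    traits: str | None = None
    ppi_edges: str | None = None
    gene_sets: str | None = None
    normal_expression: str | None = None
    ppi_score_dialect: str = "unit"
    exclude_samples: tuple[str, ...] = ()
    # synthetic route
    design: synthetic.SyntheticDesign | None = None
    # stage parameters
    max_missing_fraction: float = 0.5
    min_variance: float = 0.0
    top_var_fraction: float = 0.25
    outlier_method: str = "k_sd"
    outlier_param: float = 3.0
    powers: tuple[int, ...] = tuple(range(1, 13))
    r2_threshold: float = 0.9
    network_mode: str = "unsigned"
    min_module_size: int = 10
    deep_split: int = 2
    merge_height: float = 0.25
    trait: str = "recurrence"
    module_alpha: float = 0.05
    min_score: float = 0.4
    drop_grey: bool = True
    de_alpha: float = 0.05
    surv_alpha: float = 0.1
    ora_alpha: float = 0.05
    n_perm: int = 200
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        has_files = self.expression is not None
        has_design = self.design is not None
        if has_files == has_design:
            raise ConfigError("supply exactly one of: expression files, synthetic design")
        for name, value, lo, hi in [
            ("top_var_fraction", self.top_var_fraction, 0.0, 1.0),
            ("r2_threshold", self.r2_threshold, 0.0, 1.0),
            ("min_score", self.min_score, 0.0, 1.0),
            ("module_alpha", self.module_alpha, 0.0, 1.0),
            ("de_alpha", self.de_alpha, 0.0, 1.0),
            ("surv_alpha", self.surv_alpha, 0.0, 1.0),
        ]:
            if not lo <= value <= hi:
                raise ConfigError(f"{name}={value} outside [{lo}, {hi}]")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")


@dataclass
class RunReport:
    """Everything a rerun needs to verify: dimensions, choices, tables."""

    seed: int
    stage_dimensions: dict = field(default_factory=dict)
    power: int | None = None
    fit_table: pd.DataFrame | None = None
    module_sizes: dict = field(default_factory=dict)
    critical_module: str | None = None
    module_trait: pd.DataFrame | None = None
    mapped_summary: pd.DataFrame | None = None
    candidates: list = field(default_factory=list)
    final_targets: list = field(default_factory=list)
    validation_report: pd.DataFrame | None = None
    ora_table: pd.DataFrame | None = None
    gsea_tables: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _df(x):
            return None if x is None else json.loads(x.to_json(orient="split"))

        body = {
            "seed": self.seed,
            "stage_dimensions": self.stage_dimensions,
            "power": self.power,
            "fit_table": _df(self.fit_table),
            "module_sizes": self.module_sizes,
            "critical_module": self.critical_module,
            "module_trait": _df(self.module_trait),
            "mapped_summary": _df(self.mapped_summary),
            "candidates": self.candidates,
            "final_targets": self.final_targets,
            "validation": _df(self.validation_report),
            "ora": _df(self.ora_table),
            "gsea": {k: _df(v) for k, v in self.gsea_tables.items()},
            "parameters": self.parameters,
        }
        return json.dumps(body, indent=2, sort_keys=True, default=str)

    def summary(self) -> str:
        lines = [
            "Pipeline run report",
            "=" * 48,
            f"seed: {self.seed}",
        ]
        for stage, dims in self.stage_dimensions.items():
            lines.append(f"{stage}: {dims}")
        lines.append(f"soft power: {self.power}")
        lines.append(f"modules: {self.module_sizes}")
        lines.append(f"critical module: {self.critical_module}")
        lines.append(f"candidates ({len(self.candidates)}): {', '.join(self.candidates)}")
        lines.append(
            f"final targets ({len(self.final_targets)}): {', '.join(self.final_targets)}"
        )
        return "\n".join(lines)


def _load_inputs(config: PipelineConfig):
    if config.design is not None:
        design = config.design
        expr, truth = synthetic.generate_expression(design)
        traits = synthetic.generate_traits(design, truth)
        edges = ppi.ppi_from_frame(synthetic.generate_ppi(design, truth))
        sets = synthetic.generate_gene_sets(
            truth, n_sets=20, overlap_fraction=0.8, seed=design.seed
        )
        normal = synthetic.generate_normal_cohort(design, truth)
        return expr, traits, edges, sets, normal
    expr = preprocessing.read_expression(config.expression)
    traits = preprocessing.read_traits(config.traits) if config.traits else None
    edges = (
        ppi.read_ppi(config.ppi_edges, score_dialect=config.ppi_score_dialect)
        if config.ppi_edges
        else None
    )
    sets = enrichment.read_gmt(config.gene_sets) if config.gene_sets else None
    normal = (
        preprocessing.read_expression(config.normal_expression)
        if config.normal_expression
        else None
    )
    return expr, traits, edges, sets, normal


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; fail fast with the stage name on error."""
    config.validate()
    report = RunReport(seed=config.seed, parameters={
        k: v for k, v in vars(config).items() if not isinstance(v, synthetic.SyntheticDesign)
    })
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def persist(name, obj):
        if outdir is None or obj is None:
            return
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.tsv", sep="\t")
        elif isinstance(obj, pd.Series):
            obj.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t")

    try:
        expr, traits, edges, sets, normal = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc
    report.stage_dimensions["input"] = {"genes": expr.shape[0], "samples": expr.shape[1]}
    tumor_full = expr.copy()

    try:
        expr = preprocessing.filter_missing(
            expr, config.max_missing_fraction, config.min_variance
        )
        if config.top_var_fraction < 1.0:
            expr = preprocessing.top_variance(expr, config.top_var_fraction)
        if config.exclude_samples:
            expr = expr.drop(columns=list(config.exclude_samples), errors="ignore")
        outliers = preprocessing.detect_sample_outliers(
            expr, method=config.outlier_method, param=config.outlier_param
        )
        if outliers:
            expr = expr.drop(columns=outliers)
        if traits is not None:
            expr, traits = preprocessing.align(expr, traits)
        persist("expression_filtered", expr)
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc
    report.stage_dimensions["preprocessed"] = {
        "genes": expr.shape[0], "samples": expr.shape[1], "outliers_removed": len(outliers)
    }

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = CoexpressionNetwork(expr, traits)
            results = model.fit(
                powers=config.powers,
                r2_threshold=config.r2_threshold,
                mode=config.network_mode,
                min_module_size=config.min_module_size,
                deep_split=config.deep_split,
                merge_height=config.merge_height,
            )
        report.power = results.power
        report.fit_table = results.fit_table
        report.module_sizes = results.modules.sizes().to_dict()
        persist("fit_table", results.fit_table)
        persist("modules", results.modules.labels.rename("module"))
        if results.eigengenes is not None:
            persist("eigengenes", results.eigengenes.eigengenes)
        if results.trait_stats is not None:
            report.module_trait = results.trait_stats.correlation
            persist("module_trait_correlation", results.trait_stats.correlation)
            persist("module_trait_p", results.trait_stats.p_value)
        critical = results.critical_module(config.trait, alpha=config.module_alpha)
        report.critical_module = critical
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    candidates = []
    if edges is not None:
        try:
            filtered = ppi.filter_confidence(edges, config.min_score)
            mapped = ppi.map_modules(filtered, results.modules, drop_grey=config.drop_grey)
            report.mapped_summary = mapped.module_summary()
            persist("mapped_nodes", ppi.rank_nodes(mapped))
            persist("mapped_edges", mapped.edge_table)
            candidates = ppi.candidate_targets(mapped, critical)
            report.candidates = candidates
        except Exception as exc:  # noqa: BLE001
            raise StageError("ppi_mapping", exc) from exc

    if candidates and normal is not None and traits is not None:
        try:
            final, vreport = validation.evaluate_targets(
                tumor_full, normal, traits, candidates,
                de_alpha=config.de_alpha, surv_alpha=config.surv_alpha,
            )
            report.final_targets = final
            report.validation_report = vreport
            persist("validation", vreport)
        except Exception as exc:  # noqa: BLE001
            raise StageError("validation", exc) from exc

    if sets is not None:
        try:
            module_genes = results.modules.members(critical)
            background = list(expr.index)
            report.ora_table = enrichment.ora(module_genes, background, sets)
            persist("ora", report.ora_table)
            for gene in report.final_targets[:3]:
                groups = validation.split_by_expression(expr, gene)
                labels = (groups == "high").astype(int).to_numpy()
                table = enrichment.gsea_significance(
                    expr, labels, sets, n_perm=config.n_perm, seed=config.seed
                )
                report.gsea_tables[gene] = table
                persist(f"gsea_{gene}", table)
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment", exc) from exc

    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    return report


def demo(seed: int = 0, outdir: str | None = None) -> RunReport:
    """Full pipeline on the bundled small synthetic design."""
    config = PipelineConfig(
        design=synthetic.default_design(seed),
        top_var_fraction=1.0,  # synthetic rows all have unit variance
        powers=tuple(range(1, 9)),
        seed=seed,
        outdir=outdir,
    )
    return run_pipeline(config)
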