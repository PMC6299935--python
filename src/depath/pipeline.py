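"""End-to-end pipeline orchestration.

Runs the stages in order — preprocess -> id conversion (optional) -> EDA
-> DE -> enrichment -> pathway activity -> motif enrichment — from a flat
key=value config, writing every result as TSV into one output directory.
Stages whose inputs are absent are skipped and reported; a stage failure
is recorded with its stage name and downstream dependents are skipped.
Every run writes the fully resolved config next to its outputs so a run
can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import depath
from depath.deg import apply_thresholds, welch_de
from depath.eda import (
    dendrogram_to_newick,
    hierarchical_cluster,
    kmeans_cluster,
    run_pca,
    select_top_variable,
)
from depath.enrich import build_term_summary, hypergeometric_enrich, read_gmt
from depath.idmap import convert_ids, detect_species, load_mapping_table
from depath.matrix_io import (
    DesignTable,
    ExpressionMatrix,
    read_design,
    read_expression_matrix,
    write_expression_matrix,
)
from depath.motif import motif_ttest_enrich, read_pwms, scan_best_scores
from depath.pathway import anova_rank_pathways, page_scores, pca_loading_pathways, pgsea_sample_scores
from depath.preprocess import (
    PreprocessConfig,
    detect_skew,
    filter_low_expression,
    library_size_anova,
    transform_counts,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, serializable configuration of a full run."""

    matrix_path: str = ""
    design_path: str = ""
    mapping_path: str = ""
    gmt_path: str = ""
    promoter_path: str = ""
    pwm_path: str = ""
    out_dir: str = "depath_out"
    # preprocessing
    cpm_threshold: float = 0.5
    min_samples: int = 1
    pseudocount: float = 4.0
    transform: str = "log_started"
    skew_threshold: float = 2.0
    anova_alpha: float = 0.05
    # id conversion
    convert_ids: bool = False
    keep_unmatched: bool = True
    # eda
    top_genes: int = 1000
    kmeans_k: int = 4
    # de
    de_factor: str = ""
    de_level_a: str = ""
    de_level_b: str = ""
    fdr_cut: float = 0.1
    fc_cut: float = 2.0
    # pathway
    pathway_fdr_cut: float = 0.05
    pathway_top_k: int = 30
    abs_fold_change: bool = False
    # misc
    seed: int = 0

    def to_file(self, path: Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    out_dir: Path
    completed: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    failed: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failed


def _header(cfg: PipelineConfig, stage: str) -> str:
    params = ", ".join(
        f"{f.name}={getattr(cfg, f.name)}"
        for f in dataclasses.fields(cfg)
        if not f.name.endswith("_path") and f.name != "out_dir"
    )
    return f"# depath {depath.__version__} | stage={stage} | {params}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg, stage))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run all configured stages; see module docstring for the order."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(out / "resolved_config.txt")
    result = PipelineResult(out_dir=out)
    log_path = out / "pipeline.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def fail(stage: str, exc: Exception) -> None:
        result.failed[stage] = f"{type(exc).__name__}: {exc}"
        log(f"[{stage}] FAILED: {type(exc).__name__}: {exc}")
        log(traceback.format_exc(limit=3))

    matrix: ExpressionMatrix | None = None
    design: DesignTable | None = None
    transformed: ExpressionMatrix | None = None
    de_result = None
    up: list[str] = []
    down: list[str] = []
    collection = None

    # ---- preprocess -------------------------------------------------
    stage = "preprocess"
    try:
        matrix = read_expression_matrix(cfg.matrix_path)
        pre_cfg = PreprocessConfig(
            cpm_threshold=cfg.cpm_threshold,
            min_samples=cfg.min_samples,
            pseudocount=cfg.pseudocount,
            transform=cfg.transform,
            skew_threshold=cfg.skew_threshold,
            anova_alpha=cfg.anova_alpha,
        )
        if cfg.design_path:
            design = read_design(cfg.design_path, matrix)

        if cfg.convert_ids and cfg.mapping_path:
            table = load_mapping_table(cfg.mapping_path)
            ranking, warn = detect_species(matrix.gene_ids, table)
            pd.DataFrame(ranking, columns=["species", "matched"]).pipe(
                _write_tsv, out / "species_detection.tsv", cfg, stage
            )
            if warn:
                log("[preprocess] species detection: no ids matched any species")
            else:
                species = ranking[0][0]
                matrix, report = convert_ids(matrix, table, species, cfg.keep_unmatched)
                log(
                    f"[preprocess] converted to {species}: matched={report.n_matched} "
                    f"unmatched={report.n_unmatched} collapsed={report.n_collapsed}"
                )

        if matrix.scale_kind == "counts":
            if design is not None and design.factors:
                factor = design.factors[0]
                p, warn = library_size_anova(matrix, design, factor, cfg.anova_alpha)
                log(f"[preprocess] library-size ANOVA on {factor!r}: p={p:.4g} warning={warn}")
                pd.DataFrame(
                    {"factor": [factor], "anova_p": [p], "warning": [warn]}
                ).pipe(_write_tsv, out / "libsize_anova.tsv", cfg, stage)
            matrix, n_removed = filter_low_expression(matrix, pre_cfg)
            log(f"[preprocess] low-expression filter removed {n_removed} genes")
            is_skewed, skewness = detect_skew(matrix, cfg.skew_threshold)
            if is_skewed and pre_cfg.transform == "none":
                log(f"[preprocess] skewness {skewness:.2f} > {cfg.skew_threshold}: enforcing log transform")
                pre_cfg.transform = "log_started"
            transformed = transform_counts(matrix, pre_cfg)
        else:
            transformed = ExpressionMatrix(matrix.data, "transformed")
        write_expression_matrix(transformed, out / "transformed_matrix.tsv")
        result.completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - every stage error is surfaced by name
        fail(stage, exc)
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        return result

    # ---- eda --------------------------------------------------------
    stage = "eda"
    try:
        n_top = min(cfg.top_genes, transformed.n_genes)
        top = select_top_variable(transformed, n_top)
        linkage = hierarchical_cluster(top, axis="samples")
        (out / "sample_dendrogram.nwk").write_text(
            dendrogram_to_newick(linkage, top.sample_ids) + "\n"
        )
        assign = kmeans_cluster(top, k=min(cfg.kmeans_k, n_top), seed=cfg.seed)
        _write_tsv(assign.as_frame(), out / "kmeans_clusters.tsv", cfg, stage)
        _write_tsv(
            pd.DataFrame(assign.wss_curve, columns=["k", "wss"]),
            out / "kmeans_wss.tsv",
            cfg,
            stage,
        )
        pca = run_pca(transformed)
        _write_tsv(pca.scores, out / "pca_scores.tsv", cfg, stage, index=True)
        _write_tsv(pca.loadings, out / "pca_loadings.tsv", cfg, stage, index=True)
        _write_tsv(
            pd.DataFrame(
                {
                    "component": pca.scores.columns,
                    "variance_fraction": pca.variance_fraction,
                }
            ),
            out / "pca_variance.tsv",
            cfg,
            stage,
        )
        result.completed.append(stage)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
        pca = None

    # ---- deg --------------------------------------------------------
    stage = "deg"
    if design is None or not cfg.de_factor:
        result.skipped[stage] = "no design/factor configured"
        log(f"[{stage}] skipped: no design/factor configured")
    else:
        try:
            levels = design.levels(cfg.de_factor)
            level_a = cfg.de_level_a or sorted(levels.unique())[-1]
            level_b = cfg.de_level_b or design.reference_levels[cfg.de_factor]
            de_result = welch_de(transformed, design, cfg.de_factor, level_a, level_b)
            up, down = apply_thresholds(de_result, cfg.fdr_cut, cfg.fc_cut)
            _write_tsv(de_result.table, out / "de_results.tsv", cfg, stage)
            log(f"[deg] {de_result.comparison}: {len(up)} up, {len(down)} down")
            result.completed.append(stage)
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # ---- enrich -----------------------------------------------------
    stage = "enrich"
    if not cfg.gmt_path:
        result.skipped[stage] = "no GMT configured"
        log(f"[{stage}] skipped: no GMT configured")
    elif de_result is None:
        result.skipped[stage] = "requires DE results"
        log(f"[{stage}] skipped: requires DE results")
    else:
        try:
            collection = read_gmt(cfg.gmt_path)
            background = [
                g for g in transformed.gene_ids if g in collection.all_genes()
            ]
            for direction, genes in (("up", up), ("down", down)):
                if not set(genes) & set(background):
                    log(f"[enrich] {direction}: no query genes in background; skipped")
                    continue
                table = hypergeometric_enrich(genes, collection, background)
                _write_tsv(table.drop(columns=["overlap_genes"]).assign(
                    overlap_genes=[";".join(g) for g in table["overlap_genes"]]
                ), out / f"enrichment_{direction}.tsv", cfg, stage)
                enriched = table[table["fdr"] < 0.05]
                if len(enriched) >= 2:
                    summary = build_term_summary(enriched, genes)
                    (out / f"term_tree_{direction}.nwk").write_text(summary["newick"] + "\n")
                    _write_tsv(summary["nodes"], out / f"term_nodes_{direction}.tsv", cfg, stage)
                    _write_tsv(summary["edges"], out / f"term_edges_{direction}.tsv", cfg, stage)
            result.completed.append(stage)
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)
            collection = None

    # ---- pathway ----------------------------------------------------
    stage = "pathway"
    if collection is None:
        result.skipped[stage] = "requires gene sets"
        log(f"[{stage}] skipped: requires gene sets")
    else:
        try:
            if de_result is not None:
                page = page_scores(
                    de_result.fold_changes(), collection, abs_mode=cfg.abs_fold_change
                )
                _write_tsv(page, out / "page_results.tsv", cfg, stage)
            activity = pgsea_sample_scores(transformed, collection)
            if design is not None and design.factors:
                ranked = anova_rank_pathways(
                    activity,
                    design,
                    design.factors[0],
                    fdr_cut=cfg.pathway_fdr_cut,
                    top_k=cfg.pathway_top_k,
                )
                _write_tsv(
                    ranked.z.join(ranked.stats),
                    out / "pathway_activity.tsv",
                    cfg,
                    stage,
                    index=True,
                )
            else:
                _write_tsv(activity.z, out / "pathway_activity.tsv", cfg, stage, index=True)
            if pca is not None:
                pc_pathways = pca_loading_pathways(pca, collection)
                _write_tsv(pc_pathways, out / "pca_loading_pathways.tsv", cfg, stage)
            result.completed.append(stage)
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # ---- motif ------------------------------------------------------
    stage = "motif"
    if not cfg.promoter_path or not cfg.pwm_path:
        result.skipped[stage] = "no promoters/PWMs configured"
        log(f"[{stage}] skipped: no promoters/PWMs configured")
    elif de_result is None:
        result.skipped[stage] = "requires DE results"
        log(f"[{stage}] skipped: requires DE results")
    else:
        try:
            pwms = read_pwms(cfg.pwm_path)
            scores = scan_best_scores(cfg.promoter_path, pwms)
            for direction, genes in (("up", up), ("down", down)):
                overlap = [g for g in genes if g in scores.index]
                if len(overlap) < 3 or len(scores) - len(overlap) < 3:
                    log(f"[motif] {direction}: too few promoters; skipped")
                    continue
                table = motif_ttest_enrich(scores, overlap, pwms)
                _write_tsv(table, out / f"motif_enrichment_{direction}.tsv", cfg, stage)
            result.completed.append(stage)
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    log_path.write_text("\n".join(log_lines) + "\n")
    return result
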