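"""End-to-end orchestration: normalize -> decontaminate -> floor -> DE -> panels.

The pipeline mirrors the analysis order used for the translatome study design
it emulates: counts are converted to FPKM (when counts are supplied), the
contamination filter is fitted and applied *before* differential expression,
an expression floor (default 5 FPKM) restricts the DE universe, and gene-set
summaries are computed per contrast on the decontaminated matrix.

All randomness flows from the single config seed. The run produces TSV tables
(filtered matrix, score table, DE per contrast, gene-set summaries) plus a
machine-readable JSON :class:`RunReport` whose stage counts are checked for
mutual consistency on every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datamodel import CountMatrix, ExpressionMatrix, GeneAnnotation, GeneSet
from .decontam import (
    apply_contamination_filter,
    compute_contamination_profile,
    compute_gene_scores,
)
from .io import (
    read_expression_table,
    read_gene_annotation,
    read_gene_sets,
    read_library_sizes,
    read_sample_metadata,
    write_expression_table,
)
from .normalize import fpkm_from_counts
from .stats import differential_expression, gene_set_summary

logger = logging.getLogger("trapdecon")

__all__ = ["PipelineConfig", "RunReport", "run_translatome_pipeline", "run_from_objects"]


@dataclass
class PipelineConfig:
    """File paths and parameters of one pipeline run."""

    counts_path: str | None = None
    fpkm_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None
    library_sizes_path: str | None = None
    marker_gmt_path: str | None = None
    marker_set_name: str | None = None
    geneset_gmt_paths: list[str] = field(default_factory=list)
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    n_scrambles: int = 1
    z_threshold: float = 2.0
    fc_threshold: float = 1.3
    alpha: float = 0.05
    pseudocount: float = 1.0
    expression_floor: float = 5.0
    drop_markers_before_de: bool = False
    out_dir: str = "trapdecon_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c) for c in raw["contrasts"]]
        return cls(**raw)

    def validate_files(self) -> None:
        if (self.counts_path is None) == (self.fpkm_path is None):
            raise ValueError("exactly one of counts_path or fpkm_path is required")
        if self.counts_path is not None and self.annotation_path is None:
            raise ValueError("annotation_path is required with counts input")
        if self.marker_gmt_path is None:
            raise ValueError("marker_gmt_path is required")
        for p in filter(None, [self.counts_path, self.fpkm_path, self.annotation_path,
                               self.metadata_path, self.library_sizes_path,
                               self.marker_gmt_path, *self.geneset_gmt_paths]):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    version: str
    config: dict
    stages: dict
    contrasts: list[dict]
    gene_sets: list[dict]
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Check that stage gene counts are mutually consistent."""
        s = self.stages
        if s["n_scored"] + s["n_markers_in_matrix"] != s["n_input_genes"]:
            raise AssertionError("scored + markers != input genes")
        if s["n_excluded"] + s["n_retained"] != s["n_input_genes"]:
            raise AssertionError("excluded + retained != input genes")
        if not 0 <= s["n_floor_passing"] <= s["n_de_universe"] <= s["n_retained"]:
            raise AssertionError("floor/DE-universe counts inconsistent")
        for c in self.contrasts:
            if c["n_up"] + c["n_down"] > c["n_tested"]:
                raise AssertionError("more calls than tested genes")

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_from_objects(
    expression: ExpressionMatrix,
    markers: GeneSet,
    config: PipelineConfig,
    gene_sets: list[GeneSet] | None = None,
    out_dir: Path | None = None,
) -> tuple[RunReport, dict]:
    """Run decontamination -> floor -> DE -> panels on in-memory objects.

    Returns the report plus a dict of the in-memory products (filtered
    matrix, score table, DE results per contrast, gene-set summaries) so the
    pipeline is exactly the composition of the module operations, with no
    hidden state.
    """
    gene_sets = gene_sets or []
    warnings_log: list[str] = []

    if expression.sample_meta is None:
        raise ValueError("pipeline requires sample metadata with condition labels")
    known_conditions = set(expression.sample_meta["condition"])
    for a, b in config.contrasts:
        for cond in (a, b):
            if cond not in known_conditions:
                raise ValueError(
                    f"contrast condition {cond!r} absent from sample metadata "
                    f"(known: {sorted(known_conditions)})"
                )

    logger.info("decontam: scoring %d genes x %d samples",
                expression.n_genes, expression.n_samples)
    profile = compute_contamination_profile(expression, markers)
    for m, reason in profile.dropped_markers.items():
        warnings_log.append(f"marker {m} dropped: {reason}")
    scores, null = compute_gene_scores(
        expression, profile, markers,
        seed=config.seed, n_scrambles=config.n_scrambles,
        z_threshold=config.z_threshold,
    )
    filtered, filter_report = apply_contamination_filter(
        expression, scores, markers, z_threshold=config.z_threshold
    )
    logger.info("decontam: excluded %d of %d scored genes (Z > %g)",
                filter_report.n_excluded, len(scores), config.z_threshold)

    de_universe = filtered
    if config.drop_markers_before_de:
        keep = [g for g in filtered.genes if g not in set(markers.members)]
        de_universe = filtered.subset_genes(keep)

    floor_genes = [
        g for g in de_universe.genes
        if de_universe.data.loc[g].max() > config.expression_floor
    ]
    logger.info("floor: %d of %d genes exceed %g",
                len(floor_genes), de_universe.n_genes, config.expression_floor)
    floored = de_universe.subset_genes(floor_genes)

    de_results = {}
    contrast_reports = []
    for a, b in config.contrasts:
        group_a = expression.samples_in(a)
        group_b = expression.samples_in(b)
        res = differential_expression(
            floored, group_a, group_b,
            fc_threshold=config.fc_threshold, alpha=config.alpha,
            pseudocount=config.pseudocount,
        )
        de_results[(a, b)] = res
        n_tested = int(res.frame["pvalue"].notna().sum())
        logger.info("DE %s vs %s: %d up, %d down of %d tested",
                    a, b, res.n_up, res.n_down, n_tested)
        contrast_reports.append(
            {"group_a": a, "group_b": b, "n_tested": n_tested,
             "n_up": res.n_up, "n_down": res.n_down, "method": res.method}
        )

    set_summaries = []
    set_reports = []
    for gs in gene_sets:
        for a, b in config.contrasts:
            try:
                summ = gene_set_summary(
                    filtered, gs, expression.samples_in(a), expression.samples_in(b),
                    pseudocount=config.pseudocount,
                )
            except ValueError as err:
                warnings_log.append(f"gene set {gs.name} ({a} vs {b}): {err}")
                continue
            set_summaries.append(((gs.name, a, b), summ))
            set_reports.append(
                {
                    "set": gs.name, "group_a": a, "group_b": b,
                    "n_found": len(summ.log2fc), "n_missing": len(summ.missing),
                    "mean_log2fc": summ.mean_log2fc,
                    "t": summ.ttest.statistic if summ.ttest else None,
                    "pvalue": summ.ttest.pvalue if summ.ttest else None,
                }
            )

    report = RunReport(
        version=__version__,
        config={k: v for k, v in dataclasses.asdict(config).items()},
        stages={
            "n_input_genes": expression.n_genes,
            "n_markers_in_matrix": len(filter_report.marker_genes),
            "n_markers_dropped": len(profile.dropped_markers),
            "n_scored": len(scores),
            "n_degenerate": int(scores["degenerate"].sum()),
            "n_excluded": filter_report.n_excluded,
            "n_retained": filter_report.n_retained,
            "n_de_universe": de_universe.n_genes,
            "n_floor_passing": len(floor_genes),
            "null_mean": null.mean,
            "null_sd": null.sd,
            "seed": config.seed,
            "n_scrambles": config.n_scrambles,
        },
        contrasts=contrast_reports,
        gene_sets=set_reports,
        warnings=warnings_log,
    )
    report.validate()

    products = {
        "profile": profile,
        "scores": scores,
        "null": null,
        "filtered": filtered,
        "filter_report": filter_report,
        "floored": floored,
        "de_results": de_results,
        "gene_set_summaries": set_summaries,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_expression_table(filtered, out_dir / "filtered_matrix.tsv")
        scores.to_csv(out_dir / "gene_scores.tsv", sep="\t")
        for (a, b), res in de_results.items():
            res.frame.to_csv(out_dir / f"de_{a}_vs_{b}.tsv", sep="\t")
        if set_summaries:
            rows = []
            for (name, a, b), summ in set_summaries:
                for gene, lfc in summ.log2fc.items():
                    rows.append({"set": name, "group_a": a, "group_b": b,
                                 "gene": gene, "log2fc": lfc})
            pd.DataFrame(rows).to_csv(out_dir / "gene_set_summaries.tsv",
                                      sep="\t", index=False)
        report.to_json(out_dir / "report.json")

    return report, products


def run_translatome_pipeline(config: PipelineConfig) -> RunReport:
    """File-based entry point: load inputs per config, run, write outputs."""
    config.validate_files()

    meta = read_sample_metadata(config.metadata_path) if config.metadata_path else None
    if config.counts_path is not None:
        counts = read_expression_table(config.counts_path, unit="counts",
                                       sample_meta=meta)
        annot = read_gene_annotation(config.annotation_path)
        libs = (read_library_sizes(config.library_sizes_path)
                if config.library_sizes_path else None)
        logger.info("normalize: FPKM from %d x %d counts",
                    counts.data.shape[0], counts.data.shape[1])
        expression = fpkm_from_counts(counts, annot, libs)
    else:
        expression = read_expression_table(config.fpkm_path, unit="fpkm",
                                           sample_meta=meta)

    marker_sets = read_gene_sets(config.marker_gmt_path, role="contamination_marker")
    if config.marker_set_name is not None:
        by_name = {gs.name: gs for gs in marker_sets}
        if config.marker_set_name not in by_name:
            raise ValueError(
                f"marker set {config.marker_set_name!r} not in "
                f"{config.marker_gmt_path} (has: {sorted(by_name)})"
            )
        markers = by_name[config.marker_set_name]
    else:
        markers = marker_sets[0]

    gene_sets: list[GeneSet] = []
    for p in config.geneset_gmt_paths:
        gene_sets.extend(read_gene_sets(p))

    report, _ = run_from_objects(
        expression, markers, config, gene_sets=gene_sets, out_dir=Path(config.out_dir)
    )
    return report
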