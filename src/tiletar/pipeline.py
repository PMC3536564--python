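"""End-to-end pipeline: simulate/load → normalize → call → TARs → DE → stats.

Every stage writes a TSV/BED file under the run directory so stages are
independently inspectable, and a manifest records the configuration hash,
seed and library versions.  All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .annotation_io import (
    GenomeAnnotation,
    ProbeDesign,
    read_gff,
    read_probe_design,
    write_bed,
    write_gff,
    write_probe_design,
)
from .comparative_stats import (
    chisq_gof,
    classify_ortholog_groups,
    enrichment_report,
    g_test_heterogeneity,
    ks_two_sample,
    pearson_r,
    read_gene_list,
    read_ortholog_map,
)
from .differential_expression import differential_expression_table
from .expression_calling import (
    ExpressionCallSet,
    call_genes,
    call_positive,
    condition_thresholds,
    expression_summary,
    random_probe_baseline,
)
from .normalization import (
    IntensityMatrix,
    normalize,
    read_intensity_matrix,
    summarize_replicates,
    write_intensity_matrix,
)
from .synthetic_data import (
    SimulationParams,
    simulate_dataset,
    write_ground_truth,
)
from .tar_segmentation import (
    TAR,
    estimate_novel_genes,
    filter_novel,
    match_planted,
    segment_tars,
    tar_chromosome_counts,
    unique_tars,
)

log = logging.getLogger(__name__)

CONDITIONS = ("unfertilized", "fertilized")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed driving one analysis run.

    The threshold defaults are the analysis constants of the method: FPR
    0.01, expressed fraction 0.8, TAR minrun 45 / maxgap 0 / ≥3 probes,
    novel-TAR length and distance 100 bp, two-fold change at q < 0.1 and
    4.4 exons per gene for the novel-gene estimate.
    """

    simulate: bool = True
    params: SimulationParams = field(default_factory=SimulationParams)
    annotation_path: str | None = None
    design_path: str | None = None
    matrix_path: str | None = None
    ortholog_map_path: str | None = None
    gene_list_paths: dict = field(default_factory=dict)
    fpr: float = 0.01
    pooled_threshold: bool = False
    expressed_fraction: float = 0.8
    minrun: float = 45
    maxgap: int = 0
    min_probes: int = 3
    tar_min_len: int = 100
    tar_min_dist: int = 100
    fc_threshold: float = 1.0
    q_threshold: float = 0.1
    exons_per_gene: float = 4.4
    seed: int = 0
    outdir: str = "tiletar_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "params" in d and d["params"] is not None:
            if d["params"].get("chromosome_lengths") is not None:
                d["params"]["chromosome_lengths"] = tuple(d["params"]["chromosome_lengths"])
            d["params"] = SimulationParams(**d["params"])
        return cls(**d)


def validate_config(config: PipelineConfig) -> list[str]:
    """All configuration errors at once; empty list means valid."""
    errors: list[str] = []
    if not (0.0 < config.fpr < 1.0):
        errors.append(f"fpr must lie in (0, 1), got {config.fpr}")
    if not (0.0 < config.expressed_fraction < 1.0):
        errors.append(
            f"expressed_fraction must lie in (0, 1), got {config.expressed_fraction}"
        )
    if config.minrun < 0:
        errors.append(f"minrun must be non-negative, got {config.minrun}")
    if config.maxgap < 0:
        errors.append(f"maxgap must be non-negative, got {config.maxgap}")
    if config.min_probes < 1:
        errors.append(f"min_probes must be ≥1, got {config.min_probes}")
    for name in ("tar_min_len", "tar_min_dist"):
        if getattr(config, name) < 0:
            errors.append(f"{name} must be non-negative")
    if config.fc_threshold < 0:
        errors.append("fc_threshold must be non-negative")
    if not (0.0 < config.q_threshold <= 1.0):
        errors.append(f"q_threshold must lie in (0, 1], got {config.q_threshold}")
    if config.exons_per_gene <= 0:
        errors.append("exons_per_gene must be positive")
    if not config.simulate:
        for name in ("annotation_path", "design_path", "matrix_path"):
            p = getattr(config, name)
            if p is None:
                errors.append(f"{name} is required when simulate is false")
            elif not Path(p).exists():
                errors.append(f"{name} does not exist: {p}")
    for name, p in config.gene_list_paths.items():
        if not Path(p).exists():
            errors.append(f"gene list {name!r} does not exist: {p}")
    if config.ortholog_map_path and not Path(config.ortholog_map_path).exists():
        errors.append(f"ortholog map does not exist: {config.ortholog_map_path}")
    return errors


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    design: ProbeDesign
    normalized: IntensityMatrix
    summary: pd.DataFrame
    callsets: dict[str, ExpressionCallSet]
    tars: dict[str, list[TAR]]  # novel TARs per condition
    de_table: pd.DataFrame
    compare: pd.DataFrame
    truth: object | None = None
    outdir: Path | None = None


def _manifest(config: PipelineConfig, outdir: Path) -> None:
    snapshot = yaml.safe_dump(config.to_dict(), sort_keys=True)
    digest = hashlib.sha256(snapshot.encode()).hexdigest()
    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"tiletar {__version__}\n")
        fh.write(f"numpy {np.__version__}; scipy {scipy.__version__}; pandas {pd.__version__}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"config_sha256 {digest}\n")
        fh.write("--- config ---\n")
        fh.write(snapshot)


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all stage outputs."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulate:
        log.info("stage simulate")
        annotation, truth, design, matrix = simulate_dataset(config.params, config.seed)
        write_gff(annotation, outdir / "annotation.gff3")
        write_probe_design(design, outdir / "design.tsv")
        write_intensity_matrix(matrix, outdir / "matrix.tsv")
        write_ground_truth(truth, outdir / "truth_genes.tsv", outdir / "truth_tars.tsv")
    else:
        log.info("stage load")
        annotation = read_gff(config.annotation_path)
        design = read_probe_design(config.design_path, annotation)
        matrix = read_intensity_matrix(config.matrix_path)

    log.info("stage normalize")
    normalized = normalize(matrix, design)
    summary = summarize_replicates(normalized)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index_label="probe_id")

    log.info("stage call")
    thresholds = condition_thresholds(summary, design, config.fpr, config.pooled_threshold)
    baselines = random_probe_baseline(summary, design)
    callsets = call_genes(
        annotation, design, summary, thresholds, baselines, config.expressed_fraction
    )
    calls = pd.concat(
        [cs.table.assign(condition=cond) for cond, cs in callsets.items()]
    )
    calls.to_csv(outdir / "calls.tsv", sep="\t", index_label="gene_id")
    for cond, cs in callsets.items():
        expression_summary(cs, annotation).to_csv(
            outdir / f"expression_summary.{cond}.tsv", sep="\t", index=False
        )

    log.info("stage tars")
    all_tars: dict[str, list[TAR]] = {}
    novel: dict[str, list[TAR]] = {}
    for cond in summary.columns:
        positives = call_positive(summary[cond], thresholds[cond])
        segs = segment_tars(
            positives, design, summary[cond], baselines[cond], cond,
            config.minrun, config.maxgap, config.min_probes,
        )
        all_tars[cond] = segs
        novel[cond] = filter_novel(segs, annotation, config.tar_min_len, config.tar_min_dist)
    write_bed([t for lst in novel.values() for t in lst], outdir / "tars.bed",
              track_name="novel_tars")

    log.info("stage de")
    de_table = differential_expression_table(
        normalized, annotation, design, CONDITIONS,
        config.fc_threshold, config.q_threshold,
    )
    de_table.to_csv(outdir / "de.tsv", sep="\t")

    log.info("stage compare")
    compare = _compare_stage(config, annotation, callsets, novel, de_table, outdir)
    compare.to_csv(outdir / "compare.tsv", sep="\t", index=False)

    _manifest(config, outdir)
    return PipelineResult(
        annotation=annotation, design=design, normalized=normalized, summary=summary,
        callsets=callsets, tars=novel, de_table=de_table, compare=compare,
        truth=truth, outdir=outdir,
    )


def _compare_stage(
    config: PipelineConfig,
    annotation: GenomeAnnotation,
    callsets: dict[str, ExpressionCallSet],
    novel: dict[str, list[TAR]],
    de_table: pd.DataFrame,
    outdir: Path,
) -> pd.DataFrame:
    rows: list[tuple[str, float]] = []
    unf = callsets.get("unfertilized")
    fert = callsets.get("fertilized")

    if unf is not None:
        summ = expression_summary(unf, annotation)
        per_chrom = summ[summ["chromosome"] != "TOTAL"]
        table = np.column_stack(
            [per_chrom["n_expressed"], per_chrom["n_testable"] - per_chrom["n_expressed"]]
        )
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            G, df, p = g_test_heterogeneity(table)
            rows += [("chromosome_heterogeneity_G", G),
                     ("chromosome_heterogeneity_df", df),
                     ("chromosome_heterogeneity_p", p)]
        total = summ[summ["chromosome"] == "TOTAL"].iloc[0]
        genome_frac = total["fraction"]
        rows.append(("maternal_fraction", float(genome_frac)))
        x_rows = per_chrom[per_chrom["class"] == "X"]
        if len(x_rows) and x_rows["n_testable"].sum() > 0:
            gof = chisq_gof(
                int(x_rows["n_expressed"].sum()), int(x_rows["n_testable"].sum()),
                round(float(genome_frac), 3),
            )
            rows += [("x_enrichment_chi2", gof.chi2), ("x_enrichment_p", gof.p_value)]

    for cond, lst in novel.items():
        rows.append((f"novel_tars_{cond}", len(lst)))
        rows.append(
            (f"novel_genes_{cond}", estimate_novel_genes(len(lst), config.exons_per_gene))
        )
        counts = tar_chromosome_counts(lst, annotation)
        if counts["n_tars"].std() > 0 and len(counts) >= 3:
            rows.append(
                (f"tar_length_correlation_{cond}",
                 pearson_r(counts["n_tars"], counts["length"]))
            )
    if set(novel) >= {"unfertilized", "fertilized"}:
        rows.append(
            ("unique_tars_unfertilized",
             len(unique_tars(novel["unfertilized"], novel["fertilized"])))
        )
        rows.append(
            ("unique_tars_fertilized",
             len(unique_tars(novel["fertilized"], novel["unfertilized"])))
        )
        if novel["unfertilized"] and novel["fertilized"]:
            k, p = ks_two_sample(
                [t.interval.length for t in novel["unfertilized"]],
                [t.interval.length for t in novel["fertilized"]],
            )
            rows += [("tar_size_ks_k", k), ("tar_size_ks_p", p)]

    n_de = int((de_table["q"] < config.q_threshold).sum())
    rows.append(("n_de_genes", n_de))
    for cls in ("maternal_degraded", "zygotic_activated"):
        rows.append((f"n_{cls}", int((de_table["de_class"] == cls).sum())))

    if config.ortholog_map_path and unf is not None and fert is not None:
        omap = read_ortholog_map(config.ortholog_map_path)
        groups = classify_ortholog_groups(omap, unf, fert)
        groups.to_csv(outdir / "ortholog_groups.tsv", sep="\t", index_label="source_id")
        for grp in ("A", "B", "C", "excluded"):
            rows.append((f"ortholog_group_{grp}", int((groups == grp).sum())))

    if config.gene_list_paths and unf is not None:
        lists = {name: read_gene_list(p) for name, p in config.gene_list_paths.items()}
        report = enrichment_report(unf, lists, annotation)
        report.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    return pd.DataFrame(rows, columns=["metric", "value"])
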