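"""End-to-end orchestration of the synthetic case analysis.

A single master seed deterministically derives per-stage seeds, so a whole
pipeline run — simulation, germline filtering, somatic subtraction,
CNV/LOH detection, expression-outlier ranking, tissue assignment, report
assembly — is reproducible bit for bit (timestamps aside).
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from oncocase import io as ocio
from oncocase.containers import ExpressionMatrix
from oncocase.loh import call_loh_segments, pair_tumor_normal, segment_depth_ratio, select_informative_hets
from oncocase.outliers import diff_expr_outlier
from oncocase.report import CaseReport, assemble_case_report
from oncocase.synthetic import (
    ExpressionSimConfig,
    GenomeLayout,
    VariantSimConfig,
    simulate_depth_track,
    simulate_expression_compendium,
    simulate_tumor_normal_variants,
)
from oncocase.tissue import (
    SimilaritySpace,
    assign_tissue,
    correlation_similarity,
    embed_2d,
    subsample_per_type,
    transform_compendium,
)
from oncocase.variants import (
    GeneLists,
    call_somatic_by_subtraction,
    characterize_somatic,
    records_from_frame,
    run_filter_cascade,
)

logger = logging.getLogger("oncocase")

STAGES = ("variants", "depth", "expression", "tissue")

DEFAULT_CONFIG: dict[str, Any] = {
    "master_seed": 17,
    "variants": {
        "n_germline_het": 800,
        "n_germline_hom": 100,
        "n_somatic": 20,
        "somatic_af_range": [0.15, 0.5],
        "normal_contamination_af": 0.0,
        "mean_depth": 500.0,
        "fraction_in_cosmic": 0.15,
    },
    "layout": {
        "chromosomes": [["chr1", 60_000_000], ["chr2", 50_000_000],
                        ["chr8", 40_000_000], ["chr17", 30_000_000]],
        "bin_size": 100_000,
        "loh_segments": [["chr2", 10_000_000, 40_000_000, "copy_neutral"],
                         ["chr8", 5_000_000, 35_000_000, "gain"],
                         ["chr17", 5_000_000, 25_000_000, "deletion"]],
    },
    "expression": {
        "n_genes": 1200,
        "n_housekeeping": 120,
        "n_tissues": 4,
        "samples_per_tissue": 30,
        "n_outlier_genes_up": 8,
        "n_outlier_genes_down": 8,
    },
    "gene_lists": {
        "reference_range": ["GENE0001", "GENE0002", "GENE0003", "GENE0004"],
        "acmg": ["GENE0010", "GENE0011", "GENE0012"],
    },
    "analysis": {
        "test_tissue": 2,
        "top_frac": 0.10,
        "max_per_type": 100,
        "perplexity": 30.0,
        "knn": 15,
        "depth_noise_sd": 0.2,
    },
}


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-2^31 seed per stage from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {stage: int(s & 0x7FFFFFFF) for stage, s in zip(STAGES, state)}


def merged_config(config: dict | None) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _build_layout(cfg: dict) -> GenomeLayout:
    return GenomeLayout(
        chromosomes=tuple((str(c), int(l)) for c, l in cfg["chromosomes"]),
        bin_size=int(cfg["bin_size"]),
        loh_segments=tuple(
            (str(c), int(s), int(e), str(k)) for c, s, e, k in cfg["loh_segments"]
        ),
    )


def simulate_case(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run only the generators; returns (and optionally writes) the inputs."""
    cfg = merged_config(config)
    seeds = stage_seeds(int(cfg["master_seed"]))
    layout = _build_layout(cfg["layout"])
    vkw = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg["variants"].items()}
    normal, tumor, truth = simulate_tumor_normal_variants(
        VariantSimConfig(**vkw, seed=seeds["variants"]), layout
    )
    depth = simulate_depth_track(
        layout, VariantSimConfig(**vkw, seed=seeds["depth"]),
        noise_sd=float(cfg["analysis"]["depth_noise_sd"]),
    )
    reference, test, expr_truth = simulate_expression_compendium(
        ExpressionSimConfig(**cfg["expression"], seed=seeds["expression"]),
        test_tissue=int(cfg["analysis"]["test_tissue"]),
    )
    artifacts = {
        "layout": layout, "normal": normal, "tumor": tumor, "truth": truth,
        "depth": depth, "reference": reference, "test": test,
        "expression_truth": expr_truth, "seeds": seeds,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ocio.write_variants_vcf(normal, out / "normal.vcf", "NORMAL", layout.chromosomes)
        ocio.write_variants_vcf(tumor, out / "tumor.vcf", "TUMOR", layout.chromosomes)
        truth.to_csv(out / "variants_truth.tsv", sep="\t", index=False)
        depth.to_csv(out / "depth_bins.tsv", sep="\t", index=False)
        reference.to_tsv(out / "expression_reference.tsv", out / "expression_labels.tsv",
                         out / "housekeeping_genes.txt")
        test.rename("TEST").to_csv(out / "expression_test.tsv", sep="\t", index_label="gene")
        expr_truth["outliers"].to_csv(out / "expression_truth.tsv", sep="\t", index=False)
        ocio.write_provenance(out / "provenance.json", config=cfg, seeds=seeds)
    return artifacts


def run_all(config: dict | None = None, outdir: str | Path | None = None) -> tuple[CaseReport, dict]:
    """Run the full synthetic case analysis; returns (report, artifacts).

    ``artifacts`` carries every intermediate stage object keyed by stage
    name.  When ``outdir`` is given, stage outputs are also written as
    VCF/TSV/BED files plus report.json and report.txt.
    """
    cfg = merged_config(config)
    seeds = stage_seeds(int(cfg["master_seed"]))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    layout = _build_layout(cfg["layout"])
    vcfg = VariantSimConfig(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in cfg["variants"].items()},
        seed=seeds["variants"],
    )
    normal, tumor, truth = simulate_tumor_normal_variants(vcfg, layout)
    depth = simulate_depth_track(layout, VariantSimConfig(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in cfg["variants"].items()},
        seed=seeds["depth"],
    ), noise_sd=float(cfg["analysis"]["depth_noise_sd"]))
    ecfg = ExpressionSimConfig(**cfg["expression"], seed=seeds["expression"])
    reference, test, expr_truth = simulate_expression_compendium(
        ecfg, test_tissue=int(cfg["analysis"]["test_tissue"])
    )
    logger.info("simulate: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    normal_records = records_from_frame(normal, "normal")
    tumor_records = records_from_frame(tumor, "tumor")
    lists = GeneLists.from_iterables(
        cfg["gene_lists"]["reference_range"], cfg["gene_lists"]["acmg"]
    )
    germline_decisions = run_filter_cascade(normal_records, lists)
    somatic = call_somatic_by_subtraction(tumor_records, normal_records)
    annotations = characterize_somatic(somatic)
    logger.info("variant filtering: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    paired = pair_tumor_normal(normal_records, tumor_records)
    sites = select_informative_hets(paired)
    cnv = segment_depth_ratio(depth)
    loh = call_loh_segments(sites, cnv)
    logger.info("loh/cnv: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    outlier_report = diff_expr_outlier(
        reference, test, top_frac=float(cfg["analysis"]["top_frac"])
    )
    logger.info("expression outliers: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    labels = reference.sample_labels
    kept = subsample_per_type(
        labels, max_per_type=int(cfg["analysis"]["max_per_type"]), seed=seeds["tissue"]
    )
    pool = pd.concat([reference.values[kept], test.rename("TEST")], axis=1)
    transformed, fits = transform_compendium(pool, seed=seeds["tissue"])
    ref_transformed = transformed[kept]
    space = SimilaritySpace(
        transformed=ref_transformed,
        similarity=correlation_similarity(ref_transformed),
        labels=labels.loc[kept],
    )
    assignment = assign_tissue(transformed["TEST"], space, k=int(cfg["analysis"]["knn"]))
    embedding = embed_2d(
        correlation_similarity(transformed),
        perplexity=float(cfg["analysis"]["perplexity"]), seed=seeds["tissue"],
    )
    logger.info("tissue similarity: %.2fs", time.perf_counter() - t0)

    report = assemble_case_report(
        germline_decisions, annotations, cnv, loh, outlier_report, assignment,
        config=cfg, seeds=seeds,
    )

    artifacts = {
        "layout": layout,
        "normal": normal, "tumor": tumor, "truth": truth,
        "depth": depth,
        "reference": reference, "test": test, "expression_truth": expr_truth,
        "germline_decisions": germline_decisions,
        "somatic": somatic, "annotations": annotations,
        "sites": sites, "cnv": cnv, "loh": loh,
        "outlier_report": outlier_report,
        "transformed": transformed, "fits": fits, "space": space,
        "assignment": assignment, "embedding": embedding,
        "seeds": seeds,
    }

    if out is not None:
        write_stage_outputs(out, cfg, artifacts, report)
    return report, artifacts


def write_stage_outputs(out: Path, cfg: dict, artifacts: dict, report: CaseReport) -> None:
    layout: GenomeLayout = artifacts["layout"]
    ocio.write_variants_vcf(artifacts["normal"], out / "normal.vcf", "NORMAL", layout.chromosomes)
    ocio.write_variants_vcf(artifacts["tumor"], out / "tumor.vcf", "TUMOR", layout.chromosomes)
    artifacts["truth"].to_csv(out / "variants_truth.tsv", sep="\t", index=False)
    artifacts["depth"].to_csv(out / "depth_bins.tsv", sep="\t", index=False)
    reference: ExpressionMatrix = artifacts["reference"]
    reference.to_tsv(out / "expression_reference.tsv", out / "expression_labels.tsv",
                     out / "housekeeping_genes.txt")
    artifacts["test"].rename("TEST").to_csv(out / "expression_test.tsv", sep="\t",
                                            index_label="gene")
    artifacts["expression_truth"]["outliers"].to_csv(
        out / "expression_truth.tsv", sep="\t", index=False
    )
    ocio.write_segments_bed(artifacts["cnv"], out / "cnv_segments.bed")
    ocio.write_segments_bed(artifacts["loh"], out / "loh_segments.bed")
    from oncocase.outliers import write_outlier_report

    write_outlier_report(artifacts["outlier_report"], out / "outlier_report.tsv")
    coords = artifacts["embedding"].coordinates.copy()
    labels = artifacts["space"].labels
    coords["label"] = [labels.get(s, "TEST") for s in coords.index]
    coords.to_csv(out / "embedding.tsv", sep="\t", index_label="sample")
    ocio.write_provenance(out / "provenance.json", config=cfg, seeds=artifacts["seeds"])
    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.txt").write_text(report.to_text())
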