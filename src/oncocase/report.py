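"""Tiered case-report assembly.

Collects the per-stage outputs — germline filter decisions, characterized
somatic variants, copy-number and LOH segments, flagged expression
outliers, and the tissue-of-origin assignment — into one validated,
machine-readable case report, cross-referencing somatic variants against
the LOH segments containing them and against expression-outlier flags on
the same gene.  Segment coordinates are 0-based half-open and variant
positions 1-based; the intersection converts explicitly (pos - 1 in
[start, end)).
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from oncocase.loh import CnvSegment, LohSegment
from oncocase.variants import FilterDecision, SomaticAnnotation


class GermlineFinding(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    report_bucket: str
    normal_af: float | None = None
    population_af: float | None = None


class SomaticFinding(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    tumor_af: float
    normal_af: float
    flags: list[str] = Field(default_factory=list)
    loh_segment_class: str | None = None
    expression_flag: str | None = None


class SegmentReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str
    start: int
    end: int
    segment_class: str
    mean_statistic: float
    n_features: int


class ExpressionOutlierReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gene: str
    normalized: float
    rank: float
    percentile: float
    z: float | None = None
    flag: str


class TissueAssignment(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    vote_fraction: float
    per_label_similarity: dict[str, float]


class Provenance(BaseModel):
    model_config = ConfigDict(extra="forbid")
    config: dict
    seeds: dict[str, int]
    version: str
    timestamp: str


class CaseReport(BaseModel):
    """Machine-readable multi-evidence case summary."""

    model_config = ConfigDict(extra="forbid")
    germline_findings: list[GermlineFinding]
    somatic_findings: list[SomaticFinding]
    cnv_segments: list[SegmentReport]
    loh_segments: list[SegmentReport]
    expression_outliers: list[ExpressionOutlierReport]
    tissue_assignment: TissueAssignment | None = None
    provenance: Provenance

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = ["# Case report", ""]
        lines.append(f"Germline findings ({len(self.germline_findings)}):")
        for g in self.germline_findings:
            lines.append(
                f"  {g.gene} {g.chrom}:{g.pos} {g.ref}>{g.alt} "
                f"[{g.consequence}] bucket={g.report_bucket}"
            )
        lines.append("")
        lines.append(f"Somatic findings ({len(self.somatic_findings)}):")
        for s in self.somatic_findings:
            extra = ",".join(s.flags) or "-"
            loh = f" in {s.loh_segment_class}" if s.loh_segment_class else ""
            expr = f" expr={s.expression_flag}" if s.expression_flag else ""
            lines.append(
                f"  {s.gene} {s.chrom}:{s.pos} {s.ref}>{s.alt} [{s.consequence}] "
                f"tumorAF={s.tumor_af:.2f} flags={extra}{loh}{expr}"
            )
        lines.append("")
        lines.append(f"CNV segments ({len(self.cnv_segments)}):")
        for seg in self.cnv_segments:
            lines.append(
                f"  {seg.chrom}:{seg.start}-{seg.end} {seg.segment_class} "
                f"log2={seg.mean_statistic:.2f} ({seg.n_features} bins)"
            )
        lines.append("")
        lines.append(f"LOH segments ({len(self.loh_segments)}):")
        for seg in self.loh_segments:
            lines.append(
                f"  {seg.chrom}:{seg.start}-{seg.end} {seg.segment_class} "
                f"BAF-dev={seg.mean_statistic:.2f} ({seg.n_features} sites)"
            )
        lines.append("")
        lines.append(f"Expression outliers ({len(self.expression_outliers)}):")
        for o in self.expression_outliers[:25]:
            z = f"{o.z:+.2f}" if o.z is not None else "NA"
            lines.append(f"  {o.gene} flag={o.flag} percentile={o.percentile:.3f} z={z}")
        if len(self.expression_outliers) > 25:
            lines.append(f"  ... and {len(self.expression_outliers) - 25} more")
        lines.append("")
        if self.tissue_assignment is not None:
            t = self.tissue_assignment
            lines.append(
                f"Tissue of origin: {t.label} (vote {t.vote_fraction:.2f})"
            )
        return "\n".join(lines) + "\n"


def strip_timestamps(report_json: str) -> dict:
    """Parse report JSON and drop timestamp fields (for determinism checks)."""
    data = json.loads(report_json)
    data.get("provenance", {}).pop("timestamp", None)
    return data


def case_report_schema() -> dict:
    return CaseReport.model_json_schema()


def assemble_case_report(
    germline_decisions: Sequence[FilterDecision],
    somatic_annotations: Sequence[SomaticAnnotation],
    cnv_segments: Sequence[CnvSegment],
    loh_segments: Sequence[LohSegment],
    outlier_report: pd.DataFrame,
    tissue_assignment: tuple[str, float, pd.Series] | None,
    config: dict,
    seeds: dict[str, int],
    version: str = "0.1.0",
    timestamp: str | None = None,
) -> CaseReport:
    """Assemble stage outputs into a validated CaseReport.

    Somatic variants are cross-referenced against LOH segments (a variant
    whose locus lies inside a segment carries that segment's class) and
    against flagged expression outliers on the same gene.  Only germline
    variants in reportable buckets (reference_range / reportable_range)
    are listed.
    """
    germline = [
        GermlineFinding(
            chrom=d.variant.chrom, pos=d.variant.pos, ref=d.variant.ref,
            alt=d.variant.alt, gene=d.variant.gene,
            consequence=d.variant.consequence, report_bucket=d.report_bucket,
            normal_af=None if pd.isna(d.variant.normal_af) else d.variant.normal_af,
            population_af=d.variant.population_af,
        )
        for d in germline_decisions
        if d.report_bucket in ("reference_range", "reportable_range")
    ]

    flagged = outlier_report[outlier_report["flag"] != "none"]
    flag_by_gene = flagged["flag"].to_dict()

    somatic = []
    for ann in somatic_annotations:
        rec = ann.variant
        loh_class = None
        for seg in loh_segments:
            if seg.chrom == rec.chrom and seg.start <= rec.pos - 1 < seg.end:
                loh_class = seg.loh_class
                break
        somatic.append(
            SomaticFinding(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt,
                gene=rec.gene, consequence=rec.consequence,
                tumor_af=rec.tumor_af, normal_af=rec.normal_af,
                flags=ann.flags(), loh_segment_class=loh_class,
                expression_flag=flag_by_gene.get(rec.gene),
            )
        )

    cnv = [
        SegmentReport(chrom=s.chrom, start=s.start, end=s.end, segment_class=s.call,
                      mean_statistic=s.mean_log2_ratio, n_features=s.n_bins)
        for s in cnv_segments
    ]
    loh = [
        SegmentReport(chrom=s.chrom, start=s.start, end=s.end, segment_class=s.loh_class,
                      mean_statistic=s.mean_baf_deviation, n_features=s.n_sites)
        for s in loh_segments
    ]
    outliers = [
        ExpressionOutlierReport(
            gene=str(gene), normalized=float(row["normalized"]),
            rank=float(row["rank"]), percentile=float(row["percentile"]),
            z=None if pd.isna(row.get("z")) else float(row["z"]),
            flag=str(row["flag"]),
        )
        for gene, row in flagged.iterrows()
    ]

    assignment = None
    if tissue_assignment is not None:
        label, vote, per_label = tissue_assignment
        assignment = TissueAssignment(
            label=label, vote_fraction=vote,
            per_label_similarity={str(k): float(v) for k, v in per_label.items()},
        )

    return CaseReport(
        germline_findings=germline,
        somatic_findings=somatic,
        cnv_segments=cnv,
        loh_segments=loh,
        expression_outliers=outliers,
        tissue_assignment=assignment,
        provenance=Provenance(
            config=config, seeds=seeds, version=version,
            timestamp=timestamp or _dt.datetime.now(_dt.timezone.utc).isoformat(),
        ),
    )


def load_case_report(path: str | Path) -> CaseReport:
    """Parse and validate a case-report JSON file."""
    return CaseReport.model_validate_json(Path(path).read_text())
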