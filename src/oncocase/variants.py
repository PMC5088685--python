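"""Germline filter cascade, tumor/normal somatic subtraction, and
characterization of somatic variants.

The germline cascade mirrors a clinical exome workflow: a *reference range*
filter (cancer-predisposition / pharmacogenomics / patient-care genes), a
*reportable range* filter (variants catalogued in COSMIC, or in genes on the
ACMG secondary-findings list), and a population-frequency filter retaining
variants whose 1000-Genomes minor allele frequency is strictly below 1%
(missing frequency is treated as rare).  Somatic calls are obtained by
subtracting the normal call set (at >= 5% allelic fraction) from the tumor
call set (at >= 10% allelic fraction), matched exactly on
(chrom, pos, ref, alt).  Coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DISRUPTIVE_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice"})

VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One called small variant with tumor/normal evidence and annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    normal_af: float = math.nan
    tumor_af: float = math.nan
    normal_depth: int = 0
    tumor_depth: int = 0
    genotype_normal: str = "missing"
    population_af: float | None = None
    in_cosmic: bool = False
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for af in (self.normal_af, self.tumor_af):
            if not math.isnan(af) and not 0.0 <= af <= 1.0:
                raise ValueError("allelic fractions must lie in [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneLists:
    """Gene panels driving the reference/reportable range filters."""

    reference_range_genes: frozenset[str] = frozenset()
    acmg_genes: frozenset[str] = frozenset()

    @classmethod
    def from_iterables(cls, reference_range: Iterable[str], acmg: Iterable[str]) -> "GeneLists":
        return cls(
            reference_range_genes=frozenset(g.upper() for g in reference_range),
            acmg_genes=frozenset(g.upper() for g in acmg),
        )


#: genotype per site for proband, mother, father: {ref, het, hom, missing}
TrioGenotypes = Mapping[VariantKey, tuple[str, str, str]]


@dataclass
class FilterDecision:
    """Outcome of the germline filter cascade for one variant."""

    variant: VariantRecord
    passed_filters: list[str] = field(default_factory=list)
    failed_filter: str | None = None
    report_bucket: str = "frequency_pass"  # reference_range | reportable_range | frequency_pass | excluded

    def __post_init__(self) -> None:
        if (self.failed_filter is not None) != (self.report_bucket == "excluded"):
            raise ValueError("failed_filter must be set iff report_bucket is 'excluded'")


def _as_decisions(variants: Sequence[VariantRecord | FilterDecision]) -> list[FilterDecision]:
    return [
        v if isinstance(v, FilterDecision) else FilterDecision(variant=v) for v in variants
    ]


def apply_reference_range_filter(
    variants: Sequence[VariantRecord | FilterDecision], lists: GeneLists
) -> list[FilterDecision]:
    """Bucket variants in reference-range genes; pass everything else through.

    No variant is dropped: on-panel variants get ``report_bucket =
    "reference_range"``, the rest continue to later filters unchanged.
    """
    if not lists.reference_range_genes:
        raise ValueError("reference range filter enabled with an empty gene list")
    out = []
    for dec in _as_decisions(variants):
        if dec.report_bucket == "excluded":
            out.append(dec)
            continue
        if dec.variant.gene.upper() in lists.reference_range_genes:
            dec.report_bucket = "reference_range"
        dec.passed_filters.append("reference_range")
        out.append(dec)
    return out


def apply_reportable_range_filter(
    variants: Sequence[VariantRecord | FilterDecision], lists: GeneLists
) -> list[FilterDecision]:
    """Bucket COSMIC variants and variants in ACMG secondary-findings genes.

    A variant already bucketed as reference_range keeps that bucket (the
    panels are tiers, reference range first).
    """
    out = []
    for dec in _as_decisions(variants):
        if dec.report_bucket in ("excluded", "reference_range"):
            out.append(dec)
            continue
        if dec.variant.in_cosmic or dec.variant.gene.upper() in lists.acmg_genes:
            dec.report_bucket = "reportable_range"
        dec.passed_filters.append("reportable_range")
        out.append(dec)
    return out


def apply_frequency_filter(
    variants: Sequence[VariantRecord | FilterDecision], threshold: float = 0.01
) -> list[FilterDecision]:
    """Exclude variants whose population minor allele frequency is >= threshold.

    Retention is strict: ``population_af < threshold``.  A missing population
    frequency is treated as rare (novel variants are retained).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    out = []
    for dec in _as_decisions(variants):
        if dec.report_bucket == "excluded":
            out.append(dec)
            continue
        paf = dec.variant.population_af
        missing = paf is None or (isinstance(paf, float) and math.isnan(paf))
        if missing or paf < threshold:
            dec.passed_filters.append("frequency")
        else:
            dec.failed_filter = "frequency"
            dec.report_bucket = "excluded"
        out.append(dec)
    return out


def run_filter_cascade(
    variants: Sequence[VariantRecord],
    lists: GeneLists,
    frequency_threshold: float = 0.01,
) -> list[FilterDecision]:
    """Full germline cascade: frequency, then reference range, then reportable.

    Every input variant lands in exactly one bucket: excluded,
    reference_range, reportable_range, or frequency_pass.
    """
    decisions = apply_frequency_filter(variants, threshold=frequency_threshold)
    decisions = apply_reference_range_filter(decisions, lists)
    decisions = apply_reportable_range_filter(decisions, lists)
    return decisions


# ---------------------------------------------------------------------------
# somatic subtraction and characterization
# ---------------------------------------------------------------------------

def _index_by_key(records: Sequence[VariantRecord], table: str) -> dict[VariantKey, VariantRecord]:
    index: dict[VariantKey, VariantRecord] = {}
    for rec in records:
        if rec.key in index:
            raise ValueError(f"duplicate variant key {rec.key} in {table} table")
        index[rec.key] = rec
    return index


def call_somatic_by_subtraction(
    tumor_variants: Sequence[VariantRecord],
    normal_variants: Sequence[VariantRecord],
    normal_min_af: float = 0.05,
    tumor_min_af: float = 0.10,
) -> list[VariantRecord]:
    """Somatic = tumor calls (AF >= 10%) minus normal calls (AF >= 5%).

    Records are matched exactly on (chrom, pos, ref, alt).  Output records
    carry both fractions: the matched normal AF when the site was seen in
    the normal below its calling threshold, else 0.
    """
    normal_index = _index_by_key(normal_variants, "normal")
    _index_by_key(tumor_variants, "tumor")  # duplicate check
    somatic = []
    for rec in tumor_variants:
        if rec.tumor_af < tumor_min_af:
            continue
        match = normal_index.get(rec.key)
        if match is not None and match.normal_af >= normal_min_af:
            continue
        out = replace(rec)
        out.normal_af = match.normal_af if match is not None else 0.0
        out.normal_depth = match.normal_depth if match is not None else 0
        out.genotype_normal = match.genotype_normal if match is not None else "missing"
        somatic.append(out)
    return somatic


@dataclass
class SomaticAnnotation:
    """Characterization flags for one somatic variant."""

    variant: VariantRecord
    homozygous: bool = False
    compound_heterozygous: bool = False
    de_novo: bool | None = None  # None = indeterminate (no trio / missing parent)
    disruptive: bool = False
    loh_suggestive: bool = False

    def flags(self) -> list[str]:
        out = []
        for name in ("homozygous", "compound_heterozygous", "disruptive", "loh_suggestive"):
            if getattr(self, name):
                out.append(name)
        if self.de_novo:
            out.append("de_novo")
        return out


def characterize_somatic(
    somatic: Sequence[VariantRecord],
    trio: TrioGenotypes | None = None,
    hom_af_threshold: float = 0.85,
    loh_af_threshold: float = 0.70,
) -> list[SomaticAnnotation]:
    """Flag variants as homozygous, compound het, de novo, disruptive, LOH-like.

    * homozygous: tumor AF >= ``hom_af_threshold``.
    * compound_heterozygous: >= 2 retained non-homozygous variants in the
      same gene.
    * de_novo: present in the proband germline and absent (ref) in both
      parents; requires a trio, else ``None`` (indeterminate).  A missing
      parental genotype at the site yields ``None``, never ``False``.
    * disruptive: loss-of-function consequence (nonsense/frameshift/splice).
    * loh_suggestive: tumor AF >= ``loh_af_threshold`` while the normal
      genotype at the site is heterozygous.
    """
    annotations = [SomaticAnnotation(variant=rec) for rec in somatic]
    by_gene: dict[str, list[SomaticAnnotation]] = {}
    for ann in annotations:
        rec = ann.variant
        ann.homozygous = rec.tumor_af >= hom_af_threshold
        ann.disruptive = rec.consequence in DISRUPTIVE_CONSEQUENCES
        ann.loh_suggestive = rec.genotype_normal == "het" and rec.tumor_af >= loh_af_threshold
        if trio is not None:
            genos = trio.get(rec.key)
            if genos is None:
                ann.de_novo = None
            else:
                proband, mother, father = genos
                if proband in ("het", "hom") and "missing" not in (mother, father):
                    ann.de_novo = mother == "ref" and father == "ref"
                elif proband == "ref":
                    ann.de_novo = False
                else:
                    ann.de_novo = None
        if rec.gene:
            by_gene.setdefault(rec.gene, []).append(ann)
    for anns in by_gene.values():
        non_hom = [a for a in anns if not a.homozygous]
        if len(non_hom) >= 2:
            for a in non_hom:
                a.compound_heterozygous = True
    return annotations


# ---------------------------------------------------------------------------
# table adapters
# ---------------------------------------------------------------------------

def records_from_frame(df: pd.DataFrame, role: str) -> list[VariantRecord]:
    """Build VariantRecords from a simulated call table (see synthetic)."""
    if role not in ("normal", "tumor"):
        raise ValueError("role must be 'normal' or 'tumor'")
    records = []
    for row in df.itertuples(index=False):
        paf = getattr(row, "population_af", None)
        if paf is not None and isinstance(paf, float) and np.isnan(paf):
            paf = None
        kwargs = dict(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene=getattr(row, "gene", ""),
            consequence=getattr(row, "consequence", "other"),
            population_af=paf,
            in_cosmic=bool(getattr(row, "in_cosmic", False)),
            quality=float(getattr(row, "quality", 0.0)),
        )
        if role == "normal":
            kwargs.update(normal_af=float(row.af), normal_depth=int(row.depth),
                          genotype_normal=str(getattr(row, "genotype", "missing")))
        else:
            kwargs.update(tumor_af=float(row.af), tumor_depth=int(row.depth))
        records.append(VariantRecord(**kwargs))
    return records
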