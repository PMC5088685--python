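"""File I/O: VCF 4.2 variant tables, TSV tracks and matrices, gene lists.

Variant tables are written as single-sample VCF 4.2 with per-sample GT,
AD (ref/alt read counts) and DP, plus INFO annotations (gene, consequence
class, population allele frequency, COSMIC membership).  Multi-allelic
records are decomposed into biallelic records on read so that
(chrom, pos, ref, alt) keys are unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from oncocase.loh import CnvSegment, LohSegment
from oncocase.variants import GeneLists, VariantRecord

_GT = {"het": (0, 1), "hom": (1, 1), "missing": (None,)}


def write_variants_vcf(
    table: pd.DataFrame,
    path: str | Path,
    sample: str,
    chromosomes: Sequence[tuple[str, int]],
) -> None:
    """Write a simulated call table (see synthetic module) as VCF 4.2."""
    header = pysam.VariantHeader()
    for chrom, length in chromosomes:
        header.contigs.add(chrom, length=length)
    header.add_meta("INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Gene symbol")])
    header.add_meta("INFO", items=[("ID", "CSQ"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Consequence class")])
    header.add_meta("INFO", items=[("ID", "PAF"), ("Number", "1"), ("Type", "Float"),
                                   ("Description", "Population minor allele frequency")])
    header.add_meta("INFO", items=[("ID", "COSMIC"), ("Number", "0"), ("Type", "Flag"),
                                   ("Description", "Catalogued somatic variant")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Read depth per allele")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Total read depth")])
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in table.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt), qual=float(row.quality),
            )
            rec.info["GENE"] = row.gene
            rec.info["CSQ"] = row.consequence
            paf = row.population_af
            if paf is not None and not (isinstance(paf, float) and math.isnan(paf)):
                rec.info["PAF"] = float(paf)
            if bool(row.in_cosmic):
                rec.info["COSMIC"] = True
            depth = int(row.depth)
            alt_count = int(row.alt_count)
            rec.samples[sample]["GT"] = _GT.get(str(getattr(row, "genotype", "missing")), (None,))
            rec.samples[sample]["AD"] = (depth - alt_count, alt_count)
            rec.samples[sample]["DP"] = depth
            vcf.write(rec)


def read_variants_vcf(path: str | Path, role: str) -> list[VariantRecord]:
    """Read a single-sample VCF into VariantRecords.

    ``role`` ("normal" or "tumor") decides which AF/depth slots the sample
    evidence fills.  Multi-allelic records are decomposed into biallelic
    ones; the per-allele AF uses that allele's AD over DP.
    """
    if role not in ("normal", "tumor"):
        raise ValueError("role must be 'normal' or 'tumor'")
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, found {len(samples)} samples")
        sample = samples[0]
        for rec in vcf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            gt = fmt.get("GT")
            for allele_idx, alt in enumerate(rec.alts or (), start=1):
                depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad or ()))
                alt_count = int(ad[allele_idx]) if ad is not None and len(ad) > allele_idx else 0
                af = alt_count / depth if depth > 0 else float("nan")
                if gt is None or all(g is None for g in gt):
                    genotype = "missing"
                elif all(g == allele_idx for g in gt if g is not None) and len(gt) > 1:
                    genotype = "hom"
                elif allele_idx in gt:
                    genotype = "het"
                else:
                    genotype = "missing"
                paf = rec.info.get("PAF")
                kwargs = dict(
                    chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                    gene=str(rec.info.get("GENE", "")),
                    consequence=str(rec.info.get("CSQ", "other")),
                    population_af=float(paf) if paf is not None else None,
                    in_cosmic=bool(rec.info.get("COSMIC", False)),
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                )
                if role == "normal":
                    kwargs.update(normal_af=af, normal_depth=depth, genotype_normal=genotype)
                else:
                    kwargs.update(tumor_af=af, tumor_depth=depth)
                records.append(VariantRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# segments, gene lists, provenance
# ---------------------------------------------------------------------------

def write_segments_bed(
    segments: Sequence[CnvSegment | LohSegment], path: str | Path
) -> None:
    """Write segments as BED: name = class/call, score = mean statistic."""
    with open(path, "w") as fh:
        for seg in segments:
            if isinstance(seg, LohSegment):
                name, score = seg.loh_class, seg.mean_baf_deviation
            else:
                name, score = seg.call, seg.mean_log2_ratio
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{name}\t{score:.4f}\n")


def read_gene_lists(path: str | Path) -> GeneLists:
    """Read reference-range and ACMG gene panels from a YAML file.

    Expected keys: ``reference_range`` and ``acmg``, each a list of gene
    symbols.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneLists.from_iterables(
        reference_range=data.get("reference_range", []),
        acmg=data.get("acmg", []),
    )


def read_af_table(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """Read a population allele-frequency TSV (chrom, pos, ref, alt, af)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.af)
        for r in df.itertuples(index=False)
    }


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_provenance(path: str | Path, **blocks) -> None:
    """Echo generation parameters into a JSON provenance block."""
    Path(path).write_text(json.dumps(_jsonable(blocks), indent=2, sort_keys=True) + "\n")
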