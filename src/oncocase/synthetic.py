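"""Seeded synthetic-data generators with ground truth.

Three generators emulate the inputs of the case-analysis pipeline:

* paired tumor/normal small-variant tables with germline heterozygous /
  homozygous sites, spiked somatic variants at controlled allelic
  fractions, and allelic-imbalance (LOH) segments;
* a binned log2 tumor/normal depth-ratio track with copy-number segments;
* a gene x sample expression compendium with housekeeping genes, tissue
  cluster structure and spiked outlier genes, plus a test sample.

Every generator is deterministic given its config seed and emits a truth
table so downstream detections can be scored exactly.  Allelic-fraction
noise follows read sampling: per-site depth is Poisson(mean_depth) and the
alternate-read count is Binomial(depth, true fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from oncocase.containers import ExpressionMatrix

# tumor-cell fraction of the shifted allele inside an LOH segment; 0.85 is
# a ~70%-pure tumor losing one allele
LOH_TUMOR_BAF = 0.85

_CONSEQUENCES = ("missense", "synonymous", "nonsense", "frameshift", "splice", "other")
_CONSEQUENCE_P = (0.50, 0.20, 0.08, 0.07, 0.05, 0.10)
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantSimConfig:
    """Parameters of the paired tumor/normal variant simulation."""

    n_germline_het: int = 500
    n_germline_hom: int = 100
    n_somatic: int = 20
    somatic_af_range: tuple[float, float] = (0.15, 0.5)
    normal_contamination_af: float = 0.0
    mean_depth: float = 500.0
    af_noise_model: str = "binomial"
    # ("beta", a, b, p_missing): population AF ~ Beta(a, b), with a fraction
    # p_missing of variants absent from the population table (novel).
    population_af_spec: tuple = ("beta", 0.2, 2.0, 0.2)
    fraction_in_cosmic: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.somatic_af_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("somatic_af_range must satisfy 0 < lo < hi < 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in ("normal_contamination_af", "fraction_in_cosmic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.af_noise_model != "binomial":
            raise ValueError("only the binomial AF noise model is supported")
        for n in ("n_germline_het", "n_germline_hom", "n_somatic"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be non-negative")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes, binning, and true LOH/CNV segments.

    ``loh_segments`` are (chrom, start, end, class) tuples with 0-based
    half-open coordinates and class in {copy_neutral, deletion, gain};
    ``cnv_log2_ratios`` gives the true depth log2 ratio of each segment
    (defaults: copy_neutral 0.0, deletion -1.0, gain +0.58).
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 100_000_000),)
    bin_size: int = 100_000
    loh_segments: tuple[tuple[str, int, int, str], ...] = ()
    cnv_log2_ratios: tuple[float, ...] = ()

    _DEFAULT_RATIOS = {"copy_neutral": 0.0, "deletion": -1.0, "gain": 0.58}

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        sizes = dict(self.chromosomes)
        for chrom, start, end, cls in self.loh_segments:
            if chrom not in sizes:
                raise ValueError(f"segment on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= sizes[chrom]):
                raise ValueError(f"segment {chrom}:{start}-{end} outside chromosome bounds")
            if cls not in self._DEFAULT_RATIOS:
                raise ValueError(f"unknown segment class {cls!r}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.loh_segments:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom}")
        if self.cnv_log2_ratios and len(self.cnv_log2_ratios) != len(self.loh_segments):
            raise ValueError("cnv_log2_ratios must match loh_segments in length")

    def segment_log2_ratios(self) -> tuple[float, ...]:
        if self.cnv_log2_ratios:
            return self.cnv_log2_ratios
        return tuple(self._DEFAULT_RATIOS[cls] for _, _, _, cls in self.loh_segments)


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the synthetic expression compendium.

    Expression is simulated on the log2(FPKM+1) scale as a two-component
    mixture (non-expressed vs expressed genes) and exponentiated to FPKM.
    The expressed/non-expressed assignment of a gene is shared within a
    tissue and partially re-drawn across tissues (``tissue_distinct_frac``)
    so tissues form separable clusters.
    """

    n_genes: int = 2000
    n_housekeeping: int = 200
    n_tissues: int = 5
    samples_per_tissue: int = 50
    frac_expressed: float = 0.5
    nonexpressed_mean: float = 0.0
    expressed_mean: float = 5.0
    component_sd: float = 1.0
    n_outlier_genes_up: int = 10
    n_outlier_genes_down: int = 10
    outlier_effect: float = 4.0
    tissue_distinct_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_expressed < 1.0:
            raise ValueError("frac_expressed must lie in (0, 1)")
        if self.expressed_mean <= self.nonexpressed_mean:
            raise ValueError("expressed_mean must exceed nonexpressed_mean")
        if self.component_sd <= 0:
            raise ValueError("component_sd must be positive")
        if self.n_housekeeping > self.n_genes:
            raise ValueError("n_housekeeping cannot exceed n_genes")
        for n in ("n_genes", "n_housekeeping", "n_tissues", "samples_per_tissue"):
            if getattr(self, n) <= 0:
                raise ValueError(f"{n} must be positive")
        if self.n_outlier_genes_up < 0 or self.n_outlier_genes_down < 0:
            raise ValueError("outlier gene counts must be non-negative")


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------

def _draw_unique_sites(rng: np.random.Generator, n: int,
                       chromosomes: Sequence[tuple[str, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Draw n distinct (chrom, pos) sites, chromosome weighted by length."""
    names = np.array([c for c, _ in chromosomes])
    lengths = np.array([l for _, l in chromosomes], dtype=np.int64)
    weights = lengths / lengths.sum()
    acc = pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
    while len(acc) < n:
        need = n - len(acc)
        idx = rng.choice(len(names), size=2 * need + 16, p=weights)
        pos = 1 + (rng.random(len(idx)) * lengths[idx]).astype(np.int64)
        batch = pd.DataFrame({"chrom": names[idx], "pos": pos})
        acc = pd.concat([acc, batch], ignore_index=True).drop_duplicates(ignore_index=True)
    acc = acc.iloc[:n]
    return acc["chrom"].to_numpy(), acc["pos"].to_numpy()


def _in_segments(chroms: np.ndarray, poss: np.ndarray,
                 segments: Sequence[tuple[str, int, int, str]]) -> np.ndarray:
    """Index of the containing segment per site (-1 if none); 1-based pos."""
    seg_idx = np.full(len(chroms), -1, dtype=int)
    for i, (chrom, start, end, _) in enumerate(segments):
        hit = (chroms == chrom) & (poss - 1 >= start) & (poss - 1 < end)
        seg_idx[hit] = i
    return seg_idx


def simulate_tumor_normal_variants(
    cfg: VariantSimConfig, layout: GenomeLayout
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate paired normal/tumor variant call tables with ground truth.

    Returns ``(normal, tumor, truth)`` DataFrames.  Germline heterozygous
    sites have a true allelic fraction of 0.5 in the normal; inside LOH
    segments the tumor fraction is shifted to ``LOH_TUMOR_BAF`` toward 0 or
    1 (direction a seeded fair coin per segment).  Somatic variants are
    absent from the normal table unless ``normal_contamination_af > 0``, and
    present in the tumor at fractions drawn uniformly from
    ``somatic_af_range``.  Truth labels every record
    {germline_het, germline_hom, somatic} and carries the true tumor
    fraction and containing LOH segment index.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n_total = cfg.n_germline_het + cfg.n_germline_hom + cfg.n_somatic

    # per-segment LOH shift direction, drawn before sites for stability
    shift_up = rng.random(len(layout.loh_segments)) < 0.5

    chroms, poss = _draw_unique_sites(rng, n_total, layout.chromosomes)
    order = np.lexsort((poss, chroms.astype(str)))
    chroms, poss = chroms[order], poss[order]

    labels = np.array(
        ["germline_het"] * cfg.n_germline_het
        + ["germline_hom"] * cfg.n_germline_hom
        + ["somatic"] * cfg.n_somatic
    )
    rng.shuffle(labels)

    ref_idx = rng.integers(0, 4, n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, n_total)) % 4
    refs, alts = _BASES[ref_idx], _BASES[alt_idx]

    n_gene_pool = max(50, n_total // 3)
    genes = np.array([f"GENE{i:04d}" for i in rng.integers(0, n_gene_pool, n_total)])
    consequences = rng.choice(_CONSEQUENCES, size=n_total, p=_CONSEQUENCE_P)
    quality = np.round(rng.normal(50.0, 8.0, n_total).clip(1.0, 99.0), 2)
    in_cosmic = rng.random(n_total) < cfg.fraction_in_cosmic

    dist, a, b, p_missing = cfg.population_af_spec
    if dist != "beta":
        raise ValueError("population_af_spec must be ('beta', a, b, p_missing)")
    pop_af = rng.beta(a, b, n_total)
    pop_af[rng.random(n_total) < p_missing] = np.nan
    pop_af[labels == "somatic"] = np.nan  # somatic events are novel in the population

    seg_idx = _in_segments(chroms, poss, layout.loh_segments)

    is_het = labels == "germline_het"
    is_hom = labels == "germline_hom"
    is_som = labels == "somatic"

    # true fractions
    normal_p = np.where(is_hom, 1.0, np.where(is_het, 0.5, cfg.normal_contamination_af))
    tumor_p = np.where(is_hom, 1.0, 0.5)
    in_loh = seg_idx >= 0
    het_loh = is_het & in_loh
    if het_loh.any():
        direction = shift_up[seg_idx[het_loh]]
        tumor_p[het_loh] = np.where(direction, LOH_TUMOR_BAF, 1.0 - LOH_TUMOR_BAF)
    som_p = rng.uniform(*cfg.somatic_af_range, size=int(is_som.sum()))
    tumor_p[is_som] = som_p

    normal_depth = rng.poisson(cfg.mean_depth, n_total).clip(min=1)
    tumor_depth = rng.poisson(cfg.mean_depth, n_total).clip(min=1)
    normal_alt = rng.binomial(normal_depth, normal_p)
    tumor_alt = rng.binomial(tumor_depth, tumor_p)

    base = pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "pos": poss,
            "ref": refs,
            "alt": alts,
            "gene": genes,
            "consequence": consequences,
            "population_af": pop_af,
            "in_cosmic": in_cosmic,
            "quality": quality,
        }
    )

    normal = base.copy()
    normal["alt_count"] = normal_alt
    normal["depth"] = normal_depth
    normal["af"] = normal_alt / normal_depth
    normal["genotype"] = np.where(is_hom, "hom", np.where(is_het, "het", "missing"))
    if cfg.normal_contamination_af == 0.0:
        normal = normal.loc[~is_som].reset_index(drop=True)

    tumor = base.copy()
    tumor["alt_count"] = tumor_alt
    tumor["depth"] = tumor_depth
    tumor["af"] = tumor_alt / tumor_depth
    tumor["genotype"] = "missing"

    truth = base[["chrom", "pos", "ref", "alt", "gene"]].copy()
    truth["label"] = labels
    truth["true_normal_af"] = normal_p
    truth["true_tumor_af"] = tumor_p
    truth["loh_segment"] = seg_idx

    return normal.reset_index(drop=True), tumor.reset_index(drop=True), truth.reset_index(drop=True)


def simulate_depth_track(
    layout: GenomeLayout, cfg: VariantSimConfig, noise_sd: float = 0.2
) -> pd.DataFrame:
    """Simulate a binned log2 tumor/normal depth-ratio track.

    Each bin's ratio is its containing segment's true log2 ratio (0 outside
    any segment) plus Gaussian noise of sd ``noise_sd``.  Bins carry the
    true segment index (-1 for background).
    """
    if not layout.chromosomes:
        raise ValueError("layout has no chromosomes")
    rng = np.random.default_rng([cfg.seed, 1])
    ratios = layout.segment_log2_ratios()
    rows = []
    for chrom, length in layout.chromosomes:
        n_bins = length // layout.bin_size
        if n_bins == 0:
            continue
        starts = np.arange(n_bins, dtype=np.int64) * layout.bin_size
        ends = starts + layout.bin_size
        mids = (starts + ends) // 2
        seg = np.full(n_bins, -1, dtype=int)
        true = np.zeros(n_bins)
        for i, (schrom, s, e, _) in enumerate(layout.loh_segments):
            if schrom != chrom:
                continue
            hit = (mids >= s) & (mids < e)
            seg[hit] = i
            true[hit] = ratios[i]
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "log2_ratio": true + (rng.normal(0.0, noise_sd, n_bins) if noise_sd > 0 else 0.0),
                 "segment_id": seg}
            )
        )
    if not rows:
        raise ValueError("layout produced no bins; check bin_size vs chromosome lengths")
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _log2_to_fpkm(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp2(x) - 1.0, 0.0)


def simulate_expression_compendium(
    cfg: ExpressionSimConfig, test_tissue: int = 0
) -> tuple[ExpressionMatrix, pd.Series, dict]:
    """Simulate a reference compendium, a test sample, and its truth.

    Housekeeping genes are expressed in every sample with reduced variance
    (sd = component_sd / 4).  The test sample is drawn from
    ``tissue_{test_tissue}`` with ``n_outlier_genes_up`` genes shifted up
    and ``n_outlier_genes_down`` shifted down by ``outlier_effect`` log2
    units.  Down-shifted outliers are chosen among genes expressed in every
    tissue and up-shifted ones among genes expressed in none, so that the
    spiked signal is not confounded with ordinary tissue-specific expression.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    if not 0 <= test_tissue < cfg.n_tissues:
        raise ValueError("test_tissue out of range")

    n_hk = cfg.n_housekeeping
    n_other = cfg.n_genes - n_hk
    gene_ids = [f"HK{i:04d}" for i in range(n_hk)] + [f"G{i:05d}" for i in range(n_other)]
    roles = pd.Series(["housekeeping"] * n_hk + ["other"] * n_other, index=gene_ids)

    base_expr = rng.random(n_other) < cfg.frac_expressed
    tissue_ind = np.tile(base_expr, (cfg.n_tissues, 1))
    n_flip = int(round(cfg.tissue_distinct_frac * n_other))
    for t in range(cfg.n_tissues):
        flips = rng.choice(n_other, size=n_flip, replace=False)
        tissue_ind[t, flips] = ~tissue_ind[t, flips]

    hk_sd = cfg.component_sd / 4.0

    def tissue_params(t: int) -> tuple[np.ndarray, np.ndarray]:
        means = np.concatenate(
            [np.full(n_hk, cfg.expressed_mean),
             np.where(tissue_ind[t], cfg.expressed_mean, cfg.nonexpressed_mean)]
        )
        sds = np.concatenate([np.full(n_hk, hk_sd), np.full(n_other, cfg.component_sd)])
        return means, sds

    columns, labels, data = [], [], []
    for t in range(cfg.n_tissues):
        means, sds = tissue_params(t)
        vals = rng.normal(means, sds, size=(cfg.samples_per_tissue, cfg.n_genes))
        data.append(_log2_to_fpkm(vals).T)
        columns += [f"tissue_{t}_s{j:03d}" for j in range(cfg.samples_per_tissue)]
        labels += [f"tissue_{t}"] * cfg.samples_per_tissue
    values = pd.DataFrame(np.hstack(data), index=gene_ids, columns=columns)
    reference = ExpressionMatrix(
        values=values,
        sample_labels=pd.Series(labels, index=columns, name="tissue"),
        gene_roles=roles,
    )

    # outlier gene choice: down among universally expressed, up among
    # universally silent (both relative to all tissues' indicators)
    always_on = np.flatnonzero(tissue_ind.all(axis=0))
    always_off = np.flatnonzero(~tissue_ind.any(axis=0))
    if cfg.n_outlier_genes_down > len(always_on) or cfg.n_outlier_genes_up > len(always_off):
        raise ValueError("not enough eligible genes for the requested outlier counts")
    down = rng.choice(always_on, size=cfg.n_outlier_genes_down, replace=False)
    up = rng.choice(always_off, size=cfg.n_outlier_genes_up, replace=False)

    means, sds = tissue_params(test_tissue)
    means = means.copy()
    means[n_hk + up] += cfg.outlier_effect
    means[n_hk + down] -= cfg.outlier_effect
    test_vals = _log2_to_fpkm(rng.normal(means, sds))
    test = pd.Series(test_vals, index=gene_ids, name="TEST")

    other_ids = np.array(gene_ids[n_hk:])
    truth = {
        "outliers": pd.DataFrame(
            {"gene": np.concatenate([other_ids[up], other_ids[down]]),
             "direction": ["up"] * len(up) + ["down"] * len(down)}
        ),
        "test_tissue": f"tissue_{test_tissue}",
        "tissue_expressed": pd.DataFrame(
            tissue_ind.T, index=other_ids, columns=[f"tissue_{t}" for t in range(cfg.n_tissues)]
        ),
        "mixture": {
            "nonexpressed_mean": cfg.nonexpressed_mean,
            "expressed_mean": cfg.expressed_mean,
            "component_sd": cfg.component_sd,
            "frac_expressed": cfg.frac_expressed,
        },
    }
    return reference, test, truth
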