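"""Copy-number segmentation and LOH detection from allelic ratios.

Copy-number segments come from recursive binary segmentation of the binned
log2 tumor/normal depth-ratio track: the track is split at the position
maximizing a pooled-variance t statistic for the difference of means,
whenever that statistic exceeds a threshold, and the recursion continues
within each side.  Loss/neutral/gain calls use fixed log2-ratio cutoffs.

LOH detection follows the heterozygous-site rule: germline sites whose
allelic ratio in the normal lies in the 45-55% window ("informative hets")
are scanned in the tumor for runs of B-allele-frequency deviation
|tumor_af - 0.5| above a threshold.  Runs of at least ``min_sites``
deviating sites (bridging up to ``gap_tolerance`` consecutive quiet sites)
become LOH segments, classified by the overlapping copy-number call:
neutral -> copy-neutral LOH, loss -> deletion LOH, gain -> allelic
imbalance with gain.

Site coordinates are 1-based (VCF convention); emitted segments are
0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from oncocase.variants import VariantRecord


@dataclass(frozen=True)
class InformativeSite:
    """A germline het usable to read tumor allelic imbalance (1-based pos)."""

    chrom: str
    pos: int
    normal_af: float
    tumor_af: float
    quality: float

    @property
    def baf_deviation(self) -> float:
        return abs(self.tumor_af - 0.5)


@dataclass(frozen=True)
class CnvSegment:
    """Depth-ratio segment, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    n_bins: int
    call: str  # loss | neutral | gain

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class LohSegment:
    """Allelic-imbalance segment, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    mean_baf_deviation: float
    n_sites: int
    loh_class: str  # copy_neutral_loh | deletion_loh | gain_allelic_imbalance


def pair_tumor_normal(
    normal_variants: Sequence[VariantRecord], tumor_variants: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Merge tumor allelic fractions into normal records, matched by key."""
    tumor_index = {rec.key: rec for rec in tumor_variants}
    paired = []
    for rec in normal_variants:
        t = tumor_index.get(rec.key)
        if t is None:
            continue
        merged = VariantRecord(**{**rec.__dict__})
        merged.tumor_af = t.tumor_af
        merged.tumor_depth = t.tumor_depth
        paired.append(merged)
    return paired


def select_informative_hets(
    normal_variants: Sequence[VariantRecord],
    low: float = 0.45,
    high: float = 0.55,
    min_quality: float = 30.0,
    min_depth: int = 20,
) -> list[InformativeSite]:
    """Select high-quality germline hets with normal AF in [low, high].

    The window is inclusive on both sides.  Records must carry both a
    normal and a tumor allelic fraction (see :func:`pair_tumor_normal`).
    Output is sorted by (chrom, pos).
    """
    if low >= high:
        raise ValueError("low must be < high")
    sites = [
        InformativeSite(
            chrom=rec.chrom, pos=rec.pos,
            normal_af=rec.normal_af, tumor_af=rec.tumor_af, quality=rec.quality,
        )
        for rec in normal_variants
        if low <= rec.normal_af <= high
        and rec.quality >= min_quality
        and rec.normal_depth >= min_depth
        and not np.isnan(rec.tumor_af)
    ]
    return sorted(sites, key=lambda s: (s.chrom, s.pos))


# ---------------------------------------------------------------------------
# depth-ratio segmentation
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best split index (left size) and its t statistic; (-1, 0) if none."""
    n = len(x)
    if n < 2 * min_bins:
        return -1, 0.0
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(min_bins, n - min_bins + 1)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = cs[k - 1]
    m1 = s1 / n1
    m2 = (cs[-1] - s1) / n2
    ss1 = css[k - 1] - n1 * m1 * m1
    ss2 = (css[-1] - css[k - 1]) - n2 * m2 * m2
    pooled = np.maximum(ss1 + ss2, 0.0) / max(n - 2, 1)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff > 0, np.inf, 0.0))
    best = int(np.argmax(t))
    return int(k[best]), float(t[best])


def _classify(mean: float, loss_threshold: float, gain_threshold: float) -> str:
    if mean <= loss_threshold:
        return "loss"
    if mean >= gain_threshold:
        return "gain"
    return "neutral"


def segment_depth_ratio(
    bins: pd.DataFrame,
    min_bins: int = 5,
    change_threshold: float = 8.0,
    loss_threshold: float = -0.3,
    gain_threshold: float = 0.3,
) -> list[CnvSegment]:
    """Recursive binary segmentation of a binned log2 depth-ratio track.

    ``bins`` must have columns chrom, start, end, log2_ratio, sorted by
    position within each chromosome.  A split is accepted when the pooled
    t statistic of the mean difference exceeds ``change_threshold``; both
    sides must keep at least ``min_bins`` bins.
    """
    if bins.empty:
        raise ValueError("empty depth-ratio table")
    segments: list[CnvSegment] = []
    if len(bins) < min_bins:
        warnings.warn("fewer bins than min_bins; emitting a single segment")
    for chrom, sub in bins.groupby("chrom", sort=False):
        x = sub["log2_ratio"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()

        def recurse(lo: int, hi: int) -> None:
            split, stat = _best_split(x[lo:hi], min_bins)
            if split > 0 and stat > change_threshold:
                recurse(lo, lo + split)
                recurse(lo + split, hi)
            else:
                mean = float(np.mean(x[lo:hi]))
                segments.append(
                    CnvSegment(
                        chrom=str(chrom), start=int(starts[lo]), end=int(ends[hi - 1]),
                        mean_log2_ratio=mean, n_bins=hi - lo,
                        call=_classify(mean, loss_threshold, gain_threshold),
                    )
                )

        recurse(0, len(x))
    return segments


# ---------------------------------------------------------------------------
# LOH calling
# ---------------------------------------------------------------------------

_CNV_TO_LOH = {
    "neutral": "copy_neutral_loh",
    "loss": "deletion_loh",
    "gain": "gain_allelic_imbalance",
}


def call_loh_segments(
    sites: Sequence[InformativeSite],
    cnv: Sequence[CnvSegment] = (),
    baf_dev_threshold: float = 0.15,
    min_sites: int = 10,
    gap_tolerance: int = 2,
) -> list[LohSegment]:
    """Merge runs of BAF-deviating informative hets into LOH segments.

    A run collects consecutive sites with |tumor_af - 0.5| >=
    ``baf_dev_threshold``, bridging at most ``gap_tolerance`` consecutive
    quiet sites (bridged sites are not members).  Runs with at least
    ``min_sites`` members become segments spanning the first to last member
    site; the class comes from the copy-number call with the largest
    overlap (no overlapping call defaults to copy-neutral).
    """
    segments: list[LohSegment] = []

    def close(members: list[InformativeSite]) -> None:
        if len(members) < min_sites:
            return
        chrom = members[0].chrom
        start, end = members[0].pos - 1, members[-1].pos
        best_call, best_ov = "neutral", 0
        for seg in cnv:
            ov = seg.overlap(chrom, start, end)
            if ov > best_ov:
                best_call, best_ov = seg.call, ov
        segments.append(
            LohSegment(
                chrom=chrom, start=start, end=end,
                mean_baf_deviation=float(np.mean([s.baf_deviation for s in members])),
                n_sites=len(members),
                loh_class=_CNV_TO_LOH[best_call],
            )
        )

    members: list[InformativeSite] = []
    gap = 0
    prev_chrom: str | None = None
    for site in sites:
        if site.chrom != prev_chrom:
            close(members)
            members, gap = [], 0
            prev_chrom = site.chrom
        if site.baf_deviation >= baf_dev_threshold:
            members.append(site)
            gap = 0
        elif members:
            gap += 1
            if gap > gap_tolerance:
                close(members)
                members, gap = [], 0
    close(members)
    return segments
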