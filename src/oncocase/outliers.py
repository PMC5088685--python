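"""Rank-based expression-outlier detection against a normal compendium.

The procedure (a) normalizes every sample — reference and test alike — by
the median FPKM of a housekeeping-gene panel, on the linear scale with a
small pseudocount, then takes log2; (b) ranks the test sample's normalized
value for each gene within the reference samples (mid-rank for ties,
percentile denominator n_ref + 1, since the test sample joins the pool);
(c) flags genes whose percentile falls in the top or bottom decile; and
(d) reports a per-gene z score of the test value against the reference
mean and standard deviation for display.

Normalization by a within-sample ratio makes the whole report invariant to
global per-sample scaling of FPKM (library-size effects cancel).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from oncocase.containers import ExpressionMatrix

DEFAULT_EPS = 0.1


def housekeeping_normalize(
    values: pd.DataFrame | pd.Series,
    housekeeping_ids: Sequence[str],
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame | pd.Series:
    """Housekeeping-ratio normalization per sample, on the log2 scale.

    Each value is divided by the sample's median housekeeping FPKM first,
    then log-transformed with a *relative* pseudocount::

        normalized = log2(FPKM / median_hk + eps) - log2(1 + eps)

    The pseudocount is applied to the ratio (i.e. it scales with the
    sample's housekeeping median) so normalization is exactly invariant to
    a global rescaling of a sample's FPKM, and a gene at the housekeeping
    median maps exactly to 0.  ``values`` is a genes x samples DataFrame or
    a single-sample Series indexed by gene.  A zero housekeeping median
    raises, naming the sample.
    """
    hk = [g for g in housekeeping_ids if g in values.index]
    if not hk:
        raise ValueError("no housekeeping genes present in the expression index")
    shift = np.log2(1.0 + eps)
    if isinstance(values, pd.Series):
        med = float(values.loc[hk].median())
        if med <= 0:
            raise ValueError(
                f"zero housekeeping median in sample {values.name!r}; cannot normalize"
            )
        return np.log2(values / med + eps) - shift
    med = values.loc[hk].median(axis=0)
    bad = med[med <= 0]
    if len(bad):
        raise ValueError(f"zero housekeeping median in sample {bad.index[0]!r}")
    return np.log2(values.div(med, axis=1) + eps) - shift


def rank_test_sample(
    test_norm: pd.Series, reference_norm: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene rank and percentile of the test sample within the reference.

    rank = 1 + (# reference values strictly below) + 0.5 * (# ties);
    percentile = rank / (n_ref + 1).  Genes missing from the reference are
    excluded.
    """
    genes = test_norm.index.intersection(reference_norm.index)
    test = test_norm.loc[genes].to_numpy(dtype=float)[:, None]
    ref = reference_norm.loc[genes].to_numpy(dtype=float)
    n_ref = ref.shape[1]
    below = (ref < test).sum(axis=1)
    ties = (ref == test).sum(axis=1)
    rank = 1.0 + below + 0.5 * ties
    percentile = rank / (n_ref + 1)
    return pd.DataFrame({"rank": rank, "percentile": percentile}, index=genes)


def flag_outliers(ranks: pd.DataFrame, top_frac: float = 0.10) -> pd.DataFrame:
    """Flag genes in the top/bottom ``top_frac`` of the reference ranking.

    flag = "over" iff percentile >= 1 - top_frac, "under" iff percentile <=
    top_frac (both inclusive), else "none".  The report is sorted by
    |percentile - 0.5| descending (most extreme genes first).
    """
    if not 0.0 < top_frac < 0.5:
        raise ValueError("top_frac must lie in (0, 0.5)")
    report = ranks.copy()
    pct = report["percentile"]
    report["flag"] = np.where(
        pct >= 1.0 - top_frac, "over", np.where(pct <= top_frac, "under", "none")
    )
    order = (pct - 0.5).abs().sort_values(ascending=False, kind="stable")
    return report.loc[order.index]


def z_normalize_ranks(
    test_norm: pd.Series, reference_norm: pd.DataFrame
) -> pd.Series:
    """Per-gene z score of the test sample against the reference.

    z = (test - mean_ref) / sd_ref on normalized values; genes with zero
    reference standard deviation are excluded.
    """
    genes = test_norm.index.intersection(reference_norm.index)
    ref = reference_norm.loc[genes]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    return ((test_norm.loc[genes] - mean) / sd)[keep]


def diff_expr_outlier(
    reference: ExpressionMatrix,
    test: pd.Series,
    top_frac: float = 0.10,
    eps: float = DEFAULT_EPS,
    tissue_subset: str | None = None,
) -> pd.DataFrame:
    """Full outlier report: normalize, rank, flag, and z-normalize.

    ``tissue_subset`` optionally restricts the reference to samples of one
    tissue label before ranking.  Returns a DataFrame with columns
    normalized, rank, percentile, z, flag, sorted most-extreme first.
    """
    ref_values = reference.values
    if tissue_subset is not None:
        if reference.sample_labels is None:
            raise ValueError("tissue_subset requires sample labels")
        cols = reference.sample_labels.index[reference.sample_labels == tissue_subset]
        if len(cols) == 0:
            raise ValueError(f"no reference samples labeled {tissue_subset!r}")
        ref_values = ref_values[cols]
    hk = reference.housekeeping_ids
    ref_norm = housekeeping_normalize(ref_values, hk, eps=eps)
    test_norm = housekeeping_normalize(test, hk, eps=eps)
    ranks = rank_test_sample(test_norm, ref_norm)
    report = flag_outliers(ranks, top_frac=top_frac)
    z = z_normalize_ranks(test_norm, ref_norm)
    report.insert(0, "normalized", test_norm.loc[report.index])
    report["z"] = z.reindex(report.index)
    return report


def write_outlier_report(report: pd.DataFrame, path) -> None:
    """Write the outlier report as TSV, floats at 10 significant digits."""
    report.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
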