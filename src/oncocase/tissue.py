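"""Transcriptome similarity in a mixture-transformed expression space.

Tissue-of-origin assessment proceeds in five steps:

1. library-size normalization of raw counts by median-of-ratios size
   factors (per sample: median over all-nonzero genes of the ratio to the
   per-gene geometric mean);
2. per-sample fit, by EM, of a two-component Gaussian mixture to the
   probability density of log2(FPKM + eps) — the low component modelling
   very-low-to-non-expressed transcripts, the high one expressed
   transcripts;
3. transformation of every gene's value to the posterior probability of
   the expressed component ("relative likelihood of expression"), which
   shrinks variance among expressed genes while amplifying the contrast
   between expressed and non-expressed genes;
4. Pearson-correlation similarity between samples in the transformed
   space, optionally after subsampling at most ``max_per_type`` samples
   per tissue type, and a seeded 2D t-SNE embedding of 1 - correlation;
5. a k-nearest-neighbor majority vote over reference tissue labels for
   the test sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from oncocase.containers import ExpressionMatrix

_LOG_2PI = math.log(2.0 * math.pi)
MIXTURE_EPS = 0.1


# ---------------------------------------------------------------------------
# size-factor normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Genes with a zero count in any sample are excluded from the median.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "consider adding a pseudocount before normalization"
        )
    sub = arr[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def size_factor_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample by its median-of-ratios size factor."""
    return counts.div(size_factors(counts), axis=1)


# ---------------------------------------------------------------------------
# two-component Gaussian mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    """Two-Gaussian fit of one sample's expression density.

    Components are ordered so ``mean_expressed > mean_nonexpressed``.
    ``identifiable`` is False when the fit is effectively unimodal (a
    component weight below 2% or component separation D = |dm| /
    sqrt((s1^2 + s2^2)/2) below 2).
    """

    weight_nonexpressed: float
    weight_expressed: float
    mean_nonexpressed: float
    mean_expressed: float
    sd_nonexpressed: float
    sd_expressed: float
    converged: bool
    log_likelihood: float
    n_iterations: int
    identifiable: bool = True


def _component_loglik(x: np.ndarray, w: np.ndarray, m: np.ndarray, s: np.ndarray) -> np.ndarray:
    # (n, 2) log of w_k * phi(x; m_k, s_k)
    z = (x[:, None] - m[None, :]) / s[None, :]
    return np.log(w)[None, :] - np.log(s)[None, :] - 0.5 * (z * z + _LOG_2PI)


def _em_chains(
    X: np.ndarray, w: np.ndarray, m: np.ndarray, s: np.ndarray,
    max_iter: int, tol: float, sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM on C independent chains at once.

    ``X`` is (n, C) data per chain; ``w``, ``m``, ``s`` are (C, 2) parameter
    arrays, updated in place.  Chains are frozen individually once their
    relative log-likelihood change falls below ``tol``.  Returns
    (w, m, s, log_likelihood (C,), n_iterations (C,), converged (C,)).
    """
    n, n_chains = X.shape
    ll = np.full(n_chains, -np.inf)
    iters = np.zeros(n_chains, dtype=int)
    converged = np.zeros(n_chains, dtype=bool)
    active = np.arange(n_chains)
    xa = np.array(X)          # (n, A), compacted as chains converge
    x2a = xa * xa
    sum_x = xa.sum(axis=0)
    sum_x2 = x2a.sum(axis=0)
    const = -0.5 * _LOG_2PI * n
    for _ in range(max_iter):
        wa, ma, sa = w[active], m[active], s[active]
        z0 = (xa - ma[:, 0]) / sa[:, 0]
        z1 = (xa - ma[:, 1]) / sa[:, 1]
        l0 = np.log(wa[:, 0]) - np.log(sa[:, 0]) - 0.5 * z0 * z0
        l1 = np.log(wa[:, 1]) - np.log(sa[:, 1]) - 0.5 * z1 * z1
        dl = l1 - l0
        with np.errstate(over="ignore"):
            r1 = 1.0 / (1.0 + np.exp(-dl))  # responsibility of component 1
        lse = np.maximum(l0, l1) + np.log1p(np.exp(-np.abs(dl)))
        new_ll = lse.sum(axis=0) + const
        nk1 = np.maximum(r1.sum(axis=0), 1e-12)
        nk0 = np.maximum(n - nk1, 1e-12)
        s1x = (r1 * xa).sum(axis=0)
        s1x2 = (r1 * x2a).sum(axis=0)
        m1 = s1x / nk1
        m0 = (sum_x - s1x) / nk0
        v1 = np.maximum(s1x2 / nk1 - m1 * m1, 0.0)
        v0 = np.maximum((sum_x2 - s1x2) / nk0 - m0 * m0, 0.0)
        w[active, 0], w[active, 1] = nk0 / n, nk1 / n
        m[active, 0], m[active, 1] = m0, m1
        s[active, 0] = np.maximum(np.sqrt(v0), sd_floor)
        s[active, 1] = np.maximum(np.sqrt(v1), sd_floor)
        iters[active] += 1
        done = np.abs(new_ll - ll[active]) < tol * np.maximum(np.abs(new_ll), 1.0)
        ll[active] = new_ll
        converged[active] |= done
        if done.any():
            keep = ~done
            active = active[keep]
            if len(active) == 0:
                break
            xa = xa[:, keep]
            x2a = x2a[:, keep]
            sum_x = sum_x[keep]
            sum_x2 = sum_x2[keep]
    return w, m, s, ll, iters, converged


def _kmeans_1d_init(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lloyd's algorithm with 2 centers on 1D data (quantile start)."""
    c = np.quantile(x, [0.25, 0.75])
    if c[0] == c[1]:
        c = np.array([x.min(), x.max()], dtype=float)
    for _ in range(50):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            x[assign == k].mean() if (assign == k).any() else c[k] for k in (0, 1)
        ])
        if np.allclose(new, c):
            break
        c = new
    assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
    w = np.array([(assign == k).mean() for k in (0, 1)])
    w = np.clip(w, 0.05, 0.95)
    w = w / w.sum()
    s = np.array([
        x[assign == k].std() if (assign == k).sum() > 1 else x.std() for k in (0, 1)
    ])
    s = np.maximum(s, 1e-2)
    return w, c.astype(float), s


def _mixture_inits(x: np.ndarray, n_restarts: int, seed: int) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """One k-means init plus seeded random restarts for one sample."""
    rng = np.random.default_rng(seed)
    inits = [_kmeans_1d_init(x)]
    sd0 = max(float(x.std()), 1e-2)
    for _ in range(n_restarts):
        m0 = np.sort(rng.choice(x, size=2, replace=False).astype(float))
        if m0[0] == m0[1]:
            m0 = np.array([x.min(), x.max()], dtype=float)
        inits.append((np.array([0.5, 0.5]), m0, np.array([sd0, sd0])))
    return inits


def _select_fit(
    w: np.ndarray, m: np.ndarray, s: np.ndarray,
    ll: np.ndarray, iters: np.ndarray, conv: np.ndarray, sd_floor: float,
) -> MixtureFit:
    """Pick the best chain: highest likelihood among converged, non-collapsed.

    A solution whose component sd sits at the floor is a degeneracy (e.g. a
    component collapsed onto an atom of tied values) and is discarded
    unless nothing else is available.
    """
    collapsed = (s <= sd_floor * 1.01).any(axis=1)
    for mask in (conv & ~collapsed, ~collapsed, np.ones_like(conv)):
        if mask.any():
            pool = np.flatnonzero(mask)
            break
    best = pool[np.argmax(ll[pool])]
    order = np.argsort(m[best])
    wb, mb, sb = w[best][order], m[best][order], s[best][order]
    separation = abs(mb[1] - mb[0]) / math.sqrt((sb[0] ** 2 + sb[1] ** 2) / 2.0)
    return MixtureFit(
        weight_nonexpressed=float(wb[0]), weight_expressed=float(wb[1]),
        mean_nonexpressed=float(mb[0]), mean_expressed=float(mb[1]),
        sd_nonexpressed=float(sb[0]), sd_expressed=float(sb[1]),
        converged=bool(conv[best]), log_likelihood=float(ll[best]),
        n_iterations=int(iters[best]),
        identifiable=bool(min(wb) >= 0.02 and separation >= 2.0),
    )


def _validate_mixture_input(x: np.ndarray) -> None:
    if x.ndim != 1 or len(x) < 200:
        raise ValueError("mixture fitting requires a 1D vector of >= 200 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values equal")


def fit_two_component_mixture(
    values: Sequence[float] | np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    sd_floor: float = 1e-3,
) -> MixtureFit:
    """Fit a non-expressed/expressed two-Gaussian mixture by EM.

    One k-means-initialized run plus ``n_restarts`` seeded random
    initializations guard against label-swap local optima; the best
    log-likelihood among converged, non-collapsed solutions is kept.
    """
    x = np.asarray(values, dtype=float)
    _validate_mixture_input(x)
    inits = _mixture_inits(x, n_restarts, seed)
    w0 = np.stack([w for w, _, _ in inits])
    m0 = np.stack([m for _, m, _ in inits])
    s0 = np.stack([s for _, _, s in inits])
    X = np.repeat(x[:, None], len(inits), axis=1)
    w, m, s, ll, iters, conv = _em_chains(X, w0, m0, s0, max_iter, tol, sd_floor)
    return _select_fit(w, m, s, ll, iters, conv, sd_floor)


def expression_likelihood(
    values: Sequence[float] | np.ndarray, fit: MixtureFit
) -> np.ndarray:
    """Posterior probability of the expressed component at each value."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge; refuse to transform")
    x = np.asarray(values, dtype=float)
    w = np.array([fit.weight_nonexpressed, fit.weight_expressed])
    m = np.array([fit.mean_nonexpressed, fit.mean_expressed])
    s = np.array([fit.sd_nonexpressed, fit.sd_expressed])
    lk = _component_loglik(x, w, m, s)
    mx = lk.max(axis=1, keepdims=True)
    p = np.exp(lk - mx)
    return p[:, 1] / p.sum(axis=1)


def transform_compendium(
    fpkm: pd.DataFrame,
    seed: int = 0,
    n_restarts: int = 5,
    eps: float = MIXTURE_EPS,
) -> tuple[pd.DataFrame, dict[str, MixtureFit]]:
    """Per-sample mixture fit and likelihood transform of an FPKM matrix.

    Fits are performed on log2(FPKM + eps) independently per sample, each
    with a seed derived from ``seed`` and the column order.
    """
    log_expr = np.log2(fpkm.to_numpy(dtype=float) + eps)
    n_samples = log_expr.shape[1]
    chains_per = n_restarts + 1
    w0, m0, s0, cols = [], [], [], []
    for j in range(n_samples):
        x = log_expr[:, j]
        _validate_mixture_input(x)
        sample_seed = int(np.random.SeedSequence([seed, j]).generate_state(1)[0] & 0x7FFFFFFF)
        for w, m, s in _mixture_inits(x, n_restarts, sample_seed):
            w0.append(w)
            m0.append(m)
            s0.append(s)
            cols.append(j)
    X = log_expr[:, cols]
    sd_floor = 1e-3
    w, m, s, ll, iters, conv = _em_chains(
        X, np.stack(w0), np.stack(m0), np.stack(s0), 500, 1e-8, sd_floor
    )
    transformed = np.empty_like(log_expr)
    fits: dict[str, MixtureFit] = {}
    for j, sample in enumerate(fpkm.columns):
        sl = slice(j * chains_per, (j + 1) * chains_per)
        fit = _select_fit(w[sl], m[sl], s[sl], ll[sl], iters[sl], conv[sl], sd_floor)
        fits[sample] = fit
        transformed[:, j] = expression_likelihood(log_expr[:, j], fit)
    return pd.DataFrame(transformed, index=fpkm.index, columns=fpkm.columns), fits


# ---------------------------------------------------------------------------
# similarity, embedding, assignment
# ---------------------------------------------------------------------------

@dataclass
class SimilaritySpace:
    """Likelihood-transformed matrix with its sample similarity and labels."""

    transformed: pd.DataFrame  # genes x samples, values in [0, 1]
    similarity: pd.DataFrame   # samples x samples Pearson correlation
    labels: pd.Series          # tissue per sample


@dataclass
class Embedding2D:
    coordinates: pd.DataFrame  # samples x (x, y)
    perplexity: float
    seed: int


def subsample_per_type(
    labels: pd.Series, max_per_type: int = 100, seed: int = 0,
    keep: Sequence[str] = (),
) -> list[str]:
    """At most ``max_per_type`` sample ids per label, drawn without replacement.

    Samples listed in ``keep`` (e.g. the test sample) are always retained
    on top of the per-type draw.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for label in labels.unique():
        ids = labels.index[labels == label].to_numpy()
        if len(ids) > max_per_type:
            ids = rng.choice(ids, size=max_per_type, replace=False)
        chosen.extend(ids.tolist())
    for sample in keep:
        if sample not in chosen:
            chosen.append(sample)
    return [s for s in labels.index if s in set(chosen)]


def correlation_similarity(transformed: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between sample columns; symmetric, unit diagonal."""
    if transformed.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = transformed.std(axis=0, ddof=0)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance sample column {flat.index[0]!r}")
    sim = np.corrcoef(transformed.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=transformed.columns, columns=transformed.columns)


def embed_2d(
    data: SimilaritySpace | pd.DataFrame,
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding2D:
    """Seeded 2D t-SNE of the samples, on distance = 1 - correlation.

    ``data`` may be a SimilaritySpace, a square similarity matrix, or a
    likelihood-transformed genes x samples matrix (correlation is then
    computed first).
    """
    if isinstance(data, SimilaritySpace):
        sim = data.similarity
    elif data.shape[0] == data.shape[1] and data.index.equals(pd.Index(data.columns)):
        sim = data
    else:
        sim = correlation_similarity(data)
    n = sim.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} samples is too few for perplexity {perplexity}; "
            f"try perplexity <= {max(2, n // 3)}"
        )
    dist = np.clip(1.0 - sim.to_numpy(dtype=float), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    tsne = TSNE(
        n_components=2, metric="precomputed", init="random",
        perplexity=perplexity, random_state=seed,
    )
    coords = tsne.fit_transform(dist)
    return Embedding2D(
        coordinates=pd.DataFrame(coords, index=sim.index, columns=["x", "y"]),
        perplexity=perplexity, seed=seed,
    )


def assign_tissue(
    test_transformed: pd.Series,
    space: SimilaritySpace,
    k: int = 15,
) -> tuple[str, float, pd.Series]:
    """k-NN majority tissue vote for a likelihood-transformed test sample.

    Returns (label, vote fraction, per-label mean correlation to the test
    sample).  Ties in the vote are broken by the higher mean similarity
    among the tied labels' voting neighbors.
    """
    n_ref = space.transformed.shape[1]
    if k > n_ref:
        raise ValueError(f"k={k} exceeds the {n_ref} reference samples")
    genes = space.transformed.index
    test = test_transformed.reindex(genes).to_numpy(dtype=float)
    ref = space.transformed.to_numpy(dtype=float)
    test_c = test - test.mean()
    ref_c = ref - ref.mean(axis=0)
    denom = np.linalg.norm(test_c) * np.linalg.norm(ref_c, axis=0)
    if not (denom > 0).all():
        raise ValueError("zero-variance sample in correlation computation")
    corr = pd.Series(ref_c.T @ test_c / denom, index=space.transformed.columns)

    top = corr.sort_values(ascending=False, kind="stable").iloc[:k]
    votes = space.labels.loc[top.index].value_counts()
    best = votes.max()
    tied = votes.index[votes == best]
    if len(tied) > 1:
        tie_sim = {
            lab: top[space.labels.loc[top.index] == lab].mean() for lab in tied
        }
        label = max(sorted(tie_sim), key=lambda lab: tie_sim[lab])
    else:
        label = tied[0]
    per_label = corr.groupby(space.labels).mean().sort_values(ascending=False)
    return str(label), float(best / k), per_label
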