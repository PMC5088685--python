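"""Size factors, mixture fitting, likelihood transform, similarity, embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.mixture import GaussianMixture

from oncocase.tissue import (
    MixtureFit,
    SimilaritySpace,
    assign_tissue,
    correlation_similarity,
    embed_2d,
    expression_likelihood,
    fit_two_component_mixture,
    size_factor_normalize,
    size_factors,
    subsample_per_type,
    transform_compendium,
)


def two_gaussian_sample(n=2000, seed=0, means=(0.0, 5.0), sds=(1.0, 1.0), w=0.5):
    rng = np.random.default_rng(seed)
    n0 = int(round(n * w))
    return np.concatenate([
        rng.normal(means[0], sds[0], n0), rng.normal(means[1], sds[1], n - n0)
    ])


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_pure_depth_difference_normalized_away(self):
        a = pd.Series([10, 20, 40, 5, 100])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        norm = size_factor_normalize(counts)
        assert np.allclose(norm["a"], norm["b"])

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(50, size=(5, 3)) + 1,
                              columns=["s1", "s2", "s3"])
        factors = size_factors(counts)
        arr = counts.to_numpy(dtype=float)
        geomean = np.array([np.prod(row) ** (1 / 3) for row in arr])
        for j, s in enumerate(counts.columns):
            expected = np.median([arr[i, j] / geomean[i] for i in range(5)])
            assert factors[s] == pytest.approx(expected, rel=1e-12)

    def test_no_universally_nonzero_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)


class TestMixtureFit:
    def test_recovers_known_components(self):
        fit = fit_two_component_mixture(two_gaussian_sample(seed=1), seed=1)
        assert fit.converged and fit.identifiable
        assert fit.mean_nonexpressed == pytest.approx(0.0, abs=0.2)
        assert fit.mean_expressed == pytest.approx(5.0, abs=0.2)
        assert fit.weight_expressed == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_sklearn_gaussian_mixture(self):
        """Independent EM implementation cross-check on the same sample."""
        x = two_gaussian_sample(seed=3)
        fit = fit_two_component_mixture(x, seed=3)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        means = np.sort(gm.means_.ravel())
        assert fit.mean_nonexpressed == pytest.approx(means[0], abs=0.05)
        assert fit.mean_expressed == pytest.approx(means[1], abs=0.05)

    def test_deterministic_given_seed(self):
        x = two_gaussian_sample(seed=5)
        assert fit_two_component_mixture(x, seed=9) == fit_two_component_mixture(x, seed=9)

    def test_all_equal_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_two_component_mixture(np.ones(500))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="200"):
            fit_two_component_mixture(np.random.default_rng(0).normal(size=100))

    def test_unimodal_input_flagged_non_identifiable(self):
        x = np.random.default_rng(7).normal(2.0, 1.0, 2000)
        fit = fit_two_component_mixture(x, seed=7)
        assert not fit.identifiable or min(fit.weight_expressed, fit.weight_nonexpressed) < 0.02


class TestLikelihoodTransform:
    FIT = MixtureFit(0.5, 0.5, 0.0, 5.0, 1.0, 1.0, True, 0.0, 1)

    def test_midpoint_is_half(self):
        assert expression_likelihood([2.5], self.FIT)[0] == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_posterior(self):
        x = 3.5
        phi = lambda v, m: np.exp(-0.5 * (v - m) ** 2) / np.sqrt(2 * np.pi)  # noqa: E731
        expected = 0.5 * phi(x, 5.0) / (0.5 * phi(x, 0.0) + 0.5 * phi(x, 5.0))
        assert expression_likelihood([x], self.FIT)[0] == pytest.approx(expected, rel=1e-12)

    def test_saturates_far_above_expressed_mean(self):
        assert expression_likelihood([20.0], self.FIT)[0] > 1 - 1e-9

    def test_monotone_with_equal_sds(self):
        grid = np.linspace(-5, 10, 301)
        lik = expression_likelihood(grid, self.FIT)
        assert (np.diff(lik) >= 0).all()

    def test_unconverged_fit_refused(self):
        bad = MixtureFit(0.5, 0.5, 0.0, 5.0, 1.0, 1.0, False, 0.0, 1)
        with pytest.raises(ValueError, match="converge"):
            expression_likelihood([1.0], bad)

    def test_variance_reshaping_on_simulated_sample(self, small_compendium):
        """Transform shrinks expressed-gene variance but amplifies the
        expressed vs non-expressed group contrast."""
        _, reference, _, truth = small_compendium
        sample = reference.sample_ids[0]
        tissue = reference.sample_labels[sample]
        log_expr = np.log2(reference.values[sample].to_numpy() + 0.1)
        fit = fit_two_component_mixture(log_expr, seed=0)
        lik = expression_likelihood(log_expr, fit)
        expressed = truth["tissue_expressed"][tissue].reindex(
            reference.values.index, fill_value=True
        ).to_numpy()  # housekeeping genes count as expressed
        var_raw = log_expr[expressed].var()
        var_lik = lik[expressed].var()
        assert var_lik < var_raw

        def smd(values):
            a, b = values[expressed], values[~expressed]
            pooled = np.sqrt((a.var() + b.var()) / 2)
            return abs(a.mean() - b.mean()) / pooled

        assert smd(lik) > smd(log_expr)


class TestSubsampling:
    LABELS = pd.Series(
        ["A"] * 40 + ["B"] * 250,
        index=[f"s{i}" for i in range(290)],
    )

    def test_small_type_fully_retained(self):
        kept = subsample_per_type(self.LABELS, max_per_type=100, seed=1)
        assert sum(s.startswith("s") and int(s[1:]) < 40 for s in kept) == 40

    def test_large_type_capped_at_max(self):
        kept = subsample_per_type(self.LABELS, max_per_type=100, seed=1)
        assert sum(self.LABELS[s] == "B" for s in kept) == 100

    def test_deterministic_and_keep_honored(self):
        a = subsample_per_type(self.LABELS, seed=3)
        b = subsample_per_type(self.LABELS, seed=3)
        assert a == b
        kept = subsample_per_type(self.LABELS, seed=3, keep=["s289"])
        assert "s289" in kept


class TestSimilarity:
    def test_duplicate_sample_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        col = rng.random(100)
        m = pd.DataFrame({"a": col, "b": col, "c": rng.random(100)})
        sim = correlation_similarity(m)
        assert sim.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(sim) == 1.0).all()

    def test_complement_anticorrelated(self):
        rng = np.random.default_rng(1)
        col = rng.random(100)
        sim = correlation_similarity(pd.DataFrame({"a": col, "b": 1 - col}))
        assert sim.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        sim = correlation_similarity(m)
        for i in "abcd":
            for j in "abcd":
                x, y = m[i].to_numpy(), m[j].to_numpy()
                expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
                assert abs(sim.loc[i, j] - expected) < 1e-10

    def test_zero_variance_column_named(self):
        m = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_similarity(m)


class TestEmbeddingAndAssignment:
    def test_embedding_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((200, 40)),
                         columns=[f"s{i}" for i in range(40)])
        a = embed_2d(m, perplexity=10, seed=5)
        b = embed_2d(m, perplexity=10, seed=5)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_too_few_samples_suggests_perplexity(self):
        m = pd.DataFrame(np.random.default_rng(0).random((50, 10)))
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(m, perplexity=30)

    def test_identical_test_sample_votes_its_label(self):
        rng = np.random.default_rng(3)
        transformed = pd.DataFrame(rng.random((300, 20)),
                                   columns=[f"s{i}" for i in range(20)])
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=transformed.columns)
        space = SimilaritySpace(transformed, correlation_similarity(transformed), labels)
        label, vote, sims = assign_tissue(transformed["s15"], space, k=1)
        assert label == "B" and vote == 1.0
        assert sims.index[0] in ("A", "B")

    def test_k_larger_than_reference_rejected(self):
        transformed = pd.DataFrame(np.random.default_rng(0).random((50, 4)),
                                   columns=list("abcd"))
        labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        space = SimilaritySpace(transformed, correlation_similarity(transformed), labels)
        with pytest.raises(ValueError, match="k="):
            assign_tissue(transformed["a"], space, k=10)

    def test_synthetic_test_sample_assigned_to_source_tissue(self, small_compendium):
        _, reference, test, truth = small_compendium
        pool = pd.concat([reference.values, test.rename("TEST")], axis=1)
        transformed, fits = transform_compendium(pool, seed=11)
        assert all(f.converged for f in fits.values())
        ref_t = transformed[reference.sample_ids]
        space = SimilaritySpace(ref_t, correlation_similarity(ref_t),
                                reference.sample_labels)
        label, vote, _ = assign_tissue(transformed["TEST"], space)
        assert label == truth["test_tissue"]
        assert vote >= 0.8
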