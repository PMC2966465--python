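"""Null AUC envelopes, informative excess, concordance, normality profile."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaroc import nulldist, roc


def frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i:05d}" for i in range(values.shape[0])],
        columns=[f"s{j:03d}" for j in range(values.shape[1])],
    )


def balanced_labels(matrix):
    n = matrix.shape[1]
    return pd.Series([0] * (n // 2) + [1] * (n - n // 2), index=matrix.columns)


class TestRandomizeDataset:
    def test_deterministic_given_seed(self):
        matrix = frame(np.random.default_rng(0).normal(2, 3, (50, 12)))
        a = nulldist.randomize_dataset(matrix, seed=5)
        b = nulldist.randomize_dataset(matrix, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = nulldist.randomize_dataset(matrix, seed=6)
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_per_gene_moments_preserved(self):
        rng = np.random.default_rng(1)
        matrix = frame(rng.normal(5, 2, (30, 400)))
        randomized = nulldist.randomize_dataset(matrix, seed=2)
        mean_se = matrix.std(axis=1, ddof=1) / np.sqrt(matrix.shape[1])
        diff = (randomized.mean(axis=1) - matrix.mean(axis=1)).abs()
        assert (diff < 3.5 * mean_se).mean() > 0.98

    def test_zero_sd_gene_becomes_constant(self):
        matrix = frame(np.vstack([np.full(8, 4.0),
                                  np.arange(8, dtype=float)]))
        randomized = nulldist.randomize_dataset(matrix, seed=0)
        assert (randomized.iloc[0] == 4.0).all()

    def test_global_mode(self):
        rng = np.random.default_rng(2)
        matrix = frame(rng.normal(0, 1, (200, 30)) + np.arange(200)[:, None])
        randomized = nulldist.randomize_dataset(matrix, seed=3, per_gene=False)
        # global randomisation flattens the per-gene mean gradient
        assert randomized.mean(axis=1).std() < matrix.mean(axis=1).std() / 5


class TestNullAucInterval:
    def test_envelope_matches_normal_approximation(self):
        rng = np.random.default_rng(10)
        matrix = frame(rng.standard_normal((10000, 60)))
        labels = balanced_labels(matrix)
        dist = nulldist.null_auc_interval(matrix, labels, coverage=0.99)
        n0 = n1 = 30
        sd = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        expected_half = stats.norm.ppf(0.995) * sd
        assert dist.upper == pytest.approx(0.5 + expected_half, abs=0.02)
        assert dist.lower == pytest.approx(0.5 - expected_half, abs=0.02)
        # symmetry about 0.5
        assert abs((dist.upper - 0.5) - (0.5 - dist.lower)) < 0.02

    def test_full_coverage_gives_min_max(self):
        rng = np.random.default_rng(3)
        matrix = frame(rng.standard_normal((500, 20)))
        labels = balanced_labels(matrix)
        dist = nulldist.null_auc_interval(matrix, labels, coverage=1.0)
        aucs = roc.auc_matrix(matrix.to_numpy(), labels.to_numpy())
        assert dist.lower == pytest.approx(aucs.min())
        assert dist.upper == pytest.approx(aucs.max())

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (20, 80):
            matrix = frame(rng.standard_normal((3000, n)))
            labels = balanced_labels(matrix)
            dist = nulldist.null_auc_interval(matrix, labels)
            widths.append(dist.upper - dist.lower)
        assert widths[1] < widths[0]

    def test_few_genes_warn(self):
        rng = np.random.default_rng(5)
        matrix = frame(rng.standard_normal((20, 10)))
        with pytest.warns(UserWarning, match="unstable"):
            nulldist.null_auc_interval(matrix, balanced_labels(matrix))


class TestInformativeFraction:
    def test_excess_arithmetic(self):
        null = nulldist.NullDistribution(coverage=0.99, lower=0.3, upper=0.7,
                                         n_genes_simulated=1000)
        aucs = np.concatenate([np.full(69, 0.5), np.full(31, 0.9)])
        outside, excess = nulldist.informative_fraction(aucs, null)
        assert outside == pytest.approx(0.31)
        assert excess == pytest.approx(0.30)

    def test_all_inside(self):
        null = nulldist.NullDistribution(coverage=0.99, lower=0.3, upper=0.7,
                                         n_genes_simulated=1000)
        assert nulldist.informative_fraction([0.5, 0.6], null) == (0.0, 0.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        matrix = frame(rng.standard_normal((8000, 40)))
        labels = balanced_labels(matrix)
        dist = nulldist.null_auc_interval(matrix, labels)
        fresh = frame(rng.standard_normal((8000, 40)))
        aucs = roc.auc_matrix(fresh.to_numpy(), labels.to_numpy())
        outside, _ = nulldist.informative_fraction(aucs, dist)
        assert outside == pytest.approx(0.01, abs=0.01)


class TestAucConcordance:
    def null(self):
        return nulldist.NullDistribution(coverage=0.99, lower=0.3, upper=0.7,
                                         n_genes_simulated=1000)

    def test_identical_vectors(self):
        aucs = np.array([0.2, 0.5, 0.9, 0.75])
        r, cat = nulldist.auc_concordance(aucs, aucs, self.null(), self.null())
        assert r == pytest.approx(1.0)
        assert list(cat) == ["concordant_low", "uninformative",
                             "concordant_high", "concordant_high"]

    def test_antisymmetric_vectors(self):
        aucs = np.array([0.2, 0.45, 0.9, 0.8])
        r, cat = nulldist.auc_concordance(aucs, 1 - aucs, self.null(),
                                          self.null())
        assert r == pytest.approx(-1.0)
        assert list(cat) == ["discordant", "uninformative", "discordant",
                             "discordant"]

    def test_independent_null_vectors(self):
        rng = np.random.default_rng(7)
        sd = np.sqrt(41 / (12 * 400))
        a = np.clip(0.5 + sd * rng.standard_normal(5000), 0, 1)
        b = np.clip(0.5 + sd * rng.standard_normal(5000), 0, 1)
        lo, hi = np.quantile(a, [0.005, 0.995])
        null = nulldist.NullDistribution(coverage=0.99, lower=lo, upper=hi,
                                         n_genes_simulated=5000)
        r, cat = nulldist.auc_concordance(a, b, null, null)
        assert abs(r) < 0.05
        conc = np.isin(cat, ["concordant_high", "concordant_low"]).mean()
        assert conc < 5e-4  # ~ (0.005)^2 * 2 per side under independence

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            nulldist.auc_concordance([0.5, 0.6], [0.5, 0.6], self.null(),
                                     self.null())


class TestNormalityVarianceProfile:
    def test_gaussian_rows_calibrated(self):
        rng = np.random.default_rng(8)
        matrix = frame(rng.standard_normal((400, 50)))
        profile = nulldist.normality_variance_profile(matrix)
        pvals = 10 ** (-profile["shapiro_neglog10_p"])
        # uniform p-values: roughly 5% below 0.05
        assert pvals.lt(0.05).mean() == pytest.approx(0.05, abs=0.04)

    def test_bimodal_row_detected(self):
        rng = np.random.default_rng(9)
        bimodal = np.concatenate([rng.normal(-4, 0.3, 25),
                                  rng.normal(4, 0.3, 25)])
        matrix = frame(np.vstack([bimodal, rng.standard_normal(50)]))
        profile = nulldist.normality_variance_profile(matrix)
        assert profile["shapiro_neglog10_p"].iloc[0] > 3.0

    def test_sample_sd(self):
        matrix = frame(np.array([[1.0, 2.0, 3.0]]))
        profile = nulldist.normality_variance_profile(matrix)
        assert profile["sd"].iloc[0] == pytest.approx(1.0)

    def test_constant_gene_reported_missing(self):
        matrix = frame(np.vstack([np.full(10, 2.0),
                                  np.arange(10, dtype=float)]))
        profile = nulldist.normality_variance_profile(matrix)
        assert np.isnan(profile["shapiro_neglog10_p"].iloc[0])

    def test_groups_attached(self):
        rng = np.random.default_rng(10)
        matrix = frame(rng.standard_normal((4, 10)))
        groups = pd.Series(["a", "a", "b", "b"], index=matrix.index)
        profile = nulldist.normality_variance_profile(matrix, groups)
        assert list(profile["group"]) == ["a", "a", "b", "b"]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nulldist.normality_variance_profile(frame(np.ones((2, 2))))
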