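"""Null-distribution diagnostics for per-gene AUC values.

Randomising an expression matrix gene-by-gene (Gaussian draws with each
gene's observed mean and SD) destroys any gene-class association while
preserving the per-gene marginal scale.  The empirical interval containing
99% of the per-gene AUCs on such data is the chance envelope: genes of the
real data falling outside it in excess of the nominal 1% are informative,
and that excess bounds the useful signature size.  Additional diagnostics
cover cross-cohort AUC concordance and per-gene normality/variance
profiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import roc
from .classifier import _align_labels

__all__ = [
    "NullDistribution",
    "randomize_dataset",
    "null_auc_interval",
    "informative_fraction",
    "auc_concordance",
    "normality_variance_profile",
]

_SHAPIRO_CAP = 5000


@dataclass
class NullDistribution:
    """Empirical chance envelope of per-gene AUC values."""

    coverage: float
    lower: float
    upper: float
    n_genes_simulated: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= 0.5 <= self.upper <= 1.0:
            raise ValueError(
                f"null interval [{self.lower}, {self.upper}] must bracket 0.5"
            )


def randomize_dataset(
    matrix: pd.DataFrame, seed: int, per_gene: bool = True
) -> pd.DataFrame:
    """Replace every gene row with Gaussian draws matching the observed
    mean and SD (per gene by default; ``per_gene=False`` uses the global
    mean/SD of the whole matrix).  A zero-SD gene becomes a constant row."""
    if matrix.isna().any().any():
        raise ValueError("randomize_dataset requires a matrix without missing values")
    values = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if per_gene:
        means = values.mean(axis=1, keepdims=True)
        sds = values.std(axis=1, ddof=1, keepdims=True)
    else:
        means = np.full((values.shape[0], 1), values.mean())
        sds = np.full((values.shape[0], 1), values.std(ddof=1))
    out = means + sds * rng.standard_normal(values.shape)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def null_auc_interval(
    matrix_random: pd.DataFrame,
    labels: pd.Series,
    coverage: float = 0.99,
    seed: int | None = None,
) -> NullDistribution:
    """Empirical central ``coverage`` interval of per-gene AUCs on
    randomised data (order-statistic quantiles with interpolation)."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    if matrix_random.shape[0] < 100:
        warnings.warn(
            f"only {matrix_random.shape[0]} genes; null quantiles are unstable",
            stacklevel=2,
        )
    z = _align_labels(matrix_random, labels)
    aucs = roc.auc_matrix(matrix_random.to_numpy(dtype=float), z)
    alpha = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(aucs, [alpha, 1.0 - alpha])
    return NullDistribution(
        coverage=coverage,
        lower=float(lower),
        upper=float(upper),
        n_genes_simulated=int(matrix_random.shape[0]),
        seed=seed,
    )


def informative_fraction(
    aucs, null: NullDistribution
) -> tuple[float, float]:
    """Share of genes outside the null envelope, and the excess over the
    nominal false-discovery share (1 - coverage); the excess estimates the
    fraction of genuinely informative genes."""
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size == 0:
        raise ValueError("aucs must be non-empty")
    outside = np.mean((aucs < null.lower) | (aucs > null.upper))
    excess = max(0.0, float(outside) - (1.0 - null.coverage))
    return float(outside), excess


def auc_concordance(
    aucs_a, aucs_b, null_a: NullDistribution, null_b: NullDistribution
) -> tuple[float, pd.Series]:
    """Pearson correlation of two cohorts' AUC vectors on shared genes,
    plus a per-gene concordance category.

    Categories: ``concordant_high`` (above the upper null bound in both),
    ``concordant_low`` (below the lower bound in both), ``discordant``
    (outside the envelope in both but on opposite sides), ``uninformative``
    (inside the envelope in at least one cohort).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC vectors must share the same genes in the same order")
    if a.size < 3:
        raise ValueError("concordance needs at least 3 genes")
    r = float(stats.pearsonr(a, b).statistic)
    high = (a > null_a.upper) & (b > null_b.upper)
    low = (a < null_a.lower) & (b < null_b.lower)
    out_a = (a < null_a.lower) | (a > null_a.upper)
    out_b = (b < null_b.lower) | (b > null_b.upper)
    category = np.select(
        [high, low, out_a & out_b],
        ["concordant_high", "concordant_low", "discordant"],
        default="uninformative",
    )
    index = aucs_a.index if isinstance(aucs_a, pd.Series) else None
    return r, pd.Series(category, index=index, name="category")


def normality_variance_profile(
    matrix: pd.DataFrame, gene_groups: pd.Series | None = None
) -> pd.DataFrame:
    """Shapiro-Wilk normality (-log10 p) and sample SD per gene.

    Constant genes have an undefined Shapiro p-value and are reported as
    missing.  At most 5000 samples per gene enter the test.  ``gene_groups``
    optionally attaches a category per gene for grouped comparison.
    """
    if matrix.shape[1] < 3:
        raise ValueError("Shapiro test needs at least 3 samples per gene")
    values = matrix.to_numpy(dtype=float)
    neglog10_p = np.full(values.shape[0], np.nan)
    for i, row in enumerate(values):
        sample = row[:_SHAPIRO_CAP]
        if np.ptp(sample) == 0.0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.shapiro(sample).pvalue
        neglog10_p[i] = -np.log10(max(p, np.finfo(float).tiny))
    out = pd.DataFrame(
        {
            "shapiro_neglog10_p": neglog10_p,
            "sd": values.std(axis=1, ddof=1),
        },
        index=matrix.index,
    )
    if gene_groups is not None:
        out["group"] = gene_groups.reindex(matrix.index)
    return out
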