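"""Leakage-safe evaluation of the metagene classifier.

Leave-one-out cross-validation repeats the *entire* training procedure —
gene ranking by oriented AUC, signature selection, sign assignment and
threshold fitting — inside every fold on the n-1 retained samples, so the
held-out sample never influences its own prediction.  Held-out predictions
are pooled into one global confusion table per signature size, from which
the balanced accuracy (sensitivity + specificity)/2 is computed; balanced
accuracy is independent of class prevalence.

`external_validate` implements the gene-transfer protocol for independent
cohorts: only the gene identities of a signature are carried over; per-gene
signs and the decision threshold are re-derived inside a LOOCV loop on the
validation cohort itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc
from .classifier import _align_labels, fit_threshold

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "ValidationReport",
    "balanced_accuracy",
    "loocv",
    "signature_sweep",
    "accuracy_deltas",
    "external_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2; requires both classes in the truth."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("balanced accuracy requires both classes in the truth")
    return (counts.sensitivity + counts.specificity) / 2.0


@dataclass
class CVReport:
    """Held-out predictions and pooled accuracies per signature size."""

    sizes: list[int]
    predictions: pd.DataFrame  # samples x sizes, held-out 0/1 calls
    truth: pd.Series
    confusion: dict[int, ConfusionCounts] = field(default_factory=dict)
    balanced_accuracies: dict[int, float] = field(default_factory=dict)

    def accuracy_curve(self) -> pd.Series:
        return pd.Series(
            [self.balanced_accuracies[x] for x in self.sizes],
            index=pd.Index(self.sizes, name="xgenes"),
            name="balanced_accuracy",
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for x in self.sizes:
            c = self.confusion[x]
            rows.append(
                {
                    "xgenes": x, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                    "sensitivity": c.sensitivity, "specificity": c.specificity,
                    "balanced_accuracy": self.balanced_accuracies[x],
                }
            )
        return pd.DataFrame(rows)


def _check_cv_viability(z: np.ndarray) -> None:
    if z.size < 3:
        raise ValueError("LOOCV requires at least 3 samples")
    if np.sum(z == 1) < 2 or np.sum(z == 0) < 2:
        raise ValueError(
            "LOOCV requires at least 2 samples per class so every fold "
            "retains both classes"
        )


def loocv(matrix: pd.DataFrame, labels: pd.Series, xgenes_list) -> CVReport:
    """LOOCV with feature selection repeated inside every fold.

    For each held-out sample, genes are ranked, the top ``xgenes`` selected,
    signs assigned and the threshold fitted on the remaining n-1 samples
    only; the held-out sample is then classified.  One pooled confusion
    table per signature size yields the balanced accuracy.
    """
    sizes = [int(x) for x in np.atleast_1d(np.asarray(xgenes_list, dtype=int))]
    if not sizes:
        raise ValueError("xgenes_list must be non-empty")
    n_genes = matrix.shape[0]
    for x in sizes:
        if not 1 <= x <= n_genes:
            raise ValueError(f"xgenes={x} out of range [1, {n_genes}]")
    if matrix.index.has_duplicates:
        raise ValueError("gene identifiers must be unique")
    z = _align_labels(matrix, labels).astype(bool)
    _check_cv_viability(z)

    values = matrix.to_numpy(dtype=float)
    gene_ids = matrix.index.to_numpy(dtype=str)
    n = z.size
    max_size = max(sizes)
    preds = np.zeros((n, len(sizes)), dtype=int)

    for i in range(n):
        idx = np.delete(np.arange(n), i)
        aucs = roc.auc_matrix(values[:, idx], z[idx])
        oriented = np.maximum(aucs, 1.0 - aucs)
        signs = np.where(aucs < 0.5, -1.0, 1.0)
        order = np.lexsort((gene_ids, -oriented))[:max_size]
        # prefix sums over the ranked signed rows give every signature size
        signed = values[order] * signs[order, None]
        prefix = np.cumsum(signed, axis=0)
        for j, x in enumerate(sizes):
            metagene = prefix[x - 1] / x
            t, _ = fit_threshold(metagene[idx], z[idx])
            preds[i, j] = int(metagene[i] > t)

    predictions = pd.DataFrame(preds, index=matrix.columns, columns=sizes)
    report = CVReport(
        sizes=sizes,
        predictions=predictions,
        truth=pd.Series(z.astype(int), index=matrix.columns, name="label"),
    )
    for x in sizes:
        c = ConfusionCounts.from_predictions(z, predictions[x])
        report.confusion[x] = c
        report.balanced_accuracies[x] = balanced_accuracy(c)
    return report


def signature_sweep(matrix: pd.DataFrame, labels: pd.Series, sizes) -> CVReport:
    """LOOCV balanced-accuracy curve over a grid of signature sizes
    (e.g. 5..500 in steps of 5)."""
    sizes = list(np.atleast_1d(np.asarray(sizes, dtype=int)))
    if not sizes:
        raise ValueError("size grid must be non-empty")
    if max(sizes) > matrix.shape[0]:
        raise ValueError(
            f"largest signature size {max(sizes)} exceeds gene count "
            f"{matrix.shape[0]}"
        )
    return loocv(matrix, labels, sizes)


def accuracy_deltas(curve) -> np.ndarray:
    """Step-to-step changes of an accuracy-vs-size curve."""
    values = np.asarray(curve, dtype=float)
    if values.size < 2:
        raise ValueError("accuracy curve needs at least 2 points")
    return np.diff(values)


@dataclass
class ValidationReport:
    """Gene-transfer validation: fixed gene identities, re-learned
    signs/thresholds per validation LOOCV fold."""

    genes_requested: list[str]
    genes_used: list[str]
    genes_missing: list[str]
    fold_thresholds: list[float]
    fold_signs: np.ndarray  # folds x genes_used
    predictions: pd.Series
    truth: pd.Series
    confusion: ConfusionCounts
    balanced_accuracy: float


def external_validate(
    signature_genes, matrix: pd.DataFrame, labels: pd.Series
) -> ValidationReport:
    """Evaluate a transferred signature on an independent cohort.

    Only gene identities cross cohorts; AUC orientation (signs) and the
    threshold are re-derived on each fold's n-1 training samples.  Signature
    genes absent from the validation matrix are dropped with a warning.
    """
    requested = [str(g) for g in signature_genes]
    if not requested:
        raise ValueError("signature must contain at least one gene")
    present_mask = [g in matrix.index for g in requested]
    used = [g for g, p in zip(requested, present_mask) if p]
    missing = [g for g, p in zip(requested, present_mask) if not p]
    if not used:
        raise KeyError("no signature gene overlaps the validation matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(requested)} signature genes absent from "
            "validation data; proceeding on the intersection",
            stacklevel=2,
        )
    z = _align_labels(matrix, labels).astype(bool)
    _check_cv_viability(z)

    sub = matrix.loc[used].to_numpy(dtype=float)
    n = z.size
    preds = np.zeros(n, dtype=int)
    thresholds: list[float] = []
    fold_signs = np.zeros((n, len(used)))
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        aucs = roc.auc_matrix(sub[:, idx], z[idx])
        signs = np.where(aucs < 0.5, -1.0, 1.0)
        fold_signs[i] = signs
        metagene = (sub * signs[:, None]).mean(axis=0)
        t, _ = fit_threshold(metagene[idx], z[idx])
        thresholds.append(t)
        preds[i] = int(metagene[i] > t)

    predictions = pd.Series(preds, index=matrix.columns, name="predicted_class")
    confusion = ConfusionCounts.from_predictions(z, preds)
    return ValidationReport(
        genes_requested=requested,
        genes_used=used,
        genes_missing=missing,
        fold_thresholds=thresholds,
        fold_signs=fold_signs,
        predictions=predictions,
        truth=pd.Series(z.astype(int), index=matrix.columns, name="label"),
        confusion=confusion,
        balanced_accuracy=balanced_accuracy(confusion),
    )
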