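"""The univariate gene-expression-average (metagene) classifier.

A signature is the top ``xgenes`` genes by oriented AUC.  The metagene of a
sample is the arithmetic mean of the signature's expression values after
multiplying genes negatively associated with the class (AUC < 0.5) by -1.
The decision threshold is the metagene value maximising (unbalanced) training
accuracy over all splits of the samples sorted by metagene value, placed at
the midpoint of the two border samples; a sample with metagene strictly above
the threshold is called class 1, otherwise class 0.

`MetageneClassifier` exposes this as a scikit-learn estimator (samples x
features orientation) so it composes with sklearn model selection; `train` /
`predict_samples` are the genes x samples domain wrappers used by the CLI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import roc

__all__ = [
    "MetageneModel",
    "MetageneClassifier",
    "build_metagene",
    "fit_threshold",
    "train",
    "predict_samples",
]


@dataclass
class MetageneModel:
    """A trained metagene classifier: ordered genes, signs and threshold."""

    genes: list[str]
    signs: list[int]
    threshold: float
    n_pos: int = 0
    n_neg: int = 0
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.signs = [int(s) for s in self.signs]
        if len(self.genes) != len(self.signs) or len(self.genes) < 1:
            raise ValueError("genes and signs must be equal-length and non-empty")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be -1 or +1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def build_metagene(
    matrix: pd.DataFrame, genes: list[str], signs: list[int]
) -> pd.Series:
    """Per-sample metagene: mean of sign-corrected expression over ``genes``.

    ``matrix`` is genes x samples.  Raises if any signature gene is absent.
    """
    genes = [str(g) for g in genes]
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    if len(genes) != len(signs):
        raise ValueError("genes and signs must have equal length")
    signed = matrix.loc[genes].to_numpy(dtype=float) * np.asarray(signs)[:, None]
    return pd.Series(signed.mean(axis=0), index=matrix.columns, name="metagene")


def _threshold_candidates(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct metagene values, plus sentinel
    thresholds below the minimum and above the maximum.

    The sentinel gap is half the smallest positive gap between sorted values
    (1 if all values are equal) so all-on-one-side splits stay finite.
    """
    v = np.unique(values)
    delta = np.min(np.diff(v)) / 2.0 if v.size > 1 else 1.0
    return np.concatenate([[v[0] - delta], (v[:-1] + v[1:]) / 2.0, [v[-1] + delta]])


def fit_threshold(metagene: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Threshold maximising training accuracy under the ``x > t -> 1`` rule.

    Ties in accuracy are broken by highest sensitivity, then by the largest
    threshold, so the result is deterministic.  Returns (threshold, accuracy).
    """
    metagene = np.asarray(metagene, dtype=float)
    z = np.asarray(z).astype(bool)
    if z.all() or not z.any():
        raise ValueError("both classes must be present to fit a threshold")
    cands = _threshold_candidates(metagene)
    pred = metagene[None, :] > cands[:, None]
    acc = (pred == z[None, :]).mean(axis=1)
    sens = pred[:, z].mean(axis=1)
    best = np.lexsort((cands, sens, acc))[-1]
    return float(cands[best]), float(acc[best])


class MetageneClassifier(ClassifierMixin, BaseEstimator):
    """ROC/AUC-ranked metagene classifier with in-fit feature selection.

    Parameters
    ----------
    n_genes : int, default=200
        Signature size: the number of top oriented-AUC features averaged into
        the metagene.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; ``classes_[1]`` is the positive class.
    ranking_ : DataFrame
        Full feature ranking (gene_id, auc, oriented_auc, sign, rank) computed
        on the training data; gene_id holds feature names when fitted on a
        DataFrame, else stringified column indices.
    support_ : ndarray of int
        Column indices of the selected signature, in ranking order.
    genes_ : list of str
        Signature identifiers corresponding to ``support_``.
    signs_ : ndarray of int
        Per-gene orientation (+1/-1) applied before averaging.
    threshold_ : float
        Metagene decision threshold.
    training_accuracy_ : float
        Unbalanced accuracy of the fitted threshold on the training samples.
    """

    def __init__(self, n_genes: int = 200):
        self.n_genes = n_genes

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError(
                f"metagene classifier requires exactly 2 classes, "
                f"got {self.classes_.size}"
            )
        z = y_idx.astype(bool)
        if not 1 <= self.n_genes <= X.shape[1]:
            raise ValueError(
                f"n_genes must be in [1, {X.shape[1]}], got {self.n_genes}"
            )
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = np.array([str(j) for j in range(X.shape[1])])
        frame = pd.DataFrame(X.T, index=names)
        self.ranking_ = roc.rank_genes(frame, z)
        sig = roc.top_signature(self.ranking_, self.n_genes)
        name_to_col = {str(n): j for j, n in enumerate(names)}
        self.support_ = np.array([name_to_col[g] for g in sig["gene_id"]])
        self.genes_ = list(sig["gene_id"])
        self.signs_ = sig["sign"].to_numpy()
        metagene = (X[:, self.support_] * self.signs_).mean(axis=1)
        self.threshold_, self.training_accuracy_ = fit_threshold(metagene, z)
        return self

    def decision_function(self, X):
        """Metagene value minus threshold; positive means class 1."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        metagene = (X[:, self.support_] * self.signs_).mean(axis=1)
        return metagene - self.threshold_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def _align_labels(matrix: pd.DataFrame, labels: pd.Series) -> np.ndarray:
    missing = matrix.columns.difference(labels.index)
    if len(missing):
        raise KeyError(f"samples without labels: {list(missing)}")
    z = labels.reindex(matrix.columns).to_numpy()
    if not np.isin(z, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return z.astype(int)


def train(matrix: pd.DataFrame, labels: pd.Series, xgenes: int) -> MetageneModel:
    """Train a metagene classifier on a genes x samples matrix.

    Ranks all genes by oriented AUC, keeps the top ``xgenes``, orients each by
    its AUC sign and fits the accuracy-optimal threshold on the metagene.
    """
    if matrix.index.has_duplicates:
        raise ValueError("gene identifiers must be unique for training")
    z = _align_labels(matrix, labels)
    # fit on the transposed DataFrame so tie-breaking uses gene ids, not
    # row positions, keeping the model invariant under gene reordering
    clf = MetageneClassifier(n_genes=xgenes).fit(matrix.T, z)
    return MetageneModel(
        genes=clf.genes_,
        signs=list(clf.signs_),
        threshold=clf.threshold_,
        n_pos=int(np.sum(z == 1)),
        n_neg=int(np.sum(z == 0)),
        training_accuracy=clf.training_accuracy_,
    )


def predict_samples(
    model: MetageneModel, matrix: pd.DataFrame, mode: str = "strict"
) -> pd.DataFrame:
    """Classify the samples of ``matrix`` with a trained model.

    mode="strict" (default) errors when signature genes are absent;
    mode="intersect" re-averages over the available genes with a warning, for
    cross-platform use.  Returns a DataFrame (sample_id, metagene_value,
    predicted_class); a sample is class 1 iff its metagene exceeds the
    threshold strictly.
    """
    genes, signs = model.genes, model.signs
    present = [g in matrix.index for g in genes]
    if not all(present):
        absent = [g for g, p in zip(genes, present) if not p]
        if mode == "strict":
            raise KeyError(f"signature genes absent from matrix: {absent}")
        if mode != "intersect":
            raise ValueError(f"unknown prediction mode: {mode!r}")
        if not any(present):
            raise KeyError("no signature gene present in matrix")
        warnings.warn(
            f"{len(absent)} of {len(genes)} signature genes absent; "
            "re-averaging over the intersection",
            stacklevel=2,
        )
        genes = [g for g, p in zip(genes, present) if p]
        signs = [s for s, p in zip(signs, present) if p]
    metagene = build_metagene(matrix, genes, signs)
    return pd.DataFrame(
        {
            "sample_id": matrix.columns,
            "metagene_value": metagene.to_numpy(),
            "predicted_class": (metagene.to_numpy() > model.threshold).astype(int),
        }
    )
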