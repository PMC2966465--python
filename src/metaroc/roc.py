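"""Per-gene ROC/AUC statistics, orientation and ranking.

The area under the empirical ROC curve for a covariate ``x`` against a binary
class variable ``z`` is computed through the Mann-Whitney rank identity

    AUC = U / (n1 * n0),   U = R1 - n1 (n1 + 1) / 2,

where ``R1`` is the midrank sum of the class-1 values, so ties between a
positive and a negative value contribute 1/2 of a concordant pair.  A covariate
negatively associated with the class has AUC < 0.5; flipping its sign turns AUC
into 1 - AUC, so max(AUC, 1 - AUC) — the *oriented* AUC — is the covariate's
performance and the quantity genes are ranked by for signature selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["auc", "orient", "auc_matrix", "rank_genes", "top_signature"]


def _validate_labels(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z)
    if not np.isin(z, (0, 1)).all():
        raise ValueError("class labels must be 0 or 1")
    z = z.astype(bool)
    if z.all() or not z.any():
        raise ValueError("both classes must be present")
    return z


def auc_matrix(values: np.ndarray, z: np.ndarray) -> np.ndarray:
    """AUC of every row of ``values`` (genes x samples) against labels ``z``.

    Vectorised midrank Mann-Whitney; returns one AUC per row.
    """
    z = _validate_labels(z)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != z.size:
        raise ValueError(
            f"covariate has {values.shape[1]} samples but labels have {z.size}"
        )
    if not np.isfinite(values).all():
        raise ValueError("covariate values must be finite")
    n1 = int(z.sum())
    n0 = z.size - n1
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, z].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def auc(x: np.ndarray, z: np.ndarray) -> float:
    """Empirical ROC AUC of a single covariate (ties counted half)."""
    return float(auc_matrix(np.asarray(x, dtype=float)[None, :], z)[0])


def orient(auc_value: float) -> tuple[float, int]:
    """Map an AUC to (oriented AUC, sign).

    Sign is -1 for AUC < 0.5 (negatively associated genes are multiplied by -1
    before averaging) and +1 otherwise; AUC exactly 0.5 keeps sign +1.
    """
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc_value}")
    if auc_value < 0.5:
        return 1.0 - auc_value, -1
    return auc_value, +1


def rank_genes(matrix: pd.DataFrame, z: np.ndarray) -> pd.DataFrame:
    """Rank all genes of a genes x samples matrix by oriented AUC.

    Returns a DataFrame with columns ``gene_id, auc, oriented_auc, sign, rank``
    sorted by oriented AUC descending.  Ties in oriented AUC are broken by
    gene_id lexicographically so the ranking does not depend on input row
    order.
    """
    if matrix.index.has_duplicates:
        raise ValueError("gene identifiers must be unique for ranking")
    aucs = auc_matrix(matrix.to_numpy(dtype=float), z)
    oriented = np.maximum(aucs, 1.0 - aucs)
    signs = np.where(aucs < 0.5, -1, 1)
    out = pd.DataFrame(
        {
            "gene_id": matrix.index.astype(str),
            "auc": aucs,
            "oriented_auc": oriented,
            "sign": signs,
        }
    )
    out = out.sort_values(
        ["oriented_auc", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_signature(ranking: pd.DataFrame, xgenes: int) -> pd.DataFrame:
    """First ``xgenes`` entries of a ranking (order preserved)."""
    if not 1 <= xgenes <= len(ranking):
        raise ValueError(
            f"xgenes must be in [1, {len(ranking)}], got {xgenes}"
        )
    return ranking.iloc[:xgenes].reset_index(drop=True)
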