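"""Reading, writing and preprocessing of expression matrices and labels.

Expression matrices are pandas DataFrames with genes as rows (index =
gene_id) and samples as columns, log-scale values; labels are pandas Series
of 0/1 indexed by sample_id.  Files are UTF-8, tab-delimited by default,
'.' decimal, with empty string or "NA" read as missing.

The preprocessing transforms mirror a common microarray pipeline: duplicate
gene symbols merged by their element-wise median, k-nearest-neighbour
imputation (genes with more than 20% missing values dropped first), per-gene
mean-centering, and quantile normalisation across samples.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import MetageneModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "merge_duplicate_genes",
    "knn_impute",
    "mean_center",
    "quantile_normalize",
    "read_model",
    "write_model",
]

MODEL_FORMAT_VERSION = 1
_NA_VALUES = ["", "NA"]
_SEPS = {"tsv": "\t", "csv": ","}


def read_expression(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    First column holds gene ids, the header row holds sample ids.  Empty
    cells and "NA" become missing values; duplicate gene ids are preserved
    (see `merge_duplicate_genes`); duplicate sample ids are an error.
    """
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}, got {dialect!r}")
    # pandas mangles duplicate header names, so check the raw header line
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(_SEPS[dialect])[1:]
                break
        else:
            raise ValueError("empty expression file")
    seen: set[str] = set()
    dup = [s for s in header if s in seen or seen.add(s)]
    if dup:
        raise ValueError(f"duplicate sample ids in header: {sorted(set(dup))}")
    raw = pd.read_csv(
        path, sep=_SEPS[dialect], header=0, index_col=0, dtype=str,
        na_values=_NA_VALUES, keep_default_na=False, comment="#",
    )
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique()
        raise ValueError(f"duplicate sample ids in header: {list(dups)}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = pd.to_numeric(raw[col]).to_numpy()
        except (ValueError, TypeError):
            for i, cell in enumerate(raw[col]):
                if pd.notna(cell):
                    try:
                        float(cell)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric value {cell!r} at gene "
                            f"{raw.index[i]!r}, sample {col!r}"
                        ) from None
            raise
    return pd.DataFrame(values, index=raw.index.astype(str).rename("gene_id"),
                        columns=raw.columns.astype(str))


def write_expression(matrix: pd.DataFrame, path, header_comment: str | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.rename_axis("gene_id").to_csv(fh, sep="\t", na_rep="NA")


def read_labels(path) -> pd.Series:
    """Read a two-column sample_id <TAB> label file; labels must be 0 or 1.

    A file containing a single class is accepted here — training and
    evaluation operations reject it when both classes are required.
    """
    table = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#",
                        na_values=_NA_VALUES, keep_default_na=False)
    if table.shape[1] != 2:
        raise ValueError(f"expected 2 columns (sample_id, label), got {table.shape[1]}")
    sample_ids = table.iloc[:, 0].astype(str)
    if sample_ids.duplicated().any():
        dups = sample_ids[sample_ids.duplicated()].unique()
        raise ValueError(f"duplicate sample ids in labels: {list(dups)}")
    raw = table.iloc[:, 1]
    if not raw.isin(["0", "1"]).all():
        bad = sorted(set(raw[~raw.isin(["0", "1"])].astype(str)))
        raise ValueError(f"labels must be 0 or 1, found {bad}")
    return pd.Series(raw.astype(int).to_numpy(), index=pd.Index(sample_ids, name="sample_id"),
                     name="label")


def write_labels(labels: pd.Series, path, header_comment: str | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        labels.rename("label").rename_axis("sample_id").to_csv(fh, sep="\t")


def merge_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene id to their element-wise median.

    Keeps the first-occurrence order of gene ids; idempotent.
    """
    if not matrix.index.has_duplicates:
        return matrix.copy()
    merged = matrix.groupby(level=0, sort=False).median()
    order = matrix.index.drop_duplicates()
    return merged.loc[order]


def knn_impute(
    matrix: pd.DataFrame, k: int = 10, max_missing_frac: float = 0.20
) -> pd.DataFrame:
    """k-nearest-neighbour imputation of missing expression values.

    Genes missing in more than ``max_missing_frac`` of samples are dropped
    first.  Each remaining missing cell is replaced by the mean, over the k
    genes nearest in mean squared difference on mutually observed samples, of
    those genes' values at that sample.  Candidate neighbours must share at
    least one observed sample with the target gene and have an observed value
    at the target sample; with fewer than k candidates all are used (with a
    warning), with none it is an error.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    frac = matrix.isna().mean(axis=1)
    kept = matrix.loc[frac <= max_missing_frac].copy()
    values = kept.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    if obs.all():
        return kept
    filled = values.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        shared = obs & obs[i]                       # (G, S) mutually observed
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, values - values[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.einsum("gs,gs->g", diff, diff) / n_shared
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for s in np.flatnonzero(~obs[i]):
            cand = np.isfinite(dist) & obs[:, s]
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                raise ValueError(
                    f"no neighbour with an observed value for gene "
                    f"{kept.index[i]!r} at sample {kept.columns[s]!r}"
                )
            if idx.size < k:
                warnings.warn(
                    f"only {idx.size} neighbours available for gene "
                    f"{kept.index[i]!r} at sample {kept.columns[s]!r} (k={k})",
                    stacklevel=2,
                )
                chosen = idx
            else:
                chosen = idx[np.argsort(dist[idx], kind="stable")[:k]]
            filled[i, s] = values[chosen, s].mean()
    return pd.DataFrame(filled, index=kept.index, columns=kept.columns)


def mean_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean expression from its row."""
    if matrix.isna().any().any():
        raise ValueError("mean_center requires a matrix without missing values")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise samples: every column gets the same sorted vector,
    the element-wise mean of the per-column sorted vectors; within-column ties
    receive the mean of the reference values at their tied ranks."""
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation requires at least 2 samples")
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize requires a matrix without missing values")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    # tied entries get the mean of the reference values across their tied ranks
    rmin = rankdata(values, axis=0, method="min").astype(int)
    rmax = rankdata(values, axis=0, method="max").astype(int)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def write_model(model: MetageneModel, path, extra_metadata: dict | None = None):
    """Serialise a trained model to JSON (lossless round-trip)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "xgenes": len(model.genes),
        "genes": model.genes,
        "signs": model.signs,
        "threshold": model.threshold,
        "trained_on": {
            "n_samples": model.n_pos + model.n_neg,
            "n_pos": model.n_pos,
            "n_neg": model.n_neg,
        },
        "training_accuracy": model.training_accuracy,
    }
    if extra_metadata:
        payload["metadata"] = extra_metadata
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_model(path) -> MetageneModel:
    """Read and validate a JSON model written by `write_model`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    for field in ("genes", "signs", "threshold"):
        if field not in payload:
            raise ValueError(f"model file missing required field {field!r}")
    trained = payload.get("trained_on", {})
    return MetageneModel(
        genes=payload["genes"],
        signs=payload["signs"],
        threshold=float(payload["threshold"]),
        n_pos=int(trained.get("n_pos", 0)),
        n_neg=int(trained.get("n_neg", 0)),
        training_accuracy=float(payload.get("training_accuracy", float("nan"))),
    )
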