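import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy4():
    """Two perfectly anti-correlated genes over 4 samples, classes 0,0,1,1."""
    matrix = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
        index=["g1", "g2"],
        columns=["a", "b", "c", "d"],
    )
    labels = pd.Series([0, 0, 1, 1], index=matrix.columns, name="label")
    return matrix, labels


@pytest.fixture
def toy6():
    """Six samples, two perfectly separating genes plus four uninformative
    genes whose per-class value multisets are identical, so they cannot
    separate the classes in any leave-one-out fold."""
    sep = np.array([[0, 0, 0, 1, 1, 1.0], [1, 1, 1, 0, 0, 0.0]])
    noise = np.array(
        [
            [5.0, 1.0, 3.0, 5.0, 1.0, 3.0],
            [2.0, 7.0, 4.0, 4.0, 2.0, 7.0],
            [1.0, 2.0, 3.0, 3.0, 1.0, 2.0],
            [9.0, 8.0, 7.0, 7.0, 9.0, 8.0],
        ]
    )
    matrix = pd.DataFrame(
        np.vstack([sep, noise]),
        index=["up", "down", "n1", "n2", "n3", "n4"],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series([0, 0, 0, 1, 1, 1], index=matrix.columns, name="label")
    return matrix, labels


def brute_force_auc(x, z):
    """Independent oracle: count concordant (pos, neg) pairs, ties half."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z).astype(bool)
    pos = x[z]
    neg = x[~z]
    total = 0.0
    for xi in pos:
        for xj in neg:
            if xi > xj:
                total += 1.0
            elif xi == xj:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_threshold(values, z):
    """Independent oracle for the optimal-accuracy threshold search.

    Enumerates every split of the sorted samples, realises it as the
    midpoint threshold of the border samples (sentinels at the ends) and
    scores the strict-greater prediction rule.
    """
    values = np.asarray(values, dtype=float)
    z = np.asarray(z).astype(bool)
    order = np.argsort(values, kind="stable")
    v = values[order]
    uniq = np.unique(values)
    delta = np.min(np.diff(uniq)) / 2.0 if uniq.size > 1 else 1.0
    best = None
    for i in range(len(v) + 1):
        if i == 0:
            t = v[0] - delta
        elif i == len(v):
            t = v[-1] + delta
        else:
            t = (v[i - 1] + v[i]) / 2.0
        pred = values > t
        acc = float(np.mean(pred == z))
        sens = float(np.mean(pred[z]))
        key = (acc, sens, t)
        if best is None or key > best:
            best = key
    return best  # (accuracy, sensitivity, threshold)
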