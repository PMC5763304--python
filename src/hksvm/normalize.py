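"""Per-array normalization for expression matrices.

Two procedures commonly applied to microarray intensity matrices before
kernel construction:

* mean scaling — each array (sample) is divided by its own mean intensity,
  so every sample ends with mean exactly 1;
* quantile normalization — the classic rank-mean transform making all
  samples' value distributions identical (ties within a sample receive the
  mean of the rank-means they span, so strict distribution identity holds
  for tie-free samples).

Arrays are rows here (samples-as-rows orientation).
"""

from __future__ import annotations

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["METHODS", "mean_scale", "quantile_normalize", "normalize"]

METHODS = ("none", "mean_scale", "quantile")


def mean_scale(X: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample vector by its own mean intensity.

    Idempotent; every output sample has mean 1.  A zero-mean sample (possible
    only on signed data, e.g. log-ratio arrays) is an error.
    """
    means = X.values.mean(axis=1)
    if np.any(means == 0):
        i = int(np.flatnonzero(means == 0)[0])
        raise ValueError(f"sample {X.sample_ids[i]} has zero mean intensity; cannot mean-scale")
    return ExpressionMatrix(X.values / means[:, None], X.sample_ids, X.feature_ids)


def _quantile_rows(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=1)
    rank_means = sorted_vals.mean(axis=0)
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        row_sorted = sorted_vals[i]
        assigned = rank_means.copy()
        # average rank-means over each tie group
        start = 0
        for stop in range(1, len(row_sorted) + 1):
            if stop == len(row_sorted) or row_sorted[stop] != row_sorted[start]:
                if stop - start > 1:
                    assigned[start:stop] = rank_means[start:stop].mean()
                start = stop
        out[i, order[i]] = assigned
    return out


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-mean quantile normalization across samples.

    Sort each sample, average across samples at each rank, and map the
    rank-means back through each sample's ordering.  Idempotent and
    equivariant under within-sample permutations.
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    return ExpressionMatrix(_quantile_rows(X.values), X.sample_ids, X.feature_ids)


def normalize(X: ExpressionMatrix, method: str = "none") -> ExpressionMatrix:
    """Apply a named normalization method (``none`` returns X unchanged)."""
    if method == "none":
        return X
    if method == "mean_scale":
        return mean_scale(X)
    if method == "quantile":
        return quantile_normalize(X)
    raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
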