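"""Quantile normalization and log transformation of intensity matrices.

All samples are quantile-normalized together before testing: after
normalization every sample's sorted value vector equals the across-sample
mean of sorted vectors, so samples share one empirical distribution and
between-group rank comparisons are not driven by per-chip intensity scale.
"""

from __future__ import annotations

import numpy as np

from .io import IntensityMatrix

__all__ = ["quantile_normalize", "log_transform"]


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize all samples together.

    Ties within a sample receive the mean of the quantile values their slots
    span (the standard "average" tie dialect).  The operation is idempotent
    and preserves each sample's rank order and the total sum.
    """
    x = matrix.values
    if x.shape[1] < 2:
        raise ValueError("nothing to normalize: need at least 2 samples")
    order = np.argsort(x, axis=0, kind="stable")
    mean_sorted = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = np.empty(x.shape[0])
        col[order[:, j]] = mean_sorted
        sorted_vals = x[order[:, j], j]
        # average quantile values over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        runs = np.split(np.arange(x.shape[0]), boundaries)
        for run in runs:
            if len(run) > 1:
                col[order[run, j]] = mean_sorted[run].mean()
        out[:, j] = col
    return IntensityMatrix(
        matrix.probe_ids, list(matrix.sample_ids), matrix.groups, out,
        log_scale=matrix.log_scale,
    )


def log_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2.  Requires strictly positive input values."""
    if matrix.log_scale:
        raise ValueError("matrix is already on the log scale")
    if np.any(matrix.values <= 0):
        raise ValueError("log transform requires positive values")
    return IntensityMatrix(
        matrix.probe_ids, list(matrix.sample_ids), matrix.groups,
        np.log2(matrix.values), log_scale=True,
    )
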