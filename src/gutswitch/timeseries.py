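"""Time-series state analysis.

Implements the steady-state detection and visualization pipeline used
on bioreactor time series: per-variable min-max scaling to [0, 1],
Bray-Curtis dissimilarity between each time point and the point two
sampling steps ahead (lag 2), maximal below-threshold runs as steady
windows, PCA trajectories, and ternary (barycentric) composition
coordinates for three-species communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateSeries",
    "SteadyCall",
    "minmax_scale",
    "bray_curtis",
    "steady_windows",
    "ternary_coords",
    "pca_trajectory",
    "DEFAULT_STEADY_THRESHOLD",
]

#: default Bray-Curtis steadiness threshold (dimensionless); the
#: sensitivity of steady-window calls to this choice is documented in
#: docs/methods.md
DEFAULT_STEADY_THRESHOLD = 0.05


@dataclass
class StateSeries:
    """Sample x variable matrix of cell and metabolite measurements."""

    times: np.ndarray
    matrix: np.ndarray
    variable_kinds: list = field(default_factory=list)  # "cell" | "metabolite"
    variable_names: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or len(self.times) != self.matrix.shape[0]:
            raise ValueError("matrix must be (n_samples, n_variables)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite values in series")

    @classmethod
    def from_dataset(cls, dataset, replicate=None):
        """Pivot a tidy ObservationDataset (one replicate) into a series."""
        rec = dataset.records
        if replicate is not None:
            rec = rec[rec["replicate"] == replicate]
        wide = rec.pivot_table(index="time_h", columns="variable",
                               values="value").sort_index()
        kinds = []
        for var in wide.columns:
            unit = rec.loc[rec["variable"] == var, "unit"].iloc[0]
            kinds.append("cell" if "cells" in unit else "metabolite")
        return cls(times=wide.index.to_numpy(), matrix=wide.to_numpy(),
                   variable_kinds=kinds, variable_names=list(wide.columns))


@dataclass
class SteadyCall:
    """Lag-k Bray-Curtis dissimilarities and the windows called steady."""

    dissimilarities: np.ndarray   # entry i compares samples i and i+lag
    threshold: float
    windows: list                 # list of (start, stop) sample-index ranges
    lag: int = 2


def minmax_scale(matrix):
    """Per-column (x - min) / (max - min); constant columns map to 0."""
    X = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    out = np.zeros_like(X)
    nz = span > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on nonneg vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative entries")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


def steady_windows(series: StateSeries, lag: int = 2,
                   threshold: float = DEFAULT_STEADY_THRESHOLD,
                   scale: bool = True) -> SteadyCall:
    """Flag steady stretches by the lag-``lag`` Bray-Curtis criterion.

    Variables are min-max scaled first (the standard order; ``scale=False``
    compares raw values).  Sample i is evaluable if i+lag exists; maximal
    runs of evaluable samples with dissimilarity below the threshold are
    returned as (start, stop) index ranges (stop exclusive).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = series.matrix.shape[0]
    if n < lag + 1:
        raise ValueError(f"need at least lag+1={lag + 1} samples")
    X = minmax_scale(series.matrix) if scale else series.matrix
    d = np.empty(n - lag)
    for i in range(n - lag):
        a, b = X[i], X[i + lag]
        d[i] = 0.0 if np.sum(a + b) == 0 else bray_curtis(a, b)
    below = d < threshold
    windows = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            windows.append((start, i))
            start = None
    if start is not None:
        windows.append((start, len(below)))
    return SteadyCall(dissimilarities=d, threshold=threshold,
                      windows=windows, lag=lag)


def ternary_coords(abundances):
    """Barycentric coordinates of a three-species composition."""
    v = np.asarray(abundances, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("need exactly three abundances")
    if np.any(v < 0):
        raise ValueError("negative abundances")
    total = v.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total abundance")
    return v / total


def pca_trajectory(series: StateSeries, n_components: int = 2):
    """Principal-component scores of the min-max-scaled series.

    Returns ``(scores, explained_variance_fractions)``; with
    ``n_components=None`` all components are kept (scores then
    reproduce the pairwise Euclidean geometry of the scaled, centered
    data).  Rank-deficient inputs are handled with a warning;
    components beyond the rank are zero.
    """
    X = minmax_scale(series.matrix)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 samples and >= 2 variables")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    k = min(n, p) if n_components is None else min(n_components, min(n, p))
    if rank < k:
        warnings.warn(f"rank-deficient data (rank {rank} < {k} components); "
                      "trailing components are zero", RuntimeWarning)
    scores = U[:, :k] * S[:k]
    total = float(np.sum(S ** 2))
    evr = (S[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return scores, evr
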