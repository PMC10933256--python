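"""Resting-state functional connectivity (RSFC).

Collapses channels (voxels, components) to regions by averaging, then
computes the N×N matrix of Pearson correlations between region time series.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["roi_average", "compute_rsfc", "validate_rsfc", "RsfcExtractor"]


def roi_average(channel_ts: np.ndarray, labels, regions=None) -> np.ndarray:
    """Average channel time series within regions.

    Parameters
    ----------
    channel_ts
        T×V matrix of channel signals.
    labels
        Length-V sequence assigning each channel to a region.
    regions
        Region order for the output columns. Defaults to sorted unique
        labels; if given, every region must own at least one channel.
    """
    channel_ts = np.asarray(channel_ts, dtype=float)
    labels = np.asarray(labels)
    if channel_ts.ndim != 2:
        raise ValueError("channel_ts must be 2-D (T x V)")
    if labels.shape[0] != channel_ts.shape[1]:
        raise ValueError(
            f"{labels.shape[0]} labels for {channel_ts.shape[1]} channels"
        )
    if regions is None:
        regions = np.unique(labels)
    out = np.empty((channel_ts.shape[0], len(regions)))
    for j, region in enumerate(regions):
        mask = labels == region
        if not mask.any():
            raise ValueError(f"region {region!r} has no channels")
        out[:, j] = channel_ts[:, mask].mean(axis=1)
    return out


def compute_rsfc(ts: np.ndarray, region_labels=None) -> np.ndarray:
    """Pearson correlation matrix between region time series.

    Returns an N×N symmetric matrix with the diagonal set to exactly 1 and
    entries clipped into [-1, 1] against floating-point overshoot.  A
    zero-variance region is an error (naming the region) rather than NaN.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be 2-D (T x N)")
    t, n = ts.shape
    if t < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(region_labels[i]) for i in bad]
            if region_labels is not None
            else [str(i) for i in bad]
        )
        raise ValueError(f"zero-variance region(s): {', '.join(names)}")
    rsfc = np.corrcoef(ts, rowvar=False)
    rsfc = np.clip((rsfc + rsfc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rsfc, 1.0)
    return rsfc


def validate_rsfc(rsfc: np.ndarray, atol: float = 1e-12) -> None:
    """Raise unless ``rsfc`` is a valid correlation matrix (shape-wise)."""
    rsfc = np.asarray(rsfc)
    if rsfc.ndim != 2 or rsfc.shape[0] != rsfc.shape[1]:
        raise ValueError("RSFC matrix must be square")
    if not np.allclose(rsfc, rsfc.T, atol=atol):
        raise ValueError("RSFC matrix must be symmetric")
    if not np.allclose(np.diag(rsfc), 1.0, atol=atol):
        raise ValueError("RSFC diagonal must be 1")
    if np.any(np.abs(rsfc) > 1 + atol):
        raise ValueError("RSFC entries must lie in [-1, 1]")


class RsfcExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping stacked subject time series to RSFC matrices.

    ``transform`` accepts an array of shape (n_subjects, T, N) and returns
    (n_subjects, N, N).  Stateless; ``fit`` records the region count.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_subjects, T, N)")
        self.n_regions_ = X.shape[2]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_subjects, T, N)")
        return np.stack([compute_rsfc(subject) for subject in X])
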