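"""Temporal cleaning of ROI time series.

Removes head-motion and physiological confounds from region-averaged BOLD
signals, then high-pass filters them.  The confound model has 27 columns:
a linear trend, the 24-parameter Friston autoregressive expansion of the six
rigid-body motion parameters, and mean white-matter and CSF time series.
The high-pass filter is realized as regression on a discrete-cosine basis
(the SPM convention) with a default cutoff of 0.01 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "friston24",
    "build_nuisance_design",
    "regress_out",
    "dct_basis",
    "highpass_dct",
    "clean_timeseries",
    "CleanTimeSeries",
]

DEFAULT_CUTOFF_HZ = 0.01


@dataclass
class CleanTimeSeries:
    """Residualized T×N signal plus the sampling metadata it was cleaned with."""

    data: np.ndarray
    tr_seconds: float
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ
    region_labels: list[str] | None = field(default=None)


def friston24(motion: np.ndarray) -> np.ndarray:
    """Expand six rigid-body motion parameters to the 24-parameter model.

    Columns are ordered ``[R(t), R(t)^2, R(t-1), R(t-1)^2]`` where ``R`` is
    the T×6 motion matrix; the lagged rows at t=0 are zero-filled.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, motion**2, lagged, lagged**2])


def build_nuisance_design(
    motion: np.ndarray, wm: np.ndarray, csf: np.ndarray
) -> np.ndarray:
    """Assemble the 27-column confound design ``[trend | friston24 | wm | csf]``.

    The linear trend is normalized to run from 0 to 1 (scale-invariant for
    OLS; fixed for reproducibility).
    """
    motion = np.asarray(motion, dtype=float)
    wm = np.asarray(wm, dtype=float).reshape(-1)
    csf = np.asarray(csf, dtype=float).reshape(-1)
    t = motion.shape[0]
    if wm.shape[0] != t or csf.shape[0] != t:
        raise ValueError(
            f"length mismatch: motion T={t}, wm T={wm.shape[0]}, csf T={csf.shape[0]}"
        )
    trend = np.arange(t, dtype=float) / (t - 1)
    return np.column_stack([trend, friston24(motion), wm, csf])


def _prune_dependent_columns(design: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (pivoted-QR rank test)."""
    _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(design.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < design.shape[1]:
        kept = np.sort(piv[:rank])
        dropped = sorted(set(range(design.shape[1])) - set(kept.tolist()))
        msg = f"nuisance design is rank deficient; dropping columns {dropped}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
        return design[:, kept]
    return design


def regress_out(ts: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each time-series column on the design.

    An intercept is always included implicitly: both the data and the design
    are demeaned before the fit, so residuals are mean-zero and orthogonal to
    every design column.  A rank-deficient design is pruned (with a warning)
    rather than rejected, because degenerate synthetic motion is legal input.
    """
    ts = np.asarray(ts, dtype=float)
    design = np.asarray(design, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    if design.ndim == 1:
        design = design[:, None]
    t = ts.shape[0]
    if design.shape[0] != t:
        raise ValueError("time dimension mismatch between data and design")
    if t <= design.shape[1]:
        raise ValueError(
            f"need more time points ({t}) than regressors ({design.shape[1]})"
        )
    if not (np.all(np.isfinite(ts)) and np.all(np.isfinite(design))):
        raise ValueError("non-finite values in data or design")

    x = design - design.mean(axis=0)
    # drop all-zero (constant) columns outright; they are absorbed by the mean
    nonzero = np.linalg.norm(x, axis=0) > 0
    x = x[:, nonzero]
    y = ts - ts.mean(axis=0)
    if x.shape[1] == 0:
        return y
    x = _prune_dependent_columns(x)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def dct_basis(n_timepoints: int, n_components: int) -> np.ndarray:
    """Discrete-cosine basis (without the constant term).

    Column ``k`` (1-based) is ``cos(pi * (t + 0.5) * k / T)``; at sampling
    interval ``tr`` it oscillates at ``k / (2 * T * tr)`` Hz.
    """
    t = np.arange(n_timepoints, dtype=float)
    k = np.arange(1, n_components + 1, dtype=float)
    return np.cos(np.pi * np.outer(t + 0.5, k) / n_timepoints)


def n_highpass_components(n_timepoints: int, tr_seconds: float, cutoff_hz: float) -> int:
    """Number of DCT regressors (besides the constant) below ``cutoff_hz``."""
    return int(np.floor(2.0 * n_timepoints * tr_seconds * cutoff_hz))


def highpass_dct(
    ts: np.ndarray, tr_seconds: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ
) -> np.ndarray:
    """High-pass filter by regressing out slow discrete-cosine components.

    All basis functions with frequency below ``cutoff_hz`` — there are
    ``floor(2 * T * tr * cutoff)`` of them — plus the constant are removed.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    t = ts.shape[0]
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if t * tr_seconds <= 1.0 / cutoff_hz:
        raise ValueError(
            "run is shorter than one cutoff period; high-pass is undefined"
        )
    k = n_highpass_components(t, tr_seconds, cutoff_hz)
    if k + 1 >= t:
        raise ValueError(f"DCT basis of size {k + 1} too large for T={t}")
    if k == 0:
        return ts - ts.mean(axis=0)
    return regress_out(ts, dct_basis(t, k))


def clean_timeseries(
    ts: np.ndarray,
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    tr_seconds: float,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
    region_labels: list[str] | None = None,
) -> CleanTimeSeries:
    """Full temporal cleaning: 27-regressor confound removal, then high-pass.

    ``cutoff_hz=None`` skips the high-pass step (confound removal only).

    The filter step re-includes the confound columns alongside the DCT
    basis, so the final residuals are exactly orthogonal to both sets (a
    purely sequential filter would leak a small confound component back in,
    because the two projections do not commute).
    """
    design = build_nuisance_design(motion, wm, csf)
    resid = regress_out(ts, design)
    if cutoff_hz is not None:
        t = resid.shape[0]
        if cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if t * tr_seconds <= 1.0 / cutoff_hz:
            raise ValueError(
                "run is shorter than one cutoff period; high-pass is undefined"
            )
        k = n_highpass_components(t, tr_seconds, cutoff_hz)
        if k + 1 >= t:
            raise ValueError(f"DCT basis of size {k + 1} too large for T={t}")
        if k > 0:
            resid = regress_out(resid, np.column_stack([design, dct_basis(t, k)]))
    return CleanTimeSeries(
        data=resid,
        tr_seconds=tr_seconds,
        cutoff_hz=cutoff_hz,
        region_labels=region_labels,
    )
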