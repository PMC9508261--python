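"""Motion QC, time-series cleaning, and Fisher-z connectivity matrices.

Implements the per-subject path from raw parcel time series plus rigid-body
motion parameters to a symmetric nonnegative connectivity matrix:

1. framewise displacement (FD) from the six motion parameters, with subject
   exclusion at mean FD > 0.25 mm and volume scrubbing at FD > 0.5 mm;
2. confound regression (OLS residuals) followed by zero-phase band-pass
   filtering (default 0.01–0.08 Hz);
3. pairwise Pearson correlation on the unscrubbed volumes, Fisher z
   transform, removal of negative edges, zero diagonal.

Scrubbed volumes are excluded at the correlation step, not from the filter:
the filter needs a contiguous series, while the correlation only needs the
retained samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Head radius (mm) used to convert rotations to arc-length displacement.
HEAD_RADIUS_MM = 50.0

#: Subject-level exclusion threshold on mean FD (mm).
MEAN_FD_MAX = 0.25

#: Volume-level scrubbing threshold on FD (mm).
SCRUB_FD = 0.5

#: Minimum number of retained volumes for a valid correlation.
MIN_VOLUMES = 10

__all__ = [
    "FDSeries",
    "QCDecision",
    "framewise_displacement",
    "motion_qc",
    "clean_timeseries",
    "connectivity_matrix",
]


@dataclass(frozen=True)
class FDSeries:
    """Per-volume framewise displacement in mm (first volume defined as 0)."""

    fd: np.ndarray

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd))

    def __len__(self) -> int:
        return len(self.fd)


@dataclass(frozen=True)
class QCDecision:
    """Outcome of motion quality control for one subject."""

    include: bool
    keep_mask: np.ndarray = field(repr=False)
    mean_fd: float = 0.0

    @property
    def scrubbed_fraction(self) -> float:
        return float(1.0 - np.mean(self.keep_mask))

    @property
    def n_scrubbed(self) -> int:
        return int((~self.keep_mask).sum())


def framewise_displacement(
    motion: np.ndarray, head_radius: float = HEAD_RADIUS_MM
) -> FDSeries:
    """FD from a T x 6 motion trace (3 rotations in rad, 3 translations in mm).

    FD_t = sum |delta translations| + head_radius * sum |delta rotations|,
    i.e. rotations are converted to arc length on a sphere of the given
    radius.  FD at the first volume is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion trace must have 6 columns (3 rotations, 3 translations), "
            f"got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = head_radius * d[:, :3].sum(axis=1) + d[:, 3:].sum(axis=1)
    return FDSeries(fd=np.concatenate([[0.0], fd]))


def motion_qc(
    fd: FDSeries,
    mean_fd_max: float = MEAN_FD_MAX,
    scrub_fd: float = SCRUB_FD,
) -> QCDecision:
    """Subject inclusion and volume scrubbing from an FD series.

    The subject is excluded iff mean FD exceeds ``mean_fd_max``; volumes
    with FD strictly above ``scrub_fd`` are marked for scrubbing either way.
    """
    keep = fd.fd <= scrub_fd
    return QCDecision(
        include=fd.mean_fd <= mean_fd_max, keep_mask=keep, mean_fd=fd.mean_fd
    )


def _regress_out(Y: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    T = Y.shape[0]
    X = np.ones((T, 1))
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != T:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, expected {T}"
            )
        X = np.column_stack([X, confounds])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "confound model is rank-deficient (rank %d of %d columns); "
            "collinear directions are dropped by the least-squares fit",
            rank,
            X.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def clean_timeseries(
    ts: pd.DataFrame | np.ndarray,
    confounds: np.ndarray | None = None,
    tr: float = 3.0,
    band: tuple[float, float] = (0.01, 0.08),
    filter_order: int = 2,
):
    """Confound regression followed by zero-phase band-pass filtering.

    Each parcel series is replaced by its OLS residual against an intercept
    plus the confound columns, then filtered with a forward-backward
    (zero-phase) Butterworth band-pass of the given order.

    Returns the same container type as the input (DataFrame columns are
    preserved).
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 <= low < high):
        raise ValueError(f"invalid band {band}")
    if high >= nyquist:
        raise ValueError(
            f"band upper edge {high} Hz is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz at TR={tr} s"
        )
    is_frame = isinstance(ts, pd.DataFrame)
    Y = np.asarray(ts, dtype=float)
    if Y.ndim != 2:
        raise ValueError("time series must be a T x n_parcels table")
    if np.isnan(Y).any():
        raise ValueError("time series contains missing values")
    if Y.shape[0] < MIN_VOLUMES:
        raise ValueError(f"need at least {MIN_VOLUMES} volumes, got {Y.shape[0]}")

    resid = _regress_out(Y, confounds)
    if low > 0:
        sos = signal.butter(
            filter_order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos"
        )
    else:
        sos = signal.butter(
            filter_order, high, btype="lowpass", fs=1.0 / tr, output="sos"
        )
    out = signal.sosfiltfilt(sos, resid, axis=0)
    if is_frame:
        return pd.DataFrame(out, columns=ts.columns, index=ts.index)
    return out


def connectivity_matrix(
    ts: pd.DataFrame | np.ndarray,
    keep_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Nonnegative Fisher-z connectivity from (scrub-masked) time series.

    Pairwise Pearson correlations are computed on the retained volumes only,
    Fisher-z transformed (``atanh`` with |r| clipped just below 1 so
    degenerate inputs stay finite), negative entries are set to zero, and
    the diagonal is zeroed.  Zero-variance parcels get all-zero edges with a
    logged warning.
    """
    Y = np.asarray(ts, dtype=float)
    if Y.ndim != 2:
        raise ValueError("time series must be a T x n_parcels table")
    if keep_mask is not None:
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape[0] != Y.shape[0]:
            raise ValueError("scrub mask length does not match volume count")
        Y = Y[keep_mask]
    if Y.shape[0] < MIN_VOLUMES:
        raise ValueError(
            f"fewer than {MIN_VOLUMES} volumes remain after scrubbing "
            f"({Y.shape[0]})"
        )
    sd = Y.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance parcel(s); their edges are set to 0",
            int(degenerate.sum()),
        )
    n = Y.shape[1]
    r = np.zeros((n, n))
    ok = ~degenerate
    if ok.sum() >= 2:
        sub = np.corrcoef(Y[:, ok], rowvar=False)
        r[np.ix_(ok, ok)] = sub
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0
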