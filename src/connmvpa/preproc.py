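"""Regional time-series preparation for resting-state connectivity.

Covers the per-subject steps between motion-corrected images and the
correlation matrix: discarding initial saturation volumes, nuisance
regression, zero-phase Chebyshev band-pass filtering (0.01-0.08 Hz at
TR = 2 s by default), frame-wise-displacement (FD) motion scrubbing with
linear interpolation, and atlas parcellation of a 4D volume into regional
mean series.

FD conventions
--------------
The per-frame motion summary is the sum of absolute backward differences
of the six rigid-body parameters, with each rotational difference
converted to millimetres as arc length on a sphere of radius 50 mm.
FD at the first frame is defined as 0. Frames with FD above a threshold
(default 0.5 mm) are flagged and their signal values replaced by linear
interpolation between the nearest unflagged neighbours; flagged runs at
the series boundary take the nearest unflagged value.

The default stage order is discard -> nuisance regression -> band-pass ->
scrub; the order is configurable (see :func:`connmvpa.pipeline.run_pipeline`)
and recorded in the run log.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

__all__ = [
    "MotionTrace",
    "FDSeries",
    "RoiTimeSeries",
    "discard_initial",
    "framewise_displacement",
    "scrub",
    "regress_nuisance",
    "bandpass",
    "parcellate",
]

SPHERE_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.5
N_DISCARD_DEFAULT = 5


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame rigid-body realignment parameters.

    Columns: tx, ty, tz in mm; rx, ry, rz in the declared angular unit
    (``"rad"`` or ``"deg"``). Realignment tools conventionally write
    radians; degrees must be declared explicitly.
    """

    params: np.ndarray  # (n_frames, 6)
    unit: str = "rad"

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.params, dtype=float))
        if p.shape[1] != 6:
            raise ValueError(f"motion trace needs 6 columns, got {p.shape[1]}")
        if self.unit not in ("rad", "deg"):
            raise ValueError(f"rotation unit must be 'rad' or 'deg', got {self.unit!r}")
        object.__setattr__(self, "params", p)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class FDSeries:
    """Frame-wise displacement in mm, with the flag mask FD > threshold."""

    fd: np.ndarray  # (n_frames,), mm
    flags: np.ndarray  # (n_frames,), bool
    threshold_mm: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class RoiTimeSeries:
    """Regional mean signal: frames x regions, with TR and 1-based IDs."""

    data: np.ndarray  # (n_frames, n_regions)
    tr: float  # seconds
    region_ids: np.ndarray  # (n_regions,)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        ids = np.asarray(self.region_ids, dtype=int)
        if d.ndim != 2:
            raise ValueError("time series must be a 2-D frames x regions matrix")
        if ids.shape != (d.shape[1],):
            raise ValueError("region_ids length must match the number of columns")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not np.all(np.isfinite(d)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def discard_initial(ts: RoiTimeSeries, k: int = N_DISCARD_DEFAULT) -> RoiTimeSeries:
    """Drop the first k frames (magnetic-saturation volumes; default 5)."""
    if not 0 <= k < ts.n_frames:
        raise ValueError(f"cannot discard {k} of {ts.n_frames} frames")
    return replace(ts, data=ts.data[k:])


def framewise_displacement(
    m: MotionTrace,
    sphere_radius_mm: float = SPHERE_RADIUS_MM,
    threshold_mm: float = FD_THRESHOLD_MM,
) -> FDSeries:
    """Frame-wise displacement from six realignment parameters.

    FD_i = sum over the six parameters of |delta between frames i and
    i-1|, rotations first converted to arc length on a sphere of
    ``sphere_radius_mm`` (degrees are converted to radians before the
    arc-length product). FD_1 = 0 by definition.
    """
    if m.n_frames < 2:
        raise ValueError("FD needs at least 2 frames")
    p = m.params.copy()
    if m.unit == "deg":
        p[:, 3:] = np.deg2rad(p[:, 3:])
    p[:, 3:] *= sphere_radius_mm  # rotation -> mm arc length
    fd = np.zeros(m.n_frames)
    fd[1:] = np.abs(np.diff(p, axis=0)).sum(axis=1)
    return FDSeries(fd=fd, flags=fd > threshold_mm, threshold_mm=threshold_mm)


def scrub(
    ts: RoiTimeSeries, fd: FDSeries, threshold_mm: float | None = None
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Replace high-motion frames by linear interpolation.

    Every frame with FD above the threshold is replaced, per region, by
    linear interpolation between the nearest unflagged neighbours; flagged
    frames at the boundaries take the nearest unflagged value. Returns the
    scrubbed series and the boolean mask of replaced frames.
    """
    if fd.fd.shape[0] != ts.n_frames:
        raise ValueError(
            f"FD has {fd.fd.shape[0]} frames but time series has {ts.n_frames}"
        )
    thr = fd.threshold_mm if threshold_mm is None else threshold_mm
    mask = fd.fd > thr
    if not mask.any():
        return ts, mask
    if mask.all():
        raise ValueError("all frames exceed the FD threshold; nothing to interpolate from")
    frames = np.arange(ts.n_frames)
    good = frames[~mask]
    data = ts.data.copy()
    for c in range(ts.n_regions):
        # np.interp clamps to the edge values outside [good[0], good[-1]]
        data[mask, c] = np.interp(frames[mask], good, ts.data[good, c])
    return replace(ts, data=data), mask


def regress_nuisance(ts: RoiTimeSeries, covariates: np.ndarray | None = None) -> RoiTimeSeries:
    """Regress nuisance covariates out of every regional series.

    The design matrix is [intercept | covariates]; the returned series are
    the least-squares residuals, orthogonal to every design column. Typical
    covariates: the six motion parameters, global mean, white-matter and
    cerebrospinal-fluid signals.

    Raises
    ------
    ValueError
        Covariate rows do not match the frame count, or the design matrix
        is rank deficient (the error lists the collinear columns).
    """
    n = ts.n_frames
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        X = np.ones((n, 1))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            if cov.shape[1] == n:  # accept p x frames
                cov = cov.T
            else:
                raise ValueError(
                    f"covariates have {cov.shape[0]} rows but series has {n} frames"
                )
        X = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(
            f"rank-deficient nuisance design (rank {rank} < {X.shape[1]} columns); "
            f"collinear column(s) {bad} (0 = intercept)"
        )
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return replace(ts, data=ts.data - X @ beta)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns lying in the span of the columns before them."""
    bad = []
    for j in range(1, X.shape[1]):
        prior = X[:, :j]
        resid = X[:, j] - prior @ np.linalg.lstsq(prior, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) <= 1e-10 * max(np.linalg.norm(X[:, j]), 1.0):
            bad.append(j)
    return bad


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
    ripple_db: float = 0.5,
) -> RoiTimeSeries:
    """Zero-phase Chebyshev type-I band-pass filter.

    Applied forward and backward (filtfilt) so the passband signal keeps
    its phase. Defaults: order 4, 0.5 dB passband ripple, 0.01-0.08 Hz --
    the conventional resting-state fluctuation band.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz at TR={ts.tr}s"
        )
    b, a = scipy.signal.cheby1(
        order, ripple_db, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr
    )
    filtered = scipy.signal.filtfilt(b, a, ts.data, axis=0)
    return replace(ts, data=filtered)


def parcellate(
    volume4d: np.ndarray,
    atlas_labels3d: np.ndarray,
    tr: float,
    region_ids: np.ndarray | None = None,
) -> RoiTimeSeries:
    """Average a 4D volume over atlas labels into regional mean series.

    Parameters
    ----------
    volume4d : array or nibabel image, shape (x, y, z, frames)
    atlas_labels3d : array or nibabel image of non-negative integers,
        0 = background. Regions are returned in ascending label order.
    region_ids : optional explicit label list; a requested label absent
        from the atlas raises an error naming it.
    """
    vol = np.asarray(getattr(volume4d, "dataobj", volume4d), dtype=float)
    atlas = np.asarray(getattr(atlas_labels3d, "dataobj", atlas_labels3d))
    if not np.issubdtype(atlas.dtype, np.integer):
        if not np.all(atlas == np.round(atlas)):
            raise ValueError("atlas labels must be integers")
        atlas = atlas.astype(int)
    if np.any(atlas < 0):
        raise ValueError("atlas labels must be non-negative (0 = background)")
    if vol.ndim != 4 or atlas.shape != vol.shape[:3]:
        raise ValueError(
            f"volume grid {vol.shape[:3]} does not match atlas grid {atlas.shape}"
        )
    present = np.unique(atlas[atlas > 0])
    if region_ids is None:
        ids = present
    else:
        ids = np.sort(np.asarray(region_ids, dtype=int))
        missing = np.setdiff1d(ids, present)
        if missing.size:
            raise ValueError(f"label(s) {missing.tolist()} absent from the atlas")
    n_frames = vol.shape[3]
    flat = vol.reshape(-1, n_frames)
    labels_flat = atlas.ravel()
    data = np.empty((n_frames, ids.size))
    for col, lab in enumerate(ids):
        data[:, col] = flat[labels_flat == lab].mean(axis=0)
    return RoiTimeSeries(data=data, tr=tr, region_ids=ids)
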