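"""Resting-state cleaning: nuisance regression, bandpass, motion scrubbing.

Reproduces the six-step cleaning sequence used for resting-state
functional-correlation data: (1) nuisance regression, (2) bandpass
filtering, (3) flagging of high-motion frames by framewise displacement
(FD), (4) interpolation over flagged frames so censoring artifacts do
not blur into kept data, (5) re-regression and refiltering of the
interpolated series, and (6) removal of the flagged frames. Participants
with fewer than ``min_frames`` surviving frames are excluded.

The motion trace is an input (frames x 6: translations in mm, rotations
in radians); discarding any leading scanner-stabilization frames is the
caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    InputError,
    ParticipantExcludedError,
    RankDeficientDesignError,
)

#: Default radius (mm) at which rotational differentials are converted to
#: arc displacement, following the motion-scrubbing literature.
ROTATION_RADIUS_MM = 50.0

FD_THRESHOLD_MM = 0.3
MIN_FRAMES = 75
BAND_HZ = (0.009, 0.08)


@dataclass
class CleanTimeSeries:
    """Residual, filtered, scrubbed time series.

    ``data`` holds only the surviving frames; ``keep_mask`` indexes the
    original frame axis (0-based) and has one entry per input frame.
    """

    data: np.ndarray  # n_kept x nodes
    keep_mask: np.ndarray  # bool, length = original frame count
    fd: np.ndarray  # per original frame, mm

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())


def compute_fd(
    trace: np.ndarray, rotation_radius_mm: float = ROTATION_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement: sum of absolute parameter differentials.

    ``FD_t = |Δd_x| + |Δd_y| + |Δd_z| + r (|Δα| + |Δβ| + |Δγ|)`` with the
    three rotational differentials scaled by ``rotation_radius_mm`` to an
    arc length. ``FD_0`` is defined as 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise InputError(f"motion trace must be frames x 6, got {trace.shape}")
    if trace.shape[0] < 2:
        raise InputError("need at least 2 frames to differentiate motion")
    bad = np.flatnonzero(~np.isfinite(trace).all(axis=1))
    if bad.size:
        raise InputError(f"non-finite realignment parameters at frame {bad[0]}")
    d = np.abs(np.diff(trace, axis=0))
    fd = np.zeros(trace.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return fd


def friston24(trace: np.ndarray) -> np.ndarray:
    """The 24-column motion design: params at t, at t-1, and their squares.

    Lagged values at frame 0 are defined as 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise InputError(f"motion trace must be frames x 6, got {trace.shape}")
    lagged = np.vstack([np.zeros((1, 6)), trace[:-1]])
    return np.hstack([trace, lagged, trace**2, lagged**2])


def nuisance_regress(
    ts: np.ndarray, regressors: np.ndarray, add_intercept: bool = True
) -> np.ndarray:
    """Residualize ``ts`` against the nuisance design (plus an intercept).

    Residuals are orthogonal to the regressor column space. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    ts = np.asarray(ts, dtype=float)
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if ts.shape[0] != X.shape[0]:
        raise InputError(
            f"time series has {ts.shape[0]} frames but design has {X.shape[0]}"
        )
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    collinear = np.flatnonzero(diag <= tol)
    if collinear.size:
        cols = ", ".join(str(c - int(add_intercept)) for c in collinear)
        raise RankDeficientDesignError(
            f"nuisance design is rank deficient; collinear column(s): {cols} "
            "(0-based, intercept excluded)"
        )
    beta = np.linalg.solve(r, q.T @ ts)
    return ts - X @ beta


def bandpass(
    ts: np.ndarray,
    tr_seconds: float,
    low_hz: float = BAND_HZ[0],
    high_hz: float = BAND_HZ[1],
    order: int = 2,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along frames."""
    ts = np.asarray(ts, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not 0.0 < low_hz < high_hz < nyquist:
        raise InputError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyquist})"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
    )
    padlen = 3 * (2 * order + 1)
    n = ts.shape[0]
    if n <= padlen:
        raise InputError(
            f"series of {n} frames is too short for the filter warm-up; "
            f"need more than {padlen} frames"
        )
    return signal.sosfiltfilt(sos, ts, axis=0)


def interpolate_frames(ts: np.ndarray, censor_mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate censored frames from the nearest kept frames.

    Censored runs at either end are held at the nearest kept value.
    """
    ts = np.asarray(ts, dtype=float)
    censor = np.asarray(censor_mask, dtype=bool)
    if censor.shape[0] != ts.shape[0]:
        raise InputError("censor mask length must equal frame count")
    if not censor.any():
        return ts.copy()
    kept = np.flatnonzero(~censor)
    if kept.size == 0:
        raise InputError("cannot interpolate: every frame is censored")
    out = ts.copy()
    frames = np.arange(ts.shape[0])
    for j in range(ts.shape[1]):
        out[censor, j] = np.interp(frames[censor], kept, ts[kept, j])
    return out


def clean_rsfc(
    ts: np.ndarray,
    regressors: np.ndarray,
    fd_series: np.ndarray,
    fd_threshold: float = FD_THRESHOLD_MM,
    min_frames: int = MIN_FRAMES,
    tr_seconds: float = 2.0,
    low_hz: float = BAND_HZ[0],
    high_hz: float = BAND_HZ[1],
) -> CleanTimeSeries:
    """Run the full six-step cleaning sequence on one participant.

    Raises :class:`ParticipantExcludedError` when fewer than
    ``min_frames`` frames survive scrubbing.
    """
    ts = np.asarray(ts, dtype=float)
    fd = np.asarray(fd_series, dtype=float)
    if fd.shape[0] != ts.shape[0]:
        raise InputError("fd_series must be frame-aligned with the time series")
    # (1) nuisance regression, (2) bandpass
    resid = nuisance_regress(ts, regressors)
    filtered = bandpass(resid, tr_seconds, low_hz, high_hz)
    # (3) flag motion-contaminated frames
    censor = fd > fd_threshold
    keep_mask = ~censor
    n_kept = int(keep_mask.sum())
    if n_kept < min_frames:
        raise ParticipantExcludedError(n_kept, min_frames)
    if censor.any():
        # (4) interpolate flagged frames, (5) re-regress and refilter
        interp = interpolate_frames(filtered, censor)
        resid2 = nuisance_regress(interp, regressors)
        filtered = bandpass(resid2, tr_seconds, low_hz, high_hz)
    # (6) drop flagged frames
    return CleanTimeSeries(data=filtered[keep_mask], keep_mask=keep_mask, fd=fd)
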