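"""Raw-signal conditioning: zero-phase low-pass filtering and release detection.

Optical-marker trajectories are low-pass filtered with a Butterworth filter
applied forward and backward (zero phase distortion), the standard
biomechanics recipe; the default is a 12th-order, 10 Hz design at 120 Hz.
Ball release is the first frame at which the Euclidean distance between the
ball marker and the index-finger marker strictly exceeds a threshold
(default 0.01 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, NoReleaseError, ParameterError

__all__ = ["zero_phase_lowpass", "detect_release", "ReleaseDetection"]


def zero_phase_lowpass(
    series,
    fs: float,
    cutoff: float = 10.0,
    order: int = 12,
    order_convention: str = "per-pass",
):
    """Forward-backward Butterworth low-pass filter (zero phase lag).

    Parameters
    ----------
    series
        Length-N real signal (or an array whose last axis is time).
    fs
        Sampling rate in Hz.
    cutoff
        -3 dB cutoff in Hz; must satisfy 0 < cutoff < fs/2.
    order
        Even filter order.  With ``order_convention="per-pass"`` (default)
        a filter of this order is designed and applied twice (the combined
        magnitude response is its square); with ``"effective"`` a filter of
        ``order // 2`` is designed so the two passes jointly realize the
        stated order.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("series contains non-finite values")
    if not 0 < cutoff < fs / 2:
        raise ParameterError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}); got {cutoff}"
        )
    if order < 2 or order % 2:
        raise ParameterError(f"order must be a positive even integer, got {order}")
    if order_convention == "per-pass":
        design_order = order
    elif order_convention == "effective":
        design_order = max(order // 2, 1)
    else:
        raise ParameterError(f"unknown order_convention {order_convention!r}")
    sos = signal.butter(design_order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * design_order
    n = x.shape[-1]
    if n <= padlen:
        raise ParameterError(
            f"series too short for stable filtering: need N > {padlen}, got {n}"
        )
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


@dataclass
class ReleaseDetection:
    """Release frame plus the full distance trace for auditing."""

    frame: int
    distance: np.ndarray
    threshold: float


def detect_release(ball_xyz, finger_xyz, threshold: float = 0.01) -> ReleaseDetection:
    """First frame at which ball-finger distance strictly exceeds ``threshold``.

    Both trajectories are N x 3 in meters.  Raises :class:`NoReleaseError`
    if the distance never crosses the threshold and :class:`DataError`
    (naming the first offending frame) on non-finite coordinates.
    """
    ball = np.asarray(ball_xyz, dtype=float)
    finger = np.asarray(finger_xyz, dtype=float)
    if ball.shape != finger.shape or ball.ndim != 2 or ball.shape[1] != 3:
        raise ParameterError(
            f"trajectories must share shape (N, 3); got {ball.shape} and {finger.shape}"
        )
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    finite = np.isfinite(ball).all(axis=1) & np.isfinite(finger).all(axis=1)
    if not finite.all():
        raise DataError(
            f"non-finite coordinates at frame {int(np.flatnonzero(~finite)[0])}"
        )
    dist = np.linalg.norm(ball - finger, axis=1)
    over = dist > threshold
    if not over.any():
        raise NoReleaseError(
            f"distance never exceeds threshold {threshold} m "
            f"(max {dist.max():.4g} m)"
        )
    return ReleaseDetection(
        frame=int(np.flatnonzero(over)[0]), distance=dist, threshold=threshold
    )
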