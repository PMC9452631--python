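"""Running speed and the immobility gate.

Sharp-wave ripples are a hallmark of awake rest, so detection is restricted
to periods in which the animal moves slower than a threshold (2 cm/s by
default).  This module turns the 50 Hz camera track into a per-LFP-sample
boolean mask and the total immobile duration used to normalize event
densities and cross-correlograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .exceptions import DataValidationError
from .signal_io import LfpTrace, PositionTrack

DEFAULT_SPEED_THRESHOLD_CM_S = 2.0
DEFAULT_SMOOTH_WINDOW_S = 0.4


@dataclass(frozen=True)
class SpeedSeries:
    """Instantaneous running speed (cm/s) at the position-track timestamps."""

    times: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        speed = np.asarray(self.speed, float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "speed", speed)
        if times.size != speed.size:
            raise DataValidationError("times and speed must have equal length")
        if np.any(~np.isfinite(speed)) or np.any(speed < 0):
            raise DataValidationError("speeds must be finite and nonnegative")


@dataclass(frozen=True)
class ImmobilityMask:
    """Per-LFP-sample immobility gate.

    ``mask[i]`` is True when the animal is immobile (speed below threshold)
    at LFP sample ``i``; samples outside the tracked time range are False.
    """

    mask: np.ndarray
    fs: float

    @property
    def total_immobile_duration(self) -> float:
        """Seconds spent immobile: (number of True samples) / fs."""
        return float(np.count_nonzero(self.mask)) / self.fs

    def __len__(self) -> int:
        return self.mask.size


def compute_speed(track: PositionTrack, smooth_window: float = DEFAULT_SMOOTH_WINDOW_S) -> SpeedSeries:
    """Running speed from a position track.

    Positions are boxcar-smoothed over ``smooth_window`` seconds (to
    suppress tracker jitter) before differentiation; speed is the Euclidean
    norm of the central-difference velocity, with one-sided differences at
    the endpoints.

    Parameters
    ----------
    track : PositionTrack
    smooth_window : float
        Boxcar width in seconds; 0 disables smoothing.
    """
    if smooth_window < 0:
        raise ValueError("smooth_window must be >= 0")
    t = track.times
    if np.any(np.diff(t) <= 0):
        raise DataValidationError("duplicate or decreasing timestamps")
    x, y = track.x, track.y
    n_win = int(round(smooth_window * track.fs_nominal))
    if n_win > 1:
        x = uniform_filter1d(x, size=n_win, mode="nearest")
        y = uniform_filter1d(y, size=n_win, mode="nearest")
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    return SpeedSeries(times=t, speed=speed)


def immobility_mask(
    speed: SpeedSeries,
    lfp: LfpTrace,
    threshold: float = DEFAULT_SPEED_THRESHOLD_CM_S,
) -> ImmobilityMask:
    """Resample speed onto the LFP clock and threshold it.

    Speed is held at its previous value between camera fixes (the mask is
    piecewise constant between 50 Hz samples).  The gate uses a strict
    inequality, ``speed < threshold``.  LFP samples before the first or
    after the last camera fix are marked mobile (False).
    """
    t_lfp = lfp.times()
    t_spd = speed.times
    if t_lfp[-1] < t_spd[0] or t_lfp[0] > t_spd[-1]:
        raise DataValidationError("speed series and LFP trace do not overlap in time")
    idx = np.searchsorted(t_spd, t_lfp, side="right") - 1
    in_range = (idx >= 0) & (t_lfp <= t_spd[-1])
    mask = np.zeros(t_lfp.size, dtype=bool)
    valid = np.flatnonzero(in_range)
    mask[valid] = speed.speed[idx[valid]] < threshold
    return ImmobilityMask(mask=mask, fs=lfp.fs)
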