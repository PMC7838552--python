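"""Sampled 2-D trajectories, binocular recordings, and velocity estimation.

The common currency of every analysis stage is a uniformly sampled bivariate
position time series in degrees of visual angle.  Velocity is estimated
either with the 5-point centered stencil used by relative-threshold saccade
detectors,

    v_i = (q_{i+2} + q_{i+1} - q_{i-1} - q_{i-2}) / (6 dt),

or as the least-squares slope of position against time over a centered
6-sample window (the scheme used for velocity-domain similarity analysis),
or with a plain central difference.  All three are exact for affine signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

from .errors import BadWindowError, TooShortError, UpsampleError

_GRID_TOL = 1e-9  # max tolerated |dt - 1/rate| in seconds


class VelocityMethod(str, Enum):
    EK5 = "ek5"
    SLOPE6 = "slope6"
    CENTRAL = "central"


@dataclass
class Trajectory:
    """Uniformly sampled bivariate position signal.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing on a uniform grid.
    x, y : array of float
        Position in degrees of visual angle (screen-centered frame).
    rate : float
        Sampling rate in Hz; ``t`` must advance by ``1/rate``.
    missing_mask : array of bool, optional
        True where the sample is missing/invalid.  Defaults to all valid.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.t.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.missing_mask) == n):
            raise ValueError("t, x, y, missing_mask must have equal length")
        if n == 0:
            raise ValueError("empty trajectory")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.rate)) >= _GRID_TOL:
                raise ValueError("t is not a uniform grid at the stated rate")
        valid = ~self.missing_mask
        if not np.all(np.isfinite(self.x[valid])) or not np.all(
            np.isfinite(self.y[valid])
        ):
            raise ValueError("non-masked samples must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n samples at the stated rate)."""
        return len(self.t) / self.rate

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of [x, y] samples."""
        return np.column_stack([self.x, self.y])

    def slice(self, start: int, stop: int) -> "Trajectory":
        """Half-open sample slice preserving absolute times."""
        return Trajectory(
            t=self.t[start:stop],
            x=self.x[start:stop],
            y=self.y[start:stop],
            rate=self.rate,
            missing_mask=self.missing_mask[start:stop],
        )

    def with_positions(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float))

    @staticmethod
    def from_xy(
        x, y, rate: float, t0: float = 0.0, missing_mask=None
    ) -> "Trajectory":
        """Build a trajectory on a fresh uniform grid starting at ``t0``."""
        x = np.asarray(x, dtype=float)
        t = t0 + np.arange(len(x)) / rate
        return Trajectory(t=t, x=x, y=np.asarray(y, dtype=float), rate=rate,
                          missing_mask=missing_mask)


class Eye(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass
class BinocularRecording:
    """Paired left/right gaze trajectories with a guiding-eye tag."""

    left: Trajectory
    right: Trajectory
    guiding: Eye = Eye.RIGHT
    pupil_left: Optional[np.ndarray] = None
    pupil_right: Optional[np.ndarray] = None

    def __post_init__(self):
        if isinstance(self.guiding, str):
            self.guiding = Eye(self.guiding)
        if self.left.rate != self.right.rate:
            raise ValueError("left and right eyes must share the sampling rate")
        if len(self.left) != len(self.right) or not np.allclose(
            self.left.t, self.right.t, atol=_GRID_TOL
        ):
            raise ValueError("left and right eyes must share the time grid")

    @property
    def rate(self) -> float:
        return self.left.rate

    @property
    def guiding_eye(self) -> Trajectory:
        return self.left if self.guiding is Eye.LEFT else self.right

    @property
    def other_eye(self) -> Trajectory:
        return self.right if self.guiding is Eye.LEFT else self.left


@dataclass
class VelocitySeries:
    """Estimated velocity signal in deg/s.

    ``t`` keeps the source time grid; edge samples where the stencil does not
    fit are masked, as are samples whose stencil touches a missing source
    sample.
    """

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    method: VelocityMethod
    window: int
    missing_mask: np.ndarray
    rate: float

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


def _window_offsets(method: VelocityMethod, window: int) -> np.ndarray:
    if method is VelocityMethod.EK5:
        if window != 5:
            raise BadWindowError("ek5 uses a fixed 5-sample stencil")
        return np.array([-2, -1, 0, 1, 2])
    if method is VelocityMethod.CENTRAL:
        if window != 3:
            raise BadWindowError("central difference uses a fixed 3-sample stencil")
        return np.array([-1, 0, 1])
    if method is VelocityMethod.SLOPE6:
        if window < 2:
            raise BadWindowError("regression slope needs >= 2 samples")
        # centered window; for even sizes one extra sample on the right
        left = (window - 1) // 2
        return np.arange(-left, window - left)
    raise BadWindowError(f"unknown method {method!r}")


def estimate_velocity(
    traj: Trajectory,
    method: VelocityMethod | str = VelocityMethod.SLOPE6,
    window: int | None = None,
) -> VelocitySeries:
    """Estimate gaze velocity from positions.

    Parameters
    ----------
    traj : Trajectory
    method : {"ek5", "slope6", "central"}
        ``ek5`` is the 5-point smoothed difference used by the saccade
        detector; ``slope6`` the least-squares slope over a centered
        6-sample window; ``central`` a plain central difference.
    window : int, optional
        Window length in samples.  Fixed at 5 (ek5) and 3 (central);
        defaults to 6 for ``slope6``.

    Returns
    -------
    VelocitySeries
        vx, vy in deg/s with edge (and missing-adjacent) samples masked.
    """
    method = VelocityMethod(method)
    if window is None:
        window = {VelocityMethod.EK5: 5, VelocityMethod.CENTRAL: 3,
                  VelocityMethod.SLOPE6: 6}[method]
    offsets = _window_offsets(method, window)
    n = len(traj)
    if n < len(offsets):
        raise TooShortError(
            f"trajectory has {n} samples, need >= {len(offsets)} for {method.value}"
        )
    dt = 1.0 / traj.rate
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    lo, hi = -offsets[0], n - offsets[-1]  # valid center range [lo, hi)

    idx = np.arange(lo, hi)
    stack_x = np.stack([traj.x[idx + o] for o in offsets])  # (w, m)
    stack_y = np.stack([traj.y[idx + o] for o in offsets])
    stack_miss = np.stack([traj.missing_mask[idx + o] for o in offsets])

    if method is VelocityMethod.EK5:
        vx[idx] = (stack_x[4] + stack_x[3] - stack_x[1] - stack_x[0]) / (6 * dt)
        vy[idx] = (stack_y[4] + stack_y[3] - stack_y[1] - stack_y[0]) / (6 * dt)
    elif method is VelocityMethod.CENTRAL:
        vx[idx] = (stack_x[2] - stack_x[0]) / (2 * dt)
        vy[idx] = (stack_y[2] - stack_y[0]) / (2 * dt)
    else:  # least-squares slope of position vs time over the window
        tau = offsets[:, None] * dt
        tau_c = tau - tau.mean()
        denom = float((tau_c**2).sum())
        vx[idx] = (tau_c * stack_x).sum(axis=0) / denom
        vy[idx] = (tau_c * stack_y).sum(axis=0) / denom

    mask[idx] = stack_miss.any(axis=0)
    return VelocitySeries(
        t=traj.t.copy(), vx=vx, vy=vy, method=method,
        window=len(offsets), missing_mask=mask, rate=traj.rate,
    )


def resample_to(traj: Trajectory, new_rate: float) -> Trajectory:
    """Linearly interpolate onto a uniform grid at ``new_rate``.

    The new grid starts at ``t[0]`` and covers the source span.  A new
    sample is masked if either source sample bracketing it is masked.
    Resampling at the source rate returns a bitwise-equal copy.
    """
    if new_rate > traj.rate:
        raise UpsampleError(
            f"cannot upsample from {traj.rate:g} Hz to {new_rate:g} Hz"
        )
    if new_rate == traj.rate:
        return Trajectory(
            t=traj.t.copy(), x=traj.x.copy(), y=traj.y.copy(),
            rate=traj.rate, missing_mask=traj.missing_mask.copy(),
        )
    n_new = int(np.floor((traj.t[-1] - traj.t[0]) * new_rate)) + 1
    t_new = traj.t[0] + np.arange(n_new) / new_rate
    x_new = np.interp(t_new, traj.t, traj.x)
    y_new = np.interp(t_new, traj.t, traj.y)
    # bracketing source indices for mask propagation
    right = np.searchsorted(traj.t, t_new, side="left")
    right = np.clip(right, 0, len(traj) - 1)
    left = np.clip(right - 1, 0, len(traj) - 1)
    exact = np.abs(traj.t[right] - t_new) < _GRID_TOL
    left = np.where(exact, right, left)
    mask_new = traj.missing_mask[left] | traj.missing_mask[right]
    return Trajectory(t=t_new, x=x_new, y=y_new, rate=new_rate,
                      missing_mask=mask_new)
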