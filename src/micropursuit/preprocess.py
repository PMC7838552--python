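"""Signal conditioning and fixation parsing/screening.

The analysis chain conditions raw binocular gaze as follows: a zero-phase
second-order Butterworth low-pass at 35 Hz (forward-backward, so the
magnitude at the cutoff is the squared -3 dB gain and the phase is exactly
zero — phase lag would bias sample-by-sample gaze-stimulus comparison),
then linear-interpolation downsampling to the 75 Hz stimulus frame grid.
Fixations are parsed with EyeLink-style absolute thresholds (velocity
30 deg/s, acceleration 9500 deg/s^2, minimum saccade displacement
0.15 deg) and screened: epochs of 80 ms or less, epochs containing missing
samples, and epochs whose screen-referenced inertia lies beyond two batch
standard deviations of the mean are removed, in that priority order.

An optional ``pupil_correction`` hook lets users of real recordings attach
their own pupil-deformation correction; the package does not implement one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import signal

from .errors import NyquistViolationError
from .metrics import inertia_screen
from .trajectory import (
    BinocularRecording,
    Trajectory,
    VelocityMethod,
    estimate_velocity,
)


def _interp_masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked samples by linear interpolation (edge-hold)."""
    if not mask.any():
        return values
    out = values.copy()
    idx = np.arange(len(values))
    good = ~mask
    if not good.any():
        return np.zeros_like(values)
    out[mask] = np.interp(idx[mask], idx[good], values[good])
    return out


def lowpass(traj: Trajectory, order: int = 2, fc: float = 35.0) -> Trajectory:
    """Zero-phase Butterworth low-pass filter.

    Masked samples are interpolated before filtering and re-masked after,
    so gaps do not inject transients.
    """
    if fc >= traj.rate / 2:
        raise NyquistViolationError(
            f"cutoff {fc:g} Hz >= Nyquist {traj.rate / 2:g} Hz"
        )
    sos = signal.butter(order, fc, btype="low", fs=traj.rate, output="sos")
    x = _interp_masked(traj.x, traj.missing_mask)
    y = _interp_masked(traj.y, traj.missing_mask)
    xf = signal.sosfiltfilt(sos, x)
    yf = signal.sosfiltfilt(sos, y)
    return Trajectory(t=traj.t.copy(), x=xf, y=yf, rate=traj.rate,
                      missing_mask=traj.missing_mask.copy())


def lowpass_recording(rec: BinocularRecording, order: int = 2,
                      fc: float = 35.0) -> BinocularRecording:
    return BinocularRecording(
        left=lowpass(rec.left, order, fc),
        right=lowpass(rec.right, order, fc),
        guiding=rec.guiding,
        pupil_left=rec.pupil_left,
        pupil_right=rec.pupil_right,
    )


@dataclass
class FixationEpoch:
    """A contiguous fixation with the co-occurring stimulus segment.

    Indices are 0-based and half-open on the working sample grid.
    ``contains_microsaccade`` is filled later by the detector;
    ``gaze_other`` optionally carries the non-guiding eye for binocular
    similarity.
    """

    start_idx: int
    end_idx: int
    gaze: Trajectory
    stimulus: Trajectory
    eye: str = "guiding"
    trial_id: str | int | None = None
    subject: str | int | None = None
    condition: str | None = None
    contains_microsaccade: bool = False
    gaze_other: Optional[Trajectory] = None
    gaze_native: Optional[Trajectory] = None       # pre-downsampling slice
    gaze_other_native: Optional[Trajectory] = None

    @property
    def duration(self) -> float:
        return (self.end_idx - self.start_idx) / self.gaze.rate

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class ScreeningReport:
    """Counts reconciling fixation screening; each epoch is removed for
    exactly one reason, in priority order short > NaN > outlier."""

    n_input: int
    n_short: int
    n_nan: int
    n_outlier: int
    n_kept: int
    min_duration_s: float
    outlier_sd: float

    def __post_init__(self):
        assert self.n_kept == self.n_input - self.n_short - self.n_nan - self.n_outlier


def parse_fixations(
    rec: BinocularRecording,
    stimulus: Trajectory,
    vel_thresh: float = 30.0,
    disp_thresh: float = 0.15,
    acc_thresh: float = 9500.0,
    trial_id=None,
    subject=None,
    condition=None,
    pupil_correction: Callable[[Trajectory], Trajectory] | None = None,
) -> list[FixationEpoch]:
    """Segment a recording into fixations with EyeLink-style thresholds.

    Samples of the guiding eye whose speed or absolute acceleration exceed
    the thresholds mark saccade periods; a saccade run is only honored if
    its net displacement exceeds ``disp_thresh`` (sub-displacement
    excursions stay inside the fixation).  Maximal complementary runs of
    valid samples become fixations, each paired with its stimulus slice.

    ``pupil_correction`` is an optional pass-through hook applied to the
    guiding eye before segmentation (no correction is implemented here).
    """
    guide = rec.guiding_eye
    if pupil_correction is not None:
        guide = pupil_correction(guide)
    if len(stimulus) != len(guide):
        raise ValueError("stimulus must share the recording grid")
    n = len(guide)
    if n < 5 or (~guide.missing_mask).sum() == 0:
        return []
    vel = estimate_velocity(guide, VelocityMethod.EK5)
    speed = np.nan_to_num(vel.speed, nan=0.0)
    acc = np.zeros(n)
    dv = np.gradient(np.nan_to_num(vel.vx, nan=0.0), 1.0 / guide.rate)
    dw = np.gradient(np.nan_to_num(vel.vy, nan=0.0), 1.0 / guide.rate)
    acc = np.hypot(dv, dw)

    saccade = (speed > vel_thresh) | (acc > acc_thresh)
    # drop candidate runs whose net displacement stays under disp_thresh
    for s, e in _runs(saccade):
        a, b = max(s - 1, 0), min(e, n - 1)
        disp = float(np.hypot(guide.x[b] - guide.x[a], guide.y[b] - guide.y[a]))
        if disp <= disp_thresh:
            saccade[s:e] = False

    fixation_ok = ~saccade & ~guide.missing_mask
    out = []
    for s, e in _runs(fixation_ok):
        out.append(
            FixationEpoch(
                start_idx=s,
                end_idx=e,
                gaze=guide.slice(s, e),
                stimulus=stimulus.slice(s, e),
                eye=rec.guiding.value,
                trial_id=trial_id,
                subject=subject,
                condition=condition,
                gaze_other=rec.other_eye.slice(s, e),
            )
        )
    return out


def _runs(mask: np.ndarray):
    """Yield (start, stop) half-open runs of True."""
    m = np.asarray(mask, bool)
    if not m.any():
        return
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    yield from zip(starts, stops)


def screen_fixations(
    fixations: list[FixationEpoch],
    min_dur: float = 0.080,
    outlier_sd: float = 2.0,
) -> tuple[list[FixationEpoch], ScreeningReport]:
    """Screen fixations: duration, missing samples, inertia outliers.

    Epochs with duration <= ``min_dur`` (strict: exactly 80 ms is removed)
    go first, then epochs containing any missing gaze sample, then epochs
    whose screen-referenced inertia is beyond ``mean +/- outlier_sd * SD``
    of the surviving batch (statistics computed once, single pass).
    """
    if not fixations:
        raise ValueError("need at least one fixation")
    n_input = len(fixations)
    long_enough = [f for f in fixations if f.duration > min_dur]
    n_short = n_input - len(long_enough)
    clean = [f for f in long_enough if not f.gaze.missing_mask.any()]
    n_nan = len(long_enough) - len(clean)
    if not clean:
        report = ScreeningReport(n_input, n_short, n_nan, 0, 0, min_dur, outlier_sd)
        return [], report
    iscr = np.array([inertia_screen(f.gaze) for f in clean])
    mu, sd = iscr.mean(), iscr.std()
    keep_mask = np.abs(iscr - mu) <= outlier_sd * sd
    kept = [f for f, k in zip(clean, keep_mask) if k]
    n_outlier = len(clean) - len(kept)
    report = ScreeningReport(
        n_input, n_short, n_nan, n_outlier, len(kept), min_dur, outlier_sd
    )
    return kept, report
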