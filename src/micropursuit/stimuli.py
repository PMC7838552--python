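"""Stimulus motion generators for the three experimental conditions.

Three motion conditions drive the target:

* **FX** — static control, the target sits at the screen center.
* **RW** — unpredictable motion: at every stimulus frame a step of length
  ``rho = G + E`` is taken in a uniformly random direction, where
  ``G ~ Normal(mu=1.1, sd=0.2)`` pixels and ``E`` is an exponential
  component with parameter 0.1 (read as the *scale*, i.e. mean 0.1 pix —
  the rate reading would give an 11-pix mean step inside a 10-pix arena,
  which contradicts the slow-motion regime; both readings are selectable).
  A 10-pix radial limit bounces offending steps back toward the center.
* **LJ** — predictable motion along a Lissajous figure
  ``x = A sin(c*theta*t), y = B sin(d*theta*t + phi)`` with A = B = 14 pix,
  phi = 0, (c, d) drawn from {(2,3), (3,2), (-2,3), (-3,2)} and
  theta = 2*pi*30/(2.21*415) ~= 0.2055 rad/s.

The luminance-report task of the replication designs alternates a target
between five luminance levels for log-normal(mu=1, sd=1) second holds.
Generators emit trajectories in degrees via a named screen preset so that
pixel parameters and degree analyses stay consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import BadRatioError
from .geometry import ScreenGeometry, get_screen
from .trajectory import Trajectory

#: theta from the printed closed form 2*pi*30/(2.21*415) rad/s
THETA_DEFAULT = 2 * math.pi * 30 / (2.21 * 415)
#: the rounded value quoted alongside it
THETA_ROUNDED = 0.2 * 2 * math.pi  # interpret "0.2 Hz" as frequency

LISSAJOUS_RATIOS = ((2, 3), (3, 2), (-2, 3), (-3, 2))
LUMINANCE_LEVELS = (0.30, 0.40, 0.50, 0.60, 0.70)


@dataclass
class RandomWalkParams:
    """Exponential-Gaussian bounded random walk (pixel units)."""

    mu: float = 1.1
    sigma: float = 0.2
    lam: float = 0.1
    radial_limit: float = 10.0
    rate: float = 75.0
    seed: int | None = None
    #: "scale" reads lam as the exponential mean; "rate" as 1/mean
    exp_parameterization: str = "scale"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.radial_limit <= 0:
            raise ValueError("radial_limit must be > 0")
        if self.exp_parameterization not in ("scale", "rate"):
            raise ValueError("exp_parameterization must be 'scale' or 'rate'")

    @property
    def exp_mean(self) -> float:
        if self.lam == 0:
            return 0.0
        return self.lam if self.exp_parameterization == "scale" else 1.0 / self.lam

    @property
    def mean_step(self) -> float:
        """Closed-form mean step length mu + E[E] (pixels)."""
        return self.mu + self.exp_mean


@dataclass
class LissajousParams:
    """Lissajous figure parameters (amplitudes in pixels)."""

    A: float = 14.0
    B: float = 14.0
    theta: float = THETA_DEFAULT
    ratio: tuple[int, int] | None = None
    phi: float = 0.0
    rate: float = 75.0
    seed: int | None = None

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.ratio is not None and tuple(self.ratio) not in LISSAJOUS_RATIOS:
            raise BadRatioError(
                f"ratio {self.ratio} not in allowed set {LISSAJOUS_RATIOS}"
            )


@dataclass
class LuminanceSchedule:
    """Piecewise-constant luminance schedule on [0, duration]."""

    boundaries: np.ndarray  # segment start times, first is 0
    levels: np.ndarray      # fraction of white per segment
    duration: float

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if len(self.boundaries) != len(self.levels):
            raise ValueError("one level per segment")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must increase")
        if np.any(np.diff(self.levels) == 0):
            raise ValueError("adjacent levels must differ")

    @property
    def n_segments(self) -> int:
        return len(self.levels)

    def level_at(self, t: float) -> float:
        i = int(np.searchsorted(self.boundaries, t, side="right")) - 1
        return float(self.levels[max(i, 0)])


def gen_fixed(duration: float, rate: float = 75.0) -> Trajectory:
    """Static control condition: the target stays at the screen center."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * rate))
    z = np.zeros(n)
    return Trajectory.from_xy(z, z, rate=rate)


def gen_random_walk(
    p: RandomWalkParams,
    duration: float,
    screen: ScreenGeometry | str = "necker",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Bounded exponential-Gaussian random walk, returned in degrees.

    Each frame takes a step of length ``G + E`` in a uniformly random
    direction.  A step that would leave the disk of radius
    ``radial_limit`` has its orientation reversed (reflected through the
    center); if the reversed step still exits, the point is clipped
    radially to the boundary.  Every output sample satisfies
    ``||q|| <= radial_limit``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    screen = get_screen(screen)
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    n = int(round(duration * p.rate))
    g = rng.normal(p.mu, p.sigma, size=n - 1)
    if p.exp_mean > 0:
        e = rng.exponential(p.exp_mean, size=n - 1)
    else:
        e = np.zeros(n - 1)
    rho = g + e
    ang = rng.uniform(-math.pi, math.pi, size=n - 1)
    steps = np.column_stack([rho * np.cos(ang), rho * np.sin(ang)])

    pos = np.zeros((n, 2))
    q = np.zeros(2)
    limit2 = p.radial_limit**2
    for i, step in enumerate(steps):
        cand = q + step
        if cand @ cand > limit2:
            cand = q - step  # bounce: reverse orientation
            r2 = cand @ cand
            if r2 > limit2:  # still outside: clip to the boundary
                cand *= p.radial_limit / math.sqrt(r2)
        q = cand
        pos[i + 1] = q
    pos_deg = screen.px_to_deg(pos)
    return Trajectory.from_xy(pos_deg[:, 0], pos_deg[:, 1], rate=p.rate)


def gen_lissajous(
    p: LissajousParams,
    duration: float,
    screen: ScreenGeometry | str = "necker",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Closed-form Lissajous trajectory in degrees.

    If ``p.ratio`` is None the (c, d) pair is drawn uniformly from the
    allowed set using ``p.seed`` (or ``rng``); generation is otherwise
    deterministic.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    screen = get_screen(screen)
    ratio = p.ratio
    if ratio is None:
        rng = rng if rng is not None else np.random.default_rng(p.seed)
        ratio = LISSAJOUS_RATIOS[int(rng.integers(len(LISSAJOUS_RATIOS)))]
    c, d = ratio
    if (c, d) not in LISSAJOUS_RATIOS:
        raise BadRatioError(f"ratio {(c, d)} not in allowed set {LISSAJOUS_RATIOS}")
    n = int(round(duration * p.rate))
    t = np.arange(n) / p.rate
    x = screen.px_to_deg(p.A * np.sin(c * p.theta * t))
    y = screen.px_to_deg(p.B * np.sin(d * p.theta * t + p.phi))
    return Trajectory(t=t, x=x, y=y, rate=p.rate)


def gen_luminance_schedule(
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    levels: Sequence[float] = LUMINANCE_LEVELS,
    mu: float = 1.0,
    sigma: float = 1.0,
) -> LuminanceSchedule:
    """Random luminance schedule for the change-report task.

    Segment durations are i.i.d. log-normal(mu, sigma) seconds; each new
    level is drawn uniformly from the levels different from the current
    one.  The schedule covers [0, duration].
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    levels = list(levels)
    bounds = [0.0]
    seq = [levels[int(rng.integers(len(levels)))]]
    t = float(rng.lognormal(mu, sigma))
    while t < duration:
        bounds.append(t)
        others = [lv for lv in levels if lv != seq[-1]]
        seq.append(others[int(rng.integers(len(others)))])
        t += float(rng.lognormal(mu, sigma))
    return LuminanceSchedule(
        boundaries=np.array(bounds), levels=np.array(seq), duration=duration
    )


#: replication trials have a fixed 34-s duration; variable-duration trials
#: are emulated with a truncated normal matching the printed moments
TRIAL_MEAN_S = 34.00
TRIAL_SD_S = 13.26
TRIAL_MIN_S = 2.0


def gen_trial_durations(
    design: str,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Trial durations in seconds for a given experimental design.

    ``replication`` trials are all 34 s.  ``necker`` trials ended on a
    perception-dependent stopping rule; durations are emulated as a
    truncated normal (mean 34 s, sd 13.26 s, left-truncated at 2 s).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if design == "replication":
        return np.full(n, TRIAL_MEAN_S)
    if design == "necker":
        rng = rng if rng is not None else np.random.default_rng(seed)
        a = (TRIAL_MIN_S - TRIAL_MEAN_S) / TRIAL_SD_S
        return stats.truncnorm.rvs(
            a, np.inf, loc=TRIAL_MEAN_S, scale=TRIAL_SD_S, size=n,
            random_state=rng,
        )
    raise ValueError(f"unknown design {design!r}")


def truncnorm_trial_mean() -> float:
    """Analytic mean of the truncated-normal trial-duration stand-in."""
    a = (TRIAL_MIN_S - TRIAL_MEAN_S) / TRIAL_SD_S
    return float(stats.truncnorm.mean(a, np.inf, loc=TRIAL_MEAN_S, scale=TRIAL_SD_S))
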