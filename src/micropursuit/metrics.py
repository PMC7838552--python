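"""Gaze dispersion (inertia) and gaze-stimulus similarity (MPC).

Two complementary fixation-level metrics:

**Inertia** is the mean squared Euclidean distance of the gaze samples to a
reference,

    I = (1/N) sum_i ||q_G^i - q_O^i||^2   [deg^2],

where the reference q_O is the screen center (``I_screen``, absolute gaze
displacement), the per-sample stimulus center of gravity (``I_stimulus``,
retinal image displacement), or the fixation's own centroid
(``I_fixation``, fixational instability).

**Maximally projected correlation (MPC)** measures similarity between two
bivariate trajectories.  Both signals are projected onto a common direction
w and the projection direction maximizing their Pearson correlation is
sought:

    rho* = max_w  w' S_SG w / sqrt(w' S_SS w * w' S_GG w),

with S_** the 1/N empirical (co)variance blocks.  rho* lies in [-1, 1], is
invariant to scaling and translation of either signal and to a common
rotation of both, and reduces to the univariate Pearson r for collinear
motion.  Because rho(w) = rho(-w), the search runs over half the circle,
w = (cos a, sin a), a in [0, pi).  The maximum is located on a dense angular
grid refined by golden-section search; directions along which either signal
has (numerically) no variance are inadmissible, and when no admissible
direction exists (e.g. a static stimulus) the result is the undefined
marker rather than an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import (
    EmptyEpochError,
    LengthMismatchError,
    TooShortError,
    ZeroStimulusMotionError,
)
from .trajectory import Trajectory, VelocityMethod, estimate_velocity

#: smallest epoch on which MPC is computed (80 ms at 75 Hz -> 7 samples)
MPC_MIN_SAMPLES = 7


class ReferenceMode(str, Enum):
    SCREEN_CENTER = "screen_center"
    STIMULUS_PATH = "stimulus_path"
    FIXATION_CENTROID = "fixation_centroid"
    FIXED_POINT = "fixed_point"


@dataclass
class ReferenceSpec:
    """Reference for inertia: a mode plus, where needed, a point or path."""

    mode: ReferenceMode
    point: Optional[tuple[float, float]] = None
    path: Optional[Trajectory] = None

    def __post_init__(self):
        self.mode = ReferenceMode(self.mode)
        if self.mode is ReferenceMode.FIXED_POINT and self.point is None:
            raise ValueError("fixed_point reference needs a point")
        if self.mode is ReferenceMode.STIMULUS_PATH and self.path is None:
            raise ValueError("stimulus_path reference needs a path")


def inertia(gaze: Trajectory, ref: ReferenceSpec) -> float:
    """Mean squared distance (deg^2) of gaze samples to the reference.

    Masked samples are excluded from both the sum and N; in
    ``stimulus_path`` mode a sample is excluded if masked in either signal.
    """
    valid = ~gaze.missing_mask
    if ref.mode is ReferenceMode.STIMULUS_PATH:
        if len(ref.path) != len(gaze):
            raise LengthMismatchError(
                f"stimulus path has {len(ref.path)} samples, gaze {len(gaze)}"
            )
        valid = valid & ~ref.path.missing_mask
    if not valid.any():
        raise EmptyEpochError("no valid samples in epoch")
    gx, gy = gaze.x[valid], gaze.y[valid]
    if ref.mode is ReferenceMode.SCREEN_CENTER:
        ox, oy = 0.0, 0.0
    elif ref.mode is ReferenceMode.FIXED_POINT:
        ox, oy = ref.point
    elif ref.mode is ReferenceMode.FIXATION_CENTROID:
        ox, oy = gx.mean(), gy.mean()
    else:  # stimulus path, per-sample reference
        ox, oy = ref.path.x[valid], ref.path.y[valid]
    return float(np.mean((gx - ox) ** 2 + (gy - oy) ** 2))


def inertia_screen(gaze: Trajectory) -> float:
    return inertia(gaze, ReferenceSpec(ReferenceMode.SCREEN_CENTER))


def inertia_stimulus(gaze: Trajectory, stimulus: Trajectory) -> float:
    return inertia(gaze, ReferenceSpec(ReferenceMode.STIMULUS_PATH, path=stimulus))


def inertia_fixation(gaze: Trajectory) -> float:
    return inertia(gaze, ReferenceSpec(ReferenceMode.FIXATION_CENTROID))


class MPCMode(str, Enum):
    POSITION = "position"
    VELOCITY = "velocity"


@dataclass
class MPCResult:
    """Signed maximum projected correlation and its direction.

    ``rho_star`` is NaN (``defined`` False) when no admissible projection
    direction exists, e.g. for a motionless stimulus.
    """

    rho_star: float
    angle: float  # argmax direction in [0, pi); NaN when undefined
    n: int
    mode: MPCMode

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho_star)

    @property
    def w_star(self) -> np.ndarray:
        return np.array([math.cos(self.angle), math.sin(self.angle)])


def _cov_blocks(s: np.ndarray, g: np.ndarray):
    """1/N covariance blocks of two (n, 2) signals."""
    sc = s - s.mean(axis=0)
    gc = g - g.mean(axis=0)
    n = len(s)
    return sc.T @ sc / n, gc.T @ gc / n, sc.T @ gc / n


def _form_coeffs(m: np.ndarray) -> tuple[float, float, float]:
    """w'Mw as a + b*cos(2a) + c*sin(2a) for w = (cos a, sin a)."""
    a = 0.5 * (m[0, 0] + m[1, 1])
    b = 0.5 * (m[0, 0] - m[1, 1])
    c = 0.5 * (m[0, 1] + m[1, 0])
    return a, b, c


def _rho_of_angle(alpha, css, cgg, csg, tol_s, tol_g):
    """Vectorized rho(alpha); -inf where a denominator is inadmissible."""
    c2, s2 = np.cos(2 * alpha), np.sin(2 * alpha)
    fss = css[0] + css[1] * c2 + css[2] * s2
    fgg = cgg[0] + cgg[1] * c2 + cgg[2] * s2
    fsg = csg[0] + csg[1] * c2 + csg[2] * s2
    ok = (fss >= tol_s) & (fgg >= tol_g) & (fss > 0) & (fgg > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(ok, fsg / np.sqrt(np.where(ok, fss * fgg, 1.0)), -np.inf)
    return rho, ok


def mpc(
    stim: Trajectory,
    gaze: Trajectory,
    mode: MPCMode | str = MPCMode.POSITION,
    var_tol: float = 1e-7,
    grid: int = 3600,
    use_abs: bool = False,
) -> MPCResult:
    """Maximally projected correlation between stimulus and gaze slices.

    Parameters
    ----------
    stim, gaze : Trajectory
        Equal-length slices (>= 7 samples).  Samples masked in either are
        dropped pairwise.
    mode : {"position", "velocity"}
        In velocity mode both signals are first differentiated with the
        6-sample regression-slope estimator.
    var_tol : float
        A direction is inadmissible when a signal's projected variance falls
        below ``var_tol`` times that signal's total variance (trace); the
        relative threshold preserves scale invariance, and the 1e-7 floor
        keeps the correlation along admissible directions numerically
        reliable to ~1e-9 (rounding error grows as 1/u for a direction
        carrying a fraction u of the variance).
    grid : int
        Number of angles in the initial dense scan of [0, pi).
    use_abs : bool
        Maximize \\|rho\\| instead of signed rho, returning the signed value at
        the \\|rho\\|-maximizing direction.

    Returns
    -------
    MPCResult
        ``rho_star`` in [-1, 1], or NaN when no direction is admissible.
    """
    mode = MPCMode(mode)
    if len(stim) != len(gaze):
        raise LengthMismatchError(
            f"stimulus has {len(stim)} samples, gaze {len(gaze)}"
        )
    if mode is MPCMode.VELOCITY:
        vs = estimate_velocity(stim, VelocityMethod.SLOPE6)
        vg = estimate_velocity(gaze, VelocityMethod.SLOPE6)
        valid = ~(vs.missing_mask | vg.missing_mask)
        s = np.column_stack([vs.vx, vs.vy])[valid]
        g = np.column_stack([vg.vx, vg.vy])[valid]
    else:
        valid = ~(stim.missing_mask | gaze.missing_mask)
        s = stim.positions[valid]
        g = gaze.positions[valid]
    if len(s) < MPC_MIN_SAMPLES:
        raise TooShortError(
            f"MPC needs >= {MPC_MIN_SAMPLES} valid samples, got {len(s)}"
        )

    sss, sgg, ssg = _cov_blocks(s, g)
    css, cgg, csg = _form_coeffs(sss), _form_coeffs(sgg), _form_coeffs(ssg)
    tol_s = var_tol * np.trace(sss)
    tol_g = var_tol * np.trace(sgg)

    alphas = np.arange(grid) * (math.pi / grid)
    rho, ok = _rho_of_angle(alphas, css, cgg, csg, tol_s, tol_g)
    if not ok.any():
        return MPCResult(math.nan, math.nan, len(s), mode)
    score = np.abs(rho) if use_abs else rho
    score = np.where(ok, score, -np.inf)
    i = int(np.argmax(score))

    # golden-section refinement within one grid cell either side
    delta = math.pi / grid

    def f(a):
        r, adm = _rho_of_angle(np.array([a]), css, cgg, csg, tol_s, tol_g)
        if not adm[0]:
            return -np.inf, math.nan
        val = abs(r[0]) if use_abs else r[0]
        return val, r[0]

    lo, hi = alphas[i] - delta, alphas[i] + delta
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, _ = f(c)
    fd, _ = f(d)
    for _ in range(80):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc, _ = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd, _ = f(d)
    best_a = 0.5 * (a + b)
    best_score, best_rho = f(best_a)
    if best_score < score[i]:  # refinement fell into an inadmissible sliver
        best_a, best_rho = alphas[i], rho[i]
    best_a = best_a % math.pi
    return MPCResult(float(np.clip(best_rho, -1.0, 1.0)), float(best_a),
                     len(s), mode)


def mpc_bruteforce(
    stim: Trajectory,
    gaze: Trajectory,
    n_angles: int = 1_000_000,
    mode: MPCMode | str = MPCMode.POSITION,
    var_tol: float = 1e-7,
) -> float:
    """Dense-grid reference value of the signed MPC maximum.

    Evaluates rho on ``n_angles`` uniformly spaced directions with no
    refinement.  Used as an independent oracle in tests.
    """
    mode = MPCMode(mode)
    valid = ~(stim.missing_mask | gaze.missing_mask)
    s = stim.positions[valid]
    g = gaze.positions[valid]
    sss, sgg, ssg = _cov_blocks(s, g)
    css, cgg, csg = _form_coeffs(sss), _form_coeffs(sgg), _form_coeffs(ssg)
    tol_s = var_tol * np.trace(sss)
    tol_g = var_tol * np.trace(sgg)
    alphas = np.arange(n_angles) * (math.pi / n_angles)
    rho, ok = _rho_of_angle(alphas, css, cgg, csg, tol_s, tol_g)
    if not ok.any():
        return math.nan
    return float(np.max(np.where(ok, rho, -np.inf)))


def binocular_similarity(rec, start: int | None = None,
                         stop: int | None = None) -> MPCResult:
    """MPC between the guiding and non-guiding eye over an epoch.

    High values indicate conjugate (centrally planned) movement; erratic
    instrument noise decorrelates the eyes.
    """
    sl = slice(start if start is not None else 0,
               stop if stop is not None else len(rec.left))
    guide = rec.guiding_eye.slice(sl.start, sl.stop)
    other = rec.other_eye.slice(sl.start, sl.stop)
    return mpc(other, guide)


def velocity_gain(stim: Trajectory, gaze: Trajectory) -> float:
    """Classical pursuit gain: mean gaze speed over mean stimulus speed."""
    if len(stim) != len(gaze):
        raise LengthMismatchError("stimulus and gaze slices differ in length")
    vs = estimate_velocity(stim, VelocityMethod.SLOPE6)
    vg = estimate_velocity(gaze, VelocityMethod.SLOPE6)
    valid = ~(vs.missing_mask | vg.missing_mask)
    mean_s = float(np.mean(vs.speed[valid]))
    if mean_s <= 0 or not np.isfinite(mean_s):
        raise ZeroStimulusMotionError("stimulus has no motion; gain undefined")
    return float(np.mean(vg.speed[valid])) / mean_s


def fixation_metrics_table(fixations, exclude_with_microsaccades: bool = True):
    """Per-fixation metric table.

    One row per retained fixation with the three inertia variants,
    position- and velocity-domain MPC, binocular similarity (when the
    epoch carries the other eye), duration, and labels.  Fixations flagged
    as containing micro-saccades are dropped when
    ``exclude_with_microsaccades`` is true.
    """
    import pandas as pd

    rows = []
    for fx in fixations:
        if exclude_with_microsaccades and fx.contains_microsaccade:
            continue
        gaze, stim = fx.gaze, fx.stimulus
        try:
            r_pos = mpc(stim, gaze)
        except TooShortError:
            r_pos = MPCResult(math.nan, math.nan, len(gaze), MPCMode.POSITION)
        try:
            r_vel = mpc(stim, gaze, mode=MPCMode.VELOCITY)
        except TooShortError:
            r_vel = MPCResult(math.nan, math.nan, len(gaze), MPCMode.VELOCITY)
        bino = math.nan
        if getattr(fx, "gaze_other", None) is not None:
            try:
                bino = mpc(fx.gaze_other, gaze).rho_star
            except TooShortError:
                pass
        rows.append(
            {
                "trial_id": fx.trial_id,
                "subject": getattr(fx, "subject", None),
                "condition": getattr(fx, "condition", None),
                "eye": getattr(fx, "eye", None),
                "duration_s": fx.duration,
                "i_screen": inertia_screen(gaze),
                "i_stimulus": inertia_stimulus(gaze, stim),
                "i_fixation": inertia_fixation(gaze),
                "mpc_position": r_pos.rho_star,
                "mpc_velocity": r_vel.rho_star,
                "binocular_similarity": bino,
                "contains_microsaccade": bool(fx.contains_microsaccade),
            }
        )
    return pd.DataFrame(rows)
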