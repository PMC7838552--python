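"""Synthetic binocular gaze from a competing-attractor Langevin model.

Gaze position is modeled as a unit-mass particle in a time-varying
potential generated by perceptual objects acting as gravitational
attractors with softened cores,

    V(q, t) = - sum_i m_i(t) / sqrt(||q - a_i(t)||^2 + eps_i^2),

integrated with the Euler-Maruyama scheme

    dq = v dt,
    dv = (-grad V(q, t) - gamma v) dt + sigma_n dW,

so the velocity receives additive white Gaussian noise (Langevin dynamics)
and gamma damps it.  A fixation instruction is a heavy static attractor at
the screen center; a tracked target is an attractor riding the stimulus
path.  Weighting the two attractor masses moves the model between a
fixation regime (heavy center, weak target — gaze hovers at the center and
similarity with the target stays at the noise baseline) and a pursuit
regime (heavy target — gaze rides the path and similarity is high for
smooth, predictable motion but degraded for jerky random-walk motion,
whose high-frequency content the damped particle cannot follow).

Near an attractor core the potential is locally quadratic with stiffness
k = m / eps^3, so ``mass_for_stiffness`` sets masses via the more intuitive
natural frequency omega_0 = sqrt(k).  Defaults were fixed once by the
calibration script shipped in ``scripts/calibrate_simulator.py``.

Micro-saccades do not emerge from the potential; they are injected
kinematically with a prescribed main-sequence slope so that the detector
can be validated against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .errors import InstabilityError, OverlapError
from .saccades import SaccadeEvent
from .stimuli import (
    LissajousParams,
    RandomWalkParams,
    gen_fixed,
    gen_lissajous,
    gen_random_walk,
    gen_trial_durations,
)
from .trajectory import BinocularRecording, Eye, Trajectory, resample_to


@dataclass
class Attractor:
    """A perceptual object: a (possibly moving) softened point mass."""

    path: Trajectory | tuple[float, float]
    mass: float | np.ndarray = 1.0
    softening: float = 0.3  # deg

    def __post_init__(self):
        if self.softening <= 0:
            raise ValueError("softening must be > 0")
        if np.any(np.asarray(self.mass) < 0):
            raise ValueError("mass must be >= 0")

    def path_at(self, t: np.ndarray) -> np.ndarray:
        """(len(t), 2) attractor position, edge-held linear interpolation."""
        if isinstance(self.path, Trajectory):
            x = np.interp(t, self.path.t, self.path.x)
            y = np.interp(t, self.path.t, self.path.y)
            return np.column_stack([x, y])
        px, py = self.path
        return np.broadcast_to(np.array([px, py], dtype=float), (len(t), 2)).copy()

    def mass_at(self, t: np.ndarray) -> np.ndarray:
        m = np.asarray(self.mass, dtype=float)
        if m.ndim == 0:
            return np.full(len(t), float(m))
        if len(m) != len(t):
            raise ValueError("per-step mass must match the step grid")
        return m


def mass_for_stiffness(omega0: float, softening: float) -> float:
    """Mass giving natural frequency omega0 (rad/s) at a softened core."""
    return omega0**2 * softening**3


@dataclass
class LangevinConfig:
    """Integrator configuration.

    damping : 1/s
        Velocity damping gamma.
    noise_sd : deg s^-3/2
        Intensity of the white velocity noise.
    dt : s
        Integration step (1 ms, matching the 1000 Hz recording rate).
    out_rate : Hz
        Output sampling rate of the returned trajectory.
    escape_radius : deg
        A particle farther than this from the screen center aborts the run.
    overdamped : bool
        Use the first-order limit dq = (F/gamma) dt + (sigma/gamma) dW
        instead of the inertial (second-order) particle.
    """

    damping: float = 14.0
    noise_sd: float = 4.2
    dt: float = 0.001
    seed: int | None = None
    out_rate: float = 1000.0
    escape_radius: float = 20.0
    overdamped: bool = False

    def __post_init__(self):
        if self.damping < 0 or self.noise_sd < 0 or self.dt <= 0:
            raise ValueError("need damping >= 0, noise_sd >= 0, dt > 0")


def _integrate_batch(
    paths: np.ndarray,     # (n_att, n_steps, B, 2)
    masses: np.ndarray,    # (n_att, n_steps)
    eps: np.ndarray,       # (n_att,)
    cfg: LangevinConfig,
    rng: np.random.Generator | None,
    q0: np.ndarray,        # (B, 2)
    v0: np.ndarray,        # (B, 2)
    noise: np.ndarray | None = None,  # (n_steps - 1, B, 2) standard normals
) -> np.ndarray:
    """Euler-Maruyama integration of B independent trials; returns
    positions of shape (n_steps, B, 2)."""
    n_att, n_steps, b, _ = paths.shape
    dt = cfg.dt
    sq = cfg.noise_sd * math.sqrt(dt)
    eps2 = eps**2
    out = np.empty((n_steps, b, 2))
    q = q0.astype(float).copy()
    v = v0.astype(float).copy()
    out[0] = q
    r_esc2 = cfg.escape_radius**2
    if noise is None:
        noise = rng.standard_normal((n_steps - 1, b, 2))
    gamma = cfg.damping
    for s in range(1, n_steps):
        force = np.zeros_like(q)
        for i in range(n_att):
            d = paths[i, s - 1] - q               # (B, 2) toward attractor
            r2 = (d * d).sum(axis=1) + eps2[i]
            force += (masses[i, s - 1] / (r2 * np.sqrt(r2)))[:, None] * d
        if cfg.overdamped:
            q = q + force * (dt / gamma) + (sq / gamma) * noise[s - 1]
        else:
            q = q + v * dt
            v = v + (force - gamma * v) * dt + sq * noise[s - 1]
        out[s] = q
        if np.any((q * q).sum(axis=1) > r_esc2):
            raise InstabilityError(step=s, radius=cfg.escape_radius)
    return out


def simulate_gaze(
    attractors: Sequence[Attractor],
    cfg: LangevinConfig,
    duration: float,
    rng: np.random.Generator | None = None,
    q0: tuple[float, float] | None = None,
    v0: tuple[float, float] = (0.0, 0.0),
) -> Trajectory:
    """Simulate a single gaze trajectory.

    The particle starts at ``q0`` (default: the first attractor's initial
    position) with velocity ``v0`` and is integrated for ``duration``
    seconds at ``cfg.dt``, then resampled to ``cfg.out_rate``.
    """
    if not attractors:
        raise ValueError("need at least one attractor")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_steps = int(round(duration / cfg.dt))
    t = np.arange(n_steps) * cfg.dt
    paths = np.stack([a.path_at(t)[:, None, :] for a in attractors])
    masses = np.stack([a.mass_at(t) for a in attractors])
    eps = np.array([a.softening for a in attractors])
    start = paths[0, 0, 0] if q0 is None else np.asarray(q0, float)
    pos = _integrate_batch(
        paths, masses, eps, cfg, rng,
        q0=start[None, :], v0=np.asarray(v0, float)[None, :],
    )[:, 0, :]
    traj = Trajectory(t=t, x=pos[:, 0], y=pos[:, 1], rate=1.0 / cfg.dt)
    return resample_to(traj, cfg.out_rate)


def make_binocular(
    traj: Trajectory,
    vergence_noise_sd: float = 0.02,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise_cutoff_hz: float = 5.0,
    guiding: Eye | str = Eye.RIGHT,
) -> BinocularRecording:
    """Duplicate a cyclopean trajectory into two eyes with disparity noise.

    Each eye receives independent low-pass Gaussian noise of standard
    deviation ``vergence_noise_sd`` (deg) per axis; zero noise yields
    identical eyes.
    """
    if vergence_noise_sd < 0:
        raise ValueError("vergence_noise_sd must be >= 0")
    if vergence_noise_sd == 0:
        left = traj.slice(0, len(traj))
        right = traj.slice(0, len(traj))
        return BinocularRecording(left=left, right=right, guiding=Eye(guiding))
    rng = rng if rng is not None else np.random.default_rng(seed)
    sos = _signal.butter(2, noise_cutoff_hz, btype="low", fs=traj.rate,
                         output="sos")

    def eye_noise():
        w = rng.standard_normal((len(traj), 2))
        f = _signal.sosfiltfilt(sos, w, axis=0)
        sd = f.std(axis=0)
        sd[sd == 0] = 1.0
        return f / sd * vergence_noise_sd

    nl, nr = eye_noise(), eye_noise()
    left = traj.with_positions(traj.x + nl[:, 0], traj.y + nl[:, 1])
    right = traj.with_positions(traj.x + nr[:, 0], traj.y + nr[:, 1])
    return BinocularRecording(left=left, right=right, guiding=Eye(guiding))


@dataclass
class SaccadeInjectionSpec:
    """Kinematic micro-saccade injection parameters."""

    rate: float = 1.5                       # events per second
    amplitude_range: tuple[float, float] = (0.15, 0.45)  # deg
    main_sequence_slope: float = 60.0       # peak velocity = slope * amplitude
    profile: str = "minimum_jerk"
    center_bias: float = 0.9  # fraction of events aimed back at the start
    corrective_gain_sd: float = 0.1  # relative amplitude jitter of corrections

    def __post_init__(self):
        if self.main_sequence_slope <= 0:
            raise ValueError("slope must be > 0")
        if self.amplitude_range[0] <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.profile not in ("minimum_jerk", "triangular"):
            raise ValueError("profile must be 'minimum_jerk' or 'triangular'")

    @property
    def event_duration(self) -> float:
        """Event duration implied by the main-sequence slope (s)."""
        peak_factor = 1.875 if self.profile == "minimum_jerk" else 2.0
        return peak_factor / self.main_sequence_slope


def _displacement_profile(n: int, profile: str) -> np.ndarray:
    """Unit displacement time course over n samples, from exactly 0 to 1."""
    tau = np.arange(n) / (n - 1)
    if profile == "minimum_jerk":
        return 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return np.where(tau < 0.5, 2 * tau**2, 1 - 2 * (1 - tau) ** 2)


def inject_microsaccades(
    traj: Trajectory,
    spec: SaccadeInjectionSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, list[SaccadeEvent]]:
    """Superimpose ballistic micro-saccades and return ground truth.

    Inter-event gaps are exponential with mean ``1/rate``; each event is a
    ballistic displacement of the drawn amplitude whose peak velocity is
    ``slope * amplitude``.  Event directions are biased back toward the
    accumulated injected offset (corrective behavior) so the gaze stays in
    the fixational range.  Raises :class:`OverlapError` when the requested
    rate cannot fit non-overlapping events.
    """
    if spec.rate < 0:
        raise ValueError("rate must be >= 0")
    if spec.rate == 0:
        return traj.slice(0, len(traj)), []
    dur_ev = spec.event_duration
    if spec.rate * dur_ev > 0.8:
        raise OverlapError(
            f"rate {spec.rate:g} Hz with {dur_ev * 1e3:.0f} ms events cannot "
            "be honored without overlap"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(traj)
    n_ev = max(int(round(dur_ev * traj.rate)), 2)
    offset = np.zeros((n, 2))
    events: list[SaccadeEvent] = []
    cum = np.zeros(2)  # accumulated injected displacement
    t = float(rng.exponential(1.0 / spec.rate))
    prof = _displacement_profile(n_ev, spec.profile)
    while True:
        i0 = int(round(t * traj.rate))
        if i0 + n_ev >= n:
            break
        if np.linalg.norm(cum) > 1e-12 and rng.random() < spec.center_bias:
            # corrective event: aim at the accumulated offset and match its
            # size (clipped to the admissible range) so offsets reset quickly
            ang = math.atan2(-cum[1], -cum[0]) + rng.normal(0, 0.15)
            a = float(
                np.clip(
                    np.linalg.norm(cum)
                    * (1.0 + rng.normal(0, spec.corrective_gain_sd)),
                    *spec.amplitude_range,
                )
            )
        else:
            ang = float(rng.uniform(-math.pi, math.pi))
            a = float(rng.uniform(*spec.amplitude_range))
        u = np.array([math.cos(ang), math.sin(ang)])
        offset[i0:i0 + n_ev] += a * prof[:, None] * u
        offset[i0 + n_ev:] += a * u
        cum += a * u
        events.append(
            SaccadeEvent(
                onset_idx=i0,
                offset_idx=i0 + n_ev,
                onset_t=float(traj.t[i0]),
                offset_t=float(traj.t[i0 + n_ev]),
                amplitude=a,
                peak_velocity=spec.main_sequence_slope * a,
            )
        )
        gap = float(rng.exponential(1.0 / spec.rate))
        t = t + dur_ev + max(gap, 2.0 / traj.rate)
    out = traj.with_positions(traj.x + offset[:, 0], traj.y + offset[:, 1])
    return out, events


# ---------------------------------------------------------------------------
# Experiment-scale synthesis


@dataclass
class DesignConfig:
    """Attractor weighting and trial plan for a synthetic cohort design."""

    name: str
    target_omega0: float      # rad/s stiffness of the moving-target attractor
    center_omega0: float      # rad/s stiffness of the static center attractor
    durations: str            # "necker" or "replication"
    screen: str


#: calibrated designs: necker/cross weight the moving target heavily,
#: square weights the static center heavily with a weak moving attractor
DESIGNS = {
    "necker_like": DesignConfig("necker_like", target_omega0=10.0,
                                center_omega0=1.0, durations="necker",
                                screen="necker"),
    "cross_like": DesignConfig("cross_like", target_omega0=10.0,
                               center_omega0=1.0, durations="replication",
                               screen="replication"),
    "square_like": DesignConfig("square_like", target_omega0=0.3,
                                center_omega0=12.0, durations="replication",
                                screen="replication"),
}

CONDITIONS = ("FX", "RW", "LJ")


@dataclass
class SyntheticTrial:
    subject: int
    trial: int
    condition: str
    stimulus: Trajectory          # 75 Hz frame grid
    recording: BinocularRecording  # 1000 Hz
    injected_events: list[SaccadeEvent]
    seed: int


@dataclass
class SyntheticExperiment:
    design: str
    trials: list[SyntheticTrial]
    seed: int
    cfg: LangevinConfig
    injection: SaccadeInjectionSpec

    @property
    def n_subjects(self) -> int:
        return len({t.subject for t in self.trials})


def _stimulus_for(condition: str, duration: float, screen: str,
                  rng: np.random.Generator) -> Trajectory:
    if condition == "FX":
        return gen_fixed(duration, rate=75.0)
    if condition == "RW":
        return gen_random_walk(RandomWalkParams(), duration, screen=screen, rng=rng)
    if condition == "LJ":
        return gen_lissajous(LissajousParams(), duration, screen=screen, rng=rng)
    raise ValueError(f"unknown condition {condition!r}")


def synth_experiment(
    design: str,
    n_subjects: int,
    n_trials: int,
    seed: int | None = None,
    cfg: LangevinConfig | None = None,
    injection: SaccadeInjectionSpec | None = None,
    duration: float | None = None,
    softening: float = 0.3,
    vergence_noise_sd: float = 0.02,
    subject_noise_cv: float = 0.3,
    subject_rate_range: tuple[float, float] = (1.5, 2.5),
) -> SyntheticExperiment:
    """Generate a full synthetic cohort: subjects x trials x conditions.

    Every (subject, trial) yields one trial per motion condition with its
    stimulus trajectory, 1000 Hz binocular gaze (injected micro-saccade
    ground truth attached), and labels.  Subjects are idiosyncratic: each
    draws a log-normal multiplier (coefficient of variation
    ``subject_noise_cv``) on the Langevin noise intensity and a
    micro-saccade rate uniform in ``subject_rate_range``.  Identical seeds
    reproduce the dataset bitwise.
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError("n_subjects and n_trials must be >= 1")
    dcfg = DESIGNS[design]
    cfg = cfg or LangevinConfig()
    injection = injection or SaccadeInjectionSpec()
    root = np.random.SeedSequence(seed)
    m_target = mass_for_stiffness(dcfg.target_omega0, softening)
    m_center = mass_for_stiffness(dcfg.center_omega0, softening)

    # stage every trial first (stimulus + per-trial RNG state), then push
    # equal-duration groups through the integrator in batches
    staged = []  # (subj, trial, cond, dur, stim, rng, seed, noise_mult, inj)
    for subj in range(n_subjects):
        subj_rng = np.random.default_rng(root.spawn(1)[0])
        sigma = math.sqrt(math.log(1.0 + subject_noise_cv**2))
        noise_mult = float(subj_rng.lognormal(-(sigma**2) / 2, sigma))
        subj_inj = replace(
            injection, rate=float(subj_rng.uniform(*subject_rate_range))
        ) if injection.rate > 0 else injection
        for k in range(n_trials):
            dur_ss, *cond_ss = root.spawn(1 + len(CONDITIONS))
            if duration is not None:
                dur = duration
            else:
                dur = float(
                    gen_trial_durations(
                        dcfg.durations, 1,
                        rng=np.random.default_rng(dur_ss),
                    )[0]
                )
            for cond, ss in zip(CONDITIONS, cond_ss):
                rng = np.random.default_rng(ss)
                stim = _stimulus_for(cond, dur, dcfg.screen, rng)
                staged.append(
                    (subj, k, cond, dur, stim, rng,
                     int(ss.generate_state(1)[0] % (2**31)),
                     noise_mult, subj_inj)
                )

    trials: list[SyntheticTrial] = []
    by_steps: dict[int, list] = {}
    for entry in staged:
        n_steps = int(round(entry[3] / cfg.dt))
        by_steps.setdefault(n_steps, []).append(entry)

    max_batch = 48  # memory cap: (2, n_steps, B, 2) path arrays
    for n_steps, entries in by_steps.items():
        t_grid = np.arange(n_steps) * cfg.dt
        for i in range(0, len(entries), max_batch):
            chunk = entries[i:i + max_batch]
            b = len(chunk)
            paths = np.empty((2, n_steps, b, 2))
            noise = np.empty((n_steps - 1, b, 2))
            for j, entry in enumerate(chunk):
                stim, rng, mult = entry[4], entry[5], entry[7]
                target = Attractor(path=stim, mass=m_target,
                                   softening=softening)
                paths[0, :, j, :] = target.path_at(t_grid)
                paths[1, :, j, :] = 0.0
                noise[:, j, :] = mult * rng.standard_normal((n_steps - 1, 2))
            masses = np.broadcast_to(
                np.array([m_target, m_center])[:, None], (2, n_steps)
            )
            eps = np.array([softening, softening])
            pos = _integrate_batch(
                paths, masses, eps, cfg, None,
                q0=np.zeros((b, 2)), v0=np.zeros((b, 2)), noise=noise,
            )
            for j, (subj, k, cond, dur, stim, rng, tseed, _, inj) in enumerate(
                chunk
            ):
                traj = Trajectory(
                    t=t_grid, x=pos[:, j, 0], y=pos[:, j, 1], rate=1.0 / cfg.dt
                )
                gaze = resample_to(traj, cfg.out_rate)
                gaze, events = inject_microsaccades(gaze, inj, rng=rng)
                rec = make_binocular(gaze, vergence_noise_sd, rng=rng)
                trials.append(
                    SyntheticTrial(
                        subject=subj, trial=k, condition=cond,
                        stimulus=stim, recording=rec,
                        injected_events=events, seed=tseed,
                    )
                )
    trials.sort(key=lambda tr: (tr.subject, tr.trial,
                                CONDITIONS.index(tr.condition)))
    return SyntheticExperiment(design=design, trials=trials,
                               seed=seed if seed is not None else -1,
                               cfg=cfg, injection=injection)
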