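"""Readers/writers for gaze, stimulus, event and result tables, plus a
minimal EyeLink-ASC subset reader and the run configuration.

Canonical on-disk formats are delimited text.  The gaze schema has one
file per trial with header ``time_s, eye, x_deg, y_deg, pupil, valid``
(pupil optional, ``eye`` in {L, R}, ``valid`` 0/1); stimulus files carry
``time_s, x_deg, y_deg``.  A sidecar manifest table records subject,
trial, condition, experiment, screen preset and rate.  All interval
columns are 0-based half-open sample indices; human-facing columns are in
seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, UnsupportedDialectError
from .geometry import get_screen
from .saccades import SaccadeEvent
from .trajectory import BinocularRecording, Eye, Trajectory

GAZE_COLUMNS = ["time_s", "eye", "x_deg", "y_deg", "pupil", "valid"]


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        raise SchemaError("cannot infer rate from fewer than 2 samples")
    dt = np.median(np.diff(t))
    return float(round(1.0 / dt, 6))


def _eye_trajectory(df: pd.DataFrame, rate: float | None) -> Trajectory:
    t = df["time_s"].to_numpy(float)
    x = df["x_deg"].to_numpy(float)
    y = df["y_deg"].to_numpy(float)
    valid = df["valid"].to_numpy(int).astype(bool) if "valid" in df else np.ones(len(df), bool)
    mask = ~valid | ~np.isfinite(x) | ~np.isfinite(y)
    x = np.where(mask, 0.0, x)
    y = np.where(mask, 0.0, y)
    return Trajectory(t=t, x=x, y=y, rate=rate or _infer_rate(t), missing_mask=mask)


def read_gaze_csv(
    path, rate: float | None = None, guiding: str = "right"
) -> BinocularRecording:
    """Read a per-trial gaze CSV into a binocular recording.

    Samples with ``valid == 0`` or non-finite coordinates are masked.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = {"time_s", "eye", "x_deg", "y_deg"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}", line=1)
    eyes = {}
    for label, sub in df.groupby("eye"):
        if label not in ("L", "R"):
            row = int(df.index[df["eye"] == label][0]) + 2
            raise SchemaError(f"eye must be 'L' or 'R', got {label!r}", line=row)
        eyes[label] = _eye_trajectory(sub.reset_index(drop=True), rate)
    if "L" in eyes and "R" in eyes:
        return BinocularRecording(left=eyes["L"], right=eyes["R"],
                                  guiding=Eye(guiding))
    only = next(iter(eyes.values()))
    return BinocularRecording(left=only, right=only, guiding=Eye(guiding))


def write_gaze_csv(path, rec: BinocularRecording, float_fmt: str = "%.12g"):
    """Write a binocular recording in the canonical gaze schema."""
    frames = []
    for label, traj, pupil in (
        ("L", rec.left, rec.pupil_left),
        ("R", rec.right, rec.pupil_right),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": traj.t,
                    "eye": label,
                    "x_deg": traj.x,
                    "y_deg": traj.y,
                    "pupil": pupil if pupil is not None else np.nan,
                    "valid": (~traj.missing_mask).astype(int),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=float_fmt)


def read_stimulus_csv(path, rate: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    missing = {"time_s", "x_deg", "y_deg"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}", line=1)
    t = df["time_s"].to_numpy(float)
    return Trajectory(
        t=t, x=df["x_deg"].to_numpy(float), y=df["y_deg"].to_numpy(float),
        rate=rate or _infer_rate(t),
    )


def write_stimulus_csv(path, traj: Trajectory, float_fmt: str = "%.12g"):
    pd.DataFrame({"time_s": traj.t, "x_deg": traj.x, "y_deg": traj.y}).to_csv(
        path, index=False, float_format=float_fmt
    )


def events_to_frame(events: list[SaccadeEvent], trial_id=None) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trial_id": ev.trial_id if ev.trial_id is not None else trial_id,
                "eye": ev.eye,
                "onset_s": ev.onset_t,
                "offset_s": ev.offset_t,
                "amplitude_deg": ev.amplitude,
                "peak_vel_deg_s": ev.peak_velocity,
                "binocular": ev.binocular,
            }
            for ev in events
        ]
    )


# ---------------------------------------------------------------------------
# EyeLink ASC subset


def read_asc_subset(path, screen="necker", rate: float | None = None):
    """Parse a minimal EyeLink ASC dialect (binocular samples + events).

    Sample lines are ``<time> <xl> <yl> <pl> <xr> <yr> <pr> ...`` in
    tracker pixels (origin top-left, y down); monocular files
    (``<time> <x> <y> <p>``) are accepted with a duplicated eye.  ``EFIX``
    lines are parsed into (start_s, end_s) tracker fixations that may
    replace threshold-based parsing.  Coordinates are converted to
    screen-centered degrees via the screen preset.

    Returns ``(BinocularRecording, fixations, raw_events)`` where
    fixations is a list of (eye, start_s, end_s) and raw_events keeps the
    SSACC/ESACC lines.
    """
    scr = get_screen(screen)
    cx, cy = scr.width_px / 2.0, scr.height_px / 2.0
    times, lx, ly, lp, rx, ry, rp = [], [], [], [], [], [], []
    fixations, raw_events = [], []
    monocular = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", ";", "**")):
                continue
            tok = s.split()
            if tok[0] in ("EFIX", "SSACC", "ESACC", "SFIX", "EBLINK", "SBLINK"):
                if tok[0] == "EFIX":
                    try:
                        fixations.append(
                            (tok[1], float(tok[2]) / 1000.0, float(tok[3]) / 1000.0)
                        )
                    except (IndexError, ValueError):
                        raise SchemaError("malformed EFIX event", line=lineno)
                else:
                    raw_events.append(s)
                continue
            if tok[0] in ("MSG", "START", "END", "SAMPLES", "EVENTS", "INPUT"):
                continue
            # sample line: first token is a timestamp
            try:
                ts = float(tok[0])
            except ValueError:
                raise SchemaError(f"unrecognized line {s[:40]!r}", line=lineno)
            vals = []
            for v in tok[1:7]:
                try:
                    vals.append(float(v))
                except ValueError:
                    vals.append(np.nan)  # EyeLink prints '.' for missing
            if len(vals) >= 6:
                monocular = False if monocular is None else monocular
                if monocular:
                    raise SchemaError("mixed sample dialects", line=lineno)
                times.append(ts / 1000.0)
                lx.append(vals[0]); ly.append(vals[1]); lp.append(vals[2])
                rx.append(vals[3]); ry.append(vals[4]); rp.append(vals[5])
            elif len(vals) >= 3:
                monocular = True if monocular is None else monocular
                if monocular is False:
                    raise SchemaError("mixed sample dialects", line=lineno)
                times.append(ts / 1000.0)
                lx.append(vals[0]); ly.append(vals[1]); lp.append(vals[2])
            else:
                raise SchemaError(f"sample line has too few fields", line=lineno)
    if not times:
        raise UnsupportedDialectError(f"{path}: no sample lines found")

    def to_traj(xs, ys):
        xs = np.asarray(xs, float)
        ys = np.asarray(ys, float)
        mask = ~np.isfinite(xs) | ~np.isfinite(ys)
        xdeg = scr.px_to_deg(np.where(mask, cx, xs) - cx)
        ydeg = -scr.px_to_deg(np.where(mask, cy, ys) - cy)  # tracker y is down
        t = np.asarray(times, float)
        return Trajectory(t=t, x=xdeg, y=ydeg, rate=rate or _infer_rate(t),
                          missing_mask=mask)

    left = to_traj(lx, ly)
    right = left if monocular else to_traj(rx, ry)
    rec = BinocularRecording(
        left=left, right=right, guiding=Eye.RIGHT,
        pupil_left=np.asarray(lp, float),
        pupil_right=None if monocular else np.asarray(rp, float),
    )
    return rec, fixations, raw_events


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All pipeline parameters plus a master seed and per-stage sub-seeds.

    Round-trips losslessly through YAML; every stochastic stage receives an
    explicit seed derived from the master seed unless overridden.
    """

    seed: int = 0
    design: str = "cross_like"
    n_subjects: int = 9
    n_trials: int = 15
    screen: str = "replication"
    filter_fc: float = 35.0
    filter_order: int = 2
    analysis_rate: float = 75.0
    min_fix_duration_s: float = 0.080
    outlier_sd: float = 2.0
    detector_lambda: float = 6.0
    detector_min_duration: int = 3
    mpc_var_tol: float = 1e-10
    n_perm: int = 10_000
    stage_seeds: dict = field(default_factory=dict)

    def seed_for(self, stage: str) -> int:
        if stage in self.stage_seeds:
            return int(self.stage_seeds[stage])
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
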