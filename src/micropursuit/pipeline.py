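"""End-to-end analysis chain: raw binocular gaze to group statistics.

Per trial: zero-phase 35 Hz low-pass on both eyes, downsampling to the
75 Hz stimulus frame grid, EyeLink-style fixation parsing on the guiding
eye, micro-saccade flagging on the native-rate signal with the binocular
relative-threshold detector, then screening (duration > 80 ms, no missing
samples, screen-inertia within 2 batch SD per condition).  The retained
fixations feed the metric table (inertia variants, position/velocity MPC,
binocular similarity) and the Monte-Carlo statistics battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateNoiseError, MicropursuitError
from .metrics import fixation_metrics_table
from .preprocess import (
    FixationEpoch,
    ScreeningReport,
    lowpass_recording,
    parse_fixations,
    screen_fixations,
)
from .saccades import DetectorParams, detect_binocular
from .stats import (
    DEFAULT_N_PERM,
    SubjectConditionMatrix,
    TestResult,
    friedman_mc,
    individual_analysis,
    pairwise_battery,
)
from .trajectory import BinocularRecording, Trajectory, resample_to


@dataclass
class PipelineConfig:
    filter_order: int = 2
    filter_fc: float = 35.0
    analysis_rate: float = 75.0
    min_fix_duration: float = 0.080
    outlier_sd: float = 2.0
    detector: DetectorParams = field(default_factory=DetectorParams)
    detect_on_native: bool = True


def analyze_trial(
    rec: BinocularRecording,
    stimulus: Trajectory,
    cfg: PipelineConfig | None = None,
    trial_id=None,
    subject=None,
    condition=None,
) -> list[FixationEpoch]:
    """Condition one trial and return its micro-saccade-flagged fixations.

    ``stimulus`` is expected on the analysis (frame) grid; the recording
    may be at any rate at or above it.
    """
    cfg = cfg or PipelineConfig()
    filtered = lowpass_recording(rec, cfg.filter_order, cfg.filter_fc)
    if rec.rate > cfg.analysis_rate:
        left = resample_to(filtered.left, cfg.analysis_rate)
        right = resample_to(filtered.right, cfg.analysis_rate)
        rec75 = BinocularRecording(left=left, right=right, guiding=rec.guiding)
    else:
        rec75 = filtered
    n = min(len(rec75.left), len(stimulus))
    rec75 = BinocularRecording(
        left=rec75.left.slice(0, n), right=rec75.right.slice(0, n),
        guiding=rec75.guiding,
    )
    stim = stimulus.slice(0, n)

    fixations = parse_fixations(
        rec75, stim, trial_id=trial_id, subject=subject, condition=condition
    )
    native = filtered if cfg.detect_on_native else rec75
    for fx in fixations:
        t0 = fx.gaze.t[0]
        t1 = fx.gaze.t[-1]
        i0 = int(np.searchsorted(native.left.t, t0 - 1e-9))
        i1 = int(np.searchsorted(native.left.t, t1 + 1e-9))
        fx.gaze_native = native.guiding_eye.slice(i0, i1)
        fx.gaze_other_native = native.other_eye.slice(i0, i1)
        try:
            events = detect_binocular(
                fx.gaze_native if native.guiding.value == "left"
                else fx.gaze_other_native,
                fx.gaze_other_native if native.guiding.value == "left"
                else fx.gaze_native,
                cfg.detector,
                guiding=native.guiding.value,
                trial_id=trial_id,
            )
        except (DegenerateNoiseError, MicropursuitError):
            events = []
        fx.contains_microsaccade = len(events) > 0
    return fixations


def analyze_experiment(
    experiment,
    cfg: PipelineConfig | None = None,
    exclude_with_microsaccades: bool = False,
) -> tuple[pd.DataFrame, dict[str, ScreeningReport]]:
    """Run the full chain over a synthetic (or loaded) experiment.

    Fixation screening is applied per condition.  Returns the per-fixation
    metric table and the per-condition screening reports.
    """
    cfg = cfg or PipelineConfig()
    by_condition: dict[str, list[FixationEpoch]] = {}
    for tr in experiment.trials:
        fixes = analyze_trial(
            tr.recording, tr.stimulus, cfg,
            trial_id=f"s{tr.subject}_t{tr.trial}_{tr.condition}",
            subject=tr.subject, condition=tr.condition,
        )
        by_condition.setdefault(tr.condition, []).extend(fixes)
    kept: list[FixationEpoch] = []
    reports: dict[str, ScreeningReport] = {}
    for cond, fixes in by_condition.items():
        good, rep = screen_fixations(fixes, cfg.min_fix_duration, cfg.outlier_sd)
        kept.extend(good)
        reports[cond] = rep
    table = fixation_metrics_table(
        kept, exclude_with_microsaccades=exclude_with_microsaccades
    )
    return table, reports


@dataclass
class GroupAnalysis:
    """Bundled group- and subject-level results for one metric."""

    metric: str
    matrix: SubjectConditionMatrix
    omnibus: TestResult
    pairwise: list[TestResult]
    individual: pd.DataFrame


def group_analysis(
    table: pd.DataFrame,
    metric: str,
    conditions=("FX", "RW", "LJ"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
) -> GroupAnalysis:
    """Group contrast of per-subject medians plus per-subject tests.

    MPC metrics are undefined under the static condition, so they are
    contrasted over the two motion conditions only (the chi-square is still
    the Friedman statistic, so Kendall W applies for k = 2 as well).
    """
    is_mpc = metric.startswith("mpc") or metric.startswith("binocular")
    conds = tuple(c for c in conditions if not (is_mpc and c == "FX"))
    m = SubjectConditionMatrix.from_table(table, metric, conds)
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    omni = friedman_mc(m, n_perm=n_perm, seed=s1)
    pw = pairwise_battery(m, alpha=alpha, n_perm=n_perm, seed=s2)
    indiv = individual_analysis(
        table.dropna(subset=[metric]), metric, conditions=conds,
        n_perm=n_perm, seed=s3, alpha=alpha,
    )
    return GroupAnalysis(metric=metric, matrix=m, omnibus=omni,
                         pairwise=pw, individual=indiv)


def summary_table(
    table: pd.DataFrame,
    metrics=("i_stimulus", "i_fixation", "mpc_position"),
    conditions=("FX", "RW", "LJ"),
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> pd.DataFrame:
    """Condition medians +/- MAD with the omnibus test per metric.

    MPC under the static condition is reported as the undefined marker
    ("n/a"), mirroring its zero-variance degeneracy.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for metric, child in zip(metrics, ss.spawn(len(metrics))):
        ga = group_analysis(
            table, metric, conditions, n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        row = {"metric": metric}
        is_mpc = metric.startswith("mpc") or metric.startswith("binocular")
        for cond in conditions:
            vals = table.loc[table["condition"] == cond, metric].dropna()
            if is_mpc and cond == "FX":
                row[cond] = "n/a"
            else:
                med = float(vals.median())
                mad = float((vals - med).abs().median())
                row[cond] = f"{med:.3f}+/-{mad:.3f}"
        row["chi2"] = ga.omnibus.statistic
        row["p_mc"] = ga.omnibus.p_mc
        row["W"] = ga.omnibus.effect_size_w
        rows.append(row)
    return pd.DataFrame(rows)
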