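"""From raw binocular gaze to the per-fixation metric table.

Runs the standard conditioning chain (zero-phase 35 Hz Butterworth,
downsampling to 75 Hz, fixation parsing, binocular micro-saccade flagging,
screening) on a small synthetic cohort and prints the per-condition medians
of the fixation metrics: the three inertia variants (deg^2), position- and
velocity-domain MPC, and guiding-vs-other-eye similarity.
"""

from micropursuit import synth_experiment
from micropursuit.pipeline import analyze_experiment

exp = synth_experiment("cross_like", n_subjects=2, n_trials=3, seed=5)
table, reports = analyze_experiment(exp)

for cond, rep in sorted(reports.items()):
    print(f"{cond}: kept {rep.n_kept}/{rep.n_input} fixations "
          f"(short {rep.n_short}, missing {rep.n_nan}, "
          f"outliers {rep.n_outlier})")

cols = ["i_screen", "i_stimulus", "i_fixation", "mpc_position",
        "binocular_similarity"]
print()
print(table.groupby("condition")[cols].median().round(3))

# Under explicit tracking, LJ fixations show high gaze-stimulus MPC and
# elevated I_fixation (the gaze travels with the target), while I_stimulus
# stays comparable between the two motion conditions. MPC is undefined
# (NaN) for the motionless FX stimulus.
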