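"""Generate the three stimulus motion conditions and summarize them.

Builds a static target (FX), a bounded exponential-Gaussian random walk
(RW) and a Lissajous figure (LJ) at the 75 Hz frame rate, then prints each
trajectory's screen-referenced inertia (mean squared distance to the
screen center, deg^2) — the dispersion budget each condition imposes.
"""

import numpy as np

from micropursuit import (
    LissajousParams,
    RandomWalkParams,
    gen_fixed,
    gen_lissajous,
    gen_random_walk,
    inertia_screen,
)

duration = 34.0  # one trial

fx = gen_fixed(duration)
rw = gen_random_walk(RandomWalkParams(seed=1), duration)
lj = gen_lissajous(LissajousParams(ratio=(2, 3)), duration)

for name, traj in [("FX", fx), ("RW", rw), ("LJ", lj)]:
    r_max = np.hypot(traj.x, traj.y).max()
    print(
        f"{name}: {len(traj)} samples @ {traj.rate:g} Hz, "
        f"max eccentricity {r_max:.3f} deg, "
        f"I_screen = {inertia_screen(traj):.4f} deg^2"
    )

# The random walk never leaves its 10-pixel arena; the Lissajous figure's
# long-run I_screen approaches A^2 (with A = 14 pix ~ 0.55 deg).
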