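"""Simulate gaze with the attractor-Langevin model and measure tracking.

A heavy attractor riding a Lissajous path produces micro-pursuit: the gaze
particle follows the sub-degree target motion. The maximally projected
correlation (MPC) between stimulus and gaze quantifies the similarity;
values near 1 mean the gaze trajectory mirrors the target's.
"""

from micropursuit import (
    Attractor,
    LangevinConfig,
    LissajousParams,
    RandomWalkParams,
    gen_lissajous,
    gen_random_walk,
    mass_for_stiffness,
    mpc,
    resample_to,
    simulate_gaze,
)
from micropursuit.preprocess import lowpass

duration = 30.0
cfg = LangevinConfig(seed=7)

for name, stim in [
    ("LJ (predictable)", gen_lissajous(LissajousParams(ratio=(2, 3)), duration)),
    ("RW (unpredictable)", gen_random_walk(RandomWalkParams(seed=3), duration)),
]:
    target = Attractor(path=stim, mass=mass_for_stiffness(10.0, 0.3))
    center = Attractor(path=(0.0, 0.0), mass=mass_for_stiffness(1.0, 0.3))
    gaze = simulate_gaze([target, center], cfg, duration, q0=(0.0, 0.0))
    gaze75 = resample_to(lowpass(gaze), 75.0)
    n = min(len(gaze75), len(stim))
    r = mpc(stim.slice(0, n), gaze75.slice(0, n))
    print(f"{name}: MPC rho* = {r.rho_star:.3f} "
          f"(projection direction {r.angle:.2f} rad)")

# Smooth, predictable motion is tracked almost perfectly (rho* ~ 0.95);
# the jerky random walk is only partially followed (rho* ~ 0.5-0.7):
# the damped particle cannot reproduce its high-frequency content.
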