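# micropursuit

Analysis of **micro-pursuit** fixational eye movements: slow, sub-degree
gaze movements that track a smooth, predictable target trajectory during
fixation. The package provides the complete stack needed to detect and
characterize them in binocular eye-tracking data — and to exercise every
stage on fully synthetic, ground-truthed recordings.

It is aimed at visual-neuroscience and oculomotor-control researchers who
record binocular gaze at ~1000 Hz while presenting small moving targets
and want fixation-level dispersion and similarity metrics with
distribution-free statistics.

## The two core metrics

**Inertia** quantifies gaze dispersion over a fixation as the mean squared
distance to a reference (deg²):

    I = (1/N) Σᵢ ‖q_G^i − q_O^i‖²

with the reference q_O being the screen center (`I_screen`), the
per-sample stimulus center of gravity (`I_stimulus`, retinal image
displacement), or the fixation centroid (`I_fixation`).

**Maximally projected correlation (MPC)** measures similarity between two
bivariate trajectories: both are projected onto a common direction **w**
and the direction maximizing their correlation is sought,

    ρ* = max_w  wᵀΣ_SG w / √(wᵀΣ_SS w · wᵀΣ_GG w) ∈ [−1, 1],

which is invariant to scaling and translation of either signal, to common
rotations, and reduces to Pearson's r for collinear motion. ρ* near 1 over
a fixation, at drift-scale velocities, is the micro-pursuit signature.

Around these sit: stimulus generators (static control, bounded
exponential-Gaussian random walk, Lissajous figures), an attractor-based
Langevin gaze simulator with injected micro-saccades, preprocessing
(zero-phase 35 Hz Butterworth, 75 Hz downsampling, EyeLink-style fixation
parsing, screening), relative-threshold binocular micro-saccade detection
with main-sequence fits, and a Monte-Carlo nonparametric test battery
(permutation Friedman / Wilcoxon / Kruskal–Wallis / Mann–Whitney) with
Kendall *W* = χ²/(N(k−1)) effect sizes.

## Worked example

Simulate a pursuing gaze and measure its similarity to predictable vs
unpredictable motion (`examples/02_simulate_and_track.py`):

```python
from micropursuit import (Attractor, LangevinConfig, LissajousParams,
                          RandomWalkParams, gen_lissajous, gen_random_walk,
                          mass_for_stiffness, mpc, resample_to, simulate_gaze)
from micropursuit.preprocess import lowpass

cfg = LangevinConfig(seed=7)
for name, stim in [("LJ", gen_lissajous(LissajousParams(ratio=(2, 3)), 30.0)),
                   ("RW", gen_random_walk(RandomWalkParams(seed=3), 30.0))]:
    target = Attractor(path=stim, mass=mass_for_stiffness(10.0, 0.3))
    center = Attractor(path=(0.0, 0.0), mass=mass_for_stiffness(1.0, 0.3))
    gaze = simulate_gaze([target, center], cfg, 30.0, q0=(0.0, 0.0))
    gaze75 = resample_to(lowpass(gaze), 75.0)
    n = min(len(gaze75), len(stim))
    print(name, mpc(stim.slice(0, n), gaze75.slice(0, n)).rho_star)
```

prints

```
LJ (predictable): MPC rho* = 0.923 (projection direction 3.00 rad)
RW (unpredictable): MPC rho* = 0.623 (projection direction 1.03 rad)
```

— the smooth Lissajous target is tracked almost perfectly while the jerky
bounded random walk is only partially followed, the dissociation that
defines micro-pursuit. The other scripts in `examples/` walk through
stimulus generation, micro-saccade detection against injected ground
truth, the per-fixation metric table, group statistics, and effect sizes.

A thin CLI chains the stages on CSV datasets:

```sh
micropursuit simulate --design cross_like --subjects 2 --trials 2 --seed 7 --out data/
micropursuit metrics data/ --out metrics.csv
micropursuit report metrics.csv --out report.csv
```

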