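# colsync

A simulator of **collinear facilitation and suppression as a synchronization
phenomenon** in early visual cortex, for computational neuroscientists
studying gamma-band dynamics and surround modulation.

The detectability (and V1 firing response) of a target Gabor patch is
enhanced by collinear flanking Gabors when the target's contrast is low
relative to the flankers, and suppressed when it is high.  `colsync` models
this with three weakly coupled phase oscillators — one neural population per
Gabor patch — whose dynamics follow the Kuramoto equation

```
dθᵢ/dt = ωᵢ + (K/N) Σⱼ sin(θⱼ − θᵢ),        N = 3
```

Each population's intrinsic angular velocity ωᵢ = 2πfᵢ is set by the contrast
`c` in its receptive field through a saturating sigmoid fitted to macaque
V1/V2 LFP peak frequencies,

```
f(c) = γ / (1 + exp(−βc + αβ)),     α = 10.74, β = 0.057, γ = 44.77 Hz,
```

and the coupling strength K encodes the collinearity of the arrangement.
Attention acts as *response gain*: attended populations use γ = 49 Hz.
When the oscillators entrain, a slow target is pulled up toward the flanker
frequency (facilitation) and a fast one pulled down (suppression); the
sign flips exactly where target and flanker intrinsic frequencies meet.
Synchrony is measured by the Kuramoto order parameter
r = |Σⱼ e^{iθⱼ}|/N and entrainment by each oscillator's mean effective
frequency f̄ᵢ = ⟨dθᵢ/dt⟩/2π (transient-free time average).

The package provides the contrast–frequency tuning module (including sigmoid
fitting and a synthetic-data generator standing in for the restricted LFP
dataset), coupling-matrix builders for uniform and asymmetric schemes,
vectorized forward-Euler integration, preconfigured sweep experiments over
(target contrast × K) grids, and metrics for switch points and Arnold-tongue
geometry — plus a small CLI.

## Worked example

```python
from colsync import (SimulationConfig, SweepGrid, run_sweep, find_switch_point,
                     intrinsic_frequency)

sim = SimulationConfig(n_reps=20, master_seed=1)          # 20 random-phase replicates
grid = SweepGrid(target_contrasts=tuple(range(30, 71)), K_values=(10.0,))
sweep = run_sweep(grid, flanker_contrast=50.0, sim=sim)   # three oscillators, uniform K

print(f"flanker intrinsic frequency: {intrinsic_frequency(50.0):.3f} Hz")
cell = grid.target_contrasts.index(40.0)
print(f"at target contrast 40%: delta_f = {sweep.delta_f_target[cell, 0]:+.3f} Hz, "
      f"r = {sweep.r_mean[cell, 0]:.3f}")
sp = find_switch_point(sweep.delta_f_target[:, 0], sweep.target_contrasts, K=10.0)
print(f"facilitation -> suppression switch at {sp.contrast:.2f}% target contrast")
```

prints

```
flanker intrinsic frequency: 40.454 Hz
at target contrast 40%: delta_f = +0.307 Hz, r = 0.703
facilitation -> suppression switch at 49.92% target contrast
```

A 40%-contrast target oscillates intrinsically below the 50%-contrast
flankers, so the flankers speed it up by ~0.3 Hz (facilitation, positive
`delta_f`); scanning target contrast, the effect changes sign at ≈50% —
exactly where the intrinsic frequencies of target and flankers coincide.

The same sweeps are available from the shell:

```bash
colsync sweep exp1-50 --fast --seed 7 --out results/
colsync analyze results/exp1-50.csv --out analysis/
colsync fit-tuning --synthetic --noise-sd 1 --seed 1 --out fit.json
```

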