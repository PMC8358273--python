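# Methods

## Model

Three neural populations in early visual cortex — one encoding a target
Gabor, two encoding collinear flankers above and below it — are modelled as
weakly coupled phase oscillators of the Kuramoto type:

    dθᵢ/dt = ωᵢ + (1/N) Σⱼ M[i,j] · sin(θⱼ − θᵢ),      N = 3.

With a uniform coupling matrix (all off-diagonal entries K) this is the
classic (K/N)-normalized Kuramoto system; the generalized per-pair matrix M
lets the asymmetric coupling schemes below be expressed without changing the
normalization.  The model carries no noise term by default: phase noise
mainly raises the critical coupling without changing the qualitative
synchronization behavior, and an optional Euler–Maruyama additive phase-noise
term (`noise_sd`, rad/√s) is provided for robustness checks only.

Intrinsic frequencies come from stimulus contrast through a saturating
sigmoid, f(c) = γ / (1 + exp(−βc + αβ)), with α = 10.74 (% contrast,
inflection), β = 0.057 (per % contrast, slope) and γ = 44.77 Hz (gain),
values fitted to peak frequencies of macaque V1/V2 local field potentials.
Contrast is expressed in percent on [0, 100] throughout — the β value is
only meaningful in those units.  Two consequences are documented rather than
"fixed": f(0) ≈ 15.74 Hz (the curve does not pass through the origin, and we
do not clamp it), and f(33) ≈ 78% of γ (which is why 33% flankers are a
canonical condition: the flanker frequency then sits near the knee of the
curve).  Angular velocity is ω = 2πf.

Attention is response gain and nothing else: attended populations replace γ
by 49 Hz, leaving α and β untouched.  Gain on the target shifts the
facilitation→suppression switch point to the contrast where the boosted
target curve crosses the flanker frequency (≈38% for 50% flankers); gain on
the flankers widens the detuning at low target contrast and narrows it at
high contrast.

## Coupling schemes

Population order is fixed as (flanker_above, target, flanker_below); the two
flankers are exchangeable, and M[i,j] couples population j onto i.

* **uniform** — all off-diagonal entries K.
* **ff_ratio** — flanker↔flanker entries K·ratio, flanker↔target entries K;
  always symmetric.
* **directed_ratio** — flanker↔flanker stays K while the
  flanker→target / target→flanker ratio is made unequal.  How a given ratio
  is split between the two directions is genuinely underdetermined, so it is
  configurable: the default `sqrt` split uses K·√ratio and K/√ratio, keeping
  the geometric mean at K so that only the asymmetry varies along a ratio
  sweep; `one_sided` instead scales only flanker→target.  Either split
  realizes the requested entry ratio exactly.

No quantitative orientation→coupling map is shipped: K itself is the
collinearity proxy, and the weak coupling of orthogonal arrangements has no
canonical numeric value.

## Integration and measures

Forward Euler with Δt = 0.002 s over 1 s (exactly round(duration/dt) = 500
steps, no partial step), phases stored unwrapped.  Initial phases are i.i.d.
uniform on [0, 2π) per oscillator and replicate.  The recorded instantaneous
velocity at step t is the deterministic drift evaluated at the pre-update
state; when noise is enabled it perturbs the phases but is never recorded as
velocity.  Effective frequency is the mean of these recorded velocities —
not a finite difference of stored phases — divided by 2π, which avoids wrap
artifacts and matches the definition of the measure as an average rate of
phase change.

The first 99 velocity samples (steps 1–99 of 500, 1-based) are discarded as
transient, leaving 401 samples in every average.  The same discard is applied
to the time-averaged order parameter r̄; whether published coherence maps
time-average after a discard or sample the final state is not knowable from
color maps alone, and time-averaging is the lower-variance choice.  One
visible consequence: r̄ retains the tail of the synchronization transient, so
even a zero-detuning condition at moderate K averages r̄ ≈ 0.97 over 1 s while
its final-state r exceeds 0.99.  Tests assert both quantities accordingly.

Replicate streams are spawned from a master seed with counter-based keys
(master_seed, contrast index, K index, replicate index), so sweeps are
bit-reproducible, cells are independent of evaluation order, and refining a
grid never reshuffles existing cells.  The batched integrator and the
trajectory-recording single-trial integrator are separate code paths and are
cross-checked against each other to machine precision in the tests, along
with an RK-free closed-form oracle set (below).

## Experiments

Sweeps cover (target contrast × K) grids with flanker contrast fixed, 50
replicates per cell by default (10 in the `--fast` profile).  Default axes
are target contrast 1–100% in 1% steps and K 0–30 in steps of 1 — wide
enough to contain the synchronization onset (K ≈ 7 for 50% flankers under
these defaults) and the switch-point region; the exact axes behind published
figures are not stated anywhere, so qualitative claims are evaluated on
these defaults.  Reported per cell: replicate-averaged r̄, effective
frequencies, intrinsic frequencies, and the target's frequency modulation
Δf = f̄_target − f_target (positive = facilitation).

Where a comparison concerns the *strength* of facilitation or suppression
under attention, it is made in the entrained regime, i.e. at a K above the
critical coupling of every condition compared.  Below the tongue the
residual frequency shift of an unlocked oscillator scales like p²/2Δω
(p the coupling pull), which *decreases* with detuning and can invert the
comparison; inside the tongue the shift is (2/3)Δω and directly reflects the
detuning structure the attention manipulation creates.  Concretely, the
facilitation comparison at 20% target contrast uses K = 110 (critical
coupling for attended flankers there is ≈101) and the 40%-flanker
suppression comparison uses K = 40 (critical coupling without attention
≈29).  The switch-point left shift under target attention is already present
at K = 10 and is tested there.

## Arnold-tongue geometry and its two boundaries

The synchronization region is extracted by thresholding r̄ (default 0.95;
area comparisons are reported at 0.8/0.9/0.95 since no canonical threshold
exists for continuous coherence maps).  An analytic subtlety matters here:
for two oscillators with detuning Δω and pairwise coupling K/2 the phase
difference obeys dφ/dt = Δω − K·sinφ, so *frequency locking* begins exactly
at K = |Δω| = 2π|Δf| — but a locked pair sits at lag φ* = arcsin(Δω/K) with
order parameter cos(φ*/2), so the r̄ ≥ 0.95 contour lies at
K = |Δω| / sin(2·arccos 0.95) ≈ 1.69·|Δω|, well above the locking boundary.
The two notions must not be conflated.  `metrics` therefore exposes both
empirical boundary extractors (`locking_boundary` in `frequency` and `order`
mode) and both closed forms (`critical_coupling_two_oscillator`,
`r_threshold_critical_coupling`), and the acceptance suite validates each
empirical boundary against its *own* closed form: the frequency-locking
boundary matches K = 2π|Δf| within one K-grid cell at every probed contrast,
and the r̄-contour matches its closed form within two cells away from zero
detuning (near Δω = 0 the 1-s window is dominated by the synchronization
transient and the asymptotic formula does not apply).

The facilitation/suppression switch point is the first zero crossing of the
Δf row (scanning from low contrast, linear interpolation between bracketing
cells; the first-crossing rule is the tie-break under stochastic jitter).
Rows with no sign change return an explicit "no switch" result and all-zero
rows (e.g. K = 0) a degenerate flag.

## Sigmoid fitting and synthetic tuning data

The electrophysiological dataset behind the contrast–frequency curve is
restricted, so the package generates synthetic stand-ins: sigmoid values
plus additive Gaussian noise (default SD 1 Hz, ~10 samples per contrast on a
10–90% grid, two synthetic subject labels assigned round-robin).  This
emulates the first-order structure of LFP peak-frequency data — a saturating
mean with roughly contrast-independent scatter — but none of its real-world
features: no across-session drift, no subject-specific curve differences, no
heteroscedasticity, no peak-extraction failures at low contrast.  Passing
recovery tests therefore demonstrates correctness of the fitting machinery,
not robustness to real LFP data.

Fitting is pooled (both subjects jointly, matching the single published
parameter triple), unweighted nonlinear least squares with bounds
α ∈ (0, 100), β ∈ (1e-4, 1), γ ∈ (1, 200) and starting values
α₀ = median contrast, β₀ = 0.05, γ₀ = max observed frequency — a
robust recipe for sigmoid-shaped data; no loss function or weighting is
prescribed anywhere, so plain least squares is the default choice.
Noiseless data is recovered to 1e-6 relative error; constant-frequency data
leaves the slope unidentifiable and is flagged as non-converged rather than
silently returned.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced problem sizes chosen
once as the package's fast profile: 10–20 replicates per cell (against the
50 of the full protocol; a dedicated test shows 10 vs 50 replicates moves
switch-point estimates by well under one contrast step), contrast grids
spanning ±20% around the relevant flanker contrast in 1–2% steps, and K
grids of step 1–2.  The full 50-replicate, 100×31-cell reproduction of every
figure remains available through the default arguments and the CLI without
`--fast`.

Numerics: forward Euler is the model's own integration method and is kept as
the only production integrator; phases are never wrapped; zero coupling
reproduces intrinsic frequencies to machine precision; symmetric coupling
conserves the summed phase velocity to ≲1e-12 relative error at every step
(a direct consequence of sin-antisymmetry, used as an integration
invariant), and directed schemes deliberately break it.  Switch-point
interpolation is linear; sub-cell accuracy beyond that is not claimed.

## Known limitations

* Phase oscillators only: no amplitude dynamics, no spiking substrate, no
  within-population variability.
* The orientation dependence of lateral connectivity is collapsed into the
  scalar K; no receptive-field geometry or distance dependence is modelled.
* Behavioral detectability is out of scope — the model stops at frequency
  modulation and coherence.
* The contrast–frequency parameters come from awake-animal recordings;
  anesthetized preparations are known to differ, so quantitative switch
  points in such data need not sit at equal contrast.
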