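"""Sweep experiments: synchronization and flanker effects over (contrast, K) grids.

A stimulus condition fixes the flanker contrast and attention state; a sweep
then varies target contrast and coupling strength, runs ``n_reps``
random-phase replicates per grid cell and averages the order parameter and
effective frequencies.  The quantity of interest is the target's frequency
modulation

    delta_f_target = f_eff_target - f_int_target   (Hz)

whose positive/negative sign is the model's signature of collinear
facilitation/suppression.

Three preconfigured experiments mirror the study design:

* ``experiment1`` — no attention, uniform coupling, flanker contrast 50% or
  33% (facilitation below the flanker contrast, suppression above).
* ``experiment2`` — attention (response gain 49 Hz) on the target or on both
  flankers, flanker contrast 50% or 40%.
* ``experiment3`` — asymmetric coupling: flanker-flanker ratio, or directed
  flanker/target ratio, no attention.

``two_oscillator_reference`` is the two-oscillator entrainment picture (one
oscillator fixed at 50% contrast) whose Arnold tongue has the closed-form
boundary K = 2*pi*|f(c2) - f(50)|, used as an analytic oracle.

All replicate streams are pure functions of (master seed, cell index,
replicate index), so whole sweeps are bit-reproducible and cells are
independent of evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    SimulationConfig,
    random_initial_phases,
    simulate_batch,
    trial_seed_sequence,
)
from .network import CouplingSpec, TARGET, build_coupling
from .tuning import (
    AttentionCondition,
    DEFAULT_PARAMS,
    SigmoidParams,
    angular_velocity,
    effective_params,
    intrinsic_frequency,
)

__all__ = [
    "StimulusCondition",
    "SweepGrid",
    "CellResult",
    "SweepResult",
    "population_frequencies",
    "run_condition",
    "run_sweep",
    "experiment1",
    "experiment2",
    "experiment3",
    "two_oscillator_reference",
    "default_target_contrasts",
    "default_K_values",
    "fast_simulation",
]

SWEEP_CSV_COLUMNS = [
    "target_contrast",
    "K",
    "r_mean",
    "f_int_target",
    "f_eff_target",
    "delta_f_target",
    "f_eff_flanker",
]


@dataclass(frozen=True)
class StimulusCondition:
    """Target and flanker contrasts (percent) plus the attention state."""

    target_contrast: float
    flanker_contrast: float
    attention: AttentionCondition = AttentionCondition()

    def __post_init__(self) -> None:
        for name, c in (("target", self.target_contrast), ("flanker", self.flanker_contrast)):
            if not 0.0 <= c <= 100.0:
                raise ValueError(f"{name} contrast must lie in [0, 100], got {c}")


@dataclass(frozen=True)
class SweepGrid:
    """Axes of a sweep: target contrasts, coupling strengths, coupling scheme."""

    target_contrasts: tuple[float, ...]
    K_values: tuple[float, ...]
    scheme: str = "uniform"
    ff_ratio: float = 1.0
    directed_ratio: float = 1.0
    asymmetric_split: str = "sqrt"

    def __post_init__(self) -> None:
        if len(self.target_contrasts) == 0 or len(self.K_values) == 0:
            raise ValueError("sweep axes must be non-empty")
        if any(k < 0 for k in self.K_values):
            raise ValueError("K values must be >= 0")


@dataclass
class CellResult:
    """Replicate-averaged result of one (target contrast, K) condition."""

    r_mean: float
    f_eff: np.ndarray  # (N,) Hz
    f_int: np.ndarray  # (N,) Hz
    delta_f_target: float


@dataclass
class SweepResult:
    """Replicate-averaged grids over (target contrast, K), plus metadata.

    ``f_eff`` has shape (nC, nK, N) and ``f_int`` shape (nC, N); population
    order is (flanker_above, target, flanker_below) for the three-oscillator
    experiments and (reference, probe) for the two-oscillator reference, with
    ``tracked_index`` naming the oscillator whose frequency modulation is
    reported.
    """

    target_contrasts: np.ndarray
    K_values: np.ndarray
    r_mean: np.ndarray  # (nC, nK)
    f_eff: np.ndarray  # (nC, nK, N)
    f_int: np.ndarray  # (nC, N)
    flanker_contrast: float
    attention: AttentionCondition
    coupling: dict
    master_seed: int
    n_reps: int
    tracked_index: int = TARGET
    flanker_index: int = 0
    sim: dict = field(default_factory=dict)

    @property
    def n_oscillators(self) -> int:
        return self.f_eff.shape[2]

    @property
    def delta_f_target(self) -> np.ndarray:
        """Frequency modulation grid (nC, nK) of the tracked oscillator, Hz."""
        return self.f_eff[:, :, self.tracked_index] - self.f_int[:, None, self.tracked_index]

    def to_frame(self) -> pd.DataFrame:
        nC, nK = self.r_mean.shape
        cc, kk = np.meshgrid(self.target_contrasts, self.K_values, indexing="ij")
        return pd.DataFrame(
            {
                "target_contrast": cc.ravel(),
                "K": kk.ravel(),
                "r_mean": self.r_mean.ravel(),
                "f_int_target": np.repeat(self.f_int[:, self.tracked_index], nK),
                "f_eff_target": self.f_eff[:, :, self.tracked_index].ravel(),
                "delta_f_target": self.delta_f_target.ravel(),
                "f_eff_flanker": self.f_eff[:, :, self.flanker_index].ravel(),
            }
        )

    def metadata(self) -> dict:
        return {
            "flanker_contrast": self.flanker_contrast,
            "attention": {"mode": self.attention.mode, "gamma_attended": self.attention.gamma_attended},
            "coupling": self.coupling,
            "master_seed": self.master_seed,
            "n_reps": self.n_reps,
            "n_oscillators": self.n_oscillators,
            "tracked_index": self.tracked_index,
            "target_contrasts": [float(c) for c in self.target_contrasts],
            "K_values": [float(k) for k in self.K_values],
            "sim": self.sim,
            "package_version": __version__,
        }

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Tidy CSV (12 significant digits) plus a JSON sidecar of the full config."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.12g")
        if sidecar_path is None:
            sidecar_path = csv_path.with_suffix(".json")
        Path(sidecar_path).write_text(json.dumps(self.metadata(), indent=2, sort_keys=True) + "\n")


def population_frequencies(
    stimulus: StimulusCondition, params: SigmoidParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Intrinsic frequencies (Hz) of (flanker, target, flanker) for a stimulus.

    Both flankers share the flanker contrast; attention replaces the sigmoid
    gain of the populations whose role is attended.
    """
    p_target = effective_params(params, stimulus.attention, "target")
    p_flank = effective_params(params, stimulus.attention, "flanker")
    f_t = intrinsic_frequency(stimulus.target_contrast, p_target)
    f_f = intrinsic_frequency(stimulus.flanker_contrast, p_flank)
    return np.array([f_f, f_t, f_f])


def _batch_initial_phases(
    master_seed: int, cell_keys: Sequence[tuple[int, ...]], n_reps: int, n_osc: int
) -> np.ndarray:
    """(len(cell_keys)*n_reps, N) initial phases, one independent stream per trial."""
    phases = np.empty((len(cell_keys) * n_reps, n_osc))
    b = 0
    for key in cell_keys:
        for rep in range(n_reps):
            rng = np.random.default_rng(trial_seed_sequence(master_seed, key, rep))
            phases[b] = random_initial_phases(rng, n_osc)
            b += 1
    return phases


def _noise_seeds(master_seed, cell_keys, n_reps):
    # independent child streams for the optional phase noise
    return [
        trial_seed_sequence(master_seed, (*key, 10_000), rep)
        for key in cell_keys
        for rep in range(n_reps)
    ]


def run_condition(
    stimulus: StimulusCondition,
    coupling: CouplingSpec,
    sim: SimulationConfig,
    params: SigmoidParams = DEFAULT_PARAMS,
    cell_key: tuple[int, ...] = (0, 0),
) -> CellResult:
    """Run one stimulus/coupling condition, averaged over ``sim.n_reps`` replicates."""
    f_int = population_frequencies(stimulus, params)
    omegas = angular_velocity(f_int)
    M = build_coupling(coupling)
    keys = [tuple(cell_key)]
    init = _batch_initial_phases(sim.master_seed, keys, sim.n_reps, 3)
    seeds = _noise_seeds(sim.master_seed, keys, sim.n_reps) if sim.noise_sd > 0 else None
    r, f_eff = simulate_batch(np.tile(omegas, (sim.n_reps, 1)), M, sim, init, noise_seeds=seeds)
    f_eff_mean = f_eff.mean(axis=0)
    return CellResult(
        r_mean=float(r.mean()),
        f_eff=f_eff_mean,
        f_int=f_int,
        delta_f_target=float(f_eff_mean[TARGET] - f_int[TARGET]),
    )


def run_sweep(
    grid: SweepGrid,
    flanker_contrast: float,
    sim: SimulationConfig,
    attention: AttentionCondition = AttentionCondition(),
    params: SigmoidParams = DEFAULT_PARAMS,
) -> SweepResult:
    """Run the full (target contrast, K) sweep as one vectorized batch.

    Every grid cell is averaged over ``sim.n_reps`` replicates with replicate
    streams keyed by the cell's (contrast index, K index), so refining or
    reordering the grid never changes the cells already present.
    """
    contrasts = np.asarray(grid.target_contrasts, dtype=float)
    Ks = np.asarray(grid.K_values, dtype=float)
    nC, nK, reps = len(contrasts), len(Ks), sim.n_reps

    f_int = np.stack(
        [
            population_frequencies(
                StimulusCondition(c, flanker_contrast, attention), params
            )
            for c in contrasts
        ]
    )  # (nC, 3)
    omegas_cells = angular_velocity(f_int)  # (nC, 3)

    matrices = np.stack(
        [
            build_coupling(
                CouplingSpec(
                    K=float(k),
                    scheme=grid.scheme,
                    ff_ratio=grid.ff_ratio,
                    directed_ratio=grid.directed_ratio,
                    asymmetric_split=grid.asymmetric_split,
                )
            )
            for k in Ks
        ]
    )  # (nK, 3, 3)

    # trial order: cell-major (ci, ki), replicate-minor
    cell_keys = [(ci, ki) for ci in range(nC) for ki in range(nK)]
    omegas_b = np.repeat(omegas_cells, nK * reps, axis=0)  # (nC*nK*reps, 3)
    M_b = np.tile(np.repeat(matrices, reps, axis=0), (nC, 1, 1))  # (nC*nK*reps, 3, 3)
    init = _batch_initial_phases(sim.master_seed, cell_keys, reps, 3)
    seeds = _noise_seeds(sim.master_seed, cell_keys, reps) if sim.noise_sd > 0 else None

    r, f_eff = simulate_batch(omegas_b, M_b, sim, init, noise_seeds=seeds)
    r_grid = r.reshape(nC, nK, reps).mean(axis=2)
    f_grid = f_eff.reshape(nC, nK, reps, 3).mean(axis=2)

    coupling_meta = {
        "scheme": grid.scheme,
        "ff_ratio": grid.ff_ratio,
        "directed_ratio": grid.directed_ratio,
        "asymmetric_split": grid.asymmetric_split,
    }
    return SweepResult(
        target_contrasts=contrasts,
        K_values=Ks,
        r_mean=r_grid,
        f_eff=f_grid,
        f_int=f_int,
        flanker_contrast=float(flanker_contrast),
        attention=attention,
        coupling=coupling_meta,
        master_seed=sim.master_seed,
        n_reps=reps,
        sim=sim.to_dict(),
    )


def default_target_contrasts(fast: bool = False) -> tuple[float, ...]:
    """Default target-contrast axis (percent): 1..100 step 1 (step 2 when fast)."""
    step = 2 if fast else 1
    return tuple(float(c) for c in range(1, 101, step))


def default_K_values(fast: bool = False) -> tuple[float, ...]:
    """Default coupling axis: 0..30 step 1, containing the synchronization onset."""
    return tuple(float(k) for k in range(0, 31, 1))


def fast_simulation(master_seed: int = 0, noise_sd: float = 0.0) -> SimulationConfig:
    """Reduced-replicate profile (10 instead of 50) for quick runs and CI."""
    return SimulationConfig(n_reps=10, master_seed=master_seed, noise_sd=noise_sd)


def _resolve_axes(target_contrasts, K_values, fast):
    if target_contrasts is None:
        target_contrasts = default_target_contrasts(fast)
    if K_values is None:
        K_values = default_K_values(fast)
    return tuple(float(c) for c in target_contrasts), tuple(float(k) for k in K_values)


def experiment1(
    flanker_contrast: float = 50.0,
    target_contrasts: Sequence[float] | None = None,
    K_values: Sequence[float] | None = None,
    sim: SimulationConfig | None = None,
    fast: bool = False,
) -> SweepResult:
    """Facilitation/suppression sweep: no attention, uniform coupling.

    With flanker contrast 50% the target is facilitated below 50% target
    contrast and suppressed above; with 33% flankers (the contrast at which
    the sigmoid reaches ~78% of its asymptote) the switch moves to 33%.
    """
    sim = sim or (fast_simulation() if fast else SimulationConfig())
    tc, kv = _resolve_axes(target_contrasts, K_values, fast)
    grid = SweepGrid(target_contrasts=tc, K_values=kv, scheme="uniform")
    return run_sweep(grid, flanker_contrast, sim)


def experiment2(
    flanker_contrast: float = 50.0,
    attention_mode: str = "target",
    gamma_attended: float = 49.0,
    target_contrasts: Sequence[float] | None = None,
    K_values: Sequence[float] | None = None,
    sim: SimulationConfig | None = None,
    fast: bool = False,
) -> SweepResult:
    """Attention sweep: response gain ``gamma_attended`` on the target or flankers."""
    sim = sim or (fast_simulation() if fast else SimulationConfig())
    tc, kv = _resolve_axes(target_contrasts, K_values, fast)
    attention = AttentionCondition(mode=attention_mode, gamma_attended=gamma_attended)
    grid = SweepGrid(target_contrasts=tc, K_values=kv, scheme="uniform")
    return run_sweep(grid, flanker_contrast, sim, attention=attention)


def experiment3(
    scheme: str = "ff_ratio",
    ratios: Sequence[float] = (0.1, 0.5, 1.0, 2.0),
    flanker_contrast: float = 50.0,
    target_contrasts: Sequence[float] | None = None,
    K_values: Sequence[float] | None = None,
    sim: SimulationConfig | None = None,
    fast: bool = False,
    asymmetric_split: str = "sqrt",
) -> dict[float, SweepResult]:
    """Asymmetric-coupling sweeps, one per ratio, sharing grid and seeds.

    ``scheme="ff_ratio"`` varies flanker-flanker coupling relative to
    flanker-target coupling; ``scheme="directed_ratio"`` varies the directed
    flanker->target / target->flanker ratio.  Ratio 1 reproduces
    ``experiment1`` cell for cell under the same seed.
    """
    if scheme not in ("ff_ratio", "directed_ratio"):
        raise ValueError(f"scheme must be 'ff_ratio' or 'directed_ratio', got {scheme!r}")
    sim = sim or (fast_simulation() if fast else SimulationConfig())
    tc, kv = _resolve_axes(target_contrasts, K_values, fast)
    out: dict[float, SweepResult] = {}
    for ratio in ratios:
        grid = SweepGrid(
            target_contrasts=tc,
            K_values=kv,
            scheme=scheme,
            ff_ratio=float(ratio) if scheme == "ff_ratio" else 1.0,
            directed_ratio=float(ratio) if scheme == "directed_ratio" else 1.0,
            asymmetric_split=asymmetric_split,
        )
        out[float(ratio)] = run_sweep(grid, flanker_contrast, sim)
    return out


def two_oscillator_reference(
    reference_contrast: float = 50.0,
    contrasts: Sequence[float] | None = None,
    K_values: Sequence[float] | None = None,
    sim: SimulationConfig | None = None,
    params: SigmoidParams = DEFAULT_PARAMS,
) -> SweepResult:
    """Two-oscillator entrainment sweep (Arnold-tongue reference picture).

    Oscillator 0 (the reference) has fixed contrast; oscillator 1's contrast
    runs along the sweep axis, detuning their intrinsic frequencies.  The
    reported frequency modulation is that of the *reference* oscillator: it
    speeds up inside the tongue when the second oscillator is faster and
    slows down when it is slower.  The analytic locking boundary is
    K = 2*pi*|f(c2) - f(reference)|.
    """
    sim = sim or SimulationConfig()
    if contrasts is None:
        contrasts = tuple(float(c) for c in range(1, 101))
    if K_values is None:
        K_values = tuple(float(k) for k in range(0, 85, 2))
    contrasts = np.asarray(contrasts, dtype=float)
    Ks = np.asarray(K_values, dtype=float)
    nC, nK, reps = len(contrasts), len(Ks), sim.n_reps

    f_ref = intrinsic_frequency(reference_contrast, params)
    f_int = np.stack([np.full(nC, f_ref), intrinsic_frequency(contrasts, params)], axis=1)  # (nC, 2)
    omegas_cells = angular_velocity(f_int)

    matrices = np.stack([np.array([[0.0, k], [k, 0.0]]) for k in Ks])
    cell_keys = [(ci, ki) for ci in range(nC) for ki in range(nK)]
    omegas_b = np.repeat(omegas_cells, nK * reps, axis=0)
    M_b = np.tile(np.repeat(matrices, reps, axis=0), (nC, 1, 1))
    init = _batch_initial_phases(sim.master_seed, cell_keys, reps, 2)
    seeds = _noise_seeds(sim.master_seed, cell_keys, reps) if sim.noise_sd > 0 else None

    r, f_eff = simulate_batch(omegas_b, M_b, sim, init, noise_seeds=seeds)
    return SweepResult(
        target_contrasts=contrasts,
        K_values=Ks,
        r_mean=r.reshape(nC, nK, reps).mean(axis=2),
        f_eff=f_eff.reshape(nC, nK, reps, 2).mean(axis=2),
        f_int=f_int,
        flanker_contrast=float(reference_contrast),
        attention=AttentionCondition(),
        coupling={"scheme": "two_oscillator", "ff_ratio": 1.0, "directed_ratio": 1.0,
                  "asymmetric_split": "sqrt"},
        master_seed=sim.master_seed,
        n_reps=reps,
        tracked_index=0,
        flanker_index=1,
        sim=sim.to_dict(),
    )
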