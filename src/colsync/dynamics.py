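"""Kuramoto phase dynamics: forward-Euler integration and synchrony measures.

Each neural population i is a phase oscillator obeying

    dtheta_i/dt = omega_i + (1/N) * sum_j M[i, j] * sin(theta_j - theta_i)

where ``omega_i`` is its intrinsic angular velocity (set upstream by stimulus
contrast) and ``M`` the coupling matrix; a uniform M of strength K reduces the
sum to the textbook (K/N) form.  Synchrony is quantified by the Kuramoto
order parameter r = |mean_j exp(i theta_j)| and entrainment by the mean
effective frequency of each oscillator, the time average of its instantaneous
phase velocity divided by 2*pi.  Phase-velocity samples from the initial
transient (the first ``discard_steps`` Euler steps) are excluded from both
averages.

Integration is plain forward Euler on unwrapped phases (the model's own
update rule); an optional Euler-Maruyama phase-noise term is available but
off by default.  ``simulate_batch`` integrates many independent trials in one
vectorized pass and only accumulates the summary statistics, which is what
the parameter sweeps use; ``integrate`` records full trajectories for a
single trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "OscillatorEnsemble",
    "TrialResult",
    "drift",
    "order_parameter",
    "integrate",
    "simulate_batch",
    "mean_effective_frequency",
    "random_initial_phases",
    "trial_seed_sequence",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for one batch of simulations.

    Defaults follow the study protocol: Euler step dt = 0.002 s, 1 s of
    simulated time (500 steps), the first 99 steps discarded as transient,
    and 50 random-phase replicates per condition.  ``noise_sd`` is the
    intensity of optional additive phase noise in rad/sqrt(s); 0 disables it.
    """

    dt: float = 0.002
    duration: float = 1.0
    discard_steps: int = 99
    n_reps: int = 50
    master_seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt * (self.discard_steps + 1):
            raise ValueError("duration must cover at least discard_steps + 1 steps")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.discard_steps < 0:
            raise ValueError("discard_steps must be >= 0")

    @property
    def n_steps(self) -> int:
        """Number of Euler steps: round(duration / dt); no partial final step."""
        return int(round(self.duration / self.dt))

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "duration": self.duration,
            "discard_steps": self.discard_steps,
            "n_reps": self.n_reps,
            "master_seed": self.master_seed,
            "noise_sd": self.noise_sd,
        }


@dataclass
class OscillatorEnsemble:
    """A set of N phase oscillators: intrinsic angular velocities plus coupling."""

    omegas: np.ndarray  # (N,) rad/s
    coupling: np.ndarray  # (N, N); entry [i, j] couples j onto i

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        n = self.omegas.shape[0]
        if n < 1:
            raise ValueError("need at least one oscillator")
        if not np.all(np.isfinite(self.omegas)):
            raise ValueError("omegas must be finite")
        if self.coupling.shape != (n, n):
            raise ValueError(f"coupling must be {n}x{n}, got {self.coupling.shape}")

    @property
    def N(self) -> int:
        return self.omegas.shape[0]


@dataclass
class TrialResult:
    """Full record of one integrated trial.

    ``phases[t]`` is the (unwrapped) state *before* Euler step t,
    ``phase_velocities[t]`` the deterministic drift evaluated at that state
    (noise, when enabled, perturbs the phases but is never recorded as
    velocity), and ``r_trace[t]`` the order parameter of that state.
    ``r_mean`` and ``f_eff`` average over the post-transient steps.
    """

    phases: np.ndarray  # (T, N) rad, unwrapped
    phase_velocities: np.ndarray  # (T, N) rad/s
    r_trace: np.ndarray  # (T,)
    r_mean: float
    f_eff: np.ndarray  # (N,) Hz
    discard_steps: int

    def to_frame(self, dt: float) -> pd.DataFrame:
        """Long-format export (step, time_s, oscillator, phase, velocity, r)."""
        T, N = self.phases.shape
        steps = np.repeat(np.arange(T), N)
        osc = np.tile(np.arange(N), T)
        return pd.DataFrame(
            {
                "step": steps,
                "time_s": steps * dt,
                "oscillator": osc,
                "phase_rad": self.phases.ravel(),
                "velocity_rad_s": self.phase_velocities.ravel(),
                "r": np.repeat(self.r_trace, N),
            }
        )

    def to_csv(self, path: str | Path, dt: float) -> None:
        self.to_frame(dt).to_csv(path, index=False, float_format="%.12g")


def drift(phases: np.ndarray, ensemble: OscillatorEnsemble) -> np.ndarray:
    """Instantaneous phase velocity at a state: the Kuramoto right-hand side."""
    theta = np.asarray(phases, dtype=float)
    if theta.shape != (ensemble.N,):
        raise ValueError(f"phases must have shape ({ensemble.N},), got {theta.shape}")
    # diff[i, j] = theta_j - theta_i
    diff = theta[None, :] - theta[:, None]
    return ensemble.omegas + (ensemble.coupling * np.sin(diff)).sum(axis=1) / ensemble.N


def order_parameter(phases) -> float | np.ndarray:
    """Kuramoto order parameter r = |mean_j exp(i theta_j)| along the last axis.

    1 means perfect phase alignment, 0 a balanced (incoherent) configuration.
    Accepts a single phase vector or any batch stacked on leading axes.
    """
    theta = np.asarray(phases, dtype=float)
    if theta.size == 0 or theta.shape[-1] == 0:
        raise ValueError("order parameter of an empty phase vector is undefined")
    r = np.abs(np.exp(1j * theta).mean(axis=-1))
    return float(r) if r.ndim == 0 else r


def trial_seed_sequence(master_seed: int, cell_key: Sequence[int], replicate: int) -> np.random.SeedSequence:
    """Seed stream for one replicate of one sweep cell.

    Streams are a pure function of (master_seed, cell index, replicate index),
    so cells can be evaluated in any order — or in one vectorized batch —
    without changing any result.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(*map(int, cell_key), int(replicate)))


def random_initial_phases(rng: np.random.Generator, n_oscillators: int) -> np.ndarray:
    """Initial phases drawn i.i.d. uniform on [0, 2*pi) per oscillator."""
    return rng.uniform(0.0, 2.0 * np.pi, size=n_oscillators)


def integrate(
    ensemble: OscillatorEnsemble,
    config: SimulationConfig,
    initial_phases: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Integrate one trial with forward Euler, recording full trajectories.

    If ``initial_phases`` is omitted, phases are drawn uniformly at random
    from ``rng`` (or from a generator seeded with ``config.master_seed``).
    Raises a RuntimeError naming the step if the state ever becomes
    non-finite.
    """
    n_steps = config.n_steps
    if config.discard_steps >= n_steps:
        raise ValueError(f"discard_steps ({config.discard_steps}) must be < n_steps ({n_steps})")
    if initial_phases is None:
        if rng is None:
            rng = np.random.default_rng(config.master_seed)
        theta = random_initial_phases(rng, ensemble.N)
    else:
        theta = np.asarray(initial_phases, dtype=float).copy()
        if theta.shape != (ensemble.N,):
            raise ValueError(f"initial_phases must have shape ({ensemble.N},), got {theta.shape}")

    if config.noise_sd > 0 and rng is None:
        rng = np.random.default_rng(config.master_seed)
    noise_scale = config.noise_sd * np.sqrt(config.dt)

    phases = np.empty((n_steps, ensemble.N))
    velocities = np.empty((n_steps, ensemble.N))
    r_trace = np.empty(n_steps)
    for t in range(n_steps):
        phases[t] = theta
        v = drift(theta, ensemble)
        velocities[t] = v
        r_trace[t] = order_parameter(theta)
        theta = theta + config.dt * v
        if config.noise_sd > 0:
            theta = theta + noise_scale * rng.standard_normal(ensemble.N)
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"non-finite phase state after Euler step {t}")

    kept = slice(config.discard_steps, None)
    f_eff = velocities[kept].mean(axis=0) / (2.0 * np.pi)
    r_mean = float(r_trace[kept].mean())
    return TrialResult(
        phases=phases,
        phase_velocities=velocities,
        r_trace=r_trace,
        r_mean=r_mean,
        f_eff=f_eff,
        discard_steps=config.discard_steps,
    )


def mean_effective_frequency(trial: TrialResult, discard_steps: int | None = None) -> np.ndarray:
    """Mean effective frequency per oscillator in Hz.

    Averages the recorded instantaneous phase velocities over the
    post-transient steps and divides by 2*pi.  Uses the trial's own discard
    count unless an override is given.
    """
    d = trial.discard_steps if discard_steps is None else int(discard_steps)
    if d < 0:
        raise ValueError("discard_steps must be >= 0")
    if d >= trial.phase_velocities.shape[0]:
        raise ValueError(
            f"discard_steps ({d}) must be smaller than the trace length ({trial.phase_velocities.shape[0]})"
        )
    return trial.phase_velocities[d:].mean(axis=0) / (2.0 * np.pi)


def simulate_batch(
    omegas: np.ndarray,
    coupling: np.ndarray,
    config: SimulationConfig,
    initial_phases: np.ndarray,
    noise_seeds: Sequence[np.random.SeedSequence] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate B independent trials at once; return (r_mean, f_eff) per trial.

    Parameters
    ----------
    omegas:
        (B, N) intrinsic angular velocities per trial.
    coupling:
        (N, N) shared coupling matrix, or (B, N, N) per-trial matrices.
    initial_phases:
        (B, N) starting phases.
    noise_seeds:
        Per-trial seed sequences for the optional phase noise; required when
        ``config.noise_sd > 0`` so each trial keeps an independent stream.

    Returns
    -------
    r_mean : (B,) time-averaged order parameter after the transient.
    f_eff : (B, N) mean effective frequency in Hz after the transient.

    Only running sums are kept, so memory stays O(B*N) regardless of the
    number of steps.
    """
    omegas = np.asarray(omegas, dtype=float)
    if omegas.ndim != 2:
        raise ValueError("omegas must be (B, N)")
    B, N = omegas.shape
    M = np.asarray(coupling, dtype=float)
    if M.shape == (N, N):
        M = M[None, :, :]
    elif M.shape != (B, N, N):
        raise ValueError(f"coupling must be (N, N) or (B, N, N); got {M.shape}")
    theta = np.asarray(initial_phases, dtype=float).copy()
    if theta.shape != (B, N):
        raise ValueError(f"initial_phases must be (B, N) = ({B}, {N}); got {theta.shape}")

    n_steps = config.n_steps
    discard = config.discard_steps
    if discard >= n_steps:
        raise ValueError(f"discard_steps ({discard}) must be < n_steps ({n_steps})")

    noise = None
    if config.noise_sd > 0:
        if noise_seeds is None:
            raise ValueError("noise_seeds are required when noise_sd > 0")
        if len(noise_seeds) != B:
            raise ValueError("need one noise seed sequence per trial")
        scale = config.noise_sd * np.sqrt(config.dt)
        noise = np.stack(
            [scale * np.random.default_rng(ss).standard_normal((n_steps, N)) for ss in noise_seeds],
            axis=1,
        )  # (n_steps, B, N)

    vel_sum = np.zeros((B, N))
    r_sum = np.zeros(B)
    dt = config.dt
    for t in range(n_steps):
        diff = theta[:, None, :] - theta[:, :, None]  # [b, i, j] = theta_j - theta_i
        vel = omegas + (M * np.sin(diff)).sum(axis=2) / N
        if t >= discard:
            vel_sum += vel
            r_sum += order_parameter(theta)
        theta += dt * vel
        if noise is not None:
            theta += noise[t]
        if t % 100 == 99 and not np.all(np.isfinite(theta)):
            raise RuntimeError(f"non-finite phase state near Euler step {t}")

    kept = n_steps - discard
    return r_sum / kept, vel_sum / (kept * 2.0 * np.pi)
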