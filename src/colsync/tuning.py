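"""Contrast-to-frequency tuning of visual cortical oscillators.

Stimulus-induced gamma oscillations in early visual cortex have a peak
frequency that grows with stimulus contrast and saturates at high contrast.
This module represents that relationship as a three-parameter sigmoid

    f(c) = gamma / (1 + exp(-beta * c + alpha * beta))

where ``c`` is the stimulus contrast in percent, ``alpha`` is the inflection
contrast (the contrast at which the frequency reaches half its asymptote),
``beta`` the slope per percent contrast, and ``gamma`` the gain, i.e. the
asymptotic frequency in Hz.  The default parameter triple
(alpha=10.74, beta=0.057, gamma=44.77) was obtained by fitting macaque V1/V2
local-field-potential peak frequencies across contrasts.

Attention is modelled purely as *response gain*: attending a stimulus scales
the asymptote ``gamma`` of the population encoding it (default 49 Hz instead
of 44.77 Hz) while leaving the inflection and slope untouched.

Because the underlying electrophysiological dataset is restricted, the module
also ships a synthetic tuning-data generator (:func:`synthesize_tuning_data`)
that draws sigmoid-distributed peak frequencies with additive Gaussian noise;
:func:`fit_sigmoid` recovers the parameters from such tables (or from any
CSV of contrast/peak-frequency pairs) by bounded least squares.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SigmoidParams",
    "AttentionCondition",
    "TuningSample",
    "SigmoidFit",
    "DEFAULT_PARAMS",
    "DEFAULT_ATTENTION_GAIN_HZ",
    "intrinsic_frequency",
    "angular_velocity",
    "effective_params",
    "fit_sigmoid",
    "synthesize_tuning_data",
    "samples_to_frame",
    "frame_to_samples",
    "read_samples_csv",
    "write_samples_csv",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoidal contrast-frequency curve.

    Attributes
    ----------
    alpha:
        Inflection point in percent contrast; ``f(alpha) = gamma / 2``.
    beta:
        Slope of the sigmoid, per percent contrast.  Must be positive.
    gamma:
        Gain: the asymptotic oscillation frequency in Hz.  Must be positive.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta) and math.isfinite(self.gamma)):
            raise ValueError("sigmoid parameters must be finite")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    def to_dict(self) -> dict[str, float]:
        return {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}


#: Sigmoid parameters fitted to macaque V1/V2 LFP peak frequencies.
DEFAULT_PARAMS = SigmoidParams(alpha=10.74, beta=0.057, gamma=44.77)

#: Response gain (Hz) applied to attended populations.
DEFAULT_ATTENTION_GAIN_HZ = 49.0


@dataclass(frozen=True)
class AttentionCondition:
    """Which stimulus is attended and the response gain it receives.

    ``mode`` is one of ``"none"``, ``"target"`` or ``"flankers"``.  Attended
    populations have their sigmoid gain replaced by ``gamma_attended``
    (a *response gain* modulation; the inflection and slope are never touched).
    """

    mode: str = "none"
    gamma_attended: float = DEFAULT_ATTENTION_GAIN_HZ

    def __post_init__(self) -> None:
        if self.mode not in ("none", "target", "flankers"):
            raise ValueError(f"attention mode must be none/target/flankers, got {self.mode!r}")
        if self.gamma_attended <= 0:
            raise ValueError("gamma_attended must be positive")


@dataclass(frozen=True)
class TuningSample:
    """One (contrast, peak frequency) observation, with optional subject label."""

    contrast: float
    peak_frequency: float
    subject: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 100.0:
            raise ValueError(f"contrast must lie in [0, 100], got {self.contrast}")
        if self.peak_frequency <= 0:
            raise ValueError("peak_frequency must be positive")


def intrinsic_frequency(contrast, params: SigmoidParams = DEFAULT_PARAMS):
    """Intrinsic oscillation frequency (Hz) for a stimulus contrast in percent.

    Evaluates ``gamma / (1 + exp(-beta*c + alpha*beta))``.  Accepts scalars or
    arrays; the result is strictly increasing in contrast and bounded in
    ``(0, gamma)``.  Note that the curve does not pass through the origin:
    at zero contrast it still yields a nonzero baseline frequency, a documented
    property of the fitted sigmoid that we deliberately do not clamp.

    Raises
    ------
    ValueError
        If any contrast is negative or non-finite.
    """
    c = np.asarray(contrast, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("contrast must be finite")
    if np.any(c < 0):
        raise ValueError("contrast must be non-negative")
    out = params.gamma / (1.0 + np.exp(-params.beta * c + params.alpha * params.beta))
    return float(out) if np.isscalar(contrast) or out.ndim == 0 else out


def angular_velocity(frequency):
    """Convert frequency in Hz to angular velocity in rad/s (``omega = 2 pi f``)."""
    f = np.asarray(frequency, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("frequency must be finite")
    out = 2.0 * np.pi * f
    return float(out) if out.ndim == 0 else out


def effective_params(
    base: SigmoidParams,
    attention: AttentionCondition,
    population_role: str,
) -> SigmoidParams:
    """Sigmoid parameters a population actually uses under an attention condition.

    ``population_role`` is ``"target"`` or ``"flanker"``.  When the attended
    stimulus matches the population's role, the gain ``gamma`` is replaced by
    ``attention.gamma_attended``; otherwise the base parameters are returned
    unchanged.  Alpha and beta are never modified (response gain, not
    contrast gain).
    """
    if population_role not in ("target", "flanker"):
        raise ValueError(f"population_role must be 'target' or 'flanker', got {population_role!r}")
    attended = (attention.mode == "target" and population_role == "target") or (
        attention.mode == "flankers" and population_role == "flanker"
    )
    if not attended:
        return base
    return replace(base, gamma=attention.gamma_attended)


def synthesize_tuning_data(
    params: SigmoidParams = DEFAULT_PARAMS,
    contrasts: Sequence[float] = tuple(range(10, 100, 10)),
    noise_sd: float = 1.0,
    n_per_contrast: int = 10,
    seed: int = 0,
    subjects: Sequence[str] = ("synthetic-monkey-1", "synthetic-monkey-2"),
) -> list[TuningSample]:
    """Generate synthetic (contrast, peak frequency) samples from the sigmoid.

    A stand-in for the restricted LFP dataset: frequencies are the sigmoid
    value plus additive Gaussian noise of standard deviation ``noise_sd`` Hz.
    Samples are tagged with synthetic subject labels round-robin so that
    two-subject pooling (as done for the empirical fit) can be exercised.
    Deterministic for a fixed seed.
    """
    if len(contrasts) == 0:
        raise ValueError("contrasts must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_per_contrast < 1:
        raise ValueError("n_per_contrast must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[TuningSample] = []
    for c in contrasts:
        f0 = intrinsic_frequency(float(c), params)
        noise = rng.normal(0.0, noise_sd, size=n_per_contrast) if noise_sd > 0 else np.zeros(n_per_contrast)
        for k in range(n_per_contrast):
            freq = max(f0 + noise[k], 1e-6)  # peak frequencies are positive by construction
            samples.append(
                TuningSample(contrast=float(c), peak_frequency=float(freq), subject=subjects[k % len(subjects)])
            )
    return samples


@dataclass(frozen=True)
class SigmoidFit:
    """Result of a sigmoid fit: parameters plus diagnostics."""

    params: SigmoidParams
    rss: float
    converged: bool
    n_samples: int
    message: str = ""

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(rss=self.rss, converged=self.converged, n_samples=self.n_samples)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def fit_sigmoid(samples: Iterable[TuningSample]) -> SigmoidFit:
    """Fit the contrast-frequency sigmoid to tuning samples by least squares.

    Pooled, unweighted nonlinear least squares on the frequency residuals,
    with bounds alpha in (0, 100), beta in (1e-4, 1), gamma in (1, 200) and
    starting values alpha0 = median contrast, beta0 = 0.05, gamma0 = max
    observed frequency.  Subject labels are ignored (both subjects pooled).

    Raises
    ------
    ValueError
        For fewer than 4 samples or fewer than 2 distinct contrasts.

    Notes
    -----
    Degenerate data (e.g. constant frequency at every contrast, which leaves
    the slope unidentifiable) yields ``converged=False`` rather than an
    exception, so callers can flag rather than crash.
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError(f"need at least 4 samples, got {len(samples)}")
    c = np.array([s.contrast for s in samples], dtype=float)
    y = np.array([s.peak_frequency for s in samples], dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need samples at >= 2 distinct contrasts")

    def model(cc, alpha, beta, gamma):
        return gamma / (1.0 + np.exp(-beta * cc + alpha * beta))

    p0 = (float(np.median(c)), 0.05, float(np.max(y)))
    bounds = ([0.0, 1e-4, 1.0], [100.0, 1.0, 200.0])
    degenerate = float(np.ptp(y)) < 1e-9
    try:
        popt, _pcov, infodict, mesg, ier = optimize.curve_fit(
            model, c, y, p0=p0, bounds=bounds, full_output=True, maxfev=20000,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        resid = y - model(c, *popt)
        rss = float(resid @ resid)
        converged = bool(ier in (1, 2, 3, 4) or ier is None) and not degenerate
        # bounded trf reports ier=None; treat optimizer success as convergence
        fitted = SigmoidParams(alpha=float(popt[0]), beta=float(popt[1]), gamma=float(popt[2]))
        return SigmoidFit(params=fitted, rss=rss, converged=converged, n_samples=len(samples), message=str(mesg))
    except RuntimeError as err:  # optimizer failed to converge
        return SigmoidFit(params=SigmoidParams(*p0), rss=float("nan"), converged=False,
                          n_samples=len(samples), message=str(err))


# ---------------------------------------------------------------------------
# Delimited-table I/O (header: contrast,peak_frequency,subject)

_CSV_COLUMNS = ["contrast", "peak_frequency", "subject"]


def samples_to_frame(samples: Iterable[TuningSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.contrast, s.peak_frequency, s.subject) for s in samples], columns=_CSV_COLUMNS
    )


def frame_to_samples(frame: pd.DataFrame) -> list[TuningSample]:
    missing = [col for col in ("contrast", "peak_frequency") if col not in frame.columns]
    if missing:
        raise ValueError(f"tuning table is missing required column(s): {', '.join(missing)}")
    subjects = frame["subject"] if "subject" in frame.columns else [""] * len(frame)
    return [
        TuningSample(contrast=float(c), peak_frequency=float(f), subject=str(s))
        for c, f, s in zip(frame["contrast"], frame["peak_frequency"], subjects)
    ]


def write_samples_csv(samples: Iterable[TuningSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def read_samples_csv(path: str | Path) -> list[TuningSample]:
    return frame_to_samples(pd.read_csv(path))
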