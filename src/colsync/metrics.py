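"""Derived measures: switch points, Arnold-tongue geometry, locking boundaries.

The facilitation/suppression *switch point* is the target contrast at which
the target's frequency modulation delta_f crosses zero (located by linear
interpolation between grid cells).  Without attention it coincides with the
flanker contrast, because there the intrinsic frequencies of target and
flankers are equal.

The *synchronization region* (Arnold tongue) is the set of (contrast, K)
cells whose replicate-averaged order parameter exceeds a threshold.  Note
that an order-parameter threshold traces a contour strictly inside the
entrainment boundary: for two oscillators locked at phase lag phi the order
parameter is cos(phi/2), so r >= theta first holds at
K = |delta_omega| / sin(2*arccos(theta)), above the frequency-locking
boundary K = |delta_omega|.  Both closed forms are provided
(:func:`r_threshold_critical_coupling`, :func:`critical_coupling_two_oscillator`)
together with the matching empirical boundary extractors, so either notion of
"tongue" can be validated against its own analytic curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiments import SweepResult
from .tuning import DEFAULT_PARAMS, SigmoidParams, intrinsic_frequency

__all__ = [
    "SwitchPoint",
    "SyncRegion",
    "frequency_modulation",
    "find_switch_point",
    "switch_points_per_K",
    "extract_sync_region",
    "tongue_area",
    "critical_coupling_two_oscillator",
    "r_threshold_critical_coupling",
    "locking_boundary",
]


@dataclass(frozen=True)
class SwitchPoint:
    """Zero crossing of delta_f along the contrast axis at one coupling value.

    ``found`` is False when the row never changes sign; ``degenerate`` flags
    an (effectively) all-zero row where a crossing is meaningless.
    """

    contrast: float  # % (nan unless found)
    K: float
    found: bool
    degenerate: bool = False
    bracket: tuple[float, float] | None = None


@dataclass
class SyncRegion:
    """Thresholded synchronization mask over a (contrast, K) grid."""

    mask: np.ndarray  # (nC, nK) bool
    threshold: float
    target_contrasts: np.ndarray
    K_values: np.ndarray

    @property
    def area(self) -> int:
        """Number of synchronized grid cells."""
        return int(self.mask.sum())

    @property
    def contrast_extent_per_K(self) -> np.ndarray:
        """Synchronized contrast-cell count for each coupling value (nK,)."""
        return self.mask.sum(axis=0)


def frequency_modulation(sweep: SweepResult) -> np.ndarray:
    """delta_f grid (nC, nK): effective minus intrinsic frequency of the target, Hz.

    Positive values are facilitation (the target sped up toward the flankers),
    negative suppression.
    """
    return sweep.delta_f_target


def find_switch_point(
    delta_f_row: np.ndarray,
    contrasts: np.ndarray,
    K: float = float("nan"),
    zero_tol: float = 1e-9,
) -> SwitchPoint:
    """First zero crossing of a delta_f row, scanning from low contrast.

    Linear interpolation between the bracketing grid cells.  A row with no
    sign change returns ``found=False``; a row that is zero everywhere (within
    ``zero_tol``) is flagged degenerate.  When stochastic jitter produces
    several crossings, the first from low contrast wins.
    """
    d = np.asarray(delta_f_row, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    if d.shape != c.shape or d.size < 2:
        raise ValueError("delta_f row and contrast axis must match and have >= 2 points")
    if np.all(np.abs(d) <= zero_tol):
        return SwitchPoint(contrast=float("nan"), K=K, found=False, degenerate=True)
    for i in range(d.size - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            return SwitchPoint(contrast=float(c[i]), K=K, found=True, bracket=(float(c[i]), float(c[i])))
        if a * b < 0.0:
            x = c[i] + (c[i + 1] - c[i]) * a / (a - b)
            return SwitchPoint(contrast=float(x), K=K, found=True, bracket=(float(c[i]), float(c[i + 1])))
    if d[-1] == 0.0:
        return SwitchPoint(contrast=float(c[-1]), K=K, found=True, bracket=(float(c[-1]), float(c[-1])))
    return SwitchPoint(contrast=float("nan"), K=K, found=False)


def switch_points_per_K(sweep: SweepResult) -> pd.DataFrame:
    """Switch point for every coupling value; columns ``K, switch_contrast``.

    Rows without a crossing carry NaN.
    """
    delta = frequency_modulation(sweep)
    rows = []
    for ki, K in enumerate(sweep.K_values):
        sp = find_switch_point(delta[:, ki], sweep.target_contrasts, K=float(K))
        rows.append({"K": float(K), "switch_contrast": sp.contrast if sp.found else float("nan")})
    return pd.DataFrame(rows)


def extract_sync_region(sweep: SweepResult, threshold: float = 0.95) -> SyncRegion:
    """Cells whose replicate-averaged order parameter reaches ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return SyncRegion(
        mask=sweep.r_mean >= threshold,
        threshold=threshold,
        target_contrasts=np.asarray(sweep.target_contrasts),
        K_values=np.asarray(sweep.K_values),
    )


def tongue_area(region: SyncRegion, reference: SyncRegion | None = None) -> int:
    """Synchronized-cell count; with ``reference``, checks the grids match first."""
    if reference is not None:
        if region.mask.shape != reference.mask.shape or not (
            np.array_equal(region.target_contrasts, reference.target_contrasts)
            and np.array_equal(region.K_values, reference.K_values)
        ):
            raise ValueError("tongue areas are only comparable on identical grids")
    return region.area


def critical_coupling_two_oscillator(
    contrast: float,
    reference_contrast: float = 50.0,
    params: SigmoidParams = DEFAULT_PARAMS,
):
    """Closed-form entrainment boundary for two oscillators: K = 2*pi*|f(c) - f(ref)|.

    With coupling (K/2) per pairwise term, the phase difference obeys
    dphi/dt = delta_omega - K sin(phi), which has a fixed point iff
    K >= |delta_omega|.  Accepts scalar or array contrasts.
    """
    df = intrinsic_frequency(contrast, params) - intrinsic_frequency(reference_contrast, params)
    return 2.0 * np.pi * np.abs(df)


def r_threshold_critical_coupling(delta_omega, threshold: float = 0.95):
    """Coupling at which a locked two-oscillator pair first reaches order r >= threshold.

    A locked pair sits at phase lag phi* with sin(phi*) = delta_omega / K and
    order parameter cos(phi*/2); solving r = threshold gives
    K = |delta_omega| / sin(2*arccos(threshold)).  This lies strictly above
    the entrainment boundary (by a factor ~1.69 at threshold 0.95).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    phi = 2.0 * np.arccos(threshold)
    return np.abs(np.asarray(delta_omega, dtype=float)) / np.sin(phi)


def locking_boundary(
    sweep: SweepResult,
    mode: str = "frequency",
    freq_tol_hz: float = 0.3,
    r_threshold: float = 0.95,
) -> np.ndarray:
    """Empirical tongue boundary: smallest K per contrast column deemed locked.

    ``mode="frequency"`` calls a cell locked when the spread of the
    oscillators' mean effective frequencies is below ``freq_tol_hz`` (this is
    the entrainment boundary, comparable to
    :func:`critical_coupling_two_oscillator`); ``mode="order"`` uses
    ``r_mean >= r_threshold`` (comparable to
    :func:`r_threshold_critical_coupling`).  Returns one K per contrast, NaN
    where no coupling on the grid locks the column.
    """
    if mode == "frequency":
        spread = sweep.f_eff.max(axis=2) - sweep.f_eff.min(axis=2)  # (nC, nK)
        locked = spread < freq_tol_hz
    elif mode == "order":
        locked = sweep.r_mean >= r_threshold
    else:
        raise ValueError(f"mode must be 'frequency' or 'order', got {mode!r}")
    out = np.full(len(sweep.target_contrasts), np.nan)
    for ci in range(locked.shape[0]):
        hits = np.flatnonzero(locked[ci])
        if hits.size:
            out[ci] = sweep.K_values[hits[0]]
    return out
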