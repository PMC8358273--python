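"""Coupling matrices for the three-population flanker-target-flanker network.

The coupling strength K stands in for collinearity: populations whose
receptive-field contents are collinear are strongly coupled, orthogonal
arrangements weakly.  Populations are indexed ``(flanker_above, target,
flanker_below)``; entry ``M[i, j]`` is the coupling exerted *by* population
``j`` *on* population ``i``.  The phase dynamics divide the summed coupling
by N, so with a uniform matrix the classic mean-field Kuramoto form is
recovered exactly.

Besides the uniform scheme two asymmetries can be dialled in:

* ``ff_ratio`` scales the flanker-to-flanker coupling relative to the
  (fixed) flanker-target coupling K.
* ``directed_ratio`` makes flanker-to-target and target-to-flanker coupling
  unequal while keeping flanker-to-flanker coupling at K.  The ratio can be
  realized symmetrically (``sqrt`` split: K*sqrt(r) one way, K/sqrt(r) the
  other, preserving the geometric mean) or one-sidedly (flanker-to-target
  multiplied by r, target-to-flanker fixed at K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FLANKER_ABOVE",
    "TARGET",
    "FLANKER_BELOW",
    "CouplingSpec",
    "build_uniform",
    "build_ff_ratio",
    "build_directed",
    "build_coupling",
]

FLANKER_ABOVE = 0
TARGET = 1
FLANKER_BELOW = 2
_FLANKERS = (FLANKER_ABOVE, FLANKER_BELOW)


@dataclass(frozen=True)
class CouplingSpec:
    """Declarative description of a coupling scheme.

    ``scheme`` is one of ``"uniform"``, ``"ff_ratio"``, ``"directed_ratio"``.
    Ratios not used by the selected scheme must be 1.
    """

    K: float
    scheme: str = "uniform"
    ff_ratio: float = 1.0
    directed_ratio: float = 1.0
    asymmetric_split: str = "sqrt"

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"coupling strength K must be >= 0, got {self.K}")
        if self.ff_ratio <= 0 or self.directed_ratio <= 0:
            raise ValueError("coupling ratios must be positive")
        if self.scheme not in ("uniform", "ff_ratio", "directed_ratio"):
            raise ValueError(f"unknown coupling scheme {self.scheme!r}")
        if self.scheme == "uniform" and (self.ff_ratio != 1.0 or self.directed_ratio != 1.0):
            raise ValueError("uniform scheme requires both ratios = 1")
        if self.asymmetric_split not in ("sqrt", "one_sided"):
            raise ValueError(f"asymmetric_split must be 'sqrt' or 'one_sided', got {self.asymmetric_split!r}")

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "scheme": self.scheme,
            "ff_ratio": self.ff_ratio,
            "directed_ratio": self.directed_ratio,
            "asymmetric_split": self.asymmetric_split,
        }


def build_uniform(K: float) -> np.ndarray:
    """All-to-all coupling of strength K with zero diagonal."""
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    M = np.full((3, 3), float(K))
    np.fill_diagonal(M, 0.0)
    return M


def build_ff_ratio(K: float, ff_ratio: float) -> np.ndarray:
    """Flanker-flanker coupling scaled to ``K * ff_ratio``; flanker-target kept at K.

    The matrix stays symmetric for every ratio.
    """
    if ff_ratio <= 0:
        raise ValueError(f"ff_ratio must be positive, got {ff_ratio}")
    M = build_uniform(K)
    M[FLANKER_ABOVE, FLANKER_BELOW] = M[FLANKER_BELOW, FLANKER_ABOVE] = K * ff_ratio
    return M


def build_directed(K: float, directed_ratio: float, split: str = "sqrt") -> np.ndarray:
    """Asymmetric flanker-target coupling with ratio ``flanker->target / target->flanker``.

    Flanker-flanker coupling is kept at K.  With ``split="sqrt"`` the ratio is
    realized symmetrically around K (flanker->target = K*sqrt(r),
    target->flanker = K/sqrt(r)); with ``split="one_sided"`` only the
    flanker->target entries are scaled (by r) and target->flanker stays at K.
    Either way the realized entry ratio equals ``directed_ratio`` exactly.
    """
    if directed_ratio <= 0:
        raise ValueError(f"directed_ratio must be positive, got {directed_ratio}")
    if split == "sqrt":
        ft = K * np.sqrt(directed_ratio)  # flanker -> target
        tf = K / np.sqrt(directed_ratio)  # target -> flanker
    elif split == "one_sided":
        ft = K * directed_ratio
        tf = float(K)
    else:
        raise ValueError(f"split must be 'sqrt' or 'one_sided', got {split!r}")
    M = build_uniform(K)
    for fl in _FLANKERS:
        M[TARGET, fl] = ft
        M[fl, TARGET] = tf
    return M


def build_coupling(spec: CouplingSpec) -> np.ndarray:
    """Materialize a :class:`CouplingSpec` into its 3x3 coupling matrix."""
    if spec.scheme == "uniform":
        return build_uniform(spec.K)
    if spec.scheme == "ff_ratio":
        return build_ff_ratio(spec.K, spec.ff_ratio)
    return build_directed(spec.K, spec.directed_ratio, spec.asymmetric_split)
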