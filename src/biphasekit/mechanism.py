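"""Two-site enzyme-modifier kinetics behind the biphasic dose-response.

A minimal rapid-equilibrium scheme in which the same drug D both activates
and inhibits a Michaelis–Menten enzyme:

* an *activation site* (dissociation constant ``K_act``, stoichiometry
  ``n_act``) may be occupied on both free enzyme and the enzyme–substrate
  complex; its only kinetic effect is to facilitate substrate binding,
  dividing the Michaelis constant by ``alpha`` (> 1 = activation);
* an *inhibition site* (``K_inh``, ``n_inh``) exists only on
  substrate-bound states and forms a catalytically dead complex — the
  classic uncompetitive geometry of a drug bound next to the substrate.

With the occupancy weights ``a = (D/K_act)^n_act``, ``i = (D/K_inh)^n_inh``
and ``s = S/Km``, summing the rapid-equilibrium species fractions gives the
closed-form fractional velocity

    v / (kcat·E0) = s·(1 + a·alpha) / (1 + a + s·(1 + a·alpha)·(1 + i))

which reduces to Michaelis–Menten at D = 0 and, for ``alpha = 1`` and unit
stoichiometries, to the textbook uncompetitive form
``S / (Km + S·(1 + D/K_inh))``.

Activation is visible only at sub-saturating substrate: once S >> Km the
substrate no longer needs help binding, the a-dependent terms cancel, and
only the uncompetitive loss remains — which is why the same drugs give
bell-shaped dose-responses in cells (S << Km) and purely inhibitory ones in
saturated in-vitro assays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np

from .model import DoseResponseCurve

__all__ = [
    "MechanismParams",
    "ResponseClass",
    "velocity",
    "apparent_MM",
    "dose_response_curve",
    "classify_response",
    "peak_activation_ratio",
]


@dataclass(frozen=True)
class MechanismParams:
    """Kinetic constants of the two-site modifier scheme.

    kcat
        Turnover number (1/s); only scales :func:`apparent_MM` since rates
        are otherwise reported as fractions of ``kcat·E0``.
    Km
        Michaelis (substrate dissociation) constant, molar.
    K_act, n_act
        Dissociation constant (molar) and concerted stoichiometry of drug
        at the activation site.
    alpha
        Factor by which full activation-site occupancy divides the apparent
        Km (``alpha > 1`` = activation, ``alpha = 1`` = none).
    K_inh, n_inh
        Dissociation constant (molar) and stoichiometry of the dead-end
        uncompetitive site on the enzyme–substrate complex.
    """

    kcat: float
    Km: float
    K_act: float
    alpha: float
    K_inh: float
    n_act: float = 1.0
    n_inh: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kcat", "Km", "K_act", "alpha", "K_inh"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")
        if self.n_act < 1 or self.n_inh < 1:
            raise ValueError("site stoichiometries n_act, n_inh must be >= 1")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "MechanismParams":
        return cls(**{k: float(v) for k, v in d.items()})


class ResponseClass(str, Enum):
    FLAT = "flat"
    MONOTONE_INCREASING = "monotone_increasing"
    MONOTONE_DECREASING = "monotone_decreasing"
    BIPHASIC = "biphasic"


def _occupancies(params: MechanismParams, D: np.ndarray):
    a = (D / params.K_act) ** params.n_act
    i = (D / params.K_inh) ** params.n_inh
    return a, i


def velocity(params: MechanismParams, S, D):
    """Fractional rate v/(kcat·E0) at substrate S and drug D (both molar).

    ``velocity(params, S, 0)`` is exactly the Michaelis–Menten fraction
    ``S/(Km + S)``.
    """
    S = np.asarray(S, dtype=float)
    D = np.asarray(D, dtype=float)
    scalar = S.ndim == 0 and D.ndim == 0
    S, D = np.atleast_1d(S), np.atleast_1d(D)
    if np.any(S < 0) or np.any(D < 0):
        raise ValueError("substrate and drug concentrations must be non-negative")
    a, i = _occupancies(params, D)
    s = S / params.Km
    num = s * (1.0 + a * params.alpha)
    den = 1.0 + a + num * (1.0 + i)
    v = num / den
    return float(v[0]) if scalar else v


def apparent_MM(params: MechanismParams, D: float) -> tuple[float, float]:
    """Apparent Michaelis–Menten constants (Vmax_app, Km_app) at fixed drug.

    Analytic rearrangement of the rate law (with E0 = 1):

        Vmax_app = kcat / (1 + i)
        Km_app   = Km · (1 + a) / ((1 + a·alpha) · (1 + i))

    The uncompetitive signature follows: for ``alpha = 1`` both constants
    shrink by the same ``1/(1 + i)`` factor, so Vmax_app/Km_app is
    independent of D.
    """
    if D < 0:
        raise ValueError("drug concentration must be non-negative")
    a, i = _occupancies(params, np.asarray(float(D)))
    vmax_app = params.kcat / (1.0 + i)
    km_app = params.Km * (1.0 + a) / ((1.0 + a * params.alpha) * (1.0 + i))
    return float(vmax_app), float(km_app)


def dose_response_curve(params: MechanismParams, S: float, dose_grid) -> DoseResponseCurve:
    """Velocity over a dose grid, normalized so that v(S, 0) = 100 %.

    The grid (molar, strictly increasing) may include 0; the normalizing
    zero-dose rate is computed whether or not 0 is on the grid.
    """
    if S <= 0:
        raise ValueError("substrate concentration must be positive")
    grid = np.asarray(dose_grid, dtype=float)
    v = velocity(params, S, grid)
    v0 = velocity(params, S, 0.0)
    return DoseResponseCurve(grid, 100.0 * v / v0)


def classify_response(curve: DoseResponseCurve, tolerance: float = 1.0) -> ResponseClass:
    """Classify a dose-response curve as flat / monotone / biphasic.

    ``biphasic`` requires the maximum to exceed *both* endpoint responses by
    more than ``tolerance`` (same units as the responses; default 1 for
    %-normalized curves).  Monotone classes require every consecutive
    difference to stay on one side of ±tolerance; anything within tolerance
    of constant is ``flat``.
    """
    r = np.asarray(curve.responses, dtype=float)
    if len(r) < 3:
        raise ValueError("classification needs a dose grid with >= 3 points")
    if r.max() - r.min() <= tolerance:
        return ResponseClass.FLAT
    if r.max() > r[0] + tolerance and r.max() > r[-1] + tolerance:
        return ResponseClass.BIPHASIC
    d = np.diff(r)
    if np.all(d <= tolerance) and r[0] - r[-1] > tolerance:
        return ResponseClass.MONOTONE_DECREASING
    if np.all(d >= -tolerance) and r[-1] - r[0] > tolerance:
        return ResponseClass.MONOTONE_INCREASING
    # interior minimum or irregular shape: fall back to the net change
    if r[-1] >= r[0]:
        return ResponseClass.MONOTONE_INCREASING
    return ResponseClass.MONOTONE_DECREASING


def peak_activation_ratio(params: MechanismParams, S: float, dose_grid) -> float:
    """max over the dose grid of v(S, D) / v(S, 0).

    For ``alpha > 1`` this peak-over-baseline ratio decays toward 1 as S/Km
    grows — saturating substrate suppresses the activation phase.
    """
    curve = dose_response_curve(params, S, dose_grid)
    return float(curve.responses.max() / 100.0)
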