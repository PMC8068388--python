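"""Biphasic (bell-shaped) activation–inhibition dose-response model.

Many γ-secretase-targeting drugs raise Aβ1-40 production above the vehicle
baseline at low concentration and suppress it at high concentration.  That
shape is described by the sum of a rising and a falling logistic transition
in log10 drug concentration::

    S(x) = PA + (MA - PA) * A(x) - (MA - MI) * I(x),      x = log10(conc)

    A(x) = 1 / (1 + 10^((log10_EC50 - x) * p))            (activation)
    I(x) = 1 / (1 + 10^((log10_IC50 - x) * q))            (inhibition)

with the limits

* ``S(0) = PA`` — baseline activity at zero drug (DMSO vehicle),
* ``S -> MI`` as conc -> ∞ — residual activity at saturating drug,
* ``S`` plateaus near ``MA`` when the two transitions are well separated
  (the hypothetical activation level with no competing inhibition).

``p`` and ``q`` are Hill coefficients; values above one indicate that more
than one drug molecule binds per transition.  Concentrations are molar and
midpoints are stored as log10 of molar concentration, matching the
logarithmic dose axis on which these curves are fitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "BiphasicParams",
    "DoseResponseCurve",
    "PeakResult",
    "evaluate_biphasic",
    "activation_component",
    "inhibition_component",
    "peak_response",
]

_LN10 = math.log(10.0)

# Field order matters: it is the JSON serialization order and the order used
# by the fitting module when mapping parameter vectors to names.
PARAM_NAMES = ("PA", "MA", "MI", "log10_EC50", "log10_IC50", "p", "q")


@dataclass(frozen=True)
class BiphasicParams:
    """The seven parameters of the biphasic dose-response model.

    PA
        Baseline activity at zero drug (response units, e.g. % of vehicle
        or pM Aβ1-40).
    MA
        Maximal activated plateau that would be reached with no competing
        inhibition (same units).  ``MA == PA`` encodes "no activation".
    MI
        Residual activity plateau at saturating drug (same units).
    log10_EC50, log10_IC50
        log10 of the activation / inhibition midpoint concentrations (molar).
    p, q
        Hill coefficients of the activation / inhibition transitions.

    The constructor enforces: all fields finite, ``p > 0``, ``q > 0``,
    ``PA >= 0``, ``MI >= 0`` and ``MI <= MA``.  ``MA >= PA`` holds for any
    physically meaningful activation but is deliberately *not* enforced, so
    that unconstrained regression output remains representable; use
    :attr:`has_activation` to test for it.
    """

    PA: float
    MA: float
    MI: float
    log10_EC50: float
    log10_IC50: float
    p: float
    q: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        if self.p <= 0 or self.q <= 0:
            raise ValueError(f"Hill coefficients must be positive (p={self.p}, q={self.q})")
        if self.PA < 0 or self.MI < 0:
            raise ValueError(f"PA and MI must be non-negative (PA={self.PA}, MI={self.MI})")
        if self.MI > self.MA:
            raise ValueError(f"MI must not exceed MA (MI={self.MI}, MA={self.MA})")

    @property
    def has_activation(self) -> bool:
        """True when the activation plateau lies above the baseline."""
        return self.MA > self.PA

    @property
    def EC50(self) -> float:
        """Activation midpoint concentration in molar."""
        return 10.0 ** self.log10_EC50

    @property
    def IC50(self) -> float:
        """Inhibition midpoint concentration in molar."""
        return 10.0 ** self.log10_IC50

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "BiphasicParams":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})

    @classmethod
    def from_json(cls, s: str) -> "BiphasicParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class DoseResponseCurve:
    """An ordered dose grid with one response value per dose.

    Concentrations are molar, strictly increasing, and may start at 0
    (vehicle).  Responses are in whatever unit the producing stage used
    (% of the zero-dose rate for mechanism-generated curves).
    """

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.ndim != 1 or conc.shape != resp.shape:
            raise ValueError("concentrations and responses must be 1-D and equally long")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    def __len__(self) -> int:
        return len(self.concentrations)


def _as_conc_array(conc) -> tuple[np.ndarray, bool]:
    arr = np.asarray(conc, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValueError("concentration must be non-negative (molar)")
    if np.any(~np.isfinite(arr)):
        raise ValueError("concentration must be finite")
    return arr, scalar


def _logistics(params: BiphasicParams, conc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rising activation and inhibition occupancies A(x), I(x).

    conc == 0 is an exact special case (both occupancies are 0), not a
    pseudo-log floor.
    """
    pos = conc > 0
    x = np.full_like(conc, -np.inf)
    x[pos] = np.log10(conc[pos])
    A = np.zeros_like(conc)
    I = np.zeros_like(conc)
    # expit keeps both tails finite where direct 10**(...) would overflow
    A[pos] = expit(_LN10 * params.p * (x[pos] - params.log10_EC50))
    I[pos] = expit(_LN10 * params.q * (x[pos] - params.log10_IC50))
    return A, I


def _effective(params: BiphasicParams, mi_as_magnitude: bool) -> BiphasicParams:
    if not mi_as_magnitude:
        return params
    # Alternative reading: MI is the magnitude of maximal inhibition below
    # MA, so the residual plateau is MA - MI.
    return BiphasicParams(
        PA=params.PA,
        MA=params.MA,
        MI=params.MA - params.MI,
        log10_EC50=params.log10_EC50,
        log10_IC50=params.log10_IC50,
        p=params.p,
        q=params.q,
    )


def evaluate_biphasic(params: BiphasicParams, conc, *, mi_as_magnitude: bool = False):
    """Evaluate S(conc) for molar concentration(s) ``conc``.

    Parameters
    ----------
    params
        Model parameters; ``MI`` is read as the residual-activity plateau.
    conc
        Scalar or array of molar concentrations, all ``>= 0``.  ``conc == 0``
        returns exactly ``PA``.
    mi_as_magnitude
        If True, reinterpret ``params.MI`` as the magnitude of maximal
        inhibition (residual plateau ``MA - MI``) instead of the residual
        plateau itself.
    """
    params = _effective(params, mi_as_magnitude)
    arr, scalar = _as_conc_array(conc)
    A, I = _logistics(params, arr)
    s = params.PA + (params.MA - params.PA) * A - (params.MA - params.MI) * I
    return float(s[0]) if scalar else s


def activation_component(params: BiphasicParams, conc):
    """The activation curve alone: PA + (MA - PA) * A(x).

    Equals :func:`evaluate_biphasic` when ``MI == MA`` (no inhibition).
    """
    arr, scalar = _as_conc_array(conc)
    A, _ = _logistics(params, arr)
    s = params.PA + (params.MA - params.PA) * A
    return float(s[0]) if scalar else s


def inhibition_component(params: BiphasicParams, conc, *, mi_as_magnitude: bool = False):
    """The inhibition curve alone: MA - (MA - MI) * I(x).

    This is the large-concentration behaviour of the full model once the
    activation transition is saturated (EC50 << conc).
    """
    params = _effective(params, mi_as_magnitude)
    arr, scalar = _as_conc_array(conc)
    _, I = _logistics(params, arr)
    s = params.MA - (params.MA - params.MI) * I
    return float(s[0]) if scalar else s


class PeakResult(NamedTuple):
    """Location and height of the response maximum in a dose window."""

    conc_at_peak: float
    peak_response: float
    monotone_in_window: bool


def peak_response(
    params: BiphasicParams,
    conc_window: tuple[float, float],
    *,
    n_grid: int = 257,
    mi_as_magnitude: bool = False,
) -> PeakResult:
    """Locate the maximum of S over ``conc_window`` (molar, lower bound > 0).

    A coarse log-spaced grid scan brackets the maximum, which is then
    refined by bounded scalar maximization in log10 concentration.  If the
    refined peak does not exceed the larger window-edge response, the curve
    is flagged monotone (or flat) in the window and the edge value is
    returned.
    """
    lo, hi = float(conc_window[0]), float(conc_window[1])
    if not (0 < lo < hi):
        raise ValueError(f"conc_window must satisfy 0 < lower < upper, got {conc_window!r}")
    eff = _effective(params, mi_as_magnitude)

    xlo, xhi = math.log10(lo), math.log10(hi)
    xs = np.linspace(xlo, xhi, n_grid)
    vals = evaluate_biphasic(eff, 10.0 ** xs)
    k = int(np.argmax(vals))

    a = xs[max(k - 1, 0)]
    b = xs[min(k + 1, n_grid - 1)]
    if a < b:
        res = minimize_scalar(
            lambda x: -evaluate_biphasic(eff, 10.0 ** x),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-12},
        )
        x_peak, peak = float(res.x), float(-res.fun)
    else:  # pragma: no cover - degenerate 1-point bracket
        x_peak, peak = float(xs[k]), float(vals[k])

    edge = max(float(vals[0]), float(vals[-1]))
    scale = max(abs(eff.MA), abs(eff.PA), 1.0)
    if peak <= edge + 1e-9 * scale:
        x_edge = xs[0] if vals[0] >= vals[-1] else xs[-1]
        return PeakResult(10.0 ** float(x_edge), edge, True)
    return PeakResult(10.0 ** x_peak, peak, False)
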