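"""Closed-form sigmoid binding models and the ODEs they solve.

Immunoassay titrations record bound-antibody signal against the logarithm of
antigen concentration.  Three nested models are provided:

* the four-parameter logistic (4PL), the symmetric textbook dose-response
  curve, which solves the logistic growth equation in log-concentration;
* the five-parameter logistic (5PL), the conventional asymmetric extension
  used for assay calibration (included for comparison only -- its midpoint
  parameter is *not* the inflection point);
* the generalized logistic (Richards) curve, which solves
  ``da/dx = (r/nu) * a * (1 - a**nu)`` with ``x = ln[Ag]`` and is
  parameterized so that the log inflection point ``ln [Ag]_i`` is itself a
  parameter.  ``[Ag]_i`` estimates the apparent dissociation constant of the
  bound antibody pool and ``1/nu`` its limiting activity coefficient.

All models use natural logarithms internally; a base-10 rate is ``r*ln(10)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "NU_MIN",
    "NU_MAX",
    "GLParams",
    "FourPLParams",
    "FivePLParams",
    "BoundFraction",
    "gl_value",
    "gl_ode_rhs",
    "logistic_ode_rhs",
    "fourpl_value",
    "fivepl_value",
    "gl_inflection",
    "gl_solve_ode",
]

# nu outside this range makes (.)**(-1/nu) numerically meaningless
NU_MIN = 1e-4
NU_MAX = 1e3
_EXP_CLIP = 700.0  # exp argument beyond this overflows float64


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class GLParams:
    """Richards-curve parameters in measurement (signal) space.

    ``s_floor``  lower asymptote, signal units.
    ``s_span``   upper minus lower asymptote, signal units, > 0.
    ``rate``     growth rate per natural-log unit of concentration, >= 0.
    ``log_infl`` natural log of the inflection concentration [Ag]_i (mol/L).
    ``nu``       asymmetry exponent, in [1e-4, 1e3]; nu=1 is the logistic.

    The normalized (fraction-bound) form has ``s_floor=0, s_span=1``.
    """

    s_floor: float
    s_span: float
    rate: float
    log_infl: float
    nu: float

    def __post_init__(self) -> None:
        _require_finite(
            "GLParams", self.s_floor, self.s_span, self.rate, self.log_infl, self.nu
        )
        if self.s_span <= 0:
            raise ValueError(f"s_span must be > 0, got {self.s_span}")
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if not (NU_MIN <= self.nu <= NU_MAX):
            raise ValueError(f"nu must lie in [{NU_MIN}, {NU_MAX}], got {self.nu}")

    @property
    def normalized(self) -> "GLParams":
        return GLParams(0.0, 1.0, self.rate, self.log_infl, self.nu)


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic: a Richards curve with ``nu`` fixed to 1."""

    s_floor: float
    s_span: float
    rate: float
    log_infl: float

    def __post_init__(self) -> None:
        _require_finite(
            "FourPLParams", self.s_floor, self.s_span, self.rate, self.log_infl
        )
        if self.s_span <= 0:
            raise ValueError(f"s_span must be > 0, got {self.s_span}")
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")

    def as_gl(self) -> GLParams:
        return GLParams(self.s_floor, self.s_span, self.rate, self.log_infl, 1.0)


@dataclass(frozen=True)
class FivePLParams:
    """Conventional 5PL calibration curve.

    ``c_mid`` (mol/L) is the Hill-type midpoint of the inner logistic; for
    ``asym_g != 1`` it is *not* the inflection point of the curve, which is
    the reason the Richards parameterization is preferred for interpretation.
    """

    s_floor: float
    s_span: float
    slope_b: float
    c_mid: float
    asym_g: float

    def __post_init__(self) -> None:
        _require_finite(
            "FivePLParams", self.s_floor, self.s_span, self.slope_b, self.c_mid, self.asym_g
        )
        if self.s_span <= 0:
            raise ValueError(f"s_span must be > 0, got {self.s_span}")
        if self.c_mid <= 0:
            raise ValueError(f"c_mid must be > 0, got {self.c_mid}")
        if self.asym_g <= 0:
            raise ValueError(f"asym_g must be > 0, got {self.asym_g}")


@dataclass(frozen=True)
class BoundFraction:
    """Fraction of total antibody bound, a = Ab_bound / Ab_total, in [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        _require_finite("BoundFraction", self.value)
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"bound fraction must lie in [0, 1], got {self.value}")


def _as_fraction(a) -> np.ndarray:
    a = np.asarray(getattr(a, "value", a), dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("bound fraction must be finite")
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError("bound fraction must lie in [0, 1]")
    return a


def _softplus(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)) without overflow."""
    z = np.asarray(z, dtype=float)
    out = np.where(z > 33.0, z, np.log1p(np.exp(np.minimum(z, 33.0))))
    return out


def gl_value(log_ag, p: GLParams):
    """Richards curve: s_floor + s_span * (1 + nu*exp(-r*(x - x_i)))**(-1/nu).

    ``log_ag`` is ln of antigen concentration in mol/L (scalar or array).
    Strictly increasing in ``log_ag`` for rate > 0, from ``s_floor`` to
    ``s_floor + s_span``.
    """
    x = np.asarray(log_ag, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_ag must be finite")
    t = np.clip(-p.rate * (x - p.log_infl), -_EXP_CLIP, _EXP_CLIP)
    # a = exp(-log(1 + nu*e^t)/nu), stable via softplus of t + ln(nu)
    a = np.exp(-_softplus(t + np.log(p.nu)) / p.nu)
    out = p.s_floor + p.s_span * a
    return out if out.ndim else float(out)


def gl_ode_rhs(a, p: GLParams):
    """Right-hand side (rate/nu) * a * (1 - a**nu) of the Richards ODE.

    ``a`` is the bound fraction; the independent variable is ln[Ag].
    Fixed points at a=0 and a=1 exactly.
    """
    av = _as_fraction(a)
    out = (p.rate / p.nu) * av * (1.0 - av**p.nu)
    return out if out.ndim else float(out)


def logistic_ode_rhs(a, rate: float):
    """Logistic growth rate r * a * (1 - a): the nu=1 Richards RHS."""
    av = _as_fraction(a)
    _require_finite("rate", rate)
    out = rate * av * (1.0 - av)
    return out if out.ndim else float(out)


def fourpl_value(log_ag, p: FourPLParams):
    """4PL sigmoid, symmetric about its inflection at ``log_infl``."""
    x = np.asarray(log_ag, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("log_ag must be finite")
    out = p.s_floor + p.s_span * expit(p.rate * (x - p.log_infl))
    return out if out.ndim else float(out)


def fivepl_value(ag, p: FivePLParams):
    """5PL curve s_floor + s_span * (1 + (ag/c_mid)**(-b))**(-g).

    ``ag`` is antigen concentration in mol/L, > 0; increasing for slope_b > 0.
    Reduces to the 4PL (rate=slope_b, log_infl=ln c_mid) at asym_g=1.
    """
    agv = np.asarray(ag, dtype=float)
    if not np.all(np.isfinite(agv)) or np.any(agv <= 0):
        raise ValueError("ag must be finite and > 0")
    z = np.clip(-p.slope_b * (np.log(agv) - np.log(p.c_mid)), -_EXP_CLIP, _EXP_CLIP)
    out = p.s_floor + p.s_span * np.exp(-p.asym_g * _softplus(z))
    return out if out.ndim else float(out)


def gl_inflection(p: GLParams) -> tuple[float, float]:
    """Inflection point of the Richards curve.

    Returns ``(log_infl, s_floor + s_span * (1 + nu)**(-1/nu))``: the
    maximal-slope abscissa is the parameter itself, and the fraction bound
    there is ``(1+nu)**(-1/nu)`` (1/2 for the logistic, 1/e in the Gompertz
    limit nu -> 0).
    """
    value = p.s_floor + p.s_span * (1.0 + p.nu) ** (-1.0 / p.nu)
    return p.log_infl, float(value)


def gl_solve_ode(p: GLParams, log_ag_grid, a0) -> np.ndarray:
    """Numerically integrate the Richards ODE along a log-concentration grid.

    Verification oracle for :func:`gl_value`: starting from bound fraction
    ``a0`` at the first grid point, returns the integrated fraction at every
    grid point.  ``a0`` must be strictly inside (0, 1); the fixed points 0 and
    1 give degenerate (constant) trajectories and are rejected.
    """
    grid = np.asarray(log_ag_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("log_ag_grid must be a strictly increasing 1-D array")
    a0v = float(getattr(a0, "value", a0))
    if not (0.0 < a0v < 1.0):
        raise ValueError("a0 must lie strictly inside (0, 1)")

    def rhs(_x: float, a: np.ndarray) -> np.ndarray:
        ac = np.clip(a, 0.0, 1.0)
        return (p.rate / p.nu) * ac * (1.0 - ac**p.nu)

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        [a0v],
        t_eval=grid,
        method="DOP853",
        rtol=1e-12,
        # for rate > 0 the trajectory is monotone increasing from a0, so an
        # absolute tolerance scaled to a0 keeps the relative error controlled
        # even when the grid starts deep in the lower tail (a0 ~ 1e-25)
        atol=max(a0v * 1e-12, 1e-300),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]
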