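"""Thermodynamic reading of fitted binding-curve parameters.

The inflection concentration of a Richards fit, [Ag]_i = exp(log_infl),
estimates the apparent equilibrium dissociation constant of the antibody
pool bound to the antigen; the associated standard chemical potential is
RT*ln(Kd/c0) with standard state c0 = 1 mol/L (dissociation convention:
sub-molar Kd gives a negative value, and higher affinity a more negative
one).  The asymmetry exponent maps to the limiting activity coefficient of
antigen at infinite antibody dilution, gamma_inf = 1/nu, the proposed
readout of the clonal composition of the binding pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import math

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import FitResult

__all__ = [
    "GAS_CONSTANT",
    "STANDARD_CONC",
    "DEFAULT_TEMPERATURE",
    "Activity",
    "DerivedQuantities",
    "activity",
    "limiting_activity_coefficient",
    "derive_quantities",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)
STANDARD_CONC = 1.0  # mol/L standard state
DEFAULT_TEMPERATURE = 298.15  # K


@dataclass(frozen=True)
class Activity:
    """Relative thermodynamic activity a = gamma * c / c0 (dimensionless)."""

    value: float
    gamma: float
    conc: float


@dataclass(frozen=True)
class DerivedQuantities:
    """Thermodynamic descriptors derived from a Richards fit.

    ``ag_infl``           inflection concentration [Ag]_i, mol/L.
    ``kd_apparent``       apparent dissociation constant, mol/L (= ag_infl).
    ``delta_mu_standard`` standard chemical potential RT*ln(Kd/c0), J/mol.
    ``gamma_inf``         limiting activity coefficient 1/nu, dimensionless.
    ``temperature``       K.
    """

    ag_infl: float
    kd_apparent: float
    delta_mu_standard: float
    gamma_inf: float
    temperature: float


def activity(conc: float, gamma: float) -> Activity:
    """Relative activity of antigen at concentration ``conc`` (mol/L).

    ``gamma`` adjusts concentration to effective (interaction-corrected)
    concentration; the result is made dimensionless by the 1 mol/L standard
    state.
    """
    if not (conc >= 0):
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if not (gamma > 0):
        raise ValueError(f"activity coefficient must be > 0, got {gamma}")
    return Activity(value=gamma * conc / STANDARD_CONC, gamma=gamma, conc=conc)


def limiting_activity_coefficient(nu: float) -> float:
    """Limiting activity coefficient gamma_inf = 1/nu of the fitted exponent."""
    if not (nu > 0):
        raise ValueError(f"nu must be > 0, got {nu}")
    return 1.0 / nu


def derive_quantities(
    fit: "FitResult", temperature: float = DEFAULT_TEMPERATURE
) -> DerivedQuantities:
    """Convert a converged Richards fit into thermodynamic descriptors.

    Requires a converged generalized-logistic fit of an *antigen* titration;
    the symmetric 4PL and the 5PL carry no ``nu`` and are not accepted.
    """
    from .fitting import ModelKind

    if fit.model is not ModelKind.GL:
        raise ValueError("derived quantities are defined for the GL model only")
    if not fit.converged:
        raise ValueError("cannot derive quantities from a non-converged fit")
    if not (temperature > 0):
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    kd = math.exp(fit.params.log_infl)
    return DerivedQuantities(
        ag_infl=kd,
        kd_apparent=kd,
        delta_mu_standard=GAS_CONSTANT * temperature * math.log(kd / STANDARD_CONC),
        gamma_inf=limiting_activity_coefficient(fit.params.nu),
        temperature=temperature,
    )
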