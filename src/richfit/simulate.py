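"""Synthetic mono- and polyclonal binding data with known ground truth.

A polyclonal serum is represented as a mixture of antibody clones, each a
single-site (Langmuir) binder with its own dissociation constant and total
binding-site concentration.  Two regimes are provided:

* ``independent_sites`` -- clones bind independently at the nominal antigen
  concentration (antibody-dilute limit); the aggregate bound fraction is a
  concentration-weighted mixture of Langmuir isotherms;
* ``competitive`` -- all clones share one epitope and compete for a finite
  antigen pool; free antigen is found from the mass balance
  ``ag_total = ag_free * (1 + sum_j c_j/(Kd_j + ag_free))``.

A single-clone Langmuir titration is exactly the nu=1 logistic in
log-concentration with inflection at ln(Kd), which is what makes this
simulator the ground-truth oracle for the Richards-curve interpretation:
heterogeneous mixtures broaden and asymmetrize the aggregate curve, pushing
the fitted nu away from 1.

Scenario presets emulate the contrast between an ongoing (active) antibody
response -- many clones, broad affinity spread -- and a memory-phase serum
-- few, affinity-matured clones with a narrow spread.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .fitting import TitrationSeries

__all__ = [
    "Regime",
    "Clone",
    "ClonalMixture",
    "AssayConfig",
    "bound_fraction_independent",
    "solve_competitive",
    "total_bound",
    "simulate_titration",
    "generate_mixture",
    "scenario",
    "log_conc_grid",
    "heterogeneity_sweep",
]


class Regime(str, enum.Enum):
    INDEPENDENT = "independent_sites"
    COMPETITIVE = "competitive"


@dataclass(frozen=True)
class Clone:
    """One antibody clone: dissociation constant and binding-site concentration."""

    kd: float  # mol/L
    conc_total: float  # mol/L of binding sites

    def __post_init__(self) -> None:
        if not (self.kd > 0 and np.isfinite(self.kd)):
            raise ValueError(f"kd must be finite and > 0, got {self.kd}")
        if not (self.conc_total >= 0 and np.isfinite(self.conc_total)):
            raise ValueError(f"conc_total must be finite and >= 0, got {self.conc_total}")


@dataclass(frozen=True)
class ClonalMixture:
    """A set of clones standing in for a polyclonal serum.

    In the competitive regime every clone targets the same epitope.
    """

    clones: tuple
    regime: Regime = Regime.INDEPENDENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "clones", tuple(self.clones))
        object.__setattr__(self, "regime", Regime(self.regime))
        if len(self.clones) < 1:
            raise ValueError("a mixture needs at least one clone")

    @property
    def kd(self) -> np.ndarray:
        return np.array([c.kd for c in self.clones])

    @property
    def conc(self) -> np.ndarray:
        return np.array([c.conc_total for c in self.clones])

    @property
    def conc_total(self) -> float:
        return float(self.conc.sum())


@dataclass(frozen=True)
class AssayConfig:
    """Assay read-out: concentration grid, gain, background and noise.

    Noise is multiplicative log-normal with median 1 and coefficient of
    variation ``noise_cv`` (fluorescence-like); ``additive_sd`` optionally
    adds Gaussian noise in signal units on top.
    """

    conc_grid: np.ndarray
    noise_cv: float = 0.0
    replicates: int = 1
    signal_per_bound: float = 1e9  # assay units per mol/L bound
    background: float = 0.0
    seed: int = 0
    additive_sd: float = 0.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.conc_grid, dtype=float)
        object.__setattr__(self, "conc_grid", grid)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("conc_grid must be a 1-D array with >= 2 points")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("conc_grid must be positive and strictly increasing")
        if self.noise_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def log_conc_grid(center: float, decades: float = 3.0, n: int = 12) -> np.ndarray:
    """Log-spaced concentrations spanning ``center`` +/- ``decades`` decades."""
    if not (center > 0):
        raise ValueError("center must be > 0")
    return np.logspace(np.log10(center) - decades, np.log10(center) + decades, n)


def bound_fraction_independent(
    mix: ClonalMixture, ag_free: float
) -> tuple[np.ndarray, float]:
    """Per-clone and aggregate bound fraction at free antigen ``ag_free``.

    Each clone follows its Langmuir isotherm ``ag/(Kd + ag)``; the aggregate
    is the binding-site-concentration-weighted mean, i.e. total bound
    antibody over total antibody.
    """
    if not (ag_free >= 0):
        raise ValueError(f"ag_free must be >= 0, got {ag_free}")
    frac = ag_free / (mix.kd + ag_free)
    total = mix.conc_total
    agg = float(mix.conc @ frac / total) if total > 0 else 0.0
    return frac, agg


def solve_competitive(mix: ClonalMixture, ag_total: float) -> tuple[float, np.ndarray]:
    """Free antigen and per-clone bound antigen under shared-epitope competition.

    Solves the mass balance ``ag_total = ag_free*(1 + sum c_j/(Kd_j+ag_free))``
    by bracketed root finding on [0, ag_total]; the left side is strictly
    increasing in ``ag_free`` so the root is unique.  Conservation holds to
    better than 1e-9 relative.
    """
    if mix.regime is not Regime.COMPETITIVE:
        raise ValueError("solve_competitive requires a competitive-regime mixture")
    if not (ag_total >= 0):
        raise ValueError(f"ag_total must be >= 0, got {ag_total}")
    kd, c = mix.kd, mix.conc
    if ag_total == 0.0 or mix.conc_total == 0.0:
        ag_free = float(ag_total)
        bound = c * ag_free / (kd + ag_free) if ag_total else np.zeros_like(c)
        return ag_free, bound

    def balance(x: float) -> float:
        return x * (1.0 + np.sum(c / (kd + x))) - ag_total

    ag_free = brentq(balance, 0.0, ag_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    bound = c * ag_free / (kd + ag_free)
    return float(ag_free), bound


def total_bound(mix: ClonalMixture, ag_total: float) -> float:
    """Total bound antibody (mol/L) at nominal antigen ``ag_total``."""
    if mix.regime is Regime.COMPETITIVE:
        _, bound = solve_competitive(mix, ag_total)
        return float(bound.sum())
    frac, _ = bound_fraction_independent(mix, ag_total)
    return float(mix.conc @ frac)


def simulate_titration(mix: ClonalMixture, assay: AssayConfig) -> TitrationSeries:
    """Simulate one titration series under the assay model.

    ``signal = background + signal_per_bound * bound * lognormal(median 1,
    CV noise_cv) [+ N(0, additive_sd)]`` per replicate; deterministic for a
    given ``assay.seed``.
    """
    bound = np.array([total_bound(mix, ag) for ag in assay.conc_grid])
    clean = assay.signal_per_bound * bound
    rng = np.random.default_rng(assay.seed)
    shape = (assay.conc_grid.size, assay.replicates)
    mult = np.ones(shape)
    if assay.noise_cv > 0:
        sigma = np.sqrt(np.log1p(assay.noise_cv**2))
        mult = np.exp(rng.normal(0.0, sigma, shape))
    signal = assay.background + clean[:, None] * mult
    if assay.additive_sd > 0:
        signal = signal + rng.normal(0.0, assay.additive_sd, shape)
    if assay.replicates == 1:
        signal = signal[:, 0]
    meta = {
        "antigen": "synthetic",
        "regime": mix.regime.value,
        "n_clones": len(mix.clones),
        "noise_cv": assay.noise_cv,
        "seed": assay.seed,
    }
    return TitrationSeries(conc=assay.conc_grid, signal=signal, meta=meta)


def generate_mixture(
    n_clones: int,
    log10_kd_mean: float,
    log10_kd_sd: float,
    conc_total: float,
    conc_dirichlet_alpha: float = 1.0,
    seed: int = 0,
    regime: Regime = Regime.INDEPENDENT,
) -> ClonalMixture:
    """Draw a random clonal mixture.

    Affinities are log-normal over Kd (``Kd_j = 10**N(mean, sd)``), the
    standard shape of polyclonal affinity spectra; clone abundances are a
    Dirichlet split of the fixed total binding-site concentration.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if log10_kd_sd < 0:
        raise ValueError("log10_kd_sd must be >= 0")
    if not (conc_total >= 0):
        raise ValueError("conc_total must be >= 0")
    if not (conc_dirichlet_alpha > 0):
        raise ValueError("conc_dirichlet_alpha must be > 0")
    rng = np.random.default_rng(seed)
    kd = 10.0 ** (log10_kd_mean + log10_kd_sd * rng.standard_normal(n_clones))
    w = rng.dirichlet(np.full(n_clones, conc_dirichlet_alpha)) if n_clones > 1 else np.ones(1)
    clones = tuple(Clone(float(k), float(conc_total * wi)) for k, wi in zip(kd, w))
    return ClonalMixture(clones=clones, regime=regime)


# frozen scenario presets: contrast between an ongoing response (many clones,
# broad affinity spread) and a matured memory serum (few clones, narrow
# spread, ~10x higher affinity)
_SCENARIOS = {
    "active_response": dict(n_clones=20, log10_kd_mean=-8.0, log10_kd_sd=1.0),
    "memory_response": dict(n_clones=3, log10_kd_mean=-9.0, log10_kd_sd=0.2),
}
# total antibody binding sites, mol/L: dilute relative to the preset Kd
# scales so ligand depletion stays mild and the fitted asymmetry reads out
# clonal heterogeneity rather than antigen consumption
_SCENARIO_CONC_TOTAL = 5e-10
_SCENARIO_GRID = np.logspace(-12, -5, 16)


def scenario(
    name: str,
    seed: int = 0,
    noise_cv: float = 0.0,
    replicates: int = 1,
    **overrides,
) -> tuple[ClonalMixture, AssayConfig]:
    """Preset mixture + assay for a named immune-response scenario.

    ``active_response``: 20 clones, log10 Kd ~ N(-8, 1.0).
    ``memory_response``: 3 clones, log10 Kd ~ N(-9, 0.2).
    Both use the competitive (shared-epitope) regime, 0.5 nM total antibody
    and a 16-point grid from 1e-12 to 1e-5 M.  Any preset field can be
    overridden by keyword.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    params = dict(_SCENARIOS[name])
    params.update({k: v for k, v in overrides.items() if k in params})
    ss = np.random.SeedSequence(seed)
    mix_seed, assay_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    mix = generate_mixture(
        n_clones=params["n_clones"],
        log10_kd_mean=params["log10_kd_mean"],
        log10_kd_sd=params["log10_kd_sd"],
        conc_total=overrides.get("conc_total", _SCENARIO_CONC_TOTAL),
        conc_dirichlet_alpha=overrides.get("conc_dirichlet_alpha", 1.0),
        seed=mix_seed,
        regime=overrides.get("regime", Regime.COMPETITIVE),
    )
    assay = AssayConfig(
        conc_grid=overrides.get("conc_grid", _SCENARIO_GRID),
        noise_cv=noise_cv,
        replicates=replicates,
        signal_per_bound=overrides.get("signal_per_bound", 1e12),
        background=overrides.get("background", 20.0),
        seed=assay_seed,
    )
    return mix, assay


def heterogeneity_sweep(
    sd_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
    n_mixtures: int = 50,
    seed: int = 0,
    n_clones: int = 20,
    log10_kd_mean: float = -8.0,
    conc_total: float = _SCENARIO_CONC_TOTAL,
    regime: Regime = Regime.COMPETITIVE,
    conc_grid: Optional[np.ndarray] = None,
) -> dict:
    """Fitted-asymmetry magnitude as a function of affinity spread.

    For each affinity spread ``log10_kd_sd`` in ``sd_grid``, draws
    ``n_mixtures`` seeded mixtures, simulates noiseless titrations and fits
    the Richards model; returns ``{"sd": ..., "abs_log_nu": (n_sd, n_mix),
    "median_abs_log_nu": ...}``.  The medians probe the claim that the
    limiting activity coefficient (1/nu) reads out clonal heterogeneity:
    a homogeneous pool is a single Langmuir (nu = 1), and broader affinity
    spectra push |ln nu| up.
    """
    from .fitting import FitConfig, ModelKind, fit_model

    grid = _SCENARIO_GRID if conc_grid is None else np.asarray(conc_grid, float)
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(len(sd_grid) * n_mixtures) % (2**31)
    abs_log_nu = np.empty((len(sd_grid), n_mixtures))
    cfg = FitConfig()
    k = 0
    for i, sd in enumerate(sd_grid):
        for j in range(n_mixtures):
            mix = generate_mixture(
                n_clones=n_clones,
                log10_kd_mean=log10_kd_mean,
                log10_kd_sd=float(sd),
                conc_total=conc_total,
                seed=int(child[k]),
                regime=regime,
            )
            k += 1
            series = simulate_titration(mix, AssayConfig(conc_grid=grid))
            fit = fit_model(series, ModelKind.GL, cfg)
            abs_log_nu[i, j] = abs(np.log(fit.params.nu))
    return {
        "sd": np.asarray(sd_grid, float),
        "abs_log_nu": abs_log_nu,
        "median_abs_log_nu": np.median(abs_log_nu, axis=1),
    }
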