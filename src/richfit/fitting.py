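"""Nonlinear least-squares fitting of titration curves.

Fits the 4PL, 5PL and generalized-logistic (Richards) models to antigen (or
serum) titration series by bounded trust-region least squares, with
data-driven initialization, a small multi-start schedule to escape the
rate-nu correlation valley of the Richards model, parameter covariance from
the Jacobian, AIC/BIC model comparison and residual-resampling bootstrap
confidence intervals.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import FivePLParams, FourPLParams, GLParams

__all__ = [
    "ModelKind",
    "TitrationSeries",
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "BootstrapResult",
    "init_guess",
    "fit_model",
    "compare_models",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)


class ModelKind(str, enum.Enum):
    FOURPL = "4pl"
    FIVEPL = "5pl"
    GL = "gl"


_PARAM_NAMES = {
    ModelKind.FOURPL: ("s_floor", "s_span", "rate", "log_infl"),
    ModelKind.FIVEPL: ("s_floor", "s_span", "slope_b", "log_c_mid", "asym_g"),
    ModelKind.GL: ("s_floor", "s_span", "rate", "log_infl", "nu"),
}


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: concentrations, signals and identifying metadata.

    ``conc``   strictly increasing antigen concentrations, mol/L, > 0.
    ``signal`` assay signal, shape (n,) or (n, n_replicates).
    ``meta``   free-form labels (antigen, isotype, dilution, assay_id, ...).
    ``blank_signal`` signals of zero-concentration (blank) wells, excluded
        from the log-domain fit; their mean may optionally pin the floor.
    """

    conc: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)
    blank_signal: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "signal", signal)
        if conc.ndim != 1 or conc.size < 2:
            raise ValueError("conc must be a 1-D array with at least 2 points")
        if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
            raise ValueError("concentrations must be finite and > 0 (mol/L)")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if signal.shape[0] != conc.size or signal.ndim not in (1, 2):
            raise ValueError("signal must have shape (n,) or (n, n_replicates)")
        if not np.all(np.isfinite(signal)):
            raise ValueError("signals must be finite")
        if self.blank_signal is not None:
            object.__setattr__(
                self, "blank_signal", np.asarray(self.blank_signal, dtype=float).ravel()
            )

    @property
    def n_conc(self) -> int:
        return self.conc.size

    @property
    def n_replicates(self) -> int:
        return 1 if self.signal.ndim == 1 else self.signal.shape[1]

    @property
    def log_conc(self) -> np.ndarray:
        return np.log(self.conc)

    @property
    def x_flat(self) -> np.ndarray:
        """ln(conc) repeated per replicate, aligned with :attr:`y_flat`."""
        if self.signal.ndim == 1:
            return self.log_conc
        return np.repeat(self.log_conc, self.n_replicates)

    @property
    def y_flat(self) -> np.ndarray:
        return self.signal.ravel()

    @property
    def mean_signal(self) -> np.ndarray:
        return self.signal if self.signal.ndim == 1 else self.signal.mean(axis=1)

    def label(self) -> str:
        keys = ("antigen", "isotype", "dilution")
        parts = [str(self.meta[k]) for k in keys if k in self.meta and self.meta[k] is not None]
        return "/".join(parts) if parts else "series"


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    ``loss``       'ols' (plain squares) or 'soft_l1' (robust).
    ``weighting``  'none' (homoscedastic) or 'relative' (residuals divided by
                   the floor-protected model value; fluorescence-like noise).
    ``bounds_overrides`` maps parameter name -> (lo, hi), replacing the
                   data-driven default box for that parameter.
    ``pin_floor_to_blanks`` if True and blank wells exist, s_floor is fixed
                   near their mean.
    """

    loss: str = "ols"
    weighting: str = "none"
    max_iter: int = 2000
    tolerance: float = 1e-10
    bounds_overrides: dict = field(default_factory=dict)
    bootstrap_n: int = 200
    seed: int = 0
    pin_floor_to_blanks: bool = False

    def __post_init__(self) -> None:
        if self.loss not in ("ols", "soft_l1"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.weighting not in ("none", "relative"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.bootstrap_n < 0:
            raise ValueError("bootstrap_n must be >= 0")
        if not (self.tolerance > 0):
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class FitResult:
    """A fitted model with uncertainty and goodness-of-fit diagnostics."""

    model: ModelKind
    params: object  # GLParams | FourPLParams | FivePLParams
    param_names: tuple
    theta: np.ndarray  # raw parameter vector in fit space
    param_se: np.ndarray
    cov: np.ndarray
    rss: float
    aic: float
    bic: float
    r_squared: float
    converged: bool
    n_obs: int
    message: str = ""
    series_meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelComparison:
    """Fits of all requested models on one series, ranked by AIC."""

    ranked: tuple  # FitResult, ascending AIC
    errors: dict  # ModelKind -> str for models that failed

    @property
    def delta_aic(self) -> np.ndarray:
        aics = np.array([f.aic for f in self.ranked])
        return aics - aics[0] if aics.size else aics

    @property
    def indistinguishable_from_best(self) -> np.ndarray:
        """True where a model is within 2 AIC units of the best."""
        return self.delta_aic < 2.0


@dataclass(frozen=True)
class BootstrapResult:
    param_names: tuple
    lo: np.ndarray
    hi: np.ndarray
    level: float
    samples: np.ndarray  # (n_boot, n_params), fit-space


# ---------------------------------------------------------------------------
# model plumbing: predict in flat x (= ln conc) space, pack/unpack params

def _predict(model: ModelKind, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    if model is ModelKind.FOURPL:
        f, s, r, li = theta
        return f + s / (1.0 + np.exp(np.clip(-r * (x - li), -700, 700)))
    if model is ModelKind.GL:
        f, s, r, li, nu = theta
        t = np.clip(-r * (x - li), -700, 700) + np.log(nu)
        w = np.where(t > 33.0, t, np.log1p(np.exp(np.minimum(t, 33.0))))
        return f + s * np.exp(-w / nu)
    if model is ModelKind.FIVEPL:
        f, s, b, lc, g = theta
        z = np.clip(-b * (x - lc), -700, 700)
        w = np.where(z > 33.0, z, np.log1p(np.exp(np.minimum(z, 33.0))))
        return f + s * np.exp(-g * w)
    raise ValueError(f"unknown model {model}")


def _theta_to_params(model: ModelKind, theta: np.ndarray):
    if model is ModelKind.FOURPL:
        return FourPLParams(*theta)
    if model is ModelKind.GL:
        return GLParams(*theta)
    if model is ModelKind.FIVEPL:
        f, s, b, lc, g = theta
        return FivePLParams(f, s, b, float(np.exp(lc)), g)
    raise ValueError(f"unknown model {model}")


def _default_bounds(
    model: ModelKind, series: TitrationSeries, span0: float, floor0: float
) -> tuple[np.ndarray, np.ndarray]:
    lx = series.log_conc
    li_lo, li_hi = lx.min() - 3.0, lx.max() + 3.0
    floor_b = (floor0 - span0, floor0 + span0)
    span_b = (span0 * 1e-3, span0 * 10.0)
    rate_b = (1e-3, 1e3)
    nu_b = (1e-2, 1e2)
    if model is ModelKind.FOURPL:
        lo = [floor_b[0], span_b[0], rate_b[0], li_lo]
        hi = [floor_b[1], span_b[1], rate_b[1], li_hi]
    elif model is ModelKind.GL:
        lo = [floor_b[0], span_b[0], rate_b[0], li_lo, nu_b[0]]
        hi = [floor_b[1], span_b[1], rate_b[1], li_hi, nu_b[1]]
    else:
        lo = [floor_b[0], span_b[0], rate_b[0], li_lo, nu_b[0]]
        hi = [floor_b[1], span_b[1], rate_b[1], li_hi, nu_b[1]]
    return np.array(lo, dtype=float), np.array(hi, dtype=float)


def init_guess(series: TitrationSeries, model: ModelKind):
    """Data-driven starting parameters.

    Floor and span come from the signal range; the log inflection from the
    first half-range crossing (linear interpolation); the rate from the
    steepest observed slope of signal against ln(conc) scaled to a unit
    logistic (max slope of a normalized logistic is rate/4).
    """
    model = ModelKind(model)
    y = series.mean_signal
    x = series.log_conc
    floor0 = float(y.min())
    span0 = float(y.max() - y.min())
    scale = max(abs(y.max()), abs(y.min()), 1.0)
    if span0 <= 1e-12 * scale:
        raise ValueError("no dynamic range: signal is constant across the titration")
    slopes = np.diff(y) / np.diff(x)
    # overall trend must be increasing for a binding titration
    trend = np.polyfit(x, y, 1)[0]
    if trend <= 0:
        raise ValueError("non-increasing trend: signal does not grow with concentration")
    half = floor0 + span0 / 2.0
    above = np.nonzero(y >= half)[0]
    i = int(above[0]) if above.size else y.size - 1
    if i == 0:
        li0 = float(x[0])
    else:
        y0, y1 = y[i - 1], y[i]
        f = (half - y0) / (y1 - y0) if y1 != y0 else 0.5
        li0 = float(x[i - 1] + f * (x[i] - x[i - 1]))
    rate0 = float(np.clip(4.0 * slopes.max() / span0, 1e-3, 1e3))
    if model is ModelKind.FOURPL:
        return FourPLParams(floor0, span0, rate0, li0)
    if model is ModelKind.GL:
        return GLParams(floor0, span0, rate0, li0, 1.0)
    return FivePLParams(floor0, span0, rate0, float(np.exp(li0)), 1.0)


def _params_to_theta(model: ModelKind, params) -> np.ndarray:
    if model is ModelKind.FOURPL:
        return np.array([params.s_floor, params.s_span, params.rate, params.log_infl])
    if model is ModelKind.GL:
        return np.array(
            [params.s_floor, params.s_span, params.rate, params.log_infl, params.nu]
        )
    return np.array(
        [params.s_floor, params.s_span, params.slope_b, np.log(params.c_mid), params.asym_g]
    )


def _residual_fn(
    model: ModelKind,
    x: np.ndarray,
    y: np.ndarray,
    weighting: str,
    span0: float,
) -> Callable[[np.ndarray], np.ndarray]:
    guard = max(span0 * 1e-2, 1e-30)

    def fun(theta: np.ndarray) -> np.ndarray:
        r = _predict(model, theta, x) - y
        if weighting == "relative":
            r = r / np.maximum(np.abs(_predict(model, theta, x)), guard)
        return r

    return fun


def _apply_overrides(
    model: ModelKind, lo: np.ndarray, hi: np.ndarray, overrides: dict
) -> tuple[np.ndarray, np.ndarray]:
    names = _PARAM_NAMES[model]
    for name, (a, b) in overrides.items():
        if name in names:
            j = names.index(name)
            lo[j], hi[j] = a, b
    return lo, hi


def _single_fit(fun, theta0, lo, hi, config: FitConfig):
    theta0 = np.clip(theta0, lo + 1e-12 * np.maximum(1.0, np.abs(lo)), hi)
    return least_squares(
        fun,
        theta0,
        bounds=(lo, hi),
        method="trf",
        loss="linear" if config.loss == "ols" else "soft_l1",
        ftol=config.tolerance,
        xtol=config.tolerance,
        gtol=1e-12,
        max_nfev=config.max_iter,
    )


def fit_model(
    series: TitrationSeries,
    model: ModelKind,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit one model to a titration series.

    Replicates enter as independent observations.  Multi-start: besides the
    data-driven guess, the log inflection is jittered by +/-1 ln-unit with
    the asymmetry started at 0.3 and 3; the lowest residual sum wins, ties
    going to the more symmetric solution (smaller ``|ln nu|``).
    """
    model = ModelKind(model)
    config = config or FitConfig()
    x, y = series.x_flat, series.y_flat
    n_obs = y.size
    n_params = len(_PARAM_NAMES[model])
    if n_obs <= n_params:
        raise ValueError(
            f"under-determined fit: {n_obs} observations for {n_params} parameters"
        )
    if np.unique(series.conc).size < n_params:
        raise ValueError(
            f"need at least {n_params} distinct concentrations for the "
            f"{model.value} model"
        )

    guess = init_guess(series, model)
    theta0 = _params_to_theta(model, guess)
    floor0, span0 = theta0[0], theta0[1]
    lo, hi = _default_bounds(model, series, span0, floor0)
    overrides = dict(config.bounds_overrides)
    if config.pin_floor_to_blanks and series.blank_signal is not None and series.blank_signal.size:
        m = float(series.blank_signal.mean())
        eps = max(abs(m), span0) * 1e-9 + 1e-30
        overrides.setdefault("s_floor", (m - eps, m + eps))
    lo, hi = _apply_overrides(model, lo, hi, overrides)
    fun = _residual_fn(model, x, y, config.weighting, span0)

    starts = [theta0]
    if model in (ModelKind.GL, ModelKind.FIVEPL):
        for dli, asym in ((-1.0, 0.3), (1.0, 3.0)):
            t = theta0.copy()
            t[3] += dli
            t[4] = asym
            starts.append(t)
    else:
        for dli in (-1.0, 1.0):
            t = theta0.copy()
            t[3] += dli
            starts.append(t)

    best = None
    for t0 in starts:
        try:
            res = _single_fit(fun, t0, lo, hi, config)
        except Exception as exc:  # pathological start; other starts may work
            logger.debug("start %s failed: %s", t0, exc)
            continue
        if best is None:
            best = res
            continue
        rel = abs(res.cost - best.cost) / max(best.cost, 1e-300)
        if res.cost < best.cost and rel > 1e-9:
            best = res
        elif rel <= 1e-9 and model in (ModelKind.GL, ModelKind.FIVEPL):
            if abs(np.log(res.x[4])) < abs(np.log(best.x[4])):
                best = res
    if best is None:
        raise RuntimeError(f"all optimizer starts failed for model {model.value}")

    theta = best.x
    pred = _predict(model, theta, x)
    rss = float(np.sum((pred - y) ** 2))
    k = n_params + 1  # +1 for the residual variance
    with np.errstate(divide="ignore"):
        aic = n_obs * np.log(max(rss, 1e-300) / n_obs) + 2 * k
        bic = n_obs * np.log(max(rss, 1e-300) / n_obs) + k * np.log(n_obs)
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - rss / tss if tss > 0 else np.nan

    # covariance from the Jacobian at the optimum (Gauss-Newton approximation)
    dof = max(n_obs - n_params, 1)
    s2 = 2.0 * best.cost / dof
    J = best.jac
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        param_se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((n_params, n_params), np.nan)
        param_se = np.full(n_params, np.nan)

    converged = bool(best.status > 0)
    if not converged:
        logger.warning(
            "fit of %s on %s did not converge: %s", model.value, series.label(), best.message
        )
    return FitResult(
        model=model,
        params=_theta_to_params(model, theta),
        param_names=_PARAM_NAMES[model],
        theta=theta,
        param_se=param_se,
        cov=cov,
        rss=rss,
        aic=float(aic),
        bic=float(bic),
        r_squared=r_squared,
        converged=converged,
        n_obs=n_obs,
        message=str(best.message),
        series_meta=dict(series.meta),
    )


def compare_models(
    series: TitrationSeries,
    config: Optional[FitConfig] = None,
    models: Sequence[ModelKind] = (ModelKind.FOURPL, ModelKind.FIVEPL, ModelKind.GL),
) -> ModelComparison:
    """Fit several models and rank them by AIC (ascending).

    Models within 2 AIC units of the best are flagged indistinguishable.
    A model may fail (e.g. under-determined) while the others succeed; its
    error message is reported alongside the ranking.
    """
    results, errors = [], {}
    for m in models:
        try:
            results.append(fit_model(series, m, config))
        except (ValueError, RuntimeError) as exc:
            errors[ModelKind(m)] = str(exc)
            logger.warning("model %s failed on %s: %s", ModelKind(m).value, series.label(), exc)
    results.sort(key=lambda f: f.aic)
    return ModelComparison(ranked=tuple(results), errors=errors)


def bootstrap_ci(
    series: TitrationSeries,
    fit: FitResult,
    config: Optional[FitConfig] = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Residual-resampling bootstrap percentile intervals.

    Residuals (on the weighting scale of the fit) are resampled with
    replacement, synthetic series are refit starting from the point estimate,
    and percentile intervals are taken per parameter in fit space (the 5PL
    midpoint interval is on ln(c_mid)).  Bit-reproducible for a given seed.
    """
    config = config or FitConfig()
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if config.bootstrap_n < 100:
        raise ValueError("bootstrap_n must be >= 100 for percentile intervals")
    x, y = series.x_flat, series.y_flat
    pred = _predict(fit.model, fit.theta, x)
    span0 = float(fit.theta[1])
    guard = max(span0 * 1e-2, 1e-30)
    lo_b, hi_b = _default_bounds(fit.model, series, span0, float(fit.theta[0]))
    lo_b, hi_b = _apply_overrides(fit.model, lo_b, hi_b, dict(config.bounds_overrides))
    rng = np.random.default_rng(config.seed)

    if config.weighting == "relative":
        resid = (y - pred) / np.maximum(np.abs(pred), guard)
    else:
        resid = y - pred

    samples = np.empty((config.bootstrap_n, fit.theta.size))
    for b in range(config.bootstrap_n):
        r = resid[rng.integers(0, resid.size, resid.size)]
        if config.weighting == "relative":
            y_b = pred * (1.0 + r)
        else:
            y_b = pred + r
        fun = lambda th: (
            (_predict(fit.model, th, x) - y_b)
            / (np.maximum(np.abs(_predict(fit.model, th, x)), guard)
               if config.weighting == "relative" else 1.0)
        )
        res = _single_fit(fun, fit.theta.copy(), lo_b, hi_b, config)
        samples[b] = res.x

    alpha = (1.0 - level) / 2.0
    lo = np.percentile(samples, 100 * alpha, axis=0)
    hi = np.percentile(samples, 100 * (1 - alpha), axis=0)
    return BootstrapResult(
        param_names=fit.param_names, lo=lo, hi=hi, level=level, samples=samples
    )
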