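# Methods

## Binding model

An equilibrium antigen titration is modeled as growth of the bound-antibody
fraction a = Ab_bound/Ab_total along x = ln[Ag]:

    da/dx = (r/ν) · a · (1 − a^ν),        r > 0, ν > 0.

Substituting u = a^(−ν) linearizes the equation and gives the closed form

    a(x) = (1 + ν·e^(−r(x − x_i)))^(−1/ν),

chosen among the equivalent Richards parameterizations because x_i = ln[Ag]ᵢ
— the inflection abscissa — is then literally a parameter. In measurement
space the curve is s_floor + s_span·a(x). Limits and reductions: ν = 1 is
the 4PL (logistic); ν → 0 the Gompertz curve e^(−e^(−r(x−x_i))); the
normalized value at the inflection is (1+ν)^(−1/ν), which rises from 1/e
through 1/2 (ν = 1) toward 1 as ν grows.

Logarithms are natural throughout the internals; a base-10 rate is
r·ln 10. The 5PL is implemented in the conventional increasing form
s_floor + s_span·(1 + (c/c_mid)^(−b))^(−g) for comparison fits only; its
c_mid is not the inflection point for g ≠ 1, which is precisely the
interpretability defect the Richards parameterization avoids.

## Thermodynamic reading

* [Ag]ᵢ = exp(log_infl) is reported as the apparent dissociation constant
  of the bound pool. The standard chemical potential uses the dissociation
  convention Δμ° = RT·ln(Kd/c°), c° = 1 mol/L, R = 8.314462618 J/(mol·K),
  default T = 298.15 K (overridable): sub-molar Kd gives Δμ° < 0 and higher
  affinity a more negative Δμ°.
* γ∞ = 1/ν, the limiting activity coefficient of antigen at infinite
  antibody dilution; γ∞·ν = 1 holds exactly by construction.
* Derived quantities are defined only for converged Richards fits of
  antigen titrations. Serum-dilution (antibody-titration) series can be
  fit with the same models, but no thermodynamic descriptors are emitted
  for them because the inflection of a dilution curve is not an antigen
  concentration.
* How the apparent Kd of a mixture averages over clones is left to the
  simulator rather than asserted as a formula; the package reports the
  apparent (aggregate) value only.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
on replicate-flattened observations (replicates are independent data
points, preserving degrees of freedom). Initialization from the data:
floor = min, span = range, log inflection from the first half-range
crossing by linear interpolation, rate = 4·(max slope vs ln c)/span.
Multi-start guards the known rate–ν correlation valley: the plain start
plus log_infl ∓ 1 ln-unit with ν started at 0.3 and 3; lowest residual sum
wins, near-ties (≤1e−9 relative) resolved toward smaller |ln ν|.

Default bounds: rate ∈ [1e−3, 1e3], ν ∈ [1e−2, 1e2], log_infl within the
data range ±3 ln-units, floor ∈ [min−span, min+span], span ∈
[1e−3, 10]·observed span; all individually overridable. ν is additionally
clamped to [1e−4, 1e3] at the type level and exponent arguments are
clipped at ±700, with softplus-based evaluation so extreme tails return
the asymptotes instead of overflowing.

Weighting: `none` (homoscedastic default) or `relative` (residuals divided
by the model value, floor-protected at 1% of the span) for multiplicative
noise. Loss: ordinary squares or soft-L1. Goodness of fit: AIC =
n·ln(RSS/n) + 2k and the BIC analogue, with k = #parameters + 1 for the
residual variance; `compare_models` ranks 4PL/5PL/GL by AIC and flags
ΔAIC < 2 as indistinguishable. Parameter covariance is the Gauss–Newton
approximation s²·(JᵀJ)⁻¹ at the optimum (pseudo-inverse; standard errors
are NaN when the Jacobian is degenerate).

Confidence intervals are residual-resampling bootstrap percentiles:
residuals on the fit's weighting scale are resampled with replacement,
synthetic series refit from the point estimate (single start — standard
bootstrap practice and an order of magnitude faster than re-running the
multi-start schedule), and per-parameter percentile intervals taken in fit
space (the 5PL midpoint on ln c_mid). Fully reproducible for a given seed.

Under-determination is an error whenever n_obs ≤ n_params, uniformly for
all models — a 5-concentration single-replicate series therefore supports
the 4PL but neither 5-parameter model. Blank wells (conc ≤ 0) are excluded
from the log-domain fit; their mean can optionally pin the floor
(`pin_floor_to_blanks`).

## Simulator

Ground truth is mechanistic, not curve-generated: each clone is a
single-site Langmuir binder (Kd, binding-site concentration), and a serum
is a clone mixture in one of two regimes. In `independent_sites` the
nominal antigen concentration is taken as free (antibody-dilute limit). In
`competitive` all clones share one epitope and free antigen solves the
mass balance ag_total = ag_free·(1 + Σ c_j/(Kd_j + ag_free)) by Brent
bracketing on [0, ag_total] at ~machine precision (conservation holds to
≤1e−15 relative, tested at 1e−9). Antigen titration is emulated by varying
total antigen in this solution-phase balance — a deliberate simplification
of surface-microspot physics that ignores surface depletion, transport and
bivalent avidity.

Affinity spectra are log-normal over Kd (Kd_j = 10^N(μ, σ) in log₁₀
units), the standard shape for polyclonal pools; abundances are a
Dirichlet split of a fixed total. Noise is multiplicative log-normal with
median 1 and given CV (σ_log = √ln(1+CV²)), optionally plus additive
Gaussian. All randomness in a compound experiment flows from one seed
through `numpy.random.SeedSequence`, and every simulated series records
its seed in metadata.

Scenario presets contrast an ongoing response with immune memory:
`active_response` = 20 clones, log₁₀Kd ~ N(−8, 1.0); `memory_response` =
3 clones, log₁₀Kd ~ N(−9, 0.2) — fewer, affinity-matured (ten-fold lower
Kd), narrowly distributed clones. Both default to the competitive regime,
0.5 nM total antibody and a 16-point grid spanning 1e−12–1e−5 M. The
0.5 nM total was fixed by direction-verification simulation before the
presets were frozen: it keeps antibody dilute relative to the preset Kd
scales, so the fitted asymmetry reflects clonal heterogeneity rather than
ligand depletion — the dilute-antibody condition is also exactly the
regime in which γ∞ (defined at infinite antibody dilution) is meaningful.
With these defaults the memory preset shows both the smaller apparent Kd
and the more symmetric curve (|ln ν̂| ≈ 0.03 vs ≈ 0.42 median over seeds).

What the simulator does *not* emulate — surface-phase effects, avidity,
Fc-receptor binding, cross-reactivity networks, B-cell dynamics — bounds
what passing tests show: they validate the parameter → mechanism mapping
for solution-phase Langmuir mixtures, not every physical effect present
in a real microspot assay. The heterogeneity results are directional
(median |ln ν̂| non-decreasing in affinity spread), not a quantitative law
linking ν to any specific mixture statistic.

## Numerical choices

* ODE verification oracle: DOP853, rtol 1e−12, absolute tolerance scaled
  to the starting fraction (the trajectory is monotone increasing, so this
  keeps relative error controlled even from starts ~1e−25 deep in the
  lower tail); agreement with the closed form is ≤1e−11 over 50 random
  parameter sets.
* Competitive root finding: Brent with rtol ≈ 4·eps; the balance function
  is strictly monotone so non-convergence is effectively unreachable.
* I/O: concentrations only in mol/L (the column name `conc_mol_per_L`
  enforces the unit; mass units are out of scope to avoid molecular-weight
  ambiguity). Floats are written with 17 significant digits and parsed
  with correctly-rounded conversion, making simulate → write → read → fit
  → report byte-identical across runs on one platform.
* Problem sizes for the built-in validation studies (50 random parameter
  sets, 100 noisy titrations with 100-resample bootstraps, 50 mixtures per
  affinity-spread level, 1000 random competitive mixtures) were chosen so
  each study gives stable medians/extrema while the whole suite completes
  in about half a minute.

## Known limitations

Fits of strongly depleted competitive titrations (antibody ≫ Kd) yield ν̂
far from 1 for mechanistic reasons unrelated to clonal heterogeneity;
interpret γ∞ only for antibody-dilute assays. The rate–ν correlation can
leave ν weakly determined on narrow concentration ranges (< ±2 decades
around [Ag]ᵢ); bootstrap intervals make this visible. No global fitting
across antigens, no Bayesian posteriors, no kinetic (time-resolved)
modeling.
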