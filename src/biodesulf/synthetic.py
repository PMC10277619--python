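"""Seeded synthetic-data generators for every pipeline stage.

Each generator produces data with exactly the statistical structure the
matching estimator assumes: a noiseless trajectory from the forward model
plus additive Gaussian noise (the least-assumption choice, since no noise
model is published for these measurements). A given (seed, parameters)
pair always yields identical output, so zero-noise generation composed
with the matching fit is the identity on parameters.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError, NumericalError
from .growth import GrowthParams, GrowthSeries, simulate_growth
from .orthogonal import (
    FACTORS,
    L16_ARRAY,
    N_RUNS,
    DesignTable,
    build_l16_design,
)
from .shrinking_core import KineticCoefficients, time_of_conversion
from .thermal import R_GAS, STUDY_INTERCEPT_SHIFT, STUDY_SLOPE_FACTOR


def gen_growth_series(params: GrowthParams, times, noise_sd: float = 0.0,
                      seed: int | None = None) -> GrowthSeries:
    """Fe2+ depletion series: ODE trajectory plus Gaussian noise on p.

    Noisy values are clipped to [p_floor, p0] (p must stay positive for
    fitting; the floor is 1e-6 * p0). Biomass and conversion are recomputed
    from the noisy p so the mass balance holds for the emitted series.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    clean = simulate_growth(params, times)
    if noise_sd == 0.0:
        return clean
    rng = np.random.default_rng(seed)
    p = clean.p + rng.normal(0.0, noise_sd, size=clean.p.shape)
    p = np.clip(p, 1e-6 * params.p0, params.p0)
    c_l = params.cl0 + params.y * (params.p0 - p)
    eta = 100.0 * (params.p0 - p) / params.p0
    return GrowthSeries(clean.times, p, c_l, eta, params)


def gen_conversion_series(coeffs: KineticCoefficients, x_grid,
                          noise_sd: float = 0.0, seed: int | None = None,
                          max_attempts: int = 100):
    """(t, x) desulfurization series from the integrated shrinking-core law.

    t = t(x) + Gaussian noise; draws whose time sequence is non-monotone
    are resampled (up to ``max_attempts``) so the output is a valid
    strictly-increasing series.
    """
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1) or np.any(np.diff(x) <= 0):
        raise DomainError("x_grid must be strictly increasing within (0, 1)")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    t_clean = time_of_conversion(coeffs, x)
    if np.any(np.diff(t_clean) <= 0):
        raise DomainError("t(x) is not strictly increasing on the grid")
    if noise_sd == 0.0:
        return t_clean, x
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        t = t_clean + rng.normal(0.0, noise_sd, size=t_clean.shape)
        if np.all(np.diff(t) > 0) and t[0] >= 0:
            return t, x
    raise NumericalError(
        f"could not draw a monotone time series in {max_attempts} attempts; "
        "reduce noise_sd or coarsen the grid"
    )


def apre_centering_halfpoint(e_act: float, temperatures, alpha: float = 10.0) -> float:
    """Pre-exponential factor placing the decomposition half-point (x = 0.5)
    at the median 1/T of the grid.

    A realistic TG segment sweeps conversion from ~0 to ~1 across its
    temperature window; solving the linearized law for A at the window
    centre guarantees that for any activation energy.
    """
    if e_act <= 0 or alpha <= 0:
        raise DomainError("E and alpha must be > 0")
    t_arr = np.asarray(temperatures, dtype=float)
    m = float(np.median(1.0 / t_arr))
    log_a = (np.log(np.log(2.0)) + STUDY_INTERCEPT_SHIFT
             + STUDY_SLOPE_FACTOR * e_act * m) + np.log(alpha * R_GAS / e_act)
    return float(np.exp(log_a))


def gen_tg_conversion(e_act: float, a_pre: float, temperatures,
                      alpha: float = 10.0, noise_sd: float = 0.0,
                      seed: int | None = None):
    """(T, x) series satisfying the linearized rate law exactly.

    The ordinate ln[-ln(1-x)] is linear in 1/T with slope -0.1278*E and
    intercept ln(A E/(alpha R)) - 5.314; optional Gaussian noise is added
    on the ordinate before back-transforming to x in (0, 1).
    """
    if e_act <= 0 or a_pre <= 0 or alpha <= 0:
        raise DomainError("E, A and alpha must all be > 0")
    t_arr = np.asarray(temperatures, dtype=float)
    if np.any(np.diff(t_arr) <= 0) or np.any(t_arr <= 0):
        raise DomainError("temperature grid must be positive and increasing")
    intercept = np.log(a_pre * e_act / (alpha * R_GAS)) - STUDY_INTERCEPT_SHIFT
    ordinate = intercept - STUDY_SLOPE_FACTOR * e_act / t_arr
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ordinate = ordinate + rng.normal(0.0, noise_sd, size=ordinate.shape)
    elif noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    x = 1.0 - np.exp(-np.exp(ordinate))
    x = np.clip(x, 1e-12, 1.0 - 1e-12)
    return t_arr, x


def gen_design_responses(level_effects: dict, grand_mean: float,
                         noise_sd: float = 0.0, seed: int | None = None,
                         factor_specs=None) -> DesignTable:
    """L16 response table with additive factor effects plus Gaussian noise.

    ``level_effects[f]`` holds the four per-level effects of factor f;
    the response of each run is the grand mean plus the four active
    effects plus noise. The balanced L16 layout is preserved, so a
    saturated additive model reproduces the effects exactly at zero noise.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    for f in FACTORS:
        if f not in level_effects or len(level_effects[f]) != 4:
            raise DomainError(f"level_effects must give 4 values for factor {f}")
    rng = np.random.default_rng(seed)
    responses = np.full(N_RUNS, float(grand_mean))
    for j, f in enumerate(FACTORS):
        eff = np.asarray(level_effects[f], dtype=float)
        responses += eff[L16_ARRAY[:, j] - 1]
    if noise_sd > 0:
        responses += rng.normal(0.0, noise_sd, size=N_RUNS)
    responses = np.clip(responses, 0.0, None)  # responses are percentages >= 0
    if factor_specs is None:
        import pandas as pd

        frame = pd.DataFrame(L16_ARRAY, columns=list(FACTORS))
        frame.insert(0, "run", np.arange(1, N_RUNS + 1))
        design = DesignTable(frame)
    else:
        design = build_l16_design(factor_specs)
    return design.with_responses(responses)
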