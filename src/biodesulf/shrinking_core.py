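"""Three-resistance shrinking-core model of coal biodesulfurization.

A coal particle is treated as a sphere whose unreacted core (radius r_c)
shrinks inside a growing solid product layer (jarosite and similar
precipitates). Under quasi-steady state, the sulfur-removal rate combines
three resistances in series — external (liquid-film) diffusion, internal
(product-layer) diffusion and interfacial chemical reaction — and the
integrated conversion-time law is linear in three basis functions of the
conversion x:

    t = A1 * x
      + A2 * [1 - (2/3) x - (1 - x)^(2/3)]
      + A3 * [1 - (1 - x)^(1/3)]

with lumped coefficients (time units)

    A1 = gamma delta rho r_s / (3 M C_l D1)     external diffusion
    A2 = gamma rho r_s^2   / (2 M C_l D2)       internal diffusion
    A3 = rho r_s           / (M C_l k)          chemical reaction

Fitting A1..A3 to an observed (t, x) series by intercept-free least squares
and comparing the correlation of each basis term with t ranks the
resistances and identifies the rate-controlling step. All coefficients
scale as 1/C_l, the microbial concentration, which couples the model to
the growth kinetics (`simulate_coupled`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from ._util import as_1d_float
from .exceptions import (
    DomainError,
    IntegrationError,
    InversionError,
    NumericalError,
    SingularDesignError,
)
from .growth import GrowthParams

#: Clip applied wherever (1-x)^(-1/3) or (1-x)^(-2/3) is evaluated.
X_MAX = 1.0 - 1e-9

MECHANISMS = ("external_diffusion", "internal_diffusion", "chemical_reaction")


@dataclass(frozen=True)
class ShrinkingCoreParams:
    """Physical parameters of the particle-scale model (all > 0).

    gamma: stoichiometric coefficient; delta: liquid-film thickness;
    rho: coal density; M: molecular weight of the reactant in coal;
    r_s: particle radius; D1/D2: diffusivities in solution / through the
    product layer; k: interfacial rate constant; C_l: microbial
    concentration in solution. Any consistent unit system works; the
    lumped coefficients come out in the resulting time unit.
    """

    gamma: float
    delta: float
    rho: float
    M: float
    r_s: float
    D1: float
    D2: float
    k: float
    C_l: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class KineticCoefficients:
    """Lumped coefficients (A1, A2, A3) of the integrated rate law.

    Signs are unconstrained: an unconstrained regression on noisy data can
    return negative values even though the physical derivation gives
    positive ones.
    """

    A1: float
    A2: float
    A3: float

    def __iter__(self):
        return iter((self.A1, self.A2, self.A3))

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3])


def basis_functions(x):
    """The three conversion basis functions (g1, g2, g3) at ``x`` in [0, 1].

    g1 = x (external diffusion), g2 = 1 - 2x/3 - (1-x)^(2/3) (internal
    diffusion), g3 = 1 - (1-x)^(1/3) (chemical reaction).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError("conversion x must lie in [0, 1]")
    one_m = 1.0 - arr
    g1 = arr
    g2 = 1.0 - (2.0 / 3.0) * arr - one_m ** (2.0 / 3.0)
    g3 = 1.0 - one_m ** (1.0 / 3.0)
    if np.isscalar(x):
        return float(g1), float(g2), float(g3)
    return g1, g2, g3


def time_of_conversion(coeffs: KineticCoefficients, x):
    """t(x) = A1 g1 + A2 g2 + A3 g3."""
    g1, g2, g3 = basis_functions(x)
    return coeffs.A1 * g1 + coeffs.A2 * g2 + coeffs.A3 * g3


def rate_of_conversion(coeffs: KineticCoefficients, x):
    """dx/dt as the reciprocal of dt/dx from the integrated law.

    dt/dx = A1 + A2 [ (2/3)(1-x)^(-1/3) - 2/3 ] + A3 (1/3)(1-x)^(-2/3).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise DomainError("conversion x must lie in [0, 1)")
    xa = np.minimum(arr, X_MAX)
    one_m = 1.0 - xa
    dtdx = (
        coeffs.A1
        + coeffs.A2 * ((2.0 / 3.0) * one_m ** (-1.0 / 3.0) - 2.0 / 3.0)
        + coeffs.A3 * (1.0 / 3.0) * one_m ** (-2.0 / 3.0)
    )
    if np.any(dtdx <= 0):
        raise NumericalError(
            "non-physical rate: dt/dx <= 0 for the supplied coefficients"
        )
    out = 1.0 / dtdx
    return float(out) if np.isscalar(x) else out


def conversion_at_time(coeffs: KineticCoefficients, t: float) -> float:
    """Invert t(x) by bisection on [0, 1-1e-9] (abs. tolerance 1e-10).

    Requires t(x) increasing on the bracket; a non-monotone profile (e.g.
    sign-mixed coefficients) raises :class:`InversionError` naming the
    offending interval.
    """
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t}")
    if t == 0:
        return 0.0
    # monotonicity check on a coarse grid before bracketing
    probe = np.linspace(0.0, X_MAX, 257)
    tv = time_of_conversion(coeffs, probe)
    d = np.diff(tv)
    if np.any(d < -1e-12 * max(1.0, float(np.max(np.abs(tv))))):
        i = int(np.argmin(d))
        raise InversionError(
            f"t(x) is decreasing on [{probe[i]:.4f}, {probe[i + 1]:.4f}]; "
            "cannot invert"
        )
    t_max = float(tv[-1])
    if t > t_max:
        raise InversionError(f"t={t} exceeds t(x={X_MAX:.9f})={t_max}")
    root = optimize.brentq(lambda x: time_of_conversion(coeffs, x) - t,
                           0.0, X_MAX, xtol=1e-10)
    return float(root)


def coefficients_from_physical(params: ShrinkingCoreParams) -> KineticCoefficients:
    """Map physical parameters to the lumped coefficients (all positive)."""
    common = params.rho * params.r_s / (params.M * params.C_l)
    a1 = params.gamma * params.delta / (3.0 * params.D1) * common
    a2 = params.gamma * params.r_s / (2.0 * params.D2) * common
    a3 = common / params.k
    return KineticCoefficients(a1, a2, a3)


def intermediate_concentrations(params: ShrinkingCoreParams, x: float,
                                molar_rate: float):
    """Microbial concentrations at the core surface and in the film.

    Given the (negative) molar consumption rate dn/dt at conversion x,
    returns (C_s, C_ls): the concentration in the liquid film and at the
    unreacted-core surface, from the series-resistance balances.
    """
    if not 0.0 <= x < 1.0:
        raise DomainError("x must lie in [0, 1)")
    if molar_rate > 0:
        raise DomainError("molar_rate is a consumption rate and must be <= 0")
    r_c = params.r_s * (1.0 - x) ** (1.0 / 3.0)
    if r_c <= params.r_s * 1e-6:
        raise NumericalError("core radius vanished (x -> 1): concentrations diverge")
    flux = -molar_rate
    c_ls = flux / (4.0 * math.pi * r_c**2 * params.k)
    c_s = c_ls + flux * params.gamma * (params.r_s - r_c) / (
        4.0 * math.pi * params.r_s * r_c * params.D2
    )
    return c_s, c_ls


class ShrinkingCoreModel:
    """Regress observed times on the three conversion basis functions.

    Parameters
    ----------
    times, conversion : array-like
        Observed (t, x) pairs; t >= 0 strictly increasing, x in (0, 1)
        non-decreasing.
    """

    def __init__(self, times, conversion):
        t = as_1d_float(times, "times")
        x = as_1d_float(conversion, "conversion")
        if len(t) != len(x):
            raise DomainError("times and conversion must have equal length")
        if len(t) < 4:
            raise DomainError("need at least 4 points to fit 3 coefficients")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DomainError("times must be non-negative and strictly increasing")
        if np.any(x <= 0) or np.any(x >= 1):
            raise DomainError("conversion must lie strictly in (0, 1)")
        self.times = t
        self.conversion = x

    @classmethod
    def from_dataframe(cls, frame, percent: bool = False) -> "ShrinkingCoreModel":
        """Build from columns ``time, conversion`` (fraction, or % with
        ``percent=True``)."""
        x = frame["conversion"].to_numpy(dtype=float)
        if percent:
            x = x / 100.0
        return cls(frame["time"].to_numpy(), x)

    def fit(self, nonnegative: bool = False) -> "ShrinkingCoreResults":
        """Intercept-free least squares of t on (g1, g2, g3).

        ``nonnegative=True`` constrains the coefficients to be >= 0
        (physical resistances) via bounded least squares.
        """
        g1, g2, g3 = basis_functions(self.conversion)
        design = np.column_stack([g1, g2, g3])
        if np.linalg.matrix_rank(design) < 3:
            raise SingularDesignError(
                "basis functions are collinear on these conversions "
                "(e.g. too few distinct x values)"
            )
        if nonnegative:
            sol = optimize.lsq_linear(design, self.times, bounds=(0, np.inf))
            beta = sol.x
        else:
            beta, *_ = np.linalg.lstsq(design, self.times, rcond=None)
        coeffs = KineticCoefficients(*map(float, beta))
        fitted = design @ beta
        corrs = []
        for col in design.T:
            if np.ptp(col) == 0 or np.ptp(self.times) == 0:
                corrs.append(np.nan)
            else:
                corrs.append(float(stats.pearsonr(col, self.times)[0]))
        if np.ptp(fitted) == 0:
            overall = np.nan
        else:
            overall = float(stats.pearsonr(fitted, self.times)[0])
        ss_res = float(np.sum((self.times - fitted) ** 2))
        ss_tot = float(np.sum((self.times - self.times.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return ShrinkingCoreResults(self, coeffs, corrs, overall, r2, ss_res)


class ShrinkingCoreResults:
    """Fitted lumped coefficients with controlling-step diagnostics."""

    def __init__(self, model, coeffs: KineticCoefficients, term_correlations,
                 overall_correlation: float, r_squared: float, rss: float):
        self.model = model
        self.coeffs = coeffs
        #: Pearson correlation of each basis term with observed t.
        self.term_correlations = dict(zip(("r_A1", "r_A2", "r_A3"), term_correlations))
        #: Correlation between fitted and observed t (the regression R).
        self.R = overall_correlation
        self.r_squared = r_squared
        self.rss = rss

    @property
    def controlling_step(self) -> list:
        """Mechanisms ranked by descending |r|; first is rate-controlling."""
        vals = list(self.term_correlations.values())
        order = np.argsort([-abs(v) if np.isfinite(v) else np.inf for v in vals],
                           kind="stable")
        return [MECHANISMS[i] for i in order]

    @property
    def fittedvalues(self) -> np.ndarray:
        return time_of_conversion(self.coeffs, self.model.conversion)

    def predict_time(self, x):
        return time_of_conversion(self.coeffs, x)

    def summary(self) -> str:
        lines = ["Shrinking-core regression (t on three resistance terms)"]
        for name, val in zip(("A1 (external)", "A2 (internal)", "A3 (reaction)"),
                             self.coeffs):
            lines.append(f"  {name:>14s}: {val:.6g}")
        for name, val in self.term_correlations.items():
            lines.append(f"  {name:>14s}: {val:.4f}")
        lines.append(f"  R: {self.R:.4f}   R^2: {self.r_squared:.4f}")
        lines.append(f"  controlling step: {self.controlling_step[0]}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "A1": self.coeffs.A1,
            "A2": self.coeffs.A2,
            "A3": self.coeffs.A3,
            **self.term_correlations,
            "R": self.R,
            "r_squared": self.r_squared,
            "controlling_step": self.controlling_step,
        }

    def plot(self, ax=None):
        """Observed points and fitted conversion-time curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.times, self.model.conversion, "o", label="observed")
        xg = np.linspace(min(self.model.conversion), max(self.model.conversion), 200)
        ax.plot(self.predict_time(xg), xg, "-", label="fitted")
        ax.set_xlabel("time")
        ax.set_ylabel("desulfurization conversion x")
        ax.legend()
        return ax


def simulate_coupled(growth: GrowthParams, coeffs: KineticCoefficients,
                     times, cl_reference: float | None = None):
    """Conversion under a time-varying microbial concentration.

    The lumped coefficients all scale as 1/C_l, so with biomass C_l(t)
    from the growth model the instantaneous rate is the fixed-coefficient
    rate multiplied by C_l(t)/C_l(reference):

        dx/dt = [C_l(t) / C_l_ref] / (dt/dx)|_{coeffs}

    ``coeffs`` are taken at ``cl_reference`` (default: the initial biomass
    C_l(0)). Returns (times, x) with x non-decreasing and capped below 1.
    """
    times = as_1d_float(times, "times")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise DomainError("times must be ordered and non-negative")
    if cl_reference is None:
        cl_reference = growth.cl0  # biomass at t = 0

    def rhs(_t, y):
        # joint state: y = [p, x]; biomass follows from the mass balance
        p = min(max(y[0], 0.0), growth.p0)
        x = min(max(y[1], 0.0), X_MAX)
        dp = -growth.u_m * p * (growth.cl0_over_y + growth.p0 - p) / (growth.K + p)
        c_l = growth.cl0 + growth.y * (growth.p0 - p)
        dx = (c_l / cl_reference) * rate_of_conversion(coeffs, x)
        return [dp, dx]

    sol = integrate.solve_ivp(
        rhs, (0.0, max(times[-1], 1e-12)), [growth.p0, 0.0], t_eval=times,
        method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(f"coupled conversion integration failed: {sol.message}")
    x = np.clip(sol.y[1], 0.0, X_MAX)
    x = np.maximum.accumulate(x)
    return times, x
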