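"""Monod growth kinetics of an iron-oxidizing culture on Fe2+.

The culture (*Acidithiobacillus ferrooxidans*-type) gains energy by
oxidizing dissolved Fe2+, so biomass growth and substrate depletion are
coupled through a yield coefficient Y:

    dC_l/dt = u_m * p * C_l / (K + p)          (Monod growth)
    C_l     = C_l0 + Y * (p0 - p)              (mass balance)

which combine into a single autonomous ODE for the Fe2+ concentration p:

    dp/dt = -u_m * p * [C_l0 + Y (p0 - p)] / (Y (K + p))
          = -u_m * p * [C_l0/Y + p0 - p] / (K + p)

Only the ratio C_l0/Y enters the dynamics, so the model is parameterized by
(u_m, K, C_l0/Y, p0); absolute biomass is resolved only when biomass
observations are supplied. The time unit is whatever the input series uses
(u_m is per that unit); concentrations are g/L.

The implicit time-concentration relation t(p) is evaluated by quadrature of
the separated ODE; trajectory simulation integrates the ODE directly, and
the two are mutually consistent by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, optimize

from ._util import as_1d_float
from .exceptions import DomainError, FitError, IntegrationError

#: Default initial Fe2+ of 9 K medium (44.2 g/L FeSO4.7H2O), g/L.
DEFAULT_P0 = 8.88


@dataclass(frozen=True)
class GrowthParams:
    """Monod-with-balance growth parameters.

    Attributes
    ----------
    u_m : float
        Maximum specific growth rate, 1/time (time unit of the data).
    K : float
        Half-saturation (growth kinetic) parameter, g/L Fe2+.
    cl0_over_y : float
        Ratio of initial biomass to yield coefficient, g/L substrate
        equivalents — the only combination of C_l0 and Y the Fe2+
        dynamics can identify.
    p0 : float
        Initial Fe2+ concentration, g/L.
    y : float, optional
        Yield coefficient (biomass per g Fe2+). Defaults to 1 so that
        ``cl0 = cl0_over_y``; only meaningful when biomass is observed.
    """

    u_m: float
    K: float
    cl0_over_y: float
    p0: float = DEFAULT_P0
    y: float = 1.0

    def __post_init__(self):
        if self.u_m < 0:
            raise DomainError(f"u_m must be >= 0, got {self.u_m}")
        if self.K <= 0:
            raise DomainError(f"K must be > 0, got {self.K}")
        if self.p0 <= 0:
            raise DomainError(f"p0 must be > 0, got {self.p0}")
        if self.y <= 0:
            raise DomainError(f"Y must be > 0, got {self.y}")
        if self.cl0_over_y < 0:
            raise DomainError(f"C_l0/Y must be >= 0, got {self.cl0_over_y}")

    @property
    def cl0(self) -> float:
        return self.cl0_over_y * self.y


#: Parameters fitted in the source study (time unit of the original series).
FITTED_PARAMS = GrowthParams(u_m=0.0497, K=0.328, cl0_over_y=1.0838, p0=DEFAULT_P0)


@dataclass
class GrowthSeries:
    """Time series of Fe2+ (``p``, g/L), biomass (``c_l``) and Fe2+
    conversion (``eta``, %)."""

    times: np.ndarray
    p: np.ndarray
    c_l: np.ndarray
    eta: np.ndarray
    params: GrowthParams | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "fe2_gL": self.p, "biomass": self.c_l,
             "fe2_conversion_pct": self.eta}
        )


def growth_rate_rhs(p: float, params: GrowthParams) -> float:
    """Fe2+ depletion rate dp/dt at concentration ``p`` (always <= 0)."""
    p = float(p)
    if not 0.0 <= p <= params.p0 * (1 + 1e-12):
        raise DomainError(f"p={p} outside [0, p0={params.p0}]")
    return -params.u_m * p * (params.cl0_over_y + params.p0 - p) / (params.K + p)


def simulate_growth(params: GrowthParams, times) -> GrowthSeries:
    """Integrate the growth ODE over ``times`` (ordered, times[0] >= 0).

    Biomass follows from the mass balance and conversion from the Fe2+
    drop; integration uses an adaptive solver at rtol 1e-10.
    """
    times = as_1d_float(times, "times")
    if len(times) == 0 or np.any(np.diff(times) < 0) or times[0] < 0:
        raise DomainError("times must be ordered and start at t >= 0")

    def rhs(_t, y):
        p = min(max(y[0], 0.0), params.p0)
        return [-params.u_m * p * (params.cl0_over_y + params.p0 - p) / (params.K + p)]

    if params.u_m == 0.0:
        p = np.full_like(times, params.p0)
    else:
        t0 = 0.0
        sol = integrate.solve_ivp(
            rhs, (t0, times[-1] if times[-1] > t0 else t0 + 1e-12), [params.p0],
            t_eval=times, method="LSODA", rtol=1e-10, atol=1e-12,
        )
        if not sol.success:
            raise IntegrationError(f"growth ODE integration failed: {sol.message}")
        p = np.clip(sol.y[0], 0.0, params.p0)
        p = np.minimum.accumulate(p)  # enforce monotone non-increase against roundoff
    c_l = params.cl0 + params.y * (params.p0 - p)
    eta = 100.0 * (params.p0 - p) / params.p0
    return GrowthSeries(times, p, c_l, eta, params)


def time_to_concentration(params: GrowthParams, p_target: float) -> float:
    """Time at which Fe2+ first reaches ``p_target`` (0 < p_target <= p0).

    Evaluates the separated-form integral
    ``t = ∫_{p_target}^{p0} (K + p) / (u_m p (C_l0/Y + p0 - p)) dp``
    by adaptive quadrature.
    """
    if params.u_m == 0.0:
        raise DomainError("u_m = 0: concentration never changes")
    if p_target <= 0:
        raise DomainError("p_target must be > 0 (exhaustion takes infinite time)")
    if p_target > params.p0 * (1 + 1e-12):
        raise DomainError(f"p_target {p_target} exceeds p0 {params.p0}")
    if p_target >= params.p0:
        return 0.0

    def integrand(p):
        return (params.K + p) / (params.u_m * p * (params.cl0_over_y + params.p0 - p))

    val, _err = integrate.quad(integrand, p_target, params.p0, limit=200,
                               epsabs=1e-12, epsrel=1e-10)
    return float(val)


class MonodGrowthModel:
    """Fit Monod growth parameters to an observed Fe2+ depletion series.

    Parameters
    ----------
    times, fe2 : array-like
        Observation times and Fe2+ concentrations (g/L).
    p0 : float, optional
        Initial Fe2+ concentration; defaults to the 9 K medium value
        (8.88 g/L).
    biomass : array-like, optional
        Biomass observations; if given, Y and C_l0 are resolved from the
        mass balance by ordinary least squares after the kinetic fit.
    """

    def __init__(self, times, fe2, p0: float = DEFAULT_P0, biomass=None):
        self.times = as_1d_float(times, "times")
        self.fe2 = as_1d_float(fe2, "fe2")
        if len(self.times) != len(self.fe2):
            raise DomainError("times and fe2 must have equal length")
        if len(self.times) < 6:
            raise DomainError("need at least 6 time points to fit 3 parameters")
        if np.any(self.fe2 < 0) or np.any(self.fe2 > p0 * (1 + 1e-9)):
            raise DomainError("fe2 observations must lie in [0, p0]")
        self.p0 = float(p0)
        self.biomass = None if biomass is None else as_1d_float(biomass, "biomass")

    @classmethod
    def from_dataframe(cls, frame, p0: float = DEFAULT_P0) -> "MonodGrowthModel":
        """Build from a DataFrame with columns ``time, fe2_gL[, biomass]``."""
        biomass = frame["biomass"].to_numpy() if "biomass" in frame.columns else None
        return cls(frame["time"].to_numpy(), frame["fe2_gL"].to_numpy(), p0=p0,
                   biomass=biomass)

    def _predict(self, theta) -> np.ndarray:
        u_m, K, ratio = theta
        params = GrowthParams(u_m=u_m, K=K, cl0_over_y=ratio, p0=self.p0)
        return simulate_growth(params, self.times).p

    def _residuals(self, theta) -> np.ndarray:
        return self._predict(theta) - self.fe2

    def fit(self, init_guess: GrowthParams | None = None,
            multi_start: bool = True) -> "MonodGrowthResults":
        """Least-squares estimation of (u_m, K, C_l0/Y).

        Falls back to a coarse multi-start grid when the supplied guess
        does not converge to a good optimum.
        """
        if np.allclose(self.fe2, self.fe2[0], rtol=0, atol=1e-12):
            params = GrowthParams(u_m=0.0, K=1.0, cl0_over_y=0.0, p0=self.p0)
            return MonodGrowthResults(self, params, rss=0.0, success=True,
                                      degenerate=True, n_starts=0)
        guesses = []
        if init_guess is not None:
            guesses.append((init_guess.u_m, init_guess.K, init_guess.cl0_over_y))
        else:
            guesses.append((0.05, 0.3, 1.0))
        lb = np.array([0.0, 1e-6, 0.0])
        ub = np.array([np.inf, np.inf, np.inf])
        best = None
        scale = float(np.sum(self.fe2**2))

        def try_start(x0):
            nonlocal best
            try:
                sol = optimize.least_squares(
                    self._residuals, np.maximum(x0, lb + 1e-12), bounds=(lb, ub),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except (IntegrationError, DomainError):
                return
            rss = float(2 * sol.cost)
            if best is None or rss < best[1]:
                best = (sol, rss)

        for x0 in guesses:
            try_start(np.asarray(x0, dtype=float))
        # fall back to the grid only on gross misfit (noise floor RSS is
        # legitimate; a stuck local minimum is typically far worse)
        converged = (best is not None and best[0].success
                     and best[1] <= 0.05 * scale)
        if multi_start and not converged:
            grid = itertools.product((0.005, 0.05, 0.5), (0.05, 0.5, 2.0),
                                     (0.1, 1.0, 5.0))
            for x0 in grid:
                try_start(np.asarray(x0, dtype=float))
        if best is None:
            raise FitError("growth fit failed from every start")
        sol, rss = best
        u_m, K, ratio = sol.x
        params = GrowthParams(u_m=float(u_m), K=float(K), cl0_over_y=float(ratio),
                              p0=self.p0)
        if self.biomass is not None and params.cl0_over_y > 0:
            # C_l = cl0 + Y (p0 - p) with cl0 = ratio * Y  =>  C_l = Y*(ratio + p0 - p)
            basis = params.cl0_over_y + self.p0 - self.fe2
            y_hat = float(np.dot(basis, self.biomass) / np.dot(basis, basis))
            params = replace(params, y=y_hat)
        stderr = _stderr_from_jacobian(sol, len(self.times))
        return MonodGrowthResults(self, params, rss=rss, success=sol.success,
                                  degenerate=False, n_starts=1, stderr=stderr)


def _stderr_from_jacobian(sol, n_obs: int):
    """Asymptotic standard errors from the final least-squares Jacobian."""
    try:
        jac = sol.jac
        dof = max(n_obs - jac.shape[1], 1)
        s2 = 2 * sol.cost / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except Exception:
        return None


class MonodGrowthResults:
    """Fitted growth parameters with residual diagnostics."""

    param_names = ("u_m", "K", "cl0_over_y")

    def __init__(self, model: MonodGrowthModel, params: GrowthParams, rss: float,
                 success: bool, degenerate: bool, n_starts: int, stderr=None):
        self.model = model
        self.params = params
        self.rss = rss
        self.success = success
        self.degenerate = degenerate
        self.n_starts = n_starts
        self.stderr = stderr

    @property
    def fittedvalues(self) -> np.ndarray:
        return simulate_growth(self.params, self.model.times).p

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.fe2

    def predict(self, times) -> GrowthSeries:
        return simulate_growth(self.params, times)

    def summary(self) -> str:
        lines = ["Monod growth fit (Fe2+ limiting substrate)",
                 f"  n obs: {len(self.model.times)}   p0: {self.params.p0} g/L"]
        vals = (self.params.u_m, self.params.K, self.params.cl0_over_y)
        for i, (name, v) in enumerate(zip(self.param_names, vals)):
            se = "" if self.stderr is None else f"  (se {self.stderr[i]:.3g})"
            lines.append(f"  {name:>10s}: {v:.6g}{se}")
        lines.append(f"  RSS: {self.rss:.6g}   converged: {self.success}")
        if self.degenerate:
            lines.append("  WARNING: constant series; u_m at the zero boundary")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "u_m": self.params.u_m,
            "K": self.params.K,
            "cl0_over_y": self.params.cl0_over_y,
            "p0": self.params.p0,
            "rss": self.rss,
            "converged": bool(self.success),
            "degenerate": bool(self.degenerate),
        }

    def plot(self, ax=None):
        """Observed vs fitted Fe2+ depletion."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.times, self.model.fe2, "o", label="observed")
        t_dense = np.linspace(self.model.times[0], self.model.times[-1], 200)
        ax.plot(t_dense, self.predict(t_dense).p, "-", label="fitted")
        ax.set_xlabel("time")
        ax.set_ylabel("Fe2+ (g/L)")
        ax.legend()
        return ax
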