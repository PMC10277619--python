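"""Activation energy of coal oxidation from thermogravimetric data.

Non-isothermal first-order decomposition at constant heating rate alpha
(K per time unit) obeys

    dx/dT = (A / alpha) * exp(-E / (R T)) * (1 - x)

whose linearization plots ln[-ln(1 - x)] against 1/T. Two conventions for
the integrated line are supported:

* ``"study"`` (default) — the linearization used in the source analysis,

      ln[-ln(1 - x)] = ln(A E / (alpha R)) - 5.314 - 0.1278 * E / T

  so E = -slope / 0.1278 and A = (alpha R / E) * exp(intercept + 5.314).
  Note the printed constants differ from the SI Coats-Redfern values
  (1/R = 0.1203 mol/J); they are kept exactly as published.

* ``"coats-redfern"`` — the textbook form,

      ln[-ln(1 - x) / T^2] = ln(A R / (alpha E)) - E / (R T)

  so E = -slope * R, with the usual ln(AR/(alpha E)) intercept.

Activation energies come out in J/mol; an increase after desulfurization
indicates a higher barrier to self-heating (reduced spontaneous-combustion
propensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._util import as_1d_float
from .exceptions import DomainError, IncompleteDataError

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Linearization constants of the published rate law.
STUDY_SLOPE_FACTOR = 0.1278
STUDY_INTERCEPT_SHIFT = 5.314

CONVENTIONS = ("study", "coats-redfern")


def arrhenius_rate(a_pre: float, e_act: float, temperature):
    """Arrhenius rate k = A * exp(-E / (R T)); T in kelvin, E in J/mol."""
    t_arr = np.asarray(temperature, dtype=float)
    if np.any(t_arr <= 0):
        raise DomainError("absolute temperature must be > 0")
    if a_pre < 0:
        raise DomainError("pre-exponential factor must be >= 0")
    out = a_pre * np.exp(-e_act / (R_GAS * t_arr))
    return float(out) if np.isscalar(temperature) else out


@dataclass
class TgCurve:
    """Thermogravimetric mass-loss curve.

    temperature: K, strictly increasing, >= 5 points; mass: same length;
    heating_rate: alpha, K per time unit (default 10).
    """

    temperature: np.ndarray
    mass: np.ndarray
    heating_rate: float = 10.0

    def __post_init__(self):
        self.temperature = as_1d_float(self.temperature, "temperature")
        self.mass = as_1d_float(self.mass, "mass")
        if len(self.temperature) < 5:
            raise DomainError("TG curve needs at least 5 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise DomainError("temperature must be strictly increasing")
        if len(self.mass) != len(self.temperature):
            raise DomainError("mass and temperature must have equal length")
        if self.heating_rate <= 0:
            raise DomainError("heating rate alpha must be > 0")
        if self.mass[0] < self.mass[-1]:
            raise DomainError("decomposition segment must lose mass overall")

    @classmethod
    def from_celsius(cls, temperature_c, mass, heating_rate: float = 10.0):
        return cls(np.asarray(temperature_c, dtype=float) + 273.15, mass, heating_rate)


def conversion_from_mass(curve: TgCurve, m0: float | None = None,
                         mf: float | None = None) -> np.ndarray:
    """Conversion x(T) = (m0 - m) / (m0 - mf), clipped to [0, 1].

    ``m0``/``mf`` default to the window-extremal masses of the curve.
    """
    m0 = float(curve.mass.max()) if m0 is None else float(m0)
    mf = float(curve.mass.min()) if mf is None else float(mf)
    if m0 <= mf:
        raise DomainError(f"m0 ({m0}) must exceed mf ({mf})")
    return np.clip((m0 - curve.mass) / (m0 - mf), 0.0, 1.0)


def cr_transform(x, temperature, convention: str = "study"):
    """Transformed coordinates (1/T, ordinate) used in the linear fit.

    Ordinate is ln[-ln(1-x)] for the ``study`` convention and
    ln[-ln(1-x)/T^2] for ``coats-redfern``. Points with x outside (0, 1)
    are excluded; returns (inv_T, ordinate, n_excluded).
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    t_arr = np.atleast_1d(np.asarray(temperature, dtype=float))
    if np.any(t_arr <= 0):
        raise DomainError("absolute temperature must be > 0")
    usable = (x_arr > 0.0) & (x_arr < 1.0)
    n_excluded = int((~usable).sum())
    xv, tv = x_arr[usable], t_arr[usable]
    ordinate = np.log(-np.log(1.0 - xv))
    if convention == "coats-redfern":
        ordinate = ordinate - 2.0 * np.log(tv)
    elif convention != "study":
        raise DomainError(f"convention must be one of {CONVENTIONS}")
    return 1.0 / tv, ordinate, n_excluded


@dataclass
class ArrheniusFit:
    """Result of the linearized activation-energy fit."""

    e_act: float          # activation energy, J/mol
    a_pre: float          # pre-exponential factor, 1/time
    slope: float
    intercept: float
    r_squared: float
    window: tuple         # (T_min, T_max) actually used, K
    n_used: int
    n_excluded: int
    convention: str = "study"

    def summary(self) -> str:
        lines = [f"Activation-energy fit ({self.convention} linearization)",
                 f"  E: {self.e_act:.1f} J/mol   A: {self.a_pre:.4g} per time unit",
                 f"  slope: {self.slope:.4f}   intercept: {self.intercept:.4f}   "
                 f"r^2: {self.r_squared:.6f}",
                 f"  window: {self.window[0]:.1f}-{self.window[1]:.1f} K   "
                 f"points used: {self.n_used} (excluded {self.n_excluded})"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "E_J_per_mol": self.e_act,
            "A_pre": self.a_pre,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "window_K": list(self.window),
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "convention": self.convention,
        }


def fit_activation_energy(temperature, conversion, alpha: float = 10.0,
                          convention: str = "study",
                          window: tuple | None = None) -> ArrheniusFit:
    """OLS of the transformed ordinate on 1/T; E from the slope.

    Parameters
    ----------
    temperature, conversion
        (T, x) series; T in kelvin.
    alpha
        Heating rate (K per time unit), default 10.
    convention
        ``"study"`` (published constants) or ``"coats-redfern"``.
    window
        Optional (T_min, T_max) in kelvin restricting the fit; default
        keeps all points with 0.01 < x < 0.99.
    """
    t_arr = as_1d_float(temperature, "temperature")
    x_arr = as_1d_float(conversion, "conversion")
    if len(t_arr) != len(x_arr):
        raise DomainError("temperature and conversion must have equal length")
    if alpha <= 0:
        raise DomainError("alpha must be > 0")
    if window is not None:
        keep = (t_arr >= window[0]) & (t_arr <= window[1])
    else:
        keep = (x_arr > 0.01) & (x_arr < 0.99)
    t_w, x_w = t_arr[keep], x_arr[keep]
    n_windowed_out = int((~keep).sum())
    inv_t, ordinate, n_excl = cr_transform(x_w, t_w, convention)
    n_excluded = n_excl + n_windowed_out
    if len(inv_t) < 3:
        raise IncompleteDataError(
            f"only {len(inv_t)} usable points after exclusions; need >= 3"
        )
    slope, intercept = np.polyfit(inv_t, ordinate, 1)
    fitted = slope * inv_t + intercept
    ss_res = float(np.sum((ordinate - fitted) ** 2))
    ss_tot = float(np.sum((ordinate - ordinate.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        warnings.warn("non-negative slope: implied activation energy is <= 0",
                      stacklevel=2)
    if convention == "study":
        e_act = -slope / STUDY_SLOPE_FACTOR
        a_pre = np.nan
        if e_act != 0:
            a_pre = (alpha * R_GAS / e_act) * np.exp(intercept + STUDY_INTERCEPT_SHIFT)
    else:
        e_act = -slope * R_GAS
        a_pre = np.nan
        if e_act != 0:
            a_pre = (alpha * e_act / R_GAS) * np.exp(intercept)
    t_used = t_w[(x_w > 0.0) & (x_w < 1.0)]
    window_used = (float(t_used.min()), float(t_used.max()))
    return ArrheniusFit(float(e_act), float(a_pre), float(slope), float(intercept),
                        float(r2), window_used, len(inv_t), n_excluded, convention)


class CoatsRedfernModel:
    """Model-object wrapper around the linearized activation-energy fit.

    Accepts either a (T, x) conversion series or a :class:`TgCurve`
    (converted via :func:`conversion_from_mass`).
    """

    def __init__(self, temperature, conversion, alpha: float = 10.0):
        self.temperature = as_1d_float(temperature, "temperature")
        self.conversion = as_1d_float(conversion, "conversion")
        self.alpha = float(alpha)

    @classmethod
    def from_tg_curve(cls, curve: TgCurve, m0=None, mf=None) -> "CoatsRedfernModel":
        x = conversion_from_mass(curve, m0, mf)
        return cls(curve.temperature, x, alpha=curve.heating_rate)

    @classmethod
    def from_dataframe(cls, frame, alpha: float = 10.0) -> "CoatsRedfernModel":
        """Columns ``temperature_K,conversion`` or ``temperature_C,mass``."""
        if {"temperature_K", "conversion"} <= set(frame.columns):
            return cls(frame["temperature_K"].to_numpy(),
                       frame["conversion"].to_numpy(), alpha=alpha)
        if {"temperature_C", "mass"} <= set(frame.columns):
            curve = TgCurve.from_celsius(frame["temperature_C"].to_numpy(),
                                         frame["mass"].to_numpy(), heating_rate=alpha)
            return cls.from_tg_curve(curve)
        raise IncompleteDataError(
            "expected columns temperature_K,conversion or temperature_C,mass"
        )

    def fit(self, convention: str = "study", window=None) -> ArrheniusFit:
        return fit_activation_energy(self.temperature, self.conversion,
                                     alpha=self.alpha, convention=convention,
                                     window=window)
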