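"""Closed-form bioprocess metrics.

Ferrous-iron conversion in solution (a proxy for the growth activity of the
iron-oxidizing culture), the desulfurization rate of a coal sample from its
inorganic-sulfur assays, the pyritic share of total sulfur, and the Fe2+
content delivered by ferrous sulfate heptahydrate in 9 K medium.

All percentages are on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_up
from .exceptions import DomainError

#: Molar mass of iron, g/mol (IUPAC 2021).
MOLAR_MASS_FE = 55.845
#: Molar mass of FeSO4.7H2O, g/mol.
MOLAR_MASS_FESO4_7H2O = 278.01


@dataclass(frozen=True)
class SulfurAssay:
    """Sulfur speciation of a coal sample, all in % mass.

    ``s_before``/``s_after`` are the inorganic-sulfur contents before and
    after desulfurization; ``total_sulfur`` and ``pyritic_sulfur`` describe
    the raw coal.
    """

    total_sulfur: float = 2.39
    pyritic_sulfur: float = 1.35
    s_before: float = 1.35
    s_after: float = 1.35

    def __post_init__(self):
        if not 0.0 <= self.pyritic_sulfur <= self.total_sulfur:
            raise DomainError(
                f"pyritic sulfur {self.pyritic_sulfur} must lie in "
                f"[0, total sulfur {self.total_sulfur}]"
            )
        if not 0.0 <= self.s_after <= self.s_before:
            raise DomainError(
                f"post-treatment inorganic sulfur {self.s_after} must lie in "
                f"[0, pre-treatment {self.s_before}]"
            )


@dataclass(frozen=True)
class IronState:
    """Initial and instantaneous Fe2+ concentration in solution, g/L."""

    c0: float
    c: float

    def __post_init__(self):
        if self.c0 <= 0:
            raise DomainError(f"initial Fe2+ concentration must be > 0, got {self.c0}")
        if not 0.0 <= self.c <= self.c0:
            raise DomainError(
                f"instantaneous Fe2+ concentration {self.c} outside [0, {self.c0}] "
                "(reverse reaction is not modelled)"
            )


def fe2_conversion(state: IronState) -> float:
    """Fe2+ conversion eta = 100*(c0 - c)/c0, in percent (clipped to
    [0, 100] against roundoff)."""
    return float(min(max(100.0 * (state.c0 - state.c) / state.c0, 0.0), 100.0))


def desulfurization_rate(assay: SulfurAssay) -> float:
    """Desulfurization rate w = 100*(S_B - S_A)/S_B, in percent.

    S_B and S_A are the inorganic-sulfur contents of the coal before and
    after microbial treatment.
    """
    if assay.s_before <= 0:
        raise DomainError("pre-treatment inorganic sulfur must be > 0")
    return 100.0 * (assay.s_before - assay.s_after) / assay.s_before


def pyritic_share(assay: SulfurAssay, ndigits: int = 2) -> float:
    """Pyritic sulfur as a percent of total sulfur, rounded half-up for display."""
    if assay.total_sulfur <= 0:
        raise DomainError("total sulfur must be > 0")
    return round_half_up(100.0 * assay.pyritic_sulfur / assay.total_sulfur, ndigits)


def fe2_from_heptahydrate(mass_conc: float) -> float:
    """Fe2+ concentration (g/L) delivered by ``mass_conc`` g/L of FeSO4.7H2O.

    The 9 K medium's 44.2 g/L of heptahydrate corresponds to 8.88 g/L Fe2+.
    """
    if mass_conc < 0:
        raise DomainError(f"mass concentration must be >= 0, got {mass_conc}")
    return mass_conc * MOLAR_MASS_FE / MOLAR_MASS_FESO4_7H2O
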