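"""Bundled study data and published reference values.

The fixture is the run-level L16(4^4) table of the Datong coal
biodesulfurization experiment: factor levels for temperature, particle
size, initial pH and inoculum volume, plus the measured desulfurization
rate (%) of each run. Only run-level data are stored; every derived
quantity (K sums, ranges, sums of squares) is recomputed by the package.

``PUBLISHED_*`` hold the values as printed in the original study report,
used solely to cross-check recomputation (`check_published_values`): two of
the printed numbers (the level-4 sum for factor D and the pH sum of
squares, hence the total) are internally inconsistent with the printed
run-level responses, and the cross-check flags them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._util import round_half_up
from .orthogonal import DesignTable, FactorSpec, OrthogonalResults

FACTOR_SPECS = (
    FactorSpec("A", "temperature", "degC", (20.0, 25.0, 30.0, 35.0)),
    FactorSpec("B", "coal particle size", "mesh", (60.0, 80.0, 100.0, 120.0)),
    FactorSpec("C", "initial pH", "", (1.5, 2.0, 2.5, 3.0)),
    FactorSpec("D", "inoculum volume", "mL", (5.0, 10.0, 15.0, 20.0)),
)

#: Printed range-analysis table: level sums, ranges, superior levels.
PUBLISHED_RANGE = {
    "level_sums": {
        "A": [205.13, 230.86, 267.62, 221.03],
        "B": [207.97, 233.65, 235.30, 247.72],
        "C": [209.16, 255.23, 233.15, 227.10],
        "D": [211.78, 233.98, 252.06, 223.82],
    },
    "ranges": {"A": 15.63, "B": 9.94, "C": 11.52, "D": 10.07},
    "superior_levels": {"A": 3, "B": 4, "C": 2, "D": 3},
}

#: Printed ANOVA table entries (sum of squares and F).
PUBLISHED_ANOVA = {
    "sum_sq": {"A": 527.40, "B": 208.84, "C": 365.97, "D": 209.80,
               "Error": 36.95, "Total": 1348.96},
    "F": {"A": 14.28, "B": 5.65, "C": 9.90, "D": 5.68},
}


def load_desulfurization_design() -> DesignTable:
    """The bundled 16-run design with measured responses."""
    with resources.files("biodesulf.data").joinpath("l16_desulfurization.csv").open() as fh:
        frame = pd.read_csv(fh)
    return DesignTable(frame, {s.factor_id: s for s in FACTOR_SPECS})


def check_published_values(results: OrthogonalResults, atol: float = 0.005) -> list:
    """Compare recomputed range/ANOVA values against the published tables.

    Returns a list of discrepancy strings (empty if everything matches at
    2-decimal display precision). Recomputed values are authoritative; the
    published table is only a cross-check.
    """
    issues = []
    rs = results.range_summary
    for f, pub_sums in PUBLISHED_RANGE["level_sums"].items():
        for i, pub in enumerate(pub_sums):
            got = round_half_up(rs.level_sums[f][i], 2)
            if abs(got - pub) > atol:
                issues.append(
                    f"level sum K_{i + 1}{f}: recomputed {got:.2f}, published {pub:.2f}"
                )
    # published ranges difference already-rounded means
    disp_ranges = rs.rounded(2).ranges
    for f, pub in PUBLISHED_RANGE["ranges"].items():
        if abs(disp_ranges[f] - pub) > atol:
            issues.append(f"range R_{f}: recomputed {disp_ranges[f]:.2f}, published {pub:.2f}")
    for f, pub in PUBLISHED_RANGE["superior_levels"].items():
        if rs.superior_level[f] != pub:
            issues.append(
                f"superior level for {f}: recomputed {rs.superior_level[f]}, published {pub}"
            )
    an = results.anova_summary.table
    for src, pub in PUBLISHED_ANOVA["sum_sq"].items():
        got = round_half_up(float(an.loc[src, "sum_sq"]), 2)
        if abs(got - pub) > atol:
            issues.append(f"sum of squares {src}: recomputed {got:.2f}, published {pub:.2f}")
    for src, pub in PUBLISHED_ANOVA["F"].items():
        got = round_half_up(float(an.loc[src, "F"]), 2)
        if abs(got - pub) > atol:
            issues.append(f"F_{src}: recomputed {got:.2f}, published {pub:.2f}")
    return issues
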