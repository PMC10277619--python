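"""L16(4^4) orthogonal-design analysis of desulfurization experiments.

A Taguchi-style screening design: four factors (temperature, coal particle
size, initial pH, inoculum volume) at four levels each, sixteen runs, every
level of every factor appearing exactly four times. Two analyses are
provided on the run-level responses:

* range analysis — per-factor level sums ``K``, level means, range ``R``
  (spread of level means) and the "superior level" that optimizes the mean
  response;
* analysis of variance — the balanced-design sum-of-squares decomposition
  ``SS_j = sum_i K_ij^2 / 4 - T^2/16`` with 3 df per factor, 3 error df and
  F tests against the pooled error mean square on the F(3, 3) distribution.

Interactions are not modelled (the design aliases them with the error).

The model object follows the fit/Results pattern::

    model = OrthogonalModel(design)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .exceptions import IncompleteDataError, InvalidDesignError

FACTORS = ("A", "B", "C", "D")
N_RUNS = 16
N_LEVELS = 4

#: The standard L16(4^4) level assignment (rows = runs, columns = A..D).
L16_ARRAY = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [1, 4, 4, 4],
        [2, 2, 3, 4],
        [2, 1, 4, 3],
        [2, 4, 1, 2],
        [2, 3, 2, 1],
        [3, 3, 4, 2],
        [3, 4, 3, 1],
        [3, 1, 2, 4],
        [3, 2, 1, 3],
        [4, 4, 2, 3],
        [4, 3, 1, 4],
        [4, 2, 4, 1],
        [4, 1, 3, 2],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its four physical level values."""

    factor_id: str
    name: str
    unit: str
    level_values: tuple

    def __post_init__(self):
        if self.factor_id not in FACTORS:
            raise InvalidDesignError(f"factor_id must be one of {FACTORS}")
        if len(self.level_values) != N_LEVELS:
            raise InvalidDesignError(
                f"factor {self.factor_id} needs exactly {N_LEVELS} level values"
            )
        if len(set(self.level_values)) != N_LEVELS:
            raise InvalidDesignError(f"factor {self.factor_id} level values must be distinct")


class DesignTable:
    """Sixteen runs of the L16(4^4) design with an optional response column.

    Parameters
    ----------
    frame
        DataFrame with columns ``run, A, B, C, D`` (levels 1-4) and
        optionally ``response`` (desulfurization rate, %).
    factor_specs
        Optional mapping of factor id to :class:`FactorSpec` for reporting.
    """

    def __init__(self, frame: pd.DataFrame, factor_specs=None):
        frame = frame.copy()
        missing = [c for c in ("run", *FACTORS) if c not in frame.columns]
        if missing:
            raise InvalidDesignError(f"design table missing columns {missing}")
        if len(frame) != N_RUNS:
            raise InvalidDesignError(f"expected {N_RUNS} runs, got {len(frame)}")
        if sorted(frame["run"]) != list(range(1, N_RUNS + 1)):
            raise InvalidDesignError("run ids must be 1..16")
        frame = frame.sort_values("run").reset_index(drop=True)
        for f in FACTORS:
            levels = frame[f].to_numpy()
            counts = np.bincount(levels, minlength=N_LEVELS + 1)[1:]
            if not np.all(counts == N_RUNS // N_LEVELS):
                raise InvalidDesignError(
                    f"factor {f} is unbalanced: level counts {counts.tolist()}"
                )
        if "response" in frame.columns and frame["response"].notna().any():
            r = frame["response"].to_numpy(dtype=float)
            if np.isfinite(r).all() and (r < 0).any():
                raise InvalidDesignError("responses must be >= 0")
        else:
            frame["response"] = np.nan
        self.frame = frame
        self.factor_specs = dict(factor_specs or {})

    @property
    def responses(self) -> np.ndarray:
        return self.frame["response"].to_numpy(dtype=float)

    def with_responses(self, responses) -> "DesignTable":
        responses = np.asarray(responses, dtype=float)
        if responses.shape != (N_RUNS,):
            raise IncompleteDataError(f"need {N_RUNS} responses, got shape {responses.shape}")
        frame = self.frame.copy()
        frame["response"] = responses
        return DesignTable(frame, self.factor_specs)

    def require_complete(self):
        r = self.responses
        if not np.isfinite(r).all():
            bad = (self.frame["run"][~np.isfinite(r)]).tolist()
            raise IncompleteDataError(f"runs {bad} have missing responses")

    def __eq__(self, other):
        return isinstance(other, DesignTable) and self.frame.equals(other.frame)


def build_l16_design(factor_specs) -> DesignTable:
    """Construct the 16-run L16(4^4) scheme for four factor specifications.

    Responses are left unset; the returned table carries the level indices
    of the standard array together with the physical level values of each
    :class:`FactorSpec`.
    """
    specs = list(factor_specs)
    if len(specs) != 4:
        raise InvalidDesignError(f"need exactly 4 factors, got {len(specs)}")
    ids = [s.factor_id for s in specs]
    if sorted(ids) != list(FACTORS):
        raise InvalidDesignError(f"factor ids must be A,B,C,D exactly once, got {ids}")
    frame = pd.DataFrame(L16_ARRAY, columns=FACTORS)
    frame.insert(0, "run", np.arange(1, N_RUNS + 1))
    return DesignTable(frame, {s.factor_id: s for s in specs})


@dataclass
class RangeSummary:
    """Range-analysis output: level sums/means, ranges and superior levels.

    ``level_sums[f][i-1]`` is K_if, the sum of the four responses with factor
    ``f`` at level ``i``; ``ranges[f]`` is the spread of the level means and
    ``superior_level[f]`` the 1-based level index with the best mean.
    """

    level_sums: dict
    level_means: dict
    ranges: dict
    superior_level: dict
    grand_sum: float
    maximize: bool = True

    def rounded(self, ndigits: int = 2) -> "RangeSummary":
        """Display variant rounded half-up; ranges recomputed from rounded
        means, matching how printed tables difference already-rounded rows."""
        from decimal import ROUND_HALF_UP, Decimal

        sums = {f: [round_half_up(v, ndigits) for v in k] for f, k in self.level_sums.items()}
        # means are displayed as the rounded sums divided by 4 in decimal
        # arithmetic (57.715 -> 57.72), as printed tables do
        q = Decimal(10) ** -ndigits
        means = {
            f: [float((Decimal(f"{v:.{ndigits}f}") / 4).quantize(q, rounding=ROUND_HALF_UP))
                for v in k]
            for f, k in sums.items()
        }
        ranges = {f: round_half_up(max(m) - min(m), ndigits) for f, m in means.items()}
        return RangeSummary(
            sums, means, ranges, dict(self.superior_level),
            round_half_up(self.grand_sum, ndigits), self.maximize,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for i in range(N_LEVELS):
            rows[f"K{i + 1}"] = {f: self.level_sums[f][i] for f in FACTORS}
        for i in range(N_LEVELS):
            rows[f"mean{i + 1}"] = {f: self.level_means[f][i] for f in FACTORS}
        rows["R"] = dict(self.ranges)
        rows["superior_level"] = dict(self.superior_level)
        return pd.DataFrame(rows).T[list(FACTORS)]


@dataclass
class AnovaSummary:
    """Per-source ANOVA table (A, B, C, D, Error, Total)."""

    table: pd.DataFrame = field(repr=False)

    @property
    def ss(self) -> pd.Series:
        return self.table["sum_sq"]

    @property
    def f_values(self) -> pd.Series:
        return self.table.loc[list(FACTORS), "F"]

    def significance_flag(self, p: float) -> str:
        if p < 0.01:
            return "very significant"
        if p < 0.05:
            return "significant"
        return "not significant"


def range_analysis(design: DesignTable, maximize: bool = True) -> RangeSummary:
    """Per-factor K sums, level means, ranges and superior levels."""
    design.require_complete()
    y = design.responses
    sums, means, ranges, superior = {}, {}, {}, {}
    for f in FACTORS:
        levels = design.frame[f].to_numpy()
        k = [float(y[levels == i].sum()) for i in range(1, N_LEVELS + 1)]
        m = [ki / (N_RUNS // N_LEVELS) for ki in k]
        sums[f], means[f] = k, m
        ranges[f] = max(m) - min(m)
        best = np.argmax(m) if maximize else np.argmin(m)
        superior[f] = int(best) + 1
    return RangeSummary(sums, means, ranges, superior, float(y.sum()), maximize)


def anova(design: DesignTable) -> AnovaSummary:
    """Balanced L16 ANOVA with pooled 3-df error and F(3, 3) p-values."""
    design.require_complete()
    y = design.responses
    grand = y.sum()
    correction = grand**2 / N_RUNS
    ss_total = float((y**2).sum() - correction)
    rs = range_analysis(design)
    ss = {
        f: float(sum(k**2 for k in rs.level_sums[f]) / (N_RUNS // N_LEVELS) - correction)
        for f in FACTORS
    }
    ss_error = ss_total - sum(ss.values())
    # tiny negative residual from cancellation is numerically zero
    if ss_error < 0 and ss_error > -1e-9 * max(ss_total, 1.0):
        ss_error = 0.0
    df_factor, df_error = N_LEVELS - 1, 3
    ms_error = ss_error / df_error
    rows = []
    for f in FACTORS:
        ms = ss[f] / df_factor
        if ms_error == 0.0:
            warnings.warn("error mean square is zero; F reported as infinite", stacklevel=2)
            fval, p = np.inf, 0.0
        else:
            fval = ms / ms_error
            p = float(stats.f.sf(fval, df_factor, df_error))
        rows.append((f, df_factor, ss[f], ms, fval, p))
    rows.append(("Error", df_error, ss_error, ms_error, np.nan, np.nan))
    rows.append(("Total", N_RUNS - 1, ss_total, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["source", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("source")
    return AnovaSummary(table)


def significance_order(anova_summary: AnovaSummary) -> list:
    """Factors sorted by descending F (ties broken by label, with a warning)."""
    f = anova_summary.f_values
    vals = f.to_numpy()
    if len(set(np.round(vals, 12))) < len(vals):
        warnings.warn("tied F statistics; breaking ties by factor label", stacklevel=2)
    order = sorted(FACTORS, key=lambda k: (-f[k], k))
    return order


class OrthogonalModel:
    """Range analysis and ANOVA of an L16(4^4) experiment.

    Parameters
    ----------
    design
        A complete :class:`DesignTable` (all 16 responses present).
    maximize
        Whether the superior level maximizes (default) or minimizes the
        response.
    """

    def __init__(self, design: DesignTable, maximize: bool = True):
        design.require_complete()
        self.design = design
        self.maximize = maximize

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "OrthogonalModel":
        return cls(DesignTable(frame), **kwargs)

    def fit(self) -> "OrthogonalResults":
        rs = range_analysis(self.design, maximize=self.maximize)
        an = anova(self.design)
        return OrthogonalResults(self, rs, an)


class OrthogonalResults:
    """Fitted orthogonal-analysis results with a printable summary."""

    def __init__(self, model: OrthogonalModel, range_summary: RangeSummary,
                 anova_summary: AnovaSummary):
        self.model = model
        self.range_summary = range_summary
        self.anova_summary = anova_summary

    @property
    def significance_order(self) -> list:
        return significance_order(self.anova_summary)

    @property
    def superior_levels(self) -> dict:
        return dict(self.range_summary.superior_level)

    def optimum_label(self) -> str:
        """Compact condition label, e.g. ``A3B4C2D3``."""
        return "".join(f"{f}{lvl}" for f, lvl in self.superior_levels.items())

    def summary(self, ndigits: int = 2) -> str:
        rs = self.range_summary.rounded(ndigits)
        lines = ["Orthogonal experiment analysis (L16, 4 factors x 4 levels)", ""]
        lines.append("Range analysis")
        lines.append(rs.to_frame().to_string())
        lines.append(f"Optimal condition: {self.optimum_label()}")
        lines.append("")
        lines.append("Analysis of variance")
        tab = self.anova_summary.table.copy()
        for col in ("sum_sq", "mean_sq", "F"):
            tab[col] = [round_half_up(v, ndigits) if np.isfinite(v) else v for v in tab[col]]
        tab["p"] = [round_half_up(v, 3) if np.isfinite(v) else v for v in tab["p"]]
        tab["signif"] = [
            self.anova_summary.significance_flag(p) if np.isfinite(p) else ""
            for p in self.anova_summary.table["p"]
        ]
        lines.append(tab.to_string())
        lines.append(f"Significance order: {' > '.join(self.significance_order)}")
        return "\n".join(lines)

    def to_dict(self, ndigits=None) -> dict:
        """JSON-ready report; full precision by default."""
        rs = self.range_summary if ndigits is None else self.range_summary.rounded(ndigits)
        an = self.anova_summary.table
        return {
            "range_analysis": {
                "level_sums": rs.level_sums,
                "level_means": rs.level_means,
                "ranges": rs.ranges,
                "superior_levels": rs.superior_level,
            },
            "anova": {
                src: {
                    k: (None if not np.isfinite(v) else v)
                    for k, v in row.items()
                }
                for src, row in an.to_dict(orient="index").items()
            },
            "significance_order": self.significance_order,
            "optimum": self.optimum_label(),
        }

    def plot_level_means(self, ax=None):
        """Main-effects plot: mean response per level for each factor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f in FACTORS:
            ax.plot(range(1, N_LEVELS + 1), self.range_summary.level_means[f],
                    marker="o", label=f)
        ax.set_xlabel("level")
        ax.set_ylabel("mean desulfurization rate (%)")
        ax.set_xticks(range(1, N_LEVELS + 1))
        ax.legend(title="factor")
        return ax
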