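"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed engineering tables do.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    the half-up convention of the reference tables at exact .5 ties.
    """
    if not np.isfinite(value):
        return float(value)
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr
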