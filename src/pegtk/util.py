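"""Small numeric helpers shared across modules.

Rounding of values that are compared with printed report tables uses
half-up rounding (the convention of the source tables), not Python's
default banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    >>> round_half_up(136.147, 1)
    136.1
    >>> round_half_up(0.125, 2)
    0.13
    """
    q = Decimal("1") if ndigits == 0 else Decimal(f"1e-{ndigits}")
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 maps to 0)."""
    if x == 0:
        return 0.0
    return float(f"{float(x):.{sig}g}")


def trim_number(x: float) -> str:
    """Format a percentage the way report tables print it: 2 decimals with
    trailing zeros (and a bare trailing point) dropped, so 10.00 -> "10",
    0.00 -> "0", 31.58 -> "31.58"."""
    s = f"{round_half_up(x, 2):.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def as_grid(times) -> np.ndarray:
    """Validate and return a strictly increasing, non-negative time grid."""
    from .errors import InputError

    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise InputError("time grid must be a 1-D array with at least one point")
    if t[0] < 0:
        raise InputError("time grid must start at t >= 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InputError("time grid must be strictly increasing")
    return t
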