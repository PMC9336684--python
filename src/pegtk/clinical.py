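"""Adverse-reaction (AR) incidence arithmetic and two-group comparisons.

Incidences are exact rational counts expressed as percentages, rounded
half-up to 2 decimals; the display convention of the source report
tables drops trailing zeros ("10", "0").  Two-group comparisons use a
chi-square test with continuity correction, switching to Fisher's exact
test when any expected cell count is below 5; the reported clinical
claim is the significance flag at the two-sided 0.05 level, which is
robust to the choice of test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .errors import InputError
from .util import round_half_up, trim_number

AR_COLUMNS = ["arm", "period", "n", "n_ar", "n_cns_ar"]


class ARTable:
    """Per-arm, per-period adverse-reaction counts and denominators."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in AR_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"ARTable missing columns: {missing}")
        df = df[AR_COLUMNS].reset_index(drop=True)
        for i, row in df.iterrows():
            for col in ("n", "n_ar", "n_cns_ar"):
                v = row[col]
                if v < 0 or v != int(v):
                    raise InputError(f"row {i}: {col}={v} is not a non-negative integer")
            if row["n_ar"] > row["n"] or row["n_cns_ar"] > row["n"]:
                raise InputError(f"row {i}: event count exceeds denominator")
        self.df = df.astype({"n": int, "n_ar": int, "n_cns_ar": int})

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ARTable":
        return cls(pd.read_csv(path))


def incidence(events: int, n: int) -> float:
    """Percentage incidence 100*events/n, half-up to 2 decimals."""
    if n <= 0:
        raise InputError("denominator must be > 0")
    if not 0 <= events <= n:
        raise InputError(f"events must be in [0, {n}]")
    return round_half_up(100.0 * events / n, 2)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group proportion comparison."""

    p_value: float
    method: str
    significant: bool  # two-sided, alpha = 0.05

    @property
    def flag(self) -> str:
        return "significant" if self.significant else "not significant"


def compare_proportions(
    e1: int, n1: int, e2: int, n2: int, method: str = "auto"
) -> ComparisonResult:
    """Two-sided comparison of event proportions e1/n1 vs e2/n2.

    ``method``: "chi2" (with continuity correction), "fisher", or "auto"
    (Fisher whenever any expected cell count is < 5).  Degenerate tables
    with a zero margin return p = 1 with a warning.
    """
    for e, n in ((e1, n1), (e2, n2)):
        if n <= 0 or not 0 <= e <= n:
            raise InputError("invalid counts")
    table = np.array([[e1, n1 - e1], [e2, n2 - e2]])
    if table.sum(axis=0).min() == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return ComparisonResult(p_value=1.0, method="degenerate", significant=False)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if method == "auto":
        method = "fisher" if expected.min() < 5 else "chi2"
    if method == "fisher":
        p = float(fisher_exact(table, alternative="two-sided")[1])
    elif method == "chi2":
        p = float(chi2_contingency(table, correction=True)[1])
    else:
        raise InputError(f"unknown method {method!r}")
    return ComparisonResult(p_value=p, method=method, significant=p <= 0.05)


def period_table(ar: ARTable) -> pd.DataFrame:
    """Add AR% and CNS-AR% columns (numeric and display-formatted) to an
    AR table, preserving row order."""
    if ar.df.empty:
        raise InputError("AR table is empty")
    out = ar.df.copy()
    out["ar_pct"] = [incidence(e, n) for e, n in zip(out["n_ar"], out["n"])]
    out["cns_ar_pct"] = [incidence(e, n) for e, n in zip(out["n_cns_ar"], out["n"])]
    out["ar_pct_display"] = [trim_number(x) for x in out["ar_pct"]]
    out["cns_ar_pct_display"] = [trim_number(x) for x in out["cns_ar_pct"]]
    return out
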