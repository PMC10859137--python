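"""Rare-variant carrier association: Fisher's exact test on 2x2 tables.

Emulates a single-gene natural experiment (e.g. glucokinase loss-of-function
carriers, who have stable lifelong mildly raised fasting glucose): carrier
status is cross-tabulated against case status per condition and tier and
tested with Fisher's exact test.  The headline odds ratio is the conditional
maximum-likelihood estimate with an exact CI from the non-central
hypergeometric distribution; the sample OR (ad/bc) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "TableError",
    "fisher_exact",
    "carrier_association",
]


class TableError(ValueError):
    """Invalid 2x2 table."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-case counts: a=carrier cases, b=carrier non-cases,
    c=non-carrier cases, d=non-carrier non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise TableError(f"cell {name} must be a non-negative integer (got {v!r})")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def sample_or(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return self.a * self.d / (self.b * self.c)


@dataclass
class FisherResult:
    table: ContingencyTable2x2
    p: float
    odds_ratio: float  # conditional MLE
    sample_or: float
    ci_low: float
    ci_high: float
    or_defined: bool


def fisher_exact(table: ContingencyTable2x2, confidence: float = 0.95) -> FisherResult:
    """Exact two-sided test and conditional-MLE OR with exact CI.

    The two-sided p sums hypergeometric probabilities of all tables (with
    the observed margins) no more likely than the observed one.  With a
    zero margin every table consistent with the margins is the observed
    one: p = 1 and the OR is flagged undefined.
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if 0 in row or 0 in col:
        return FisherResult(
            table=table,
            p=1.0,
            odds_ratio=float("nan"),
            sample_or=table.sample_or,
            ci_low=float("nan"),
            ci_high=float("nan"),
            or_defined=False,
        )
    p = float(_scipy_fisher(arr, alternative="two-sided").pvalue)
    res = _scipy_odds_ratio(arr)  # conditional MLE
    ci = res.confidence_interval(confidence_level=confidence)
    return FisherResult(
        table=table,
        p=min(p, 1.0),
        odds_ratio=float(res.statistic),
        sample_or=table.sample_or,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        or_defined=True,
    )


def carrier_association(
    carrier_flag: np.ndarray,
    case_status: Mapping[str, np.ndarray] | np.ndarray,
) -> pd.DataFrame | tuple[ContingencyTable2x2, FisherResult]:
    """Cross-tabulate carrier status against case status and test.

    With a single status vector, returns ``(table, FisherResult)``.  With a
    mapping of labelled status vectors (e.g. ``"frozen_shoulder/specific"``),
    returns a tidy results frame with one row per label.  Zero carriers
    yield an explicit undefined-OR row (p = 1), never a crash.
    """
    carrier = np.asarray(carrier_flag, dtype=int)

    def one(status: np.ndarray) -> tuple[ContingencyTable2x2, FisherResult]:
        status = np.asarray(getattr(status, "status", status), dtype=int)
        if status.shape != carrier.shape:
            raise TableError(
                f"carrier flag (n={carrier.shape[0]}) and case status "
                f"(n={status.shape[0]}) are not aligned"
            )
        t = ContingencyTable2x2(
            a=int(np.sum((carrier == 1) & (status == 1))),
            b=int(np.sum((carrier == 1) & (status == 0))),
            c=int(np.sum((carrier == 0) & (status == 1))),
            d=int(np.sum((carrier == 0) & (status == 0))),
        )
        return t, fisher_exact(t)

    if isinstance(case_status, Mapping):
        rows = []
        for label, status in case_status.items():
            t, r = one(status)
            rows.append(
                {
                    "label": label,
                    "carrier_cases": t.a,
                    "carrier_noncases": t.b,
                    "noncarrier_cases": t.c,
                    "noncarrier_noncases": t.d,
                    "odds_ratio": r.odds_ratio,
                    "sample_or": r.sample_or,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                    "or_defined": r.or_defined,
                }
            )
        return pd.DataFrame(rows)
    return one(case_status)
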