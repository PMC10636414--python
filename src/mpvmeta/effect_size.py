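"""Standardized mean differences (SMD) from two-arm summary statistics.

Three flavors are supported:

* ``cohen`` — Cohen's d: the raw mean difference divided by the pooled SD.
* ``hedges`` — Hedges' g: d shrunk by the small-sample correction
  J = 1 - 3/(4m - 1) with m = n1 + n2 - 2 (default; an exact
  gamma-function J is available).
* ``glass`` — Glass's delta: the control-arm SD as divisor.

The sampling variance of d uses the large-sample form
``v = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))`` by default; the df-adjusted
variant replaces the second denominator with ``2*(n1+n2-2)``.  Hedges'
variance is ``J^2 * v``.  Positive SMD means the patient arm has the higher
mean.  The default flavor (Hedges, large-sample variance) is the
configuration that reproduces the published pooled results from the packaged
table; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.special import gammaln

from .study_data import StudyRecord, StudyTable

__all__ = [
    "EffectEstimate",
    "FLAVORS",
    "DEFAULT_FLAVOR",
    "pooled_sd",
    "hedges_j",
    "smd",
    "effect_table",
    "effects_frame",
]

FLAVORS = ("cohen", "hedges", "glass")
DEFAULT_FLAVOR = "hedges"
DEFAULT_VARIANCE = "large-sample"


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study SMD with its sampling variance."""

    study_id: str
    theta: float
    variance: float
    flavor: str

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def pooled_sd(s1: float, n1: int, s2: float, n2: int) -> float:
    """Pooled within-group standard deviation of two arms.

    ``sqrt(((n1-1)*s1^2 + (n2-1)*s2^2) / (n1+n2-2))``
    """
    if n1 + n2 <= 2:
        raise ValueError(f"degenerate arms: n1+n2-2 = {n1 + n2 - 2} must be positive")
    return math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))


def hedges_j(m: int, exact: bool = False) -> float:
    """Small-sample correction factor J on ``m = n1 + n2 - 2`` df.

    The default is the usual approximation ``1 - 3/(4m - 1)``; ``exact=True``
    evaluates ``Gamma(m/2) / (sqrt(m/2) * Gamma((m-1)/2))``.  The two agree to
    better than 1e-3 for m >= 10.
    """
    if exact:
        return math.exp(gammaln(m / 2) - gammaln((m - 1) / 2)) / math.sqrt(m / 2)
    return 1 - 3 / (4 * m - 1)


def smd(
    record: StudyRecord,
    flavor: str = DEFAULT_FLAVOR,
    variance: str = DEFAULT_VARIANCE,
    exact_j: bool = False,
) -> EffectEstimate:
    """Standardized mean difference for one study.

    Parameters
    ----------
    record : StudyRecord
        Valid two-arm summary row.
    flavor : {'cohen', 'hedges', 'glass'}
        SMD variant; see module docstring.
    variance : {'large-sample', 'df-adjusted'}
        Denominator of the d^2 term in the sampling variance.
    exact_j : bool
        Use the exact gamma-function small-sample correction (hedges only).
    """
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {FLAVORS}")
    if variance not in ("large-sample", "df-adjusted"):
        raise ValueError(f"unknown variance variant {variance!r}")
    n1, n2 = record.n_case, record.n_control
    m = n1 + n2 - 2
    diff = record.mean_case - record.mean_control

    if flavor == "glass":
        theta = diff / record.sd_control
        # Glass delta: d^2 term on the control-arm df
        var = (n1 + n2) / (n1 * n2) + theta**2 / (2 * (n2 - 1))
        return EffectEstimate(record.study_id, theta, var, flavor)

    d = diff / pooled_sd(record.sd_case, n1, record.sd_control, n2)
    denom = (n1 + n2) if variance == "large-sample" else m
    v = (n1 + n2) / (n1 * n2) + d**2 / (2 * denom)
    if flavor == "cohen":
        return EffectEstimate(record.study_id, d, v, flavor)
    j = hedges_j(m, exact=exact_j)
    return EffectEstimate(record.study_id, j * d, j**2 * v, flavor)


def effect_table(
    table: StudyTable,
    flavor: str = DEFAULT_FLAVOR,
    variance: str = DEFAULT_VARIANCE,
    exact_j: bool = False,
) -> list[EffectEstimate]:
    """Per-study effect estimates for a whole table, order preserved."""
    out = []
    for record in table:
        try:
            out.append(smd(record, flavor=flavor, variance=variance, exact_j=exact_j))
        except ValueError as exc:
            raise ValueError(f"study {record.study_id!r}: {exc}") from exc
    return out


def effects_frame(effects: Sequence[EffectEstimate]):
    """Effects as a DataFrame (study_id, theta, variance, se) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "theta": [e.theta for e in effects],
            "variance": [e.variance for e in effects],
            "se": [e.se for e in effects],
        }
    )
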