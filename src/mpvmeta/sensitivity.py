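"""Sensitivity analyses: leave-one-out re-pooling and exclusion re-analyses.

Leave-one-out drops each study in turn and re-pools the remaining k - 1
under DL random effects, re-estimating tau^2 each time.  Exclusion analysis
applies a named selection rule (e.g. total sample size >= 100, no recent
antipsychotic exposure) and re-pools the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .effect_size import DEFAULT_FLAVOR, DEFAULT_VARIANCE, effect_table
from .pooling import PooledSummary, pool_random_dl
from .study_data import StudyRecord, StudyTable, filter_studies

__all__ = ["LeaveOneOutResult", "leave_one_out", "exclusion_analysis"]


@dataclass(frozen=True)
class LeaveOneOutResult:
    """One DL re-pooling per excluded study, keyed by its label."""

    rows: dict  # excluded study_id -> PooledSummary on the remaining k-1
    min_theta: float
    max_theta: float
    argmin: str  # excluded study giving the minimum pooled estimate
    argmax: str

    @property
    def min_summary(self) -> PooledSummary:
        return self.rows[self.argmin]

    @property
    def max_summary(self) -> PooledSummary:
        return self.rows[self.argmax]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "excluded": sid,
                    "theta_hat": s.theta_hat,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "I2": s.I2,
                }
                for sid, s in self.rows.items()
            ]
        )


def leave_one_out(
    table: StudyTable,
    flavor: str = DEFAULT_FLAVOR,
    variance: str = DEFAULT_VARIANCE,
) -> LeaveOneOutResult:
    """Re-pool after removing each study in turn (k >= 3)."""
    if len(table) < 3:
        raise ValueError(f"leave-one-out needs k >= 3 studies, got {len(table)}")
    rows: dict[str, PooledSummary] = {}
    for record in table:
        rest = StudyTable(
            tuple(r for r in table if r.study_id != record.study_id),
            provenance=table.provenance,
        )
        rows[record.study_id] = pool_random_dl(effect_table(rest, flavor=flavor, variance=variance))
    argmin = min(rows, key=lambda sid: rows[sid].theta_hat)
    argmax = max(rows, key=lambda sid: rows[sid].theta_hat)
    return LeaveOneOutResult(
        rows=rows,
        min_theta=rows[argmin].theta_hat,
        max_theta=rows[argmax].theta_hat,
        argmin=argmin,
        argmax=argmax,
    )


def exclusion_analysis(
    table: StudyTable,
    rule: Callable[[StudyRecord], bool],
    flavor: str = DEFAULT_FLAVOR,
    variance: str = DEFAULT_VARIANCE,
) -> PooledSummary:
    """Filter by a named rule, then DL-pool the surviving studies (k >= 2)."""
    kept = filter_studies(table, rule)
    if len(kept) < 2:
        raise ValueError(
            f"exclusion rule {getattr(rule, '__name__', 'rule')!r} leaves "
            f"{len(kept)} studies; need >= 2"
        )
    return pool_random_dl(effect_table(kept, flavor=flavor, variance=variance))
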