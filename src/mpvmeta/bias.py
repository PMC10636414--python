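"""Small-study and publication-bias diagnostics.

Egger's regression test (classical 1997 form): ordinary least squares of the
standard normal deviate theta_i/se_i on precision 1/se_i.  Under funnel-plot
symmetry the intercept is zero; a two-sided t-test on k - 2 df flags
asymmetry.

Duval-Tweedie trim-and-fill: a rank-based iterative procedure that estimates
the number k0 of studies missing from one side of the funnel, trims the k0
most extreme effects from the opposite side, re-centers, and finally imputes
k0 mirror-image studies before re-pooling.  The missing-study estimators are
L0 = (4*T - n*(n+1)) / (2n - 1), with T the sum of the |centered-effect|
ranks on the suspected-excess side, and R0 = (rightmost run length) - 1.
Trimming is centered on the DL random-effects pooled value by default (a
fixed-effect center is available); the adjusted estimate re-pools observed
plus imputed studies under DL random effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .effect_size import EffectEstimate
from .pooling import PooledSummary, pool_fixed, pool_random_dl

__all__ = ["EggerResult", "TrimFillResult", "egger_test", "trim_and_fill", "funnel_frame"]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    slope: float
    se_intercept: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class TrimFillResult:
    side: str  # side of the funnel where studies are presumed missing
    estimator: str
    k0: int
    iterations: int
    adjusted: PooledSummary
    imputed_effects: tuple[EffectEstimate, ...]


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's funnel-plot asymmetry test on k >= 3 effects."""
    k = len(effects)
    if k < 3:
        raise ValueError(f"Egger's test needs k >= 3 studies, got {k}")
    se = np.array([e.se for e in effects])
    if np.allclose(se, se[0]):
        raise ValueError("all standard errors are identical: precision is constant "
                         "and the Egger regression is degenerate")
    y = np.array([e.theta for e in effects]) / se
    x = 1.0 / se
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    se_int = fit.bse[0]
    tval = intercept / se_int
    df = k - 2
    p = float(2 * stats.t.sf(abs(tval), df))
    return EggerResult(
        intercept=float(intercept),
        slope=float(slope),
        se_intercept=float(se_int),
        t=float(tval),
        df=df,
        p=p,
    )


def _estimate_k0(delta: np.ndarray, estimator: str) -> int:
    """Missing-study count from centered effects; excess side is positive."""
    n = len(delta)
    ranks = stats.rankdata(np.abs(delta))
    if estimator == "L0":
        T = float(np.sum(ranks[delta > 0]))
        val = (4 * T - n * (n + 1)) / (2 * n - 1)
    elif estimator == "R0":
        order = np.argsort(-np.abs(delta))
        run = 0
        for idx in order:
            if delta[idx] > 0:
                run += 1
            else:
                break
        val = run - 1
    else:
        raise ValueError(f"unknown estimator {estimator!r}; expected 'L0' or 'R0'")
    return max(0, math.floor(val))


def trim_and_fill(
    effects: Sequence[EffectEstimate],
    side: str = "auto",
    estimator: str = "L0",
    pool_model: str = "random_dl",
    max_iter: int = 50,
) -> TrimFillResult:
    """Duval-Tweedie trim-and-fill adjustment.

    Parameters
    ----------
    effects : sequence of EffectEstimate
        At least 3 observed study effects.
    side : {'auto', 'left', 'right'}
        Funnel side where studies are presumed missing.  'auto' takes the
        side opposite the sign of the Egger intercept.
    estimator : {'L0', 'R0'}
        Missing-study count estimator.
    pool_model : {'random_dl', 'fixed'}
        Model used for the trimming center during iteration.  The final
        adjusted estimate always re-pools under DL random effects.
    """
    if len(effects) < 3:
        raise ValueError(f"trim-and-fill needs k >= 3 studies, got {len(effects)}")
    if side == "auto":
        side = "left" if egger_test(effects).intercept > 0 else "right"
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    # Internally work with excess on the positive (right) side.
    sign = 1.0 if side == "left" else -1.0
    work = [replace(e, theta=sign * e.theta) for e in effects]
    theta = np.array([e.theta for e in work])

    pool = pool_fixed if pool_model == "fixed" else pool_random_dl
    k0 = 0
    history = [0]
    for iteration in range(1, max_iter + 1):
        order = np.argsort(theta)  # trimmed = k0 largest
        kept = [work[i] for i in order[: len(work) - k0]] if k0 else list(work)
        center = pool(kept).theta_hat
        k0_new = _estimate_k0(theta - center, estimator)
        k0_new = min(k0_new, len(work) - 2)  # keep at least two studies trimmable
        history.append(k0_new)
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(
            f"trim-and-fill did not stabilize after {max_iter} iterations; "
            f"missing-study counts: {history}"
        )

    if k0 == 0:
        adjusted = pool_random_dl(effects)
        return TrimFillResult(side, estimator, 0, iteration, adjusted, ())

    order = np.argsort(theta)
    trimmed_idx = order[len(work) - k0:]
    kept = [work[i] for i in order[: len(work) - k0]]
    center = pool(kept).theta_hat
    imputed = tuple(
        EffectEstimate(
            study_id=f"filled:{work[i].study_id}",
            theta=sign * (2 * center - work[i].theta),
            variance=work[i].variance,
            flavor=work[i].flavor,
        )
        for i in trimmed_idx
    )
    adjusted = pool_random_dl(list(effects) + list(imputed))
    return TrimFillResult(side, estimator, k0, iteration, adjusted, imputed)


def funnel_frame(effects: Sequence[EffectEstimate], result: TrimFillResult | None = None):
    """Funnel-plot data (theta, se, observed/imputed flag) for TSV export."""
    import pandas as pd

    rows = [
        {"study_id": e.study_id, "theta": e.theta, "se": e.se, "imputed": False}
        for e in effects
    ]
    if result is not None:
        rows += [
            {"study_id": e.study_id, "theta": e.theta, "se": e.se, "imputed": True}
            for e in result.imputed_effects
        ]
    return pd.DataFrame(rows)
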