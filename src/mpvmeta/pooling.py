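"""Fixed-effect and DerSimonian-Laird random-effects pooling.

The fixed-effect model weights each study by the inverse of its sampling
variance.  Heterogeneity is summarized by Cochran's Q (chi-square on k-1 df
under homogeneity) and I^2 = max(0, 100*(Q - df)/Q), the percentage of total
variation attributable to between-study heterogeneity.

The DerSimonian-Laird random-effects model adds a method-of-moments estimate
of the between-study variance,

    tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)),   S_r = sum(w_i^r),

and re-weights by 1/(v_i + tau^2).  Confidence intervals use the normal
0.975 quantile (1.959964) throughout, matching the conventional Wald-style
meta-analytic CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_size import EffectEstimate

__all__ = [
    "PooledSummary",
    "pool_fixed",
    "pool_random_dl",
    "classify_effect_size",
    "forest_frame",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class PooledSummary:
    """Pooled effect with heterogeneity statistics for one set of studies."""

    model: str  # 'fixed' or 'random_dl'
    k: int
    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    Q: float
    df: int
    p_Q: float
    I2: float  # percent, clamped to [0, 100]
    tau2: float
    study_ids: tuple[str, ...]
    weights: tuple[float, ...]  # normalized to sum 1

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _heterogeneity(theta: np.ndarray, w: np.ndarray) -> tuple[float, float, int, float, float]:
    """Fixed-effect mean, Q, df, p_Q and I2 from inverse-variance weights."""
    k = len(theta)
    theta_f = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_f) ** 2))
    df = k - 1
    p_Q = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    I2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0
    return theta_f, Q, df, p_Q, I2


def _summary(model: str, effects: Sequence[EffectEstimate], tau2: float,
             Q: float, df: int, p_Q: float, I2: float) -> PooledSummary:
    theta = np.array([e.theta for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / (v + tau2)
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = theta_hat / se
    p = float(2 * stats.norm.sf(abs(z)))
    return PooledSummary(
        model=model,
        k=len(effects),
        theta_hat=theta_hat,
        se=se,
        ci_low=theta_hat - _Z975 * se,
        ci_high=theta_hat + _Z975 * se,
        z=z,
        p=p,
        Q=Q,
        df=df,
        p_Q=p_Q,
        I2=I2,
        tau2=tau2,
        study_ids=tuple(e.study_id for e in effects),
        weights=tuple(float(x) for x in w / np.sum(w)),
    )


def pool_fixed(effects: Sequence[EffectEstimate]) -> PooledSummary:
    """Inverse-variance fixed-effect pooling with Q/I^2 heterogeneity."""
    if len(effects) == 0:
        raise ValueError("cannot pool an empty collection of effects")
    theta = np.array([e.theta for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    _, Q, df, p_Q, I2 = _heterogeneity(theta, 1.0 / v)
    return _summary("fixed", effects, 0.0, Q, df, p_Q, I2)


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledSummary:
    """DerSimonian-Laird random-effects pooling.

    Q, I^2 and p_Q are reported from the fixed-effect (inverse-variance)
    weights; tau^2 is truncated at zero, in which case the pooled estimate
    coincides with the fixed-effect one.
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling needs k >= 2 (tau^2 undefined)")
    theta = np.array([e.theta for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    _, Q, df, p_Q, I2 = _heterogeneity(theta, w)
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    tau2 = max(0.0, (Q - df) / (s1 - s2 / s1))
    return _summary("random_dl", effects, tau2, Q, df, p_Q, I2)


def classify_effect_size(theta_hat: float) -> str:
    """Conventional magnitude label: small (<0.20), medium (0.20-0.80), large (>0.80)."""
    a = abs(theta_hat)
    if a < 0.20:
        return "small"
    if a <= 0.80:
        return "medium"
    return "large"


def forest_frame(effects: Sequence[EffectEstimate], pooled: PooledSummary):
    """Forest-plot data: per-study rows plus a pooled row (for TSV export)."""
    import pandas as pd

    rows = []
    for e, w in zip(effects, pooled.weights):
        rows.append(
            {
                "study_id": e.study_id,
                "theta": e.theta,
                "ci_low": e.theta - _Z975 * e.se,
                "ci_high": e.theta + _Z975 * e.se,
                "weight": w,
                "pooled": False,
            }
        )
    rows.append(
        {
            "study_id": f"pooled ({pooled.model}, k={pooled.k})",
            "theta": pooled.theta_hat,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight": 1.0,
            "pooled": True,
        }
    )
    return pd.DataFrame(rows)
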