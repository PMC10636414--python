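"""Subgroup (stratified) analysis and random-effects meta-regression.

Meta-regression fits the mixed-effects model

    theta_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau^2),  e_i ~ N(0, v_i)

by weighted least squares with weights 1/(v_i + tau^2).  The residual tau^2
is estimated by REML (default) or by the method-of-moments extension of
DerSimonian-Laird.  Coefficient variances carry the Knapp-Hartung adjustment:
the WLS covariance is rescaled by s^2 = sum(w_i e_i^2)/(k - p) and inference
uses t/F reference distributions on k - p degrees of freedom.  By default
s^2 is applied as-is (untruncated); the truncated variant max(1, s^2) is
available.

Subgroup analysis pools each level separately under DL random effects and
tests the between-level difference by meta-regressing the effects on level
indicators (omnibus Knapp-Hartung F); the classical Q_between decomposition
is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .effect_size import DEFAULT_FLAVOR, DEFAULT_VARIANCE, EffectEstimate, effect_table
from .pooling import PooledSummary, pool_fixed, pool_random_dl
from .study_data import StudyRecord, StudyTable

__all__ = [
    "SubgroupResult",
    "MetaRegressionResult",
    "MODERATORS",
    "GROUPINGS",
    "moderator_value",
    "subgroup_analysis",
    "meta_regress",
]


@dataclass(frozen=True)
class MetaRegressionResult:
    """Knapp-Hartung weighted regression of study effects on moderators."""

    moderators: tuple[str, ...]  # slope names, intercept excluded
    coefficients: dict  # name -> estimate (includes 'intercept')
    se_kh: dict
    t: dict
    p: dict
    ci_low: dict
    ci_high: dict
    tau2_resid: float
    tau2_method: str
    k_used: int
    df_resid: int
    s2: float
    omnibus_F: float
    omnibus_p: float
    study_ids: tuple[str, ...]

    def slope(self, name: Optional[str] = None) -> float:
        name = name or self.moderators[0]
        return self.coefficients[name]


@dataclass(frozen=True)
class SubgroupResult:
    """Per-level DL poolings plus a between-level moderator test."""

    grouping: str
    per_group: dict  # level -> PooledSummary
    between_F: float
    between_p: float
    df1: int
    df2: int
    Q_between: float
    p_Q_between: float
    regression: MetaRegressionResult


# ---------------------------------------------------------------------------
# Core weighted fit

def _tau2_mm(theta: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Method-of-moments residual tau^2 (DL-type extension to regression)."""
    W = np.diag(1.0 / v)
    XtWX_inv = np.linalg.inv(X.T @ W @ X)
    P = W - W @ X @ XtWX_inv @ X.T @ W
    QE = float(theta @ P @ theta)
    k, p = X.shape
    return max(0.0, (QE - (k - p)) / float(np.trace(P)))


def _tau2_reml(theta: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """REML residual tau^2 by bounded scalar optimization."""
    def nll(tau2: float) -> float:
        V = v + tau2
        W = np.diag(1.0 / V)
        XtWX = X.T @ W @ X
        beta = np.linalg.solve(XtWX, X.T @ W @ theta)
        r = theta - X @ beta
        return 0.5 * (
            float(np.sum(np.log(V)))
            + float(np.linalg.slogdet(XtWX)[1])
            + float(np.sum(r**2 / V))
        )

    # Upper bound: generous multiple of the total observed spread.
    hi = max(10.0 * float(np.var(theta)), 10.0 * float(np.max(v)), 1.0)
    res = minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def _fit_kh(
    theta: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    tau2_method: str = "reml",
    kh: str = "untruncated",
    study_ids: Sequence[str] = (),
) -> MetaRegressionResult:
    k, p = X.shape
    if k - p <= 0:
        raise ValueError(f"not enough studies: k={k} with {p} coefficients leaves no residual df")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (constant or collinear moderator)")
    if tau2_method == "reml":
        tau2 = _tau2_reml(theta, v, X)
    elif tau2_method in ("mm", "dl"):
        tau2 = _tau2_mm(theta, v, X)
    else:
        raise ValueError(f"unknown tau2 method {tau2_method!r}")

    w = 1.0 / (v + tau2)
    W = np.diag(w)
    cov_unscaled = np.linalg.inv(X.T @ W @ X)
    beta = cov_unscaled @ X.T @ W @ theta
    resid = theta - X @ beta
    s2 = float(np.sum(w * resid**2) / (k - p))
    if kh == "truncated":
        s2_applied = max(1.0, s2)
    elif kh == "untruncated":
        s2_applied = s2
    else:
        raise ValueError(f"unknown Knapp-Hartung variant {kh!r}")
    cov = cov_unscaled * s2_applied
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    df = k - p
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(0.975, df)

    # Omnibus F over all slopes (intercept excluded)
    if p > 1:
        b_s = beta[1:]
        cov_s = cov[1:, 1:]
        if np.allclose(b_s, 0.0, atol=1e-10):
            F = 0.0  # no between-level signal; avoids 0/0 when s2 is also 0
        else:
            F = float(b_s @ np.linalg.pinv(cov_s) @ b_s / (p - 1))
        pF = float(stats.f.sf(F, p - 1, df))
    else:
        F, pF = 0.0, 1.0

    as_dict = lambda arr: {n: float(x) for n, x in zip(names, arr)}
    return MetaRegressionResult(
        moderators=tuple(names[1:]),
        coefficients=as_dict(beta),
        se_kh=as_dict(se),
        t=as_dict(tvals),
        p=as_dict(pvals),
        ci_low=as_dict(beta - tcrit * se),
        ci_high=as_dict(beta + tcrit * se),
        tau2_resid=float(tau2),
        tau2_method=tau2_method,
        k_used=k,
        df_resid=df,
        s2=s2,
        omnibus_F=F,
        omnibus_p=pF,
        study_ids=tuple(study_ids),
    )


# ---------------------------------------------------------------------------
# Moderator and grouping extraction

def _male_ratio(r: StudyRecord) -> Optional[float]:
    # male-to-female ratio from the male fraction of the total sample
    if r.male_fraction is None:
        return None
    if r.male_fraction >= 1.0:
        raise ValueError(f"study {r.study_id}: male_fraction = 1 gives an infinite male-to-female ratio")
    return r.male_fraction / (1.0 - r.male_fraction)


#: Named continuous moderators.  'age' is the patient-arm mean age; 'age_all'
#: averages the two arms; 'male_ratio' is the male-to-female ratio.
MODERATORS: dict[str, Callable[[StudyRecord], Optional[float]]] = {
    "age": lambda r: r.age_case,
    "age_all": lambda r: None if r.age_case is None or r.age_control is None
    else 0.5 * (r.age_case + r.age_control),
    "male_ratio": _male_ratio,
    "male_fraction": lambda r: r.male_fraction,
    "nos_score": lambda r: None if r.nos_score is None else float(r.nos_score),
}


def _nos_band(r: StudyRecord) -> Optional[str]:
    if r.nos_score is None:
        return None
    return "good (8-9)" if r.nos_score >= 8 else "fair (6-7)"


#: Named categorical groupings for stratified analysis.
GROUPINGS: dict[str, Callable[[StudyRecord], Optional[str]]] = {
    "diagnosis": lambda r: r.diagnosis,
    "region": lambda r: r.region,
    "region_turkey": lambda r: "Turkey" if r.region == "Turkey" else "other",
    "instrument": lambda r: r.instrument,
    "design": lambda r: r.design,
    "apd_recent": lambda r: None if r.apd_recent is None
    else ("APD history" if r.apd_recent else "no APD history"),
    "nos_band": _nos_band,
}


def moderator_value(record: StudyRecord, moderator: str) -> Optional[float]:
    """Resolve a named continuous moderator for one record (None if missing)."""
    try:
        fn = MODERATORS[moderator]
    except KeyError:
        raise ValueError(f"unknown moderator {moderator!r}; expected one of {sorted(MODERATORS)}")
    return fn(record)


# ---------------------------------------------------------------------------
# Public operations

def meta_regress(
    table: StudyTable,
    moderator: str,
    flavor: str = DEFAULT_FLAVOR,
    variance: str = DEFAULT_VARIANCE,
    tau2_method: str = "reml",
    kh: str = "untruncated",
) -> MetaRegressionResult:
    """Random-effects meta-regression of study SMDs on one continuous moderator.

    Studies with a missing moderator value are dropped; ``k_used`` counts the
    rest.  Requires at least 3 usable studies (one residual df).
    """
    rows = [(r, moderator_value(r, moderator)) for r in table]
    used = [(r, x) for r, x in rows if x is not None]
    if len(used) < 3:
        raise ValueError(
            f"moderator {moderator!r} has {len(used)} non-missing values; need >= 3"
        )
    sub = StudyTable(tuple(r for r, _ in used), provenance=table.provenance)
    effects = effect_table(sub, flavor=flavor, variance=variance)
    theta = np.array([e.theta for e in effects])
    v = np.array([e.variance for e in effects])
    x = np.array([x for _, x in used], dtype=float)
    X = np.column_stack([np.ones(len(x)), x])
    return _fit_kh(
        theta, v, X, ["intercept", moderator],
        tau2_method=tau2_method, kh=kh, study_ids=sub.study_ids,
    )


def subgroup_analysis(
    table: StudyTable,
    grouping: str,
    flavor: str = DEFAULT_FLAVOR,
    variance: str = DEFAULT_VARIANCE,
    tau2_method: str = "reml",
    kh: str = "untruncated",
) -> SubgroupResult:
    """Stratified DL poolings per level plus a between-level test.

    The between-group test meta-regresses the effects on level indicator
    variables with a shared residual tau^2 (omnibus Knapp-Hartung F on
    ``levels - 1`` and ``k - levels`` df).  Every level must contain at least
    two studies.
    """
    try:
        group_fn = GROUPINGS[grouping]
    except KeyError:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {sorted(GROUPINGS)}")

    labelled = [(r, group_fn(r)) for r in table]
    if all(g is None for _, g in labelled):
        raise ValueError(f"grouping {grouping!r} is missing in every record")
    labelled = [(r, g) for r, g in labelled if g is not None]
    levels = sorted({g for _, g in labelled}, key=lambda g: [g0 for _, g0 in labelled].index(g))
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} has a single level {levels[0]!r}")
    small = [g for g in levels if sum(1 for _, gg in labelled if gg == g) < 2]
    if small:
        raise ValueError(f"grouping {grouping!r}: level(s) {small} have fewer than 2 studies")

    per_group: dict[str, PooledSummary] = {}
    for g in levels:
        sub = StudyTable(tuple(r for r, gg in labelled if gg == g), provenance=table.provenance)
        per_group[g] = pool_random_dl(effect_table(sub, flavor=flavor, variance=variance))

    sub_all = StudyTable(tuple(r for r, _ in labelled), provenance=table.provenance)
    effects = effect_table(sub_all, flavor=flavor, variance=variance)
    theta = np.array([e.theta for e in effects])
    v = np.array([e.variance for e in effects])
    groups = [g for _, g in labelled]
    X = np.column_stack(
        [np.ones(len(groups))] + [[1.0 if g == lv else 0.0 for g in groups] for lv in levels[1:]]
    )
    reg = _fit_kh(
        theta, v, X, ["intercept"] + [f"level[{lv}]" for lv in levels[1:]],
        tau2_method=tau2_method, kh=kh, study_ids=sub_all.study_ids,
    )

    # Classical Q decomposition: Q_between = Q_total - sum of within-level Qs,
    # computed from fixed-effect weights.
    Q_total = pool_fixed(effects).Q
    Q_within = sum(per_group[g].Q for g in levels)
    Q_between = max(0.0, Q_total - Q_within)
    p_Qb = float(stats.chi2.sf(Q_between, len(levels) - 1))

    return SubgroupResult(
        grouping=grouping,
        per_group=per_group,
        between_F=reg.omnibus_F,
        between_p=reg.omnibus_p,
        df1=len(levels) - 1,
        df2=len(labelled) - len(levels),
        Q_between=Q_between,
        p_Q_between=p_Qb,
        regression=reg,
    )
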