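"""Synthetic meta-analytic study tables with known ground truth.

Each simulated study draws a true effect delta_i ~ N(mu, tau2) around the
global mean SMD, per-arm sample sizes uniformly from a range, and then
realistic summary statistics: observed arm means carry N(0, sd^2/n) sampling
error, observed arm SDs follow the exact scaled chi-square sampling law of a
sample SD on n - 1 df.  Optional one-sided p-value censoring mimics
publication bias: a study whose one-sided test of a positive effect has
p > censor_alpha is suppressed with probability censor_prob, which is the
classical suppression mechanism trim-and-fill is designed to detect.

Tables produced here satisfy every StudyRecord invariant and use the same
CSV schema as the real data, so every pipeline stage can be tested against
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .study_data import StudyRecord, StudyTable

__all__ = ["SimulationConfig", "simulate_table", "simulate_with_moderator"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; identical config and seed give identical output."""

    k: int = 24
    mu: float = 0.5
    tau2: float = 0.0
    n_range: tuple[int, int] = (15, 600)
    base_mean: float = 9.0   # fL, typical control-arm MPV
    base_sd: float = 1.2     # fL, typical within-arm SD
    censor_alpha: Optional[float] = None
    censor_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.n_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid n_range {self.n_range}: need 2 <= lo <= hi")
        if self.k < 2:
            raise ValueError(f"k = {self.k} < 2")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")
        if self.censor_alpha is not None and not 0 < self.censor_alpha < 1:
            raise ValueError("censor_alpha must lie in (0, 1)")
        if not 0 <= self.censor_prob <= 1:
            raise ValueError("censor_prob must lie in [0, 1]")


def _draw_study(rng: np.random.Generator, config: SimulationConfig,
                delta: float, index: int) -> StudyRecord:
    lo, hi = config.n_range
    n1 = int(rng.integers(lo, hi + 1))
    n2 = int(rng.integers(lo, hi + 1))
    true_c = config.base_mean
    true_t = config.base_mean + delta * config.base_sd
    m1 = float(rng.normal(true_t, config.base_sd / np.sqrt(n1)))
    m2 = float(rng.normal(true_c, config.base_sd / np.sqrt(n2)))
    s1 = float(config.base_sd * np.sqrt(rng.chisquare(n1 - 1) / (n1 - 1)))
    s2 = float(config.base_sd * np.sqrt(rng.chisquare(n2 - 1) / (n2 - 1)))
    return StudyRecord(
        study_id=f"sim{index:03d}",
        diagnosis="depression",
        region="synthetic",
        design="case-control",
        instrument="DSM-5",
        n_case=n1, mean_case=m1, sd_case=s1,
        n_control=n2, mean_control=m2, sd_control=s2,
    )


def _censored(rng: np.random.Generator, config: SimulationConfig, r: StudyRecord) -> bool:
    if config.censor_alpha is None or config.censor_prob == 0:
        return False
    res = stats.ttest_ind_from_stats(
        r.mean_case, r.sd_case, r.n_case,
        r.mean_control, r.sd_control, r.n_control,
        equal_var=True, alternative="greater",
    )
    if res.pvalue > config.censor_alpha:
        return bool(rng.random() < config.censor_prob)
    return False


def simulate_table(config: SimulationConfig) -> StudyTable:
    """Draw a study table of (up to) k studies; censoring may remove some."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.k):
        delta = float(rng.normal(config.mu, np.sqrt(config.tau2)))
        rec = _draw_study(rng, config, delta, i + 1)
        if not _censored(rng, config, rec):
            records.append(rec)
    return StudyTable(
        tuple(records),
        provenance=f"simulated: mu={config.mu}, tau2={config.tau2}, "
        f"k={config.k}, seed={config.seed}",
    )


def simulate_with_moderator(
    config: SimulationConfig,
    slope: float,
    moderator_range: tuple[float, float],
) -> StudyTable:
    """Draw studies whose true effect depends linearly on a moderator.

    The moderator x_i ~ Uniform(moderator_range) enters the true effect as
    delta_i ~ N(mu + slope * x_i, tau2) and is stored in the ``age_case``
    field, so ``meta_regress(table, 'age')`` targets ``slope`` directly.
    A degenerate range (a, a) is permitted here but makes the downstream
    regression design rank-deficient.
    """
    config.validate()
    lo, hi = moderator_range
    if lo > hi:
        raise ValueError(f"invalid moderator_range {moderator_range}")
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.k):
        x = float(rng.uniform(lo, hi))
        delta = float(rng.normal(config.mu + slope * x, np.sqrt(config.tau2)))
        rec = _draw_study(rng, config, delta, i + 1)
        rec = replace(rec, age_case=x)
        if not _censored(rng, config, rec):
            records.append(rec)
    return StudyTable(
        tuple(records),
        provenance=f"simulated with moderator: slope={slope}, seed={config.seed}",
    )
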