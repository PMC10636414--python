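# Methods

## Model

Each study *i* contributes two-arm summaries (nᵢ₁, mᵢ₁, sᵢ₁) for patients and
(nᵢ₂, mᵢ₂, sᵢ₂) for controls, converted to a standardized mean difference θᵢ
with sampling variance vᵢ. The working model is the standard two-level
normal-normal hierarchy: θᵢ | δᵢ ~ N(δᵢ, vᵢ), δᵢ ~ N(μ, τ²). The package
estimates μ by inverse-variance weighting with the DerSimonian–Laird
method-of-moments τ̂², and quantifies inconsistency with Cochran's Q and I².
Positive θ means patients have the higher MPV.

## Analysis conventions (and why)

The source analysis was run in commercial software whose exact settings were
not published, so several conventions had to be fixed by calibrating the
candidate configurations against the published pooled values. All are
exposed as options; the defaults are the calibrated choices:

- **SMD flavor: Hedges' g** (approximate J; an exact gamma-function J is
  available and differs by <10⁻³ at these sample sizes). Cohen's d and
  Glass's Δ are options. Hedges' g reproduces the published overall pooling
  and leave-one-out range slightly better than Cohen's d.
- **Sampling variance: large-sample form** v = (n₁+n₂)/(n₁n₂) +
  d²/(2(n₁+n₂)); the df-adjusted denominator 2(n₁+n₂−2) is an option
  (difference ~1% here).
- **Pooled CIs: normal quantile** (θ̂ ± 1.96 se). No Knapp–Hartung at the
  pooling stage; KH enters only through meta-regression, where the published
  t/F statistics demand it.
- **Meta-regression: REML residual τ²** (method-of-moments available) with
  **untruncated** Knapp–Hartung scaling s² = Σwᵢeᵢ²/(k−p); the truncated
  variant max(1, s²) is an option. Under the method-of-moments τ², s² is
  identically 1 whenever τ̂² is interior, so the distinction only matters
  under REML or at the τ² = 0 boundary. REML + untruncated KH reproduces the
  published age slope (−0.128 vs −.13) and its CI to two decimals, and was
  verified against r-metafor (`rma(..., method="REML", test="knha")`) to six
  decimals.
- **Moderator codings**: "age" is the patient-arm mean age (an all-participant
  average is available); "sex" is the male-to-female ratio derived from the
  male fraction.
- **Subgroup between-group test**: Knapp–Hartung meta-regression F on level
  indicators with a shared residual τ² (df₁ = levels−1, df₂ = k−levels);
  the classical Q_between decomposition is reported alongside. On the
  packaged table this construction matches the published subgroup F values
  (e.g. diagnosis 0.81 vs .84, region 3.55 vs 3.67).
- **Egger's test**: the classical unweighted OLS of the standard normal
  deviate θᵢ/seᵢ on precision 1/seᵢ, intercept t-test on k−2 df. The
  weighted variance-regression variant is out of scope.
- **Trim-and-fill**: estimator L0 = (4T − n(n+1))/(2n−1) (R0 = run length −1
  as option), missing-study count floored at each iteration, iteration cap
  50. The trimming center is the **DL random-effects** pooled value of the
  retained studies; a fixed-effect center is available via `pool_model`.
  The random-effects center was chosen because it reproduces both the
  published "no trimming" outcome on the anxiety stratum and r-metafor's
  behavior, whereas a fixed-effect center trims two studies there: with
  severe heterogeneity the fixed-effect center sits far from the
  unweighted bulk of the effects and misreads heterogeneity as asymmetry.
  Side selection (`auto`) takes the funnel side opposite the sign of the
  Egger intercept. The final adjusted estimate always re-pools observed plus
  mirror-imputed studies under DL random effects.
- **"Small study" exclusion rule**: total sample n₁ + n₂ < 100, the natural
  reading of an unqualified subject count.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `flavor` | `hedges` | SMD variant (unitless) |
| `variance` | `large-sample` | d² term denominator in vᵢ |
| `tau2_method` | `reml` | residual τ² estimator in (subgroup) meta-regression |
| `kh` | `untruncated` | Knapp–Hartung scale handling |
| `estimator` | `L0` | trim-and-fill missing-study estimator |
| `pool_model` | `random_dl` | trimming center during trim-and-fill iteration |
| `exclude_small` | 100 | total-n threshold for the exclusion sensitivity analysis |

## Numerical choices

- τ̂² truncation at zero is silent; when it triggers, random-effects results
  equal fixed-effect results by construction.
- I² is clamped to [0, 100] and reported in percent; I² = 0 when Q ≤ df.
- REML τ² is found by bounded scalar minimization of the restricted negative
  log-likelihood on [0, max(10·var(θ), 10·max v, 1)] with xatol 1e-10
  (agrees with r-metafor to ≥6 decimals on the packaged table).
- The subgroup omnibus F is set to 0 when all level coefficients vanish
  (avoids 0/0 when the residual scale is also 0 on degenerate inputs).
- Effect-size magnitude labels use closed brackets at 0.20 and 0.80
  (0.20 and 0.80 are both "medium").
- JSON reports serialize at full precision; rounding to two decimals
  (one for I²) happens only in the human-readable summary.

## Synthetic data: what it does and does not emulate

`simulate_table` draws true study effects from N(μ, τ²), per-arm sizes
uniformly from `n_range`, observed means with N(0, σ²/n) error and observed
SDs from the exact scaled-χ²ₙ₋₁ sampling law — so the variance-of-the-variance
that stresses DL weighting and Egger regression is present. Optional
censoring suppresses studies whose one-sided test of a positive effect has
p > `censor_alpha` with probability `censor_prob`, the mechanism
trim-and-fill assumes. Defaults (k = 24, MPV-like base mean 9.0 fL, SD
1.2 fL, per-arm n 15–600) mirror the packaged table's scale.

Not emulated: non-normal MPV distributions, measurement-instrument shifts
between laboratories, correlated moderators, rounding of published summaries,
or selection mechanisms other than one-sided p censoring. Passing simulation
tests therefore validate the estimators under the model's own assumptions,
not robustness to real-data violations of them.

Simulation scales used by the test suite (chosen to give tight Monte-Carlo
error at desk-scale runtimes): 2000 replicates for 95% CI coverage at τ² = 0
(k = 20), 1000 for τ² recovery (k = 40, τ² = 0.2), 1000 each for Egger and
null-slope type-I rates, 500 for trim-and-fill on symmetric funnels, 200 for
slope recovery in the age-style design (k = 23, τ² matched to the fixture
fit).

## Known limitations and documented discrepancies

- **Published-table inconsistency.** Pooling the published per-study table
  reproduces the depression, anxiety and bipolar subgroups, the overall I²,
  the meta-regression slope and the subgroup F statistics, but gives a
  schizophrenia pooling of 1.18 where the publication prints 1.06, with
  matching shifts in the overall estimate (1.038 vs 1.02) and the
  leave-one-out extremes (0.848/1.136 vs .83/1.11). The discrepancy is fully
  explained by a single study whose printed SDs (0.11 and 0.06 fL on means
  of 11.11 and 10.70 fL) imply d ≈ 4.7; a value near 3.9 would reconcile
  every affected quantity simultaneously. The packaged fixture reproduces
  the published table verbatim rather than imputing corrected inputs, so
  these comparisons fail at reproduction tolerance and are reported as-is.
- **Trim-and-fill false positives.** On perfectly symmetric simulated tables
  (k = 20, no censoring) the L0 estimator returns k0 = 0 in only ~80% of
  replicates (r-metafor: 61–72% on identical draws) — a known property of the
  rank-based estimators, whose sampling SD at k = 20 is ≈2.7 studies. A
  nonzero k0 on real data is weak evidence of bias on its own.
- **Egger with SMDs** inherits the structural correlation between d and its
  standard error; the type-I calibration in the test suite is at μ = 0,
  where the correlation vanishes.
- Moderators are fitted one at a time (matching the source analysis); no
  multivariable meta-regression, Begg test, PET-PEESE or selection models.
- The APD-history, sex-ratio and quality-score analyses require user-supplied
  per-study annotation; the published report did not include those columns,
  so they cannot be reproduced from the packaged data.
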