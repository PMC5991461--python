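# Methods

## Model

Each of *n* judges independently reports two whole-examination scores on
the percent scale: the clear-fail anchor L (highest score still clearly
incompetent) and the clear-pass anchor H (lowest score clearly
competent).  The method treats the panel's L and H values as two
independent samples whose means estimate the population anchor locations.
With X̄_L, X̄_H the sample means and SE_L = SD_L/√n, SE_H = SD_H/√n the
standard errors of those means (sample SDs use the n−1 denominator
throughout), the interface equation

    Z·SE_L + Z·SE_H = X̄_H − X̄_L

defines the unique Z at which intervals of equal Z-width around the two
anchor means meet.  The cut-score is that meeting point,

    CS = X̄_L + Z·SE_L = X̄_H − Z·SE_H,

algebraically identical from either anchor; the implementation computes
both and preserves their equality to < 1e-9 as an internal check.
Equivalently CS = (X̄_L·SE_H + X̄_H·SE_L)/(SE_L + SE_H): the cut-score is
pulled toward the anchor with the *smaller* SE, i.e. toward whichever
threshold the judges agree on more closely.  This is the moderating
mechanism against extreme judges — a wild L value inflates SE_L and
thereby *reduces* the weight of X̄_L.

Attached quantities, all driven by the standard normal CDF Φ:

* confidence = max(0, 2·Φ(Z) − 1) — the probability mass separating the
  two anchor sampling distributions at the interface; 68.3% / 95.4% /
  99.7% at Z = 1/2/3 (reported at whole-percent or 1-dp rounding this is
  the familiar 68 / 95 / 99.7 ladder);
* one-tailed p = 1 − Φ(Z);
* 95% CI = (X̄_H − 1.96·SE_H, X̄_L + 1.96·SE_L), applicable only while
  |Z| < 1.96.  The lower bound derives from the clear-pass anchor (any
  lower score is a defensible fail at the 95% level) and the upper bound
  from the clear-fail anchor.  At |Z| ≥ 1.96 the construction inverts
  (the "lower" bound exceeds the "upper"), so the interval is reported as
  absent with an applicability flag rather than replaced by a different
  construction.  The threshold is 1.96, the same quantile the bounds are
  built from.  When applicable the CI always contains CS, but its
  midpoint generally differs from CS because the two bounds carry two
  independent variances.

Classification is binary: a score at or exactly on the cut-score passes,
below fails.  Membership of the applicable CI is annotated for audit but
is never a third outcome.

### Assumptions

The judges' L and H values are assumed approximately normal, and the two
anchor questions are answered independently.  Normality is advisory, not
enforced: `normality_diagnostics` reports sample skewness, excess
kurtosis and a Shapiro–Wilk p-value and flags |skew| > 1 or p < 0.05, and
the two standard remedies are available — symmetric trimming of extreme
judges and bootstrap SEs — but the engine never refuses data.

A note on the pilot worked example: with Z = 0.30675 the consistent
confidence value is 2·Φ(Z) − 1 = 24.1%.  Summaries of this method
sometimes state "25%" with 12.5% tail areas; those numbers are not
mutually consistent with the 68/95/99.7 calibration, which this package
treats as the single definition of confidence.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| scale_max | 100 | % | percent scale; all ratings validated to [0, scale_max] |
| CI critical value | 1.96 | Z | matches the 95% bounds themselves |
| trimming `k_per_side` | 0 | judges | whole judges removed, lowest/highest k on one anchor; ties broken by input order, earlier judges first |
| bootstrap replicates | 2000 | — | stable SE of the mean at panel sizes ≤ a few hundred |
| bootstrap seed | required | — | audit reproducibility; no silent default |
| report rounding | Z 3 dp, scores 2 dp, percents 1 dp | — | conventional presentation precision |

Degenerate inputs: SE_L + SE_H = 0 with equal means yields CS = the
common mean, confidence 0, and a `degenerate` flag; with distinct means
the Z equation has no finite solution and a `DegeneratePanelError` is
raised (CLI exit code 3).  Inverted anchors (X̄_H < X̄_L) give Z < 0,
confidence clipped to 0 and an `anchors_inverted` flag — reportable for
audit, not an error.  Judges with L > H are retained by default with a
logged warning (`drop_inconsistent=True` excludes them), since dropping
them would bias both anchor distributions.

Trimming removes whole judges, not single values, so L and H remain
paired samples from the same panel.  The bootstrap SE is the n−1 SD of
the means of with-replacement resamples of the original size; at n = 2
its exact value is the population SD of the four equally likely resample
means, which is what the Monte-Carlo estimator converges to and what the
tests check against.

## Simulator

`simulate_panel` draws L_i and H_i independently per judge from normal
(optionally skew-normal) populations with configurable μ and σ,
truncated to the score bounds **by redrawing** (cap 1000 attempts per
value) rather than clipping, which would pile probability mass on the
bounds.  Skew is a skew-normal whose location and scale are re-solved so
the requested mean and SD are preserved — a device for stress-testing the
normality assumption, not part of the method.  Contamination shifts both
anchors of a random subset of judges by a fixed offset (clipped to the
bounds), emulating extreme panellists.  Seeding: one master seed; inside
`confidence_curve` each panel uses a substream derived from
(seed, n, replicate), so studies are bitwise reproducible and panels
never share draws.

`population_result` is the analytic oracle: the engine evaluated at
mean = μ and SE = σ/√n.  It refuses configurations where it is not the
truth being estimated — any skew or contamination, or *material*
truncation, operationalised as more than 10% of either anchor's normal
mass outside the bounds.  Below that threshold truncation is treated as
negligible for the oracle's purposes (at pilot-like parameters,
σ_L ≈ 23 on [0, 100], about 5.7% of the L mass is clipped, which shifts
the realised anchor means by ~2 points — visible in recovery studies as
a small bias, which is why convergence tests use anchors well inside the
bounds; see below).

What the simulator emulates: independent, exchangeable judges with a
common population per anchor.  What it does not: correlated judges,
judge-by-examination interaction, discreteness of real rating habits
(multiples of 5), or any model of examinee scores.  Passing simulation
tests therefore demonstrates the estimator's statistical behaviour under
the stated assumptions, not the method's validity on any real panel.

## Study sizes and numerical choices

The packaged property studies use panel sizes 17–500, 200–500 replicates
per condition: large enough that the monotone trends (confidence rising
with panel size; recovery error falling with n) dominate Monte-Carlo
noise, small enough to run in seconds.  Confidence-vs-size studies run
at pilot-like population parameters (μ_L = 62.65, μ_H = 65.35,
σ_L = 23.12, σ_H = 13.16) on the grid n = 17/68/272 so the analytic
column at n = 17 lands on the worked example's ≈0.24.

Parameter recovery is assessed against `population_result` with anchors
well inside the score bounds (μ = 60/66, σ = 10/6), because bound
truncation at pilot-like σ biases the realised moments and would make
the oracle the wrong target.  Cut-score RMSE is compared absolutely
(it shrinks ∝ 1/√n).  Z itself grows ∝ √n at fixed populations while
its absolute sampling error is roughly constant in n, so Z recovery is
assessed *relative to the population Z*, where convergence is clean.

Exact-moment test panels are built from a standardised equally spaced
pattern (max |z| < √3), rescaled to the target mean/SE and seed-permuted
— this keeps reconstructed pilot values on-scale, which a standardised
normal draw at SD ≈ 23 would not.

## Known limitations

* The confidence statement is normal-theory; with ~17 judges the anchor
  means are only approximately normal and no t-correction is applied
  (the method is defined with Z, and its calibration anchors 68/95/99.7
  are Z-quantiles).
* The 95% CI is undefined for well-separated anchors (|Z| ≥ 1.96); the
  package reports absence rather than substituting an interval of a
  different construction.
* Printed SD/SE pairs from rounded tables can be mutually inconsistent
  at the third decimal; when reconstructing a panel from a printed
  summary, the SEs are taken as authoritative and the implied unrounded
  SD (SE·√n) is used.
* The baselines are deliberately minimal: classic Angoff as an
  equal-weight grand mean without iteration rounds or psychometric
  feedback, and the direct-suggestion mean.  No IRT, borderline-group,
  borderline-regression, Hofstee, Ebel or bookmark methods are included.
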