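# Methods

## Model

A battery is an ordered set of tests, each with integer recruitment weights
(vp, vmc), vp + vmc = 100, expressing the judged share of visuoperceptive
vs. visuomotor-coordination involvement. For a session with administered
tests n = 1…N and age-normed z-scores z_n (negative = below norm):

- η = −Σ vp_n z_n / N and μ = −Σ vmc_n z_n / N (arbitrary units:
  percent-weight × SD). Both are 0 at z ≡ 0 and positive for a profile
  below norms.
- Expected baselines assume a *balanced* subject, i.e. the same z on every
  administered test: η_exp = mean(vp) · |z̄|, μ_exp = mean(vmc) · |z̄|,
  where z̄ is the mean z and the weight means are taken **over the
  administered subset**. For the full default battery these means are
  76/24; for a 7-test session that skips the three pure-VP memory tests
  they become 460/7 ≈ 65.71 and 240/7 ≈ 34.29. Using subset means is what
  makes incomplete sessions commensurable with complete ones — a session's
  score against the full battery equals its score against the battery
  restricted to its administered tests (tested invariant).
- Δη = η − η_exp and Δμ = μ − μ_exp. Since per-test weights sum to 100,
  η + μ = −100 z̄ exactly, and for z̄ ≤ 0 the expected values split
  100·|z̄| so Δη = −Δμ.

### Classification

Δη > τ ⇒ VP-prevalent deficit; Δμ > τ ⇒ VMC-prevalent; otherwise BALANCED
(boundary inclusive). The band half-width τ defaults to 2.0 arbitrary
units: in the reference data a Δη of 0.21 is read as "no imbalance" while
6.38 is a clear defect, and 2.0 separates those regimes with a wide margin
on either side; it is configurable everywhere (`--tolerance`), and every
result carries the tolerance used. A BALANCED verdict on a clearly
below-norm profile suggests the problem sits at the VP/VMC *integration*
level rather than in either domain.

### Sign conventions and edge cases

- Above-norm z-scores enter the sums with their sign (they reduce η/μ).
- If the *mean* z is positive, the |z̄| in the baselines breaks delta
  complementarity (Δη + Δμ = −200 z̄ < 0); the formulas are evaluated as
  written but the result is flagged "no net impairment" and classified
  BALANCED — a deficit classification is not meaningful when mean
  performance is above norms.
- |z| > 5 on any single test triggers a data-quality warning (age-normed
  clinical z-scores of that magnitude are implausible and usually typos)
  but does not abort; warnings propagate into report provenance.
- Weights are stored as integer percents; all arithmetic is double
  precision. Reports round to 2 decimals for display only.

## Cohort summaries and pre/post comparison

- Location/spread of per-session average z is summarized as the median with
  Tukey-hinge quartiles: hinges are medians of the lower/upper halves of
  the sorted data, the overall median element belonging to neither half
  when n is odd (for even n this coincides with the classical hinge
  definition; the even-n reference data cannot distinguish the odd-n
  conventions, so the simpler exclusive rule was adopted and is
  cross-checked against a brute-force oracle in the tests).
- Pre/post comparison restricts both sessions to their shared tests,
  rescores (with subset-mean weights), and reports the relative index
  reductions 100·(pre − post)/pre (undefined, reported as absent, when the
  pre index is ≤ 0), the change in average z, and a two-sided exact
  Wilcoxon signed-rank p-value on the per-test z pairs. The signed-rank
  test is a documented assumption — the source analyses never name their
  per-patient test — and identical sessions (all differences zero, where
  the statistic is undefined) are reported with p = 1.0.
- Known discrepancy: on the reference pre/post tables the relative-
  reduction metric reproduces the reported 90% VP improvement for the most
  affected child, but not the 48.7% / 8.7% figures reported for two
  others, whose formula is undocumented; the metric is reported as defined
  here.

## Synthetic data generator

The simulator is the generative inverse of the scoring equations. A
subject's ground truth is an `ImpairmentProfile` (vp_severity, vmc_severity,
noise_sd, seed): severities are in z units per unit recruitment, so test n
scores

    z_n = −(vp_severity·vp_n + vmc_severity·vmc_n)/100 + ε_n,
    ε_n ~ Normal(0, noise_sd²) i.i.d.

A balanced profile (equal severities s) yields z ≡ −s — the ideal subject
whose deltas vanish. Defaults emulate the study conditions: the 10-test
default battery; noiseless generation for analytic checks; noise_sd 0.3
(a realistic test–retest jitter for normed scores) and cohorts of a few
hundred for Monte-Carlo recovery; missingness as independent per-test drops
(emulating refusals), redrawn if a subject would lose every test. Each
subject's random stream derives from its own profile seed (cohort-level
seeds spawn per-subject child seeds), so results are independent of cohort
order and bit-reproducible.

What the simulator does **not** emulate: correlated errors across tests of
the same instrument, developmental trajectories, floor/ceiling effects of
raw instruments, and any treatment effect. Passing recovery tests therefore
show the *inferential* machinery is sound under the model's own generative
assumptions, not that real batteries satisfy those assumptions.

The recovery experiment simulates n subjects with a known profile, scores
and classifies them, and reports per-class rates plus the Pearson
correlation between |Δη| and |z̄| across subjects — near-zero correlation
supports the design claim that the detected imbalance is independent of the
overall severity. Noiseless recovery is exact: classification agrees with
sign(vp_severity − vmc_severity) whenever the analytic delta exceeds the
tolerance. With noise_sd 0.3 and n = 500 the VP-dominant profile
(severities 2 vs 0, analytic Δη = 13.28) is recovered at a rate above 0.9.

## Data handling

Subject tables are tidy CSVs (`subject_id,session,test_name,z_score`);
missing tests are simply absent rows, so no sentinels are needed. European
decimal commas are normalized on read with a warning. Duplicate
(subject, session, test) keys and malformed numbers are fatal; unknown test
names are fatal in strict mode, skipped with a warning otherwise. The
shipped reference data comprise the worked-example profile and the
four-child pilot cohort pre/post tables. The as-published post table
contains z = 10.72 for subject 1's simultaneous-memory test, which is
inconsistent with that column's own published average (−0.21), η (13.95)
and μ (7.05); the value 1.72 reproduces all three exactly, so a corrected
variant (`post_corrected`) ships alongside the verbatim one, and analyses
here use the corrected table (the literal file is retained and its outlier
is flagged on scoring). Similarly, subject 4's published post μ of 21.08
disagrees with its own z-scores; the recomputed 21.80 is consistent with
the published Δμ = 4.40, which is the quantity reported.

## Problem sizes

The reference computations are closed-form on ≤ 10 numbers per subject.
The validation suite uses 1000 random sessions for the algebraic
invariants, cohorts of 200–1000 for simulator statistics, and n = 500 for
the noisy recovery experiment — sizes at which the Monte-Carlo standard
errors are an order of magnitude below the asserted margins.

## Limitations

- Recruitment weights are expert judgments, not estimated quantities; no
  weight-fitting procedure exists or is provided.
- The model is linear in z and treats tests as exchangeable within their
  weights; it cannot represent interactions between domains.
- The BALANCED tolerance is a convention, not an estimated threshold.
- The per-patient significance test and the severity/imbalance correlation
  are exploratory utilities, not validated inference procedures.
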