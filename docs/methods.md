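# Methods

## Data model

The unit of analysis is one palliative **reirradiation course**, not one
person; a patient reirradiated twice contributes two independent records.
Survival time is stored in months from the start of the course as a real
number (no date arithmetic). The event flag is never missing; every
covariate may be. Missingness is first-class: records missing a factor are
excluded from analyses of that factor (complete-case modelling) or
reported *unassignable* by the scorer — never imputed.

## Survival estimation

Kaplan-Meier product-limit estimation with the standard tie convention
that **deaths are processed before censorings** at an identical time (a
subject censored at *t* is still at risk for the deaths at *t*). The
survival function is right-continuous, so a death at exactly the horizon
counts toward the death rate at that horizon. The "actuarial death rate"
at horizon *t* is `100 · (1 − Ŝ(t))` with Ŝ the Kaplan-Meier estimate, not
a life-table interval estimator; at month-level resolution the two agree
to the precision at which rates are reported. Greenwood's formula supplies
pointwise standard errors. Requests beyond the observed follow-up return
the last estimate and raise an `ExtrapolationWarning`.

The k-group log-rank statistic uses the hypergeometric variance of
observed-minus-expected deaths summed over distinct death times, inverted
on k−1 coordinates (pseudo-inverse for degenerate strata), with an
asymptotic χ²(k−1) p-value. Pairwise comparisons are uncorrected by
default (Bonferroni and Holm available as options), matching common
clinical reporting practice. An exact permutation p-value is *not* shipped
as the production path; the test suite compares the asymptotic p against an
exhaustive 6-subject permutation oracle, and its null calibration against
2 000 simulated null cohorts of n = 60 (observed type-I error within
3 binomial SEs of the nominal 5%).

## Cox regression and factor selection

The Cox partial likelihood uses the **Breslow** tie approximation (tied
deaths share one risk set) — the simplest convention, adequate at
month-level precision — maximized by Newton's method with step halving.
Convergence requires a score max-norm below 1e-9 (at most 50 iterations);
standard errors come from the observed information. A coefficient
excursion beyond |β| > 15 flags a monotone likelihood (e.g. perfect
separation) and the fit is returned non-converged rather than raising.
Constant covariates raise an error naming the column. Fits were verified
against independent implementations (scikit-survival and R `survival`
with Breslow ties) to 1e-6, and against a brute-force grid maximization of
a hand-coded partial likelihood on a 6-subject example.

Selection is two-stage, mirroring a common clinical workflow:

1. **Univariate screen** — one pooled log-rank test per candidate factor
   on its non-missing records (performance status enters as the 3-level
   grouping 90–100 / 70–80 / ≤60); factors with p strictly below 0.1 are
   carried forward. Untestable factors (one level, or no events) are
   excluded with a logged reason.
2. **Backward elimination** — likelihood-ratio removal tests at threshold
   0.10: refit without each remaining factor, drop the one with the
   largest removal p ≥ 0.10, repeat. Multi-level factors enter and leave
   as a block of indicator columns with matching df. The analysis set is
   fixed up front to records complete on every starting factor (listwise
   deletion) so all nested comparisons use identical data. This emulates
   a stepwise "backward conditional" routine whose exact removal statistic
   is package-specific; likelihood-ratio elimination is the closest
   principled analogue and is documented here as an approximation.

## Point-score construction

Per factor level: actuarial death rate at the horizon, divided by 10, then
rounded. The two variants:

- **v1** (1 month): floor to the nearest multiple of 0.5
  (15 → 1.5, 11 → 1, 33 → 3, 4 → 0, 3 → 0, 2 → 0);
- **v2** (2 months): round to the nearest integer, halves up
  (39 → 4, 49 → 5, 50 → 5, 28 → 3, 14 → 1, 10 → 1, 8 → 1, 7 → 1).

These rules are a **reconstruction**: the source description says only
"death rate divided by 10", and these are the unique simple rules
consistent with every published point value. A 1e-9 epsilon guards the
floor/round boundaries against float noise accumulated in long
Kaplan-Meier products. Scoring uses performance status dichotomized at
≤60 (the published table's split) even though screening uses three
levels. Risk-group cutpoints are configuration, defaulting to the
published boundaries (v1: 0 / 1.5 / 3; v2: 5 / 8 / 11 as upper bounds of
groups 1–3); no automatic cutpoint search is performed. Totals outside a
table's attainable range are rejected.

The SPS comparator counts adverse features among nonbreast primary,
metastases other than bone (the complement of the bone-only flag, which
is true also for patients with no known metastases), and KPS ≤ 60.

## Synthetic cohorts

`generate_cohort` emulates the covariate mix of a single-institution
reirradiation service: KPS bands 36 / 34 / 30 percent (90–100 / 70–80 /
≤60), steroid use 54% among known with 20% missing, liver metastases 22%,
pleural effusion 7%, primary-site distribution led by prostate (29%) and
NSCLC (11%). The bone-only-metastases prevalence (0.45) is a
reconstruction from the zero-site fraction plus the bone-dominated share
of single-site patients, not a directly reported figure. Covariates are
drawn **independently** — only marginal frequencies are targeted; any
real correlation structure (e.g. steroids given poor KPS) is an explicit
simplification.

Survival follows proportional hazards with cumulative hazard
`H(t) = ln 2 · exp(lp) · (t / m₀)^k`, baseline median `m₀ = 18.3` months
and default log-hazard-ratios 0.67 (KPS 70–80), 2.16 (KPS ≤60), 1.22
(steroids), 1.24 (liver), 1.98 (pleural effusion), calibrated from
reported group medians under an exponential model. The default shape is
**k = 2** (increasing hazard): with k = 1 the exponential front-loads
roughly twice as many deaths into the first month as clinically reported
(28% vs ~15% at a group median of 2.1 months), which pushes every
simulated patient into the top risk tier under the published cutpoints;
k = 2 reproduces realistic early-death fractions while keeping the
configured medians' rank order. A consequence, stated plainly: because
the log-HRs are kept at their exponential-calibrated values, marginal
group-median contrasts in the default cohort are compressed relative to
the clinical report (e.g. ≈10 vs ≈4 months rather than 12.2 vs 3.6 for
steroid use). Passing tests on these cohorts therefore demonstrate
machinery correctness and qualitative structure, not agreement with any
published cohort-specific number. Administrative censoring mimics
staggered accrual: entry uniform over a 30-month window, censoring at the
window's end (the reported ~5.4-month median follow-up of censored
patients is emulated mechanistically, not targeted).

`planted_rate_cohort` is a fixture generator planting exact cumulative
death probabilities at one or more horizons per factor level through a
piecewise-exponential law (a single exponential cannot satisfy published
rates at both 1 and 2 months simultaneously), with all deaths observed.
By default it draws times by inverse CDF from **shuffled midpoint
uniforms**, so the empirical death fraction at each planted horizon equals
the planted probability to within 1/n. This variance reduction matters
because one published cell (1-month rate 15% → 1.5 points) sits exactly on
the floor-to-0.5 rounding boundary, where iid sampling at any n flips the
rounded value with probability ≈ 1/2 — a knife-edge of the rounding rule
itself, not of the estimator. An iid mode is available. Beyond the last
planted horizon the hazard continues at `ln 2 / t_last`, which keeps
draws finite without affecting any planted rate.

## Pipeline and problem sizes

`run_pipeline` chains screen → elimination → table derivation (both
variants) → scoring → stratification → SPS comparison, writing every
artifact plus a SHA-256 `MANIFEST.json`; a stage failure propagates with
the stage name and the manifest marks the run incomplete. All artifacts
except the timestamped log are byte-identical across runs with the same
seed and configuration.

Default problem sizes used by the test suite: n = 10⁴ for
law-of-large-numbers checks (3 Monte-Carlo-SE bands), n = 2 × 10⁴ per
level for point-table recovery, 2 000 replicates for log-rank null
calibration, 100–200 replicates for selection-recovery and tier-ordering
simulations — sizes chosen so that every stochastic assertion has
comfortable statistical margin while the suite stays fast.

## Known limitations

- Stratified/weighted log-rank variants (Wilcoxon, Tarone-Ware), Efron or
  exact tie handling, time-varying covariates, frailty, and
  proportionality diagnostics are out of scope.
- The elimination routine approximates a package-specific "conditional"
  stepwise statistic with likelihood-ratio tests.
- Synthetic cohorts target marginal frequencies and qualitative hazard
  structure only; external validation on real cohorts and discrimination
  metrics (c-index, calibration) are out of scope.
- Risk-group cutpoints are taken as given; whether data-driven cutpoint
  selection would change the tiers is not explored.
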