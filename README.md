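# palliscore

Survival prediction scoring for **palliative reirradiation** cohorts.

Patients referred for a second course of palliative radiotherapy span an
enormous prognostic range — from days to years — and treatment regimens
(single 8 Gy fraction vs. multi-week schedules) should match expected
survival. `palliscore` implements, as a tested and reusable pipeline, the
derivation and application of a reirradiation-specific prognostic score,
together with the survival-analysis machinery it rests on and a seeded
synthetic-cohort generator so the whole pipeline is exercisable without
patient-level data.

## The method

For right-censored survival times measured in months from the start of
reirradiation:

- **Kaplan-Meier** product-limit estimation, with the *actuarial death
  rate* at horizon *t* defined as `100 · (1 − Ŝ(t))` percent, Greenwood
  standard errors, and median survival ("not reached" when Ŝ stays above
  0.5).
- **k-group log-rank tests** (hypergeometric variance, χ² with k−1 df,
  pooled over all strata for multi-level factors) plus uncorrected pairwise
  comparisons.
- **Cox proportional hazards** with Breslow tie handling, maximized by
  Newton's method; a univariate log-rank screen (carry forward at
  p &lt; 0.1) followed by likelihood-ratio **backward elimination**
  (removal at p ≥ 0.10, multi-level factors dropped as a block).
- **Point-score construction**: each prognostic factor level contributes
  points equal to its actuarial death rate (percent) at a fixed horizon
  **divided by 10**. Two variants are kept side by side:

  | variant | horizon | rounding | example |
  |---|---|---|---|
  | v1 | 1 month | floor to nearest 0.5 | 15% → 1.5 points |
  | v2 | 2 months | nearest integer, halves up | 39% → 4 points |

  A patient's total is the sum over the four component factors —
  Karnofsky performance status ≤ 60, known liver metastases, pleural
  effusion, steroid use — and maps onto four risk groups at fixed
  cutpoints (v1: 0 / ≤1.5 / ≤3 / &gt;3; v2: ≤5 / ≤8 / ≤11 / &gt;11).
  Patients missing any component are reported *unassignable*, never
  imputed.
- The three-variable **SPS comparator** (nonbreast primary, metastases
  other than bone, KPS ≤ 60): poor = 3 adverse, intermediate = 2,
  good = 0–1.

## Worked example

```python
>>> import palliscore as ps
>>> ps.assign_points(15, "v1")      # KPS <= 60, 1-month death rate 15%
1.5
>>> table = ps.reference_point_table("v2")
>>> table.min_total, table.max_total
(4.0, 17.0)
>>> patient = ps.PatientRecord("p1", time_months=3.0, event=True,
...                            kps=50, steroids=True,
...                            liver_mets=False, pleural_effusion=False)
>>> res = ps.total_score(patient, table)
>>> res.total                        # 4 (KPS<=60) + 1 + 1 + 3 (steroids)
9.0
>>> ps.assign_risk_group(res.total, "v2")
3
```

A total of 9 points under the 2-month variant places this patient in risk
group 3 (second-least-favorable tier). End to end from a shell:

```bash
palliscore run --seed 7 --n 300 --out results_run
```

generates a 300-course synthetic cohort, screens candidate factors,
runs backward elimination (retaining, for this seed, performance status,
steroid use, liver metastases, and pleural effusion), derives both point
tables, scores every patient, and writes stratification reports plus a
checksummed `MANIFEST.json`. `palliscore --help` lists the single-stage
subcommands (`generate`, `screen`, `fit`, `derive`, `apply`, `sps`,
`evaluate`).

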