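# Methods

This note records the statistical models, the synthetic-data design, the
numerical conventions and the deliberate simplifications behind
`meldalloc`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Scoring and endpoints

**MELD.** `compute_meld` evaluates
`(0.957 ln Cr + 0.378 ln Bili + 1.12 ln INR + 0.643) x 10` with the
registry conventions: each laboratory value below 1.0 enters the logarithm
as 1.0; creatinine is capped at 4.0 mg/dL and forced to 4.0 for patients
with two or more dialysis sessions in the past week or 24 h of continuous
veno-venous hemodialysis; the integer score is the raw value rounded half
up (the convention in score calculators; the source system does not state
its rounding) and capped at 40. The floor case gives raw 6.43, so the
integer score is never below 6. Bilirubin and INR carry no upper cap.

**Composite waitlist endpoint.** Removal for death or clinical
deterioration is an event (deterioration on the waitlist is almost
uniformly fatal without a graft); removal for transplant or improvement,
and continued waiting, are censoring. Times are days from registration; no
left truncation.

**Urgency statuses (previous system).** Status 1 is fulminant failure /
early graft failure; 2A requires CTP ≥ 10, ICU admission, life expectancy
under 7 days and an acute complication; 2B is CTP ≥ 10, or CTP ≥ 7 with
bleeding/refractory ascites/SBP, or stage T1–T2 HCC; 3 is CTP ≥ 7.
Precedence is by urgency. Clinical judgments are boolean inputs, not
computed.

## Survival estimation

`km_fit` implements the product-limit estimator with Greenwood variance;
at tied times events precede censorings (an observation censored at t is
still at risk at t). `logrank_test` implements the k-group log-rank
chi-square with the hypergeometric (tie-corrected) variance; the statistic
uses the first k−1 groups' observed-minus-expected vector and the matching
covariance block (pseudo-inverse fallback for singular blocks).
`permutation_logrank` permutes group labels and reports
`(1 + #{permuted ≥ observed}) / (n_perm + 1)`; it is the finite-sample
oracle for the asymptotic test in the test suite.

## Survival tree

`fit_tree` grows a binary tree over integer MELD thresholds
("≤ c vs > c", matching the inclusive band notation). At each node every
feasible threshold (both children at least `min_node_size`, default 50) is
scored by the two-group log-rank statistic; the maximal-statistic threshold
wins, ties broken towards the smallest c. The stopping rule controls the
threshold-search multiplicity: with the default asymptotic test the best
split's p is Bonferroni-multiplied by the number of candidates; with
`n_perm > 0` a max-T permutation of the best statistic over all candidates
is used instead (exact multiplicity control). Either way a homogeneous node
splits with probability at most α (default 0.05), the overfitting control
that motivates conditional-inference-style recursive partitioning.

`horizon_days` administratively censors the response before splitting and
summarising; the default is the full follow-up, and the severe-subgroup
analysis (MELD 31–40) uses a 14-day horizon, mirroring the short-horizon
question that motivates broader sharing for MELD ≥ 38. Only MELD is a split
covariate — the HCC dimension is handled by the exception model, mirroring
the two-stage design of the allocation analysis.

## HCC exception model

For each HCC band [a, b] with b ≤ 20, `find_exception_points` compares HCC
patients in the band against non-HCC patients in [a+δ, b+δ] (clipped at 40)
for δ = 0..10 by full-follow-up log-rank, and selects the δ with maximal p
among those with p ≥ α; if none passes, the maximal-p δ is reported flagged
non-equivalent. This maximises similarity of survival curves rather than
performing formal TOST equivalence testing, which matches how the published
mapping was derived (similar Kaplan-Meier curves, then committee
translation into +4/+5 points). Default bands are (6, 13) and (14, 20);
`WaitlistStratification` on non-HCC records can supply data-driven bands
instead. Above MELD 20 the presence of HCC is taken not to affect waitlist
survival and no points are added. `apply_exception` is monotone (never
decreases a score) and capped at 40.

## Allocation model

`assign_tier` implements the staged broader-sharing scheme: (1) combined
regional+national status 1; (2) regional/national MELD 38–40, offers made
per exact score with the regional leg before the national leg; (3)–(8)
alternating regional/national tiers for 31–37, 21–30 and ≤ 20.
`rank_waitlist` filters candidates by identical-or-compatible blood type
(no sub-prioritisation), applies exception points before tier assignment,
and breaks ties by allocation MELD descending then waiting time descending,
with the candidate id as a final tie-break so the ordering is total and
input-order independent. The previous system ranks by status urgency with
waiting time as tie-break; status 1/2A candidates reach donors nationally
during their first 14 days from registration (configurable). Days-on-list
is proxied by `follow_up_days` — records carry no offer date — and
out-of-region candidates who cannot receive an offer are kept at the bottom
of the ranking, flagged ineligible, so the result is always a permutation
of the blood-compatible input.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test. Its
defaults are calibrated to the published cohort; none of them is tuned to
any test outcome.

**Covariates.** HCC prevalence 0.476; sex, age, BMI, blood type, etiology
and CTP class sampled from the published group-specific marginals; region
probabilities (0.54, 0.26, 0.20) follow the population shares of the three
organ-sharing regions. CTP scores within class and complication flags use
plausible class-conditional rates (they drive the status classification
only, not survival). Fulminant failure is excluded (as in the source
cohort), so simulated statuses are 2A/2B/3.

**MELD marginal.** Band masses P(band) = (0.699, 0.194, 0.062, 0.045) over
≤20 / 21–30 / 31–37 / 38–40 are derived from the published status×MELD
table plus the severe-group counts (240 = 140 + 100 of 2248). A plain
normal matching the cohort mean 17.1 ± 8.9 underweights the severe tail
(~1% vs the observed 4.4% at 38–40), so band masses take precedence and the
within-band shape is a discretized shifted lognormal (offset 6,
moment-matched to 20.5 ± 9.2) — MELD is right-skewed in registry data.
HCC-conditional band masses (0.873, 0.114, 0.008, 0.005) reproduce the
overall prevalence and the concentration of HCC at low MELD; within the
exception region the HCC shape is the *pull-back* of the base shape through
the shift map (an HCC patient at m mirrors the non-HCC patient at m+shift
in distribution as well as hazard), with sub-band masses 0.8/0.2 over
6–13 / 14–20, which reproduces the published HCC mean MELD of ≈ 13.4. The
resulting overall mean is ≈ 18 rather than 17.1; the band masses matter
more for every downstream analysis.

**Hazards.** Event times are piecewise exponential in (MELD, time):

* within the ≤ 20 band the log-hazard rises 0.25 per MELD point (the
  canonical per-point mortality gradient), which is what makes nearby
  scores distinguishable and the +4 offset identifiable; the bands above 20
  are flat in MELD, so the band boundaries at 20/21 and 30/31 are the only
  hazard discontinuities there;
* the severe bands' early rates come in closed form from their 14-day
  survival targets (64%, 43.4%); one shared late rate after day 14
  reproduces the pooled 16.2% 90-day survival of MELD 31–40 — the early
  survivors stabilise, which a single exponential cannot express;
* after day 90 the 21–30 band's survivors converge to the same late
  progression rate: beyond its own horizon, listing MELD loses
  discrimination among decompensated patients. This progression assumption
  is what makes the 20-threshold, not the 30-threshold, the strongest
  full-follow-up split, as in the published tree;
* the two lower bands' bases are solved by 1-D root finding (Brent) so the
  model-implied stratum survival — including the HCC shift — matches 95.9%
  (≤ 20) and 64.1% (21–30) at 90 days exactly. Bands are solved from
  severe to mild because shifted HCC patients in the lowest band borrow the
  hazard of the band above 20.

**HCC effect.** The default shift is +4 on MELD 6–13 and +5 on 14–20, zero
above 20. With the shift set to 0 the two groups share one within-band
shape and one hazard, so HCC and non-HCC are exchangeable given the band —
the null that the exception search should (and in tests does) report as
offset 0. The pooled MELD > 20 comparison is *not* an exchangeability test:
HCC prevalence is ~28% in 21–30 but ~6% above 30, so the pooled groups
differ in severity mix even though hazards are identical given MELD.

**Censoring and follow-up.** Removal for transplant/improvement is an
independent exponential clock at 1e-3/day, with administrative censoring at
1095 days — roughly the accrual-plus-follow-up window of a three-year
registry study in a low-deceased-donation setting. Follow-up is recorded in
fractional days (2 decimals): rounding to whole days visibly biases 14-day
survival when daily hazards reach 3–6%.

**Determinism.** One root seed; covariates, MELD, labs, event times,
censoring times, removal reasons and tumour stages draw from separate
`SeedSequence` substreams, so adding a covariate does not perturb event
times. Laboratory panels are constructed to reproduce each sampled integer
MELD exactly (the raw score is drawn inside the rounding cell and split
across the three log terms with Dirichlet weights, respecting the
creatinine cap; saturated creatinine terms may become dialysis patients).

**What the generator does not emulate.** Longitudinal MELD updates, donor
arrival processes, dependence between transplant access and severity
(censoring is independent — in reality sicker patients are transplanted
faster), centre effects, and covariate-outcome associations other than
through MELD and HCC. Passing recovery tests therefore shows that the
pipeline identifies the structure it is designed to find when the data
contain it — not that real registry data satisfy these assumptions.

## Problem sizes and reliability of the recovery analyses

The packaged analyses use n = 20000 (stratum Kaplan-Meier checks,
accepted within 3 Greenwood standard errors), n = 5000 (tree cut-off
recovery) and n = 10000 (exception-offset recovery), the scales at which
the recoveries are stable across seeds in our validation runs. Offset
recovery for the upper HCC band (14–20) is sharply identified by the
hazard discontinuity at 20/21; the lower band (6–13) sits in a region with
few events, and its recovered offset can vary by ±1 point between seeds.
Fixed-seed tests freeze typical replicates.

## Known limitations

* The exponential-in-time pieces are a minimal model reproducing one
  survival value per band per horizon; real waitlist hazards vary
  continuously.
* The equivalence search scans integer offsets of whole bands; the
  published committee process mapped matched ranges to points in a way not
  fully specified, and this implementation reproduces the offsets, not the
  committee.
* The allocation model ranks candidates for a single offer; it is not a
  discrete-event simulator of the whole allocation system (no organ
  acceptance behaviour, no pediatric or split-liver rules).
* CTP scores are inputs, not computed from their clinical components; no
  PELD or sodium-MELD variants.
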