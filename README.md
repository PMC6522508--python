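# meldalloc

Analysis toolkit for MELD-based liver transplant waitlist stratification and
organ allocation modelling, built around the design of the Korean (KONOS)
MELD allocation system.

Liver grafts are scarce, and allocation systems must rank waitlist
candidates by medical urgency. The MELD score,

```
MELD = (0.957 ln Cr + 0.378 ln Bili + 1.12 ln INR + 0.643) x 10
```

with laboratory values floored at 1.0, creatinine capped at 4.0 mg/dL (and
set to 4.0 for patients on dialysis), and the score capped at 40, predicts
90-day waitlist mortality from three laboratory values. Designing an
allocation system around it requires answering three statistical questions,
all implemented here:

1. **Where should the MELD bands lie?** A survival CART — recursive binary
   partitioning of the composite waitlist endpoint (death or removal for
   clinical deterioration; transplant and improvement are censored) with
   log-rank split selection and a multiplicity-controlled stopping rule —
   stratifies the waitlist into bands with distinct survival (the Korean
   system's ≤20 / 21–30 / 31–37 / 38–40, with national broader sharing for
   MELD ≥ 38).
2. **How many extra points do HCC candidates need?** Hepatocellular
   carcinoma candidates have preserved liver function and low laboratory
   MELD. For each HCC MELD band at or below 20, a survival-equivalence
   search finds the upward offset δ such that HCC patients in the band are
   statistically indistinguishable (maximal log-rank p ≥ α) from non-HCC
   patients δ points higher — reproducing the KONOS +4 (MELD < 14) and +5
   (MELD 14–20) exception points.
3. **Who gets the organ?** A staged regional/national tier model ranks
   blood-compatible candidates for a donor offer (status 1, then MELD 38–40
   shared per exact score regionally-then-nationally, then alternating
   regional/national band tiers), side by side with the previous CTP-based
   status system.

Because the underlying registry is not public, the package ships a seeded
synthetic cohort generator calibrated to the published rates (90-day
survival 95.9% / 64.1% for MELD ≤ 20 / 21–30; 14-day survival 64% / 43.4%
for 31–37 / 38–40; pooled 16.2% at 90 days for 31–40; HCC prevalence 47.6%),
so every stage of the pipeline is testable end to end. Kaplan-Meier
estimation (with Greenwood errors), the k-group log-rank test and its
permutation oracle are implemented from first principles.

## Worked example

```python
from meldalloc import default_config, simulate_cohort, apply_exception
from meldalloc.tree import WaitlistStratification, TreeConfig
from meldalloc.hcc_exception import HCCExceptionModel

records = simulate_cohort(default_config(n=2248, seed=0))

res = WaitlistStratification.from_records(
    records, TreeConfig(seed=0, horizon_days=90.0)
).fit()
print(res.summary())
```

```
MELD waitlist stratification (survival tree, log-rank splits)
n = 2248, events = 417, alpha = 0.05, min node size = 50, horizon = 90 days
split thresholds: [15, 20, 30, 37]

 band  meld_lo  meld_hi    n  events  survival_at_horizon
 <=15        6       15 1166       9               0.9918
16-20       16       20  401      51               0.8678
21-30       21       30  419     145               0.6350
31-37       31       37  146     110               0.2213
38-40       38       40  116     102               0.1136
```

The tree recovers the allocation-defining cut-offs at 20, 30 and 37/38: the
90-day survival of the leaf strata falls from 99%/87% (≤ 20) through 64%
(21–30) to 22% and 11% in the severe bands. The exception search then finds
the offsets that equalise HCC and non-HCC waitlist survival:

```python
exc = HCCExceptionModel(records).fit()
for e in exc.table.entries:
    print(f"HCC MELD {e.hcc_band[0]}-{e.hcc_band[1]}: "
          f"+{e.added_points} points (log-rank p = {e.p_value:.3f})")
```

```
HCC MELD 6-13: +4 points (log-rank p = 0.926)
HCC MELD 14-20: +5 points (log-rank p = 0.887)
```

so an HCC candidate with laboratory MELD 12 is allocated at 16, one at 18
at 23, and one at 25 (above the ceiling) stays at 25:

```python
>>> apply_exception(12, hcc=True), apply_exception(18, hcc=True), apply_exception(25, hcc=True)
(16, 23, 25)
```

A command-line interface wraps the same pipeline
(`meldalloc simulate | meld | km | tree | exception | allocate | report`);
`meldalloc report --in cohort.csv --out report.md` runs everything and
writes a Markdown summary.

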