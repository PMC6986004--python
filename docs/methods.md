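# Methods

## The ascertainment model

`ckdlink` implements a deterministic, rule-based classifier for
prevalent chronic kidney disease (CKD) over four linked administrative
sources, plus a dialysis registry used only for validation.  The unit
of analysis is the person, linked across registries by an exact
pseudonymized identifier; no probabilistic linkage is attempted.  A
person is a prevalent case at the prevalence date (the last day of the
selection window, default 2012-01-01 … 2017-12-31) when at least one
source rule fires:

* **Hospital discharges (HDR).** Any discharge inside the window whose
  diagnoses (primary or secondary), procedures, or complex outpatient
  package codes hit the shipped code catalogue.  *Acute-failure trap:*
  a discharge whose only qualifying evidence is hemodialysis (39.95)
  and/or venous catheterization for dialysis (38.95) is discarded when
  any of its diagnoses is acute renal failure (584.x).  The trap is
  per record — the record ceases to exist for every downstream use,
  including severity evidence — and a person survives it whenever any
  other record qualifies.
* **Exemptions (TER).** A CKD (025.585) or kidney-transplant
  (025.V42.0) co-pay exemption registered and still active at the
  prevalence date.  An exemption revoked before that date does not
  count.
* **Outpatient services (OSSIS).** At least two nephrology visits
  (codes 89.7 / 89.01 / 89.03 with specialty branch 29) on distinct
  service dates, or one such visit confirmed by a urine-albumin
  measurement (90.33.4) or by a qualifying drug dispensing, or any
  dialysis-related service (39.95.x, 54.98.x, 38.95, 54.93, 39.99.1,
  97.82, 97.29.1).  Same-day duplicate visits are treated as billing
  artifacts and count once.  Records without a branch value never
  count as nephrology visits.
* **Dispensings (PHARM).** At least one dispensing of an
  erythropoiesis-stimulating agent or a phosphate/potassium binder
  (B03XA01–03, V03AE01/02/03/05).

The source sentence defining the outpatient rule admits two readings;
the default (`ossis_rule="drug_standalone"`) lets a dispensing alone
qualify a person through PHARM — the only reading consistent with a
nonzero PHARM-exclusive contribution — while
`ossis_rule="drug_confirms_only"` restricts dispensings to the
visit-confirmation role.  Similarly `ossis_dialysis_standalone=False`
demands visit confirmation for dialysis-related services.  When a
single visit is confirmed by a dispensing, the person is credited with
both an OSSIS and a PHARM trigger, so source attribution sees both
databases.

Qualified persons who died on or before the prevalence date, or who
were not resident (half-open residence intervals) on that date, are
excluded.  Exclusive source contributions count cases whose trigger
set names exactly one database; the "all databases" line counts cases
found in all four.

## Severity

A case is **higher severity** when the window contains (i) dialysis
evidence — a dialysis or dialysis-access procedure (39.95, 54.98,
39.27, 54.93, 39.42, 39.43, 38.95) on a non-excluded discharge, or a
dialysis-related outpatient service; (ii) transplant evidence (55.6x,
V42.0, exemption 025.V42.0, packages P585B/PV420); (iii) a hospital
diagnosis of CKD stage IV+ (585.4x–585.6x); or (iv) any qualifying
dispensing.  Everything else is lower severity.  Kidney biopsy (55.23)
qualifies a case but is deliberately not severity evidence: the
severity definition names dialysis, transplantation, advanced stage
and drugs, and biopsy is none of these.  Because criterion (iv) is a
single dispensing, every PHARM-exclusive case is necessarily higher
severity.

## Rates

Prevalence is reported per 100: cases alive and resident at the
prevalence date over the resident-alive population, within the age
classes 0–18, 19–44, 45–64, 65–74, 75–84, 85+ crossed with sex.  Age
is completed years at the prevalence date (February 29 birthdays
complete their year on March 1 in common years).

The 95% CI is the Wald normal approximation on the binomial
proportion.  The source tables do not name their interval method; the
Wald interval reproduces every printed CI cell of the published
stratum grid at these denominators (hundreds of thousands per
stratum), which is the check the package's tests freeze.  For small
strata `ci_method="clopper-pearson"` gives the exact interval.

Direct standardization averages stratum rates with weights
proportional to a user-supplied reference population (the national
reference used by the source study is not printed and therefore not
shipped), normalized within the margin being standardized; its default
CI uses the weighted sum of per-stratum binomial variances, with a
gamma interval (`ci_method="gamma"`) as the conservative alternative
for rare outcomes.  With weights proportional to the study population
itself, standardization reproduces the crude rate to machine
precision — a tested identity.

Male:female ratios divide unrounded rates and round once at the end.
All presentation rounding is half-away-from-zero (rates 2 decimals,
shares and metrics 1, ratios 2), matching the convention of the
statistical software behind the published tables (e.g. 4,143/99,457 →
4.2%).

## Validation

The dialysis registry restricted to entries starting on or before the
window end, alive and resident at the prevalence date, is the gold
standard.  The algorithm's positive set is the identified cases with
dialysis evidence (criterion i).  The true-negative denominator is the
full resident-alive population by default — specificity of a rare
treatment is only meaningful region-wide — with `denominator="cohort"`
as the restricted alternative.  A metric with a zero denominator (PPV
under an empty algorithm set) is reported as not applicable, never as
0 or 100.

## Synthetic registries

The generator emulates the six registries with planted ground truth.
Defaults follow the published study's shape: the age/sex structure and
per-stratum prevalence equal the published stratum grid (so the
marginal crude rate is ≈1.8%), 21.3% of cases are higher severity, and
30% of higher-severity cases are on chronic dialysis (the study prints
no dialysis share; this is a plausible regional figure and only scales
the validation denominators).  Each case draws a source set from
per-source emission probabilities (HDR 0.55, TER 0.15, OSSIS 0.70,
PHARM 0.35 — chosen to produce a multi-source mixture with nonzero
exclusive contributions from every database, not calibrated to the
published contribution surface) and emits, per drawn source, a record
pattern that provably satisfies that source's rule.  Dispensings are
emitted only for higher-severity cases, since a dispensing is itself a
severity criterion; higher-severity cases without dialysis receive a
stage-IV+ diagnosis, a transplant exemption or a dispensing so the
planted label is always algorithmically visible.  Non-cases emit
nothing in the base draw.

Noise channels perturb a base draw without touching its planted truth
except to flag exclusions: acute-failure-only admissions and single
unconfirmed visits for non-cases (which the rules must absorb), deaths
and emigrations of planted cases (which the cohort resolution must
drop), background records with non-catalogue codes, and two dialysis
error channels for validation: false positives (a dialysis-related
service without a registry entry) and false negatives (a registry
patient stripped of algorithm-visible dialysis records; a CKD
exemption is added so the person remains a case and only the dialysis
call degrades — otherwise the sensitivity arithmetic would be
confounded with cohort loss).  With the false-negative channel on,
planted severity labels are no longer guaranteed to be recoverable;
tests exercise the channels separately.

Randomness is a numpy `Generator` per person, keyed by
`(seed, person_index)` (noise channels use a separate sub-key), so
identical seeds give byte-identical files and enlarging the population
never reshuffles existing persons.

### What the synthetic data does not show

The generator plants records that cleanly satisfy or cleanly fail the
rules.  It does not emulate coding heterogeneity across hospitals,
miscoded or missing identifiers, registry lag, drug use for non-renal
indications, or true disease status beyond the planted labels — so
passing tests demonstrate the algorithm's internal correctness
(rules, exclusions, accounting, arithmetic), not its clinical accuracy
on real claims, which only a linked clinical gold standard could
establish.

## Problem sizes and numerical choices

Tests draw 1,500–5,000 persons with planted prevalence inflated
tenfold over the published stratum rates, so exact-recovery checks
operate on hundreds of cases rather than a handful; the
record-by-record oracle comparison runs 500 randomized 200-person
instances; the acceptance script draws 20,000 persons.  These sizes
are a package choice balancing statistical content against a fast
default test run.  Set operations are order-independent and outputs
are sorted by person identifier; reruns on identical inputs are
byte-identical.  Degenerate inputs (empty case lists, zero
denominators, strata missing from a reference population) raise or
report not-applicable explicitly rather than returning silent zeros.

## Known limitations

No probabilistic linkage; single prevalence date per run; no
incidence or temporal trends; no KDIGO staging (administrative data
carry no eGFR/albuminuria); ICD-9-CM only, as in the source coding
dialect; the shipped catalogue is frozen by checksum but fully
replaceable via a YAML file.
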