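# Methods

This note documents the statistical model, the algorithmic conventions, and
the design decisions behind `sentinelchd`, in the spirit of the methods
documentation of packages like statsmodels or msprime: what is computed, under
which assumptions, and what the bundled synthetic data can and cannot show.

## Analysis model

### Time scale and units

All event times are **integer days since birth**; the report ages of 1, 5 and
10 years are 365.25·k days. Using the age scale (rather than time since first
procedure) matches how childhood survival is reported clinically: "survival at
10 years" means survival to the 10th birthday.

### Phenotyping

A patient's diagnosis concepts are pooled across all of their procedure
records, because later procedures often carry fuller diagnostic coding. The
pooled set is matched against marker concepts for the nine sentinel CHDs; when
several match, the most clinically complex wins under the fixed precedence
HLHS > FUH > TGA > PA > AVSD > TOF > AS > COARCT > VSD. This makes combined
phenotypes deterministic: coarctation + VSD codes yield coarctation (subgroup
"with VSD"), tetralogy + AVSD codes yield AVSD (subgroup "tetralogy AVSD").
Subgroups are decided by ordered modifier rules with a residual default
(e.g. TGA with no modifier markers is TGA with intact septum), so the subgroup
partition is exhaustive and mutually exclusive. Assignment is a pure function
of the pooled concept multiset — invariant to record order and duplication —
and each rule fired is recorded in an audit trace.

The precedence order, subgroup rules and marker sets live in a versioned YAML
dictionary. The bundled dictionary is a synthetic stand-in for licensed
production code lists (its raw codes are invented), but the schema accepts a
production mapping unchanged.

### Pathway slots and reinterventions

Each diagnosis has an expected treatment pathway built from five slots:
prepathway (short-lived neonatal interventions such as balloon atrial
septostomy), stage 1 palliation, stage 2 (Glenn), stage 3 (Fontan), and
reparative surgery. Scanning records in age order, the **first** record
bearing each role fills that slot; every later occurrence of a pathway
procedure (a reoperation) and every other therapeutic intervention is a
**reintervention**, categorized as surgical (bypass, non-bypass, hybrid) or
interventional cardiology (catheter, electrophysiology). Conventions:

* Prepathway records are never reinterventions, however many occur.
* Transplant records set the competing-event age and are never
  reinterventions.
* Purely diagnostic records (diagnostic catheter, EP study) are ignored.
* Therapeutic "other" records count as reinterventions wherever they fall in
  the sequence, including before the first pathway procedure; the stricter
  alternative (counting them only after the first slot) would silently drop
  genuine early reinterventions in miscoded histories.
* Same-day ties keep file order, so a same-day duplicate of a slot procedure
  deterministically becomes a reintervention (and trips quality rule q6).

Pathway type is derived from the slots: stage 2/3 without repair is a
single-ventricle course, repair without stage 2/3 is biventricular, both or
neither is indeterminate (a quality-review target).

### Quality flags

The production audit's clinician-curated rule list is not published, so the
default ruleset is a documented reconstruction, versioned and replaceable:

| rule | fires when |
|------|-----------|
| q1 | stage 2 filled but stage 1 empty or coded after stage 2 |
| q2 | stage 3 filled but stage 2 empty or coded after stage 3 |
| q3 | staged palliation coded for an exclusively biventricular diagnosis (TOF, VSD, coarctation, AS) |
| q4 | both reparative surgery and stage 2/3 palliation present |
| q5 | first procedure age above a per-diagnosis bound (default: HLHS > 365 d) |
| q6 | a reintervention duplicates a filled slot on the same day |

Flagged patients are excluded from reintervention metrics but retained for
survival metrics by default (the published convention); both scopes are
switchable (`exclude_flagged_from_survival`, `exclude_flagged_from_completion`).

### Life-status ascertainment

Per-patient terminal state follows a strict source precedence: audit-recorded
death age, then national-register death age, then register alive-confirmation
age (censoring), then the latest hospital discharge age (censoring, flagged
lost to follow-up). A patient with no resolvable age at all is excluded with a
log entry.

### Estimators

**Survival** uses the Kaplan–Meier product-limit estimator over distinct death
ages, with Greenwood variance and 95% CIs on the log(−log S) scale
(exponential Greenwood), which stay inside [0,1]. Deaths are processed before
censorings at tied ages. With no deaths observed the CI is reported as the
degenerate [1, 1].

**Reintervention incidence** uses the Aalen–Johansen cumulative incidence
function with two causes — first reintervention, and death or
transplant-without-prior-reintervention as the competing cause — over
first-event-per-patient data: follow-up ends at the earliest of first
reintervention, death, transplant, or censoring. A reintervention tied with a
competing event on the same day resolves as a reintervention (the event of
interest ends follow-up). Variance is the Marubini–Valsecchi estimator,
computed in O(m) via cumulative-sum expansion, and CIs are delta-method on
log(−log F). The estimator's point values agree with R's `cmprsk::cuminc` to
print precision on a frozen fixture; the variances agree to a few percent
(cmprsk uses the Aalen counting-process variance, a different but
asymptotically equivalent estimator), which the test suite asserts at 10%
relative tolerance.

Category-specific incidence (surgical-only, catheter-only) treats the first
reintervention *of that category* as the event; reinterventions of the other
category do not end follow-up.

Both estimators are implemented directly in numpy because the tie-breaking,
CI transforms and exact step grids are part of the package's contract;
`lifelines` serves as an independent cross-check in the tests (KM values and
CIs agree to 1e-9), never as the implementation.

## Synthetic registry generator

The generator exists so every downstream stage is testable against known
ground truth without access-controlled data. Per diagnosis block it emulates:

* **Cohort structure** — the published block sizes (summing to 29,319
  patients), subgroup mixes, and per-subgroup log-normal age and weight at
  first procedure parameterized by median and IQR
  (σ = ln(q3/q1)/(2·z₀.₇₅)).
* **Event processes** — death as a piecewise-constant hazard on the age
  segments [0,1), [1,5), [5,10), [10,∞) years, solved in closed form from the
  block's target survival at 1/5/10 years (the tail reuses the 5–10 y
  hazard); reinterventions as a Poisson process whose piecewise intensity is
  solved segment-by-segment (Brent root-finding on the monotone closed form)
  so the *implied competing-risks incidence* at 1/5/10 years equals the
  block's target given the death hazard. Because both are exact, the
  generator's implied values equal the calibration targets, and parameter
  recovery is a pure test of the analysis chain.
* **Trajectories** — staged single-ventricle templates (stage 1 at the
  sampled first-procedure age, stage 2 after a log-normal gap of ~4–5 months,
  stage 3 after ~3 years) and biventricular templates (optional prepathway
  and palliative stage 1, then repair). Attainment of each stage is Bernoulli,
  sequential for stages 2 and 3, and truncated by death and administrative
  censoring — so observed completion fractions resemble published pathway
  diagrams without being calibration targets. The default attainment
  probabilities and gap medians are realistic choices, not published values.
  A patient attaining no stage at all receives a diagnostic catheter record so
  every patient appears in the registry.
* **Observation scheme** — uniform cohort entry across a 22-year study
  window gives administrative censoring at `first_proc + U·(window −
  first_proc)`; a 2% default loss-to-follow-up rate censors at the last
  hospital discharge, with in-hospital deaths still observed (proper
  right-censoring, since censoring times are independent of the death
  process). A patient whose sampled death precedes the sampled
  first-procedure age has the procedure moved to about half the death age —
  registry cohorts condition on entry, and this keeps the birth-origin KM
  equal to the closed-form implied survival without left-truncation
  machinery.
* **Corruption** — with 1% default probability per patient, one of: delete
  the stage-1 record while keeping stage 2 (trips q1), delete stage 2 while
  keeping stage 3 (q2), or duplicate the latest filled slot as a same-day row
  (q6). About 1–2% of corrupted staged patients are genuinely undetectable,
  because a later reoperation of the deleted stage refills the slot in
  plausible order; the flagged fraction still tracks the injected rate well
  inside 3 binomial SEs at the default cohort size.

Randomness: the global seed keys one Philox stream per diagnosis block
(seed, CRC32 of the block name), so editing one block never reshuffles
another; corruption uses a separately derived stream. Runs are byte-identical
given a seed.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: age and weight are sampled independently (their joint
distribution is unpublished); death and reintervention hazards are constant
within segments and shared across subgroups of a diagnosis, whereas real
subgroups differ markedly; no centre, era or seasonal effects; no
transplant events by default (the competing-event handling is exercised by
unit fixtures); corruption covers three mechanisms, not the full spectrum of
miscoding. Recovery of the calibration targets therefore validates the
analysis pipeline, not the clinical realism of any particular trajectory.

## Numerical and degenerate-case choices

* Percentages in published-style tables are rounded to 1 decimal.
* Empty groups are omitted from metric tables (with a log entry); empty
  groups in completion summaries report an absent percentage.
* KM with no events returns S ≡ 1 with degenerate CIs; CIF at F = 0 returns a
  (0, 0) interval, and at F ≥ 1 or zero variance a degenerate (F, F).
* Dictionary loading fails fast on duplicate codes with conflicting concepts
  and on missing required roles per diagnosis (e.g. a staged diagnosis
  without a stage-2 concept), so incomplete rule files are caught before any
  analysis.
* Life-status linkage rejects conflicting duplicate rows, naming the patient.

## Problem sizes used by the test suite

The bundled default cohort uses the published block sizes (29,319 patients);
the parameter-recovery test uses 2,000 patients per diagnosis block across 50
seeded replicates, checking that the 95% CIs cover the implied survival
(1/5/10 y) and 10-year reintervention incidence in at least 90% of
replicate-quantity checks per block; classification-recovery tests use 400
patients per block and require exact (100%) agreement with ground truth.
These sizes keep the full suite around two minutes on one CPU while leaving
the binomial tolerances meaningful.

## Known limitations

* The one-slot-per-role model cannot represent legitimately repeated pathway
  procedures (e.g. staged coarctation plus later VSD closure both being
  "expected"); the second occurrence counts as a reintervention.
* Quality rules are a reconstruction; real audits apply clinician review that
  no declarative ruleset fully captures.
* The estimators are purely descriptive: no covariate adjustment, no
  centre-level comparison, and prematurity/comorbidity flags are reported but
  not modelled.
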