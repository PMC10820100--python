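# Methods

## The analysis problem

A darting-based immunocontraception program produces event-level records:
who was darted when and with what (primer P, booster B, repeat primer
RP), whether the dose was confirmed delivered, which mares foaled and
when, what injection-site lesions were seen, and where each horse was
seen month by month. The quantities a manager needs — herd coverage,
mean active vaccinations per mare under assumed efficacy durations,
foaling and conception trends, lesion prevalence — are all functions of
these events laid out on a monthly grid. This package makes that mapping
explicit, testable and reusable.

The observation window is configurable and defaults to January 2019 –
December 2022 (48 months), indexed 1..48. Dates before the window map to
non-positive indices so that pre-program vaccination history is ordinary
data, not a special case.

## Panel construction

Each female contributes one row per month of her *activity period*:
from `max(window start, birth month)` when her date of birth is known,
otherwise from her first appearance in any table, through the month of
her death/removal or the window end. Flags:

* **Maturity.** Mature means strictly older than one year, evaluated on
  the first day of the month. Females without a recorded date of birth
  are mature from their first evaluated month (they are adults whose age
  was never captured). The eight-month threshold used for *treatment
  eligibility* is deliberately lower than the one-year maturity
  threshold used for *analysis*: the field protocol primes peripubertal
  mares early because relocating a specific mare later is unreliable.
* **Pregnancy.** Only pregnancies that end in an observed birth exist:
  conception is back-dated 354 days (equine gestation) from the birth,
  `conceived` is true in exactly that month, `pregnant` from conception
  month through birth month, `foaled` in the birth month. Pregnancy
  attrition is deliberately not modelled; true conception rates are
  therefore understated, and the proxy is biased in the same direction
  as the field analysis it reproduces.
* **Lesions.** Closed month intervals from first observation to
  resolution; unresolved lesions stay active to the window end.

Two gestations of one mare may not overlap in any month; this is raised
as an integrity error rather than silently merged.

### Geographic exclusions

A female is removed from analysis if she has a run of ≥ 12 *consecutive*
residency months with darting not permitted (12 months being the point
at which her treatment course has lapsed), or if she resides in a
configured excluded area (label `edge` in the simulator, standing for
range-edge areas that entered the program too late to contribute
efficacy data). Boundary-crossers whose longest unpermitted run is
shorter than 12 months are retained, as in the field protocol. A gap in
the residency record breaks a run: absence of evidence of residence is
not treated as residence.

## Protocol scheduler

`next_action(history, dob, query)` is a pure function implementing the
treatment ladder, precedence top-first:

1. chronology guard (query before the last recorded event is an error);
2. eligibility (older than eight months, or unknown age);
3. reproductive reset: a foaling/obvious-pregnancy observation after the
   last course start prescribes RP; the reset is consumed by that course
   start (otherwise a mare could never leave the restart state);
4. never treated → P;
5. primed but never boosted for ≥ 12 months → RP;
6. ≥ 14 months since the last booster → RP;
7. booster due: ≥ 14 days after a primer, or ≥ 8 months after the last
   booster → B;
8. otherwise up to date.

Intervals quoted in months are calendar months (dateutil arithmetic);
"two weeks" is exactly 14 days. A booster given 12–14 months after the
previous one is a *late booster*, not a restart — only the ≥ 14-month
gap restarts the course. Misfires (unconfirmed deliveries) are invisible
to the scheduler, so the mare is simply prescribed the same action at
the next encounter. The first annual booster window ("8–12 months") is
measured from the most recent treatment; reset observations are only
acted on once.

## Decay model

The efficacy window is rectangular: a vaccination in month *m* is active
for months *m..m+W−1* (the administration month is inside the window —
the convention is pinned by the worked example of a mare first
vaccinated in month 8 under W = 6 being covered months 8–13 and
reverting to zero in month 14). Permanent efficacy is the W → ∞ limit.
Continuous (e.g. exponential) waning is out of scope by design; the
scenarios {permanent, 18, 12, 6} bracket the biological uncertainty.

The per-month mean divides the total active count by the number of
mares with a *mature* panel row that month — the denominator is the
herd "at that point", not an annual total. P, RP and B all count as one
vaccination. Pre-window vaccinations participate with their true months.

## Summaries

* Treatment summaries split events by the mare's panel maturity in the
  treatment month; "mares vaccinated" counts distinct mares with ≥ 1
  confirmed treatment in the calendar year regardless of action type.
* Lesion prevalence divides annual occurrences by **all** treatments
  given that year (mature + immature combined). This denominator is the
  unique choice that reproduces all eight published prevalence cells
  (e.g. 11/(1821+57) = 0.59%, 24/1878 = 1.28%).
* The conception proportion for year Y is births of year Y+1 (the
  354-day proxy pushes conceptions into the next calendar year) over the
  mature total of year Y — again the unique convention reproducing the
  published 31.9% / 14.9% / 10.3% sequence.
* Foal mortality in year Y counts deceased foals under one year old with
  the death *recorded* in Y, even when born in Y−1, over the births of
  Y. Removals are filtered the same way for symmetry.
* Percentages are reported at the published precision: one decimal for
  coverage/reduction/mortality, two for prevalence.
* The fertility control index is the plain product coverage × efficacy,
  with both arguments constrained to [0, 1].

## Simulator

The simulator is an individual-based monthly-step model whose only
purpose is to generate datasets with known ground truth under the same
protocol the pipeline analyses. Within each month the steps are:
mortality → births due this month → residency and darting → conception.
Event dates are drawn uniformly within the month so day-based intervals
(354-day gestation, 14-day booster delay) are exact.

Key default conditions (all configurable in `SimulationConfig`):

| parameter | default | why |
|---|---|---|
| initial females | 500 | matches the scale used for recovery experiments (500 mares × 48 months) |
| conception hazard (Jan..Dec) | 0.01, 0.02, 0.05, 0.10, 0.15, 0.10, 0.05, 0.02, 0.01, 0.005, 0.005, 0.005 | spring-peaking seasonal breeding, peak conception in May, ≈ 0.53 annual hazard for an always-available mare |
| gestation | 354 days | equine gestation used by the conception proxy |
| vaccine efficacy *e* | 0.9 | high per-dose efficacy typical of boosted pZP |
| protection window *W* | 12 months | the biologically plausible single-year efficacy scenario |
| adult mortality | 0.005/month | ≈ 6%/yr for a predated free-roaming herd |
| foal mortality | 0.045/month | ≈ 42% in the first year, the low end of the published 41–63% annual foal mortality |
| encounter probability | 0.15/mare-month | opportunistic darting; most mares reached within a year |
| misfire probability | 0.05 | unconfirmed deliveries that must be repeated |
| granuloma / abscess per treatment | 0.003 / 0.010 | sub-percent to ≈ 1% lesion prevalence |
| area assignment | 5% edge, 10% south (unpermitted), 5%/month boundary crossing | exercises both exclusion rules and the retained boundary-crossers |

Darting begins in study month 4 (the program's regulatory start).
Treatment actions are exactly what the scheduler prescribes at the
encounter date, so emitted records replay through the scheduler without
disagreement (a closed-loop invariant under test). The vaccine acts as a
rectangular hazard multiplier 1 − *e* during the protection window,
mirroring the decay model's windows. Post-partum re-conception is
allowed from the month after foaling — monthly resolution cannot express
foal heat more finely. A fraction of initial mares (25%) start the
window pregnant, with pre-window conception dates drawn from the
seasonal hazard, reflecting that a year-long gestation means many mares
are already in foal when a program begins.

An optional fixed-interval policy (`annual_policy_interval_months`)
gates encounters so a mare is only treated when ≥ k months have passed
since her last confirmed treatment; with k = W = 12, certain encounters
and no misfires this produces exactly one active vaccination per mature
mare in steady state — the calibration case for the recovery
experiment. (Mares that die in their re-treatment month leave a
one-month coverage gap, so the measured plateau sits a fraction of a
percent below 1.0.)

What the simulator does **not** emulate: observation error (every birth
and death is recorded), band social structure, migration in or out,
spatial movement beyond the categorical area labels, pregnancy
attrition, and antibody-titre kinetics. Passing tests therefore
demonstrate the pipeline's arithmetic and rule logic, not the field
program's data quality.

## Recovery experiment

`recovery_experiment(cfg, replicates)` runs the full pipeline per
replicate and reports, with means and standard errors:

* the coverage plateau: the W-window mean-vaccinations series averaged
  over post-burn-in months (default burn-in 16 months, one gestation
  plus program ramp-up);
* the realised conception suppression, 1 − (observed conceptions /
  counterfactual expectation), where the counterfactual is the summed
  untreated seasonal hazard of the same at-risk mare-months — this
  construction is unbiased against the fertility-control-index
  prediction because it conditions on the realised at-risk population;
* the FCI prediction for the run: efficacy × hazard-weighted protected
  fraction of at-risk mare-months.

With the default program conditions the two agree within Monte-Carlo
error (≈ 0.64 suppression at ≈ 71% hazard-weighted protection and
e = 0.9).

## Numerical and degenerate-input conventions

* Percentages with zero denominators are NaN ("undefined"), never
  raised, matching how a report would print a dash.
* Monthly means over zero mature mares are NaN.
* Validation reports violations; it never raises and never mutates.
* All file I/O is UTF-8 CSV with ISO-8601 dates; reading then writing a
  dataset is byte-stable.
* The simulator draws from a single seeded generator in a fixed
  iteration order; equal seeds give byte-identical output files.

## Problem sizes

The test suite simulates herds of 60–250 initial females over 48 months,
and the acceptance script uses 250 females with 5–10 replicates; these
sizes give standard errors comfortably below the tolerances being
checked while keeping a full run in the tens of seconds.

## Known limitations

* The published month-by-month field series (e.g. 3.74 mean vaccinations
  at month 48, 551 pregnant mares at month 5) depend on the proprietary
  field database and are not reproducible from counts alone; they inform
  simulator calibration but are not verification targets.
* The "no recorded treatment omissions" qualifier on the
  foaling-restart rule is ambiguous in the field protocol and is not
  modelled: any observed foaling restarts the course.
* Maturity classifications disagree at the exact one-year boundary
  between published text ("> 1") and one table header ("≥ 1"); the
  strict inequality is used throughout.
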