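# Methods

## Model structure

The ED is modelled as a continuous stock-and-flow system: patients are
real-valued quantities accumulating in stocks (waiting for registration,
waiting for triage, per-priority consultation queues, in-consultation
co-flows, laboratory pipelines, waiting-area observation, observation
wards, pharmacy) connected by rate flows. The day runs from midnight over
1440 one-minute Euler steps.

Flow rules per venue:

* **Registration & triage.** Walk-ins pass through two pipeline delays
  (registration time `RT`, triage time `TT`) and are then split by a
  per-priority fraction table into critical / ambulatory / isolation care
  (rows sum to one; under the co-location policy a `gp_divert` column
  removes decanted P3/P4 patients). Ambulance arrivals (P1/P2) enter the
  critical-care queue directly, bypassing registration and triage.
* **Consultation.** Each venue has a doctor pool (`NP`, `NPAB`, `NPIS`).
  Consultation starts are `min(free doctors, queue)` cascaded strictly from
  P1 to P4; a start moves a patient into an in-consultation co-flow and
  occupies a doctor for the consultation time (`CT_cc`, `CT_ab`, `CT_is`),
  a pipeline delay.
* **Critical care routing.** Of completed consultations, fraction `fb` is
  referred to the observation ward (bed-limited), fraction `fh` of the
  rest goes home, the remainder enters the laboratory pipeline (`LIT`).
  Lab completions split `fob` to the ward (bed-limited) vs discharge; ward
  overflow is observed in the waiting area, which discharges at rate
  `1/wt` and admits at hazard `fdd` per minute.
* **Ambulatory care.** Every consultation is followed by laboratory &
  investigation; completions split `foba` to the ward vs discharge, with
  waiting-area overflow as above (`famb` admission hazard).
* **Observation ward & discharge.** Ward occupants leave at rate `OW/ot`;
  fraction `df` is discharged via pharmacy, the rest admitted to the
  hospital. Bed availability is `avb = (bc·ppb − ΣOW)/ttba` — the spare
  bed count damped by the time to make a bed available — and beds are
  granted within each step in the strict order: critical post-consult P1,
  P2; critical post-lab P1, P2; ambulatory post-lab P1…P4. This quantity
  mixes bed and rate units; it is implemented as stated, with `ttba`
  acting as an availability lag, and the occupancy bound `ΣOW ≤ bc·ppb`
  is asserted every step.
* **Isolation care** has its own observation ward (`fis_obs` of
  consultations, dwell `otis`, fraction `fah` admitted) and its own
  pharmacy drain (`1/ppt`).

## Parameters

Stage times are triangular `(low, mode, high)` in minutes; deterministic
runs use the mean `(low+mode+high)/3`, stochastic runs draw each stage once
per replicate (inverse-CDF). Values and provenance (also annotated in the
YAML config):

| key | corners | role | provenance |
|---|---|---|---|
| RT | 3, 5, 7 | registration | published estimate |
| TT | 4, 5, 7 | triage | published |
| CT_cc | 10, 15, 20 | critical consult | published |
| CT_ab | 10, 15.5, 20 | ambulatory consult | published |
| CT_is | 20, 30, 45 | isolation consult | published |
| LIT | 35, 45, 60 | laboratory turnaround | published for critical care; reused for ambulatory (the printed ambulatory pathway sums admit no other value) |
| wt | 30, 60, 90 | waiting-area observation | published ("observation waiting time") |
| ot | 100, 120, 150 | ward dwell to admit/discharge decision | inferred mapping from the published "time to admit patients" (pathway-gap arithmetic: pathway 3 − pathway 1 ≈ 123.3 = its mean) |
| otis | 30, 60, 90 | isolation ward dwell | published |
| ppt | 10, 15, 30 | pharmacy & payment | published |
| ttba | 10, 15, 25 | time to make bed available | published |

Pharmacy time drains the pharmacy stock but is not part of pathway ALOS
(the printed pathway sums leave no room for it).

Doctor and bed capacities and the routing fractions are confidential in
the source setting; the defaults (`NP=3`, `NPAB=4`, `NPIS=2`, `bc=25`,
`fb=0.30`, `fh=0.40`, `fob=0.50`, `foba=0.30`, `fis_obs=0.50`, `fah=0.30`,
`df=0.70`, `fdd=famb=0.005`/min) are package assumptions chosen so a
~350-visit day produces genuine midday congestion in critical and
ambulatory care while isolation care flows freely. `ppd`, `dpp`, `ppb`
(patients-per-doctor/-bed ratios) and the unit-bookkeeping adjustment time
`AT` default to 1. The waiting-time policy scales `LIT`, `wt`, `ot` and
`otis` — scaling `ot` as well as the laboratory leg is required to
reproduce the reference policy table deltas and is flagged as an
inference; everything is overridable via the YAML config.

### Triage fractions and venue shares

The reported marginals — 39% of all attendances to critical care, 55%
ambulatory, 6% isolation — are interpreted over *all* patients including
ambulance arrivals (assumed 10% of attendances, 30% of them P1); walk-ins
alone cannot reach a 0.39 critical share under any plausible acuity mix. A
fixed fever fraction of every priority routes to isolation; all non-fever
P1 and the non-ambulant share of P2 go to critical care; the derived
fraction table reproduces 0.39/0.55/0.06 exactly under the assumed walk-in
mix (P1 2%, P2 37%, P3 51%, P4 10%, itself an assumption).

## Synthetic demand

The real June–August arrival series is confidential. The generator
produces: a **peak** day (~350 attendances) as two Gaussian humps (late
morning, early evening; base 0.25, amplitudes 2.0 and 1.6, σ = 1.8 h)
renormalized to the daily total — shape chosen so the day stresses default
capacities, as in the original stress-test design, but not read off any
recorded figure; a **quiet** day (same shape, ~250); and an
**uncongested** regime (constant 2 walk-ins/hour, no ambulances) in which
no queue ever forms, used for the reference-table reproductions. Rate mode
spreads hourly rates uniformly per minute; count mode draws per-minute
Poisson counts. The generator does not model day-of-week effects, seasonal
or epidemic covariates, or ambulance diversion feedback — so passing tests
say nothing about forecasting real demand, only about the flow mechanics
given a demand curve.

## ALOS estimation

ALOS(venue, pathway, phase) = `RT + TT + Σ_stages (wait + service)`.
Only the consultation stage has an explicit queue; its wait is estimated by
Little's law as (time-average queue)/(time-average throughput) over the
phase window, which equals the FIFO wait both over complete congestion
cycles and under sustained overload. With the default *arrival*
attribution the measurement window is shifted downstream by the mean time
to reach the stage, charging waits to the phase the patient arrived in; an
*occupancy* mode uses the raw window. A stage with a standing queue and no
throughput reports `inf` (saturated) rather than a number. An independent
FIFO tracer-cohort estimator (virtual patients stepped through the
recorded queues) is provided and agrees with the Little's-law estimate to
within 5% on congested days.

## Numerical choices

* `dt` = 1 minute: far below the shortest stage time (3 min), so Euler
  discretization error is negligible; delays are whole pipeline transits.
* Pipeline delays with fractional durations split entering mass between
  the two bracketing step boundaries, preserving conservation and the
  exact mean transit time (ceil-bucketing would inflate a 15.17-min
  consult to an effective 16–17 min and bias saturated throughput).
* A doctor freed in minute `t` can start a new consultation in minute `t`,
  and venue inflow arriving in minute `t` is visible to that minute's
  allocation: without both, every patient pays an artifactual extra
  minute per stage and the uncongested pathway sums would not match the
  analytic stage-mean totals.
* Stocks are floored at zero; competing outflows that would overdraw a
  stock within one step are clipped proportionally (logged at debug
  level). The MIN/MAX guards make this a float-noise safeguard in
  practice.
* Stochastic replicates use seed-derived child streams (one triangular
  draw per stage per replicate, Poisson arrival counts); identical seeds
  give bit-identical trajectories.
* A warm-up option replays the arrival day before the recorded day for
  analyses that should not start from an empty ED; reference tables are
  reported from the empty-midnight start.

## Limitations

Nurse and allied-staff capacity, inter-hospital transfer, patient-level
identity, and leave-without-being-seen dynamics are out of scope. The
congested midday cells depend on the confidential arrival series and are
qualitative here; only the uncongested cells (fully determined by the
published stage times) are quantitative reproductions. The validation
statistics (MAPE, Theil U_M/U_S/U_C) are implemented and identity-tested,
but the original study's real-data values cannot be recomputed without the
hospital series.
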