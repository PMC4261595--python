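# Methods

## Snapshot semantics

The screening rule is evaluated on a *snapshot*: the most recent value of
each of the seven parameters at a time point, plus flags for active
IV-fluid-bolus and supplemental-oxygen orders. Two bounds make "most
recent" well defined:

* **Staleness windows.** A vital (temperature, pulse, respiratory rate,
  SBP, SpO₂) is usable for 4 h after charting — twice the slowest charting
  cadence — and a lab (WBC, lactate) for 24 h. Without such a bound,
  day-old vitals would keep firing alerts. Both windows are configurable;
  an observation exactly at the staleness horizon has expired (strict
  inequality).
* **Half-open intervals.** Therapy orders are active over `[start, end)`;
  an order with no discontinuation time is active until ED departure,
  because order streams record starts far more reliably than stops.

Timestamps are ISO-8601 with explicit offsets at the I/O boundary and plain
epoch seconds internally. All criteria must hold in the *same* snapshot —
the defining limitation of this alert class: derangements that never align
in time cannot fire.

## Criteria

Thresholds follow the screening rule exactly and all comparisons are
strict: 38.0 °C, 90 bpm, 20 /min, 12 and 4 (10³ cells/µL), 2.0 mmol/L do
not satisfy their criteria. WBC is stored in 10³ cells/µL. The two
therapy-conditional clauses are read as a clean partition: SBP < 86 mm Hg
is unconditional and [86, 90) requires active fluids (analogously SpO₂
< 85 % unconditional, [85, 90) on oxygen), so the clauses neither gap nor
overlap. The two-organ-dysfunction branch fires without any SIRS
requirement, as the rule lays it out. MAP is not an alert input. A
parameter missing from the snapshot can never satisfy a criterion.

## Engine and deactivation

Evaluation is data-driven: the rule is re-checked at every event arrival
(observation, therapy boundary, code-status change), never on a polling
clock, which makes replay deterministic and chunking-invariant. Events
sharing a timestamp are applied first and evaluated once.

After an alert, suppression windows anchor at the **alert** time:
48 h when the responding clinician suspects severe sepsis, 24 h when they
rule it out, indefinite when code status precludes ICU management, and
24 h by default while no disposition has arrived (a conservative reuse of
the rule-out window; the source workflow does not specify this case). The
latest disposition answering an alert overwrites the window. Additionally,
a code-status event with `precludes_sepsis_icu_care=True` in the timeline
itself gates all alerts from that moment until cleared — a design reading
of the indefinite-deactivation rule as patient state rather than only as a
nurse response. Lead time is measured from the **first** alert to ICU
referral and may be negative if referral came first.

## Accuracy statistics

Patient-level positivity (≥ 1 alert during the stay) is cross-tabulated
against the clinician reference label. Proportion intervals default to the
**Wilson score interval with continuity correction** (Newcombe 1998): this
is the method that reproduces, to the printed precision, all four interval
pairs published for the alert-accuracy study this engine re-implements
(e.g. 88.78–96.00 % for a 205/220 sensitivity). Exact Clopper–Pearson
intervals (beta quantiles) are provided alongside; they give 89.00–96.13 %
for the same counts, so the two methods are distinguishable at the second
decimal. Likelihood-ratio intervals use the log-normal approximation
(Simel et al. 1991) with
`se²(ln LR+) = 1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)` and the analogous
expression for LR−. Zero cells yield explicit undefined markers — never a
silent continuity correction, never 0 or 1. Quartiles use linear
interpolation between order statistics (the common statistical-package
default); published quartiles that depend on an unknown convention can
therefore only be matched approximately.

## Synthetic cohort

The generator emulates the study conditions the evaluation assumes: ~0.44 %
prevalence (220/49,838), triage to a critical area (hourly vitals, 85 % of
septic patients, 25 % of others) or elsewhere (2-hourly), labs ordered on
arrival and resulted after 1 h, log-normal ED stays (median 8 h septic,
4 h non-septic, clipped to plausible ranges), and stratum-specific clipped
normal / log-normal parameter distributions. Septic per-draw abnormality
rates loosely match the clinical frequencies reported for ICU-referred
septic patients (~86 % tachycardia, ~89 % tachypnea, ~70 % SBP < 90,
~40 % SpO₂ < 90, ~45 % leukocytosis, ~26 % lactate > 2) — generator
targets, not asserted test outcomes, since those frequencies describe only
the ICU-referred subset. Therapy orders are independent Bernoulli draws per
stratum (septic: fluids 0.75, oxygen 0.45) starting 15–90 min after
arrival and running to departure.

ICU referral follows the septic patient's deterioration: the referral delay
(log-normal, median 4 h, σ = 1.1, clipped to 0.5–30 h) is anchored at the
patient's first alert when one fires, else at arrival. Anchoring at the
deterioration that the alert detects is what makes the configured 4 h
median delay appear as a ~4 h median lead time; it also means the generator
cannot produce negative lead times, which real workflows occasionally do.

What the generator deliberately does **not** model: autocorrelated or
treatment-responsive physiology (every draw is independent), correlation
between therapy orders and the vitals that would prompt them, repeat lab
panels, inter-hospital clock skew, and pediatric patients. Passing tests
therefore show that the engine and statistics behave correctly under the
assumed data-generating structure — not that the alert would achieve these
operating characteristics on any particular real ED.

## Calibration

`calibrate_cohort_params` tunes one number per stratum — a global severity
shift that displaces every parameter distribution toward (or away from)
abnormality along fixed per-parameter directions — until the engine-run
patient-level alert probability matches the published stratum proportions:
205/220 (septic) and 772/49,618 (non-septic). A 1-D shift is deliberately
simple and reproducible rather than optimal. The search is a deterministic
two-stage bisection with common random numbers, followed by one Newton
correction step on large fresh samples (rate at the found shift, slope from
two flanking points) that removes the residual bias of calibrating on the
search sample. Refinement sample sizes (200k non-septic) keep calibration
error below the binomial SE that a 50,000-patient evaluation cohort can
resolve. Every Monte-Carlo batch is screened by the same engine core that
`run_screening` uses; a test asserts the batch path and the timeline path
agree patient by patient.

## Problem sizes and numerical choices

The end-to-end recovery check uses 50,000-patient cohorts over three seeds
(the package's chosen evaluation size: large enough that the ±3-binomial-SE
bands on sensitivity and false-positive rate are meaningful, small enough
to iterate on). Simultaneous same-kind observations keep the last record
in input order (logged). Exact duplicate event records are dropped.
Undefined statistics propagate as markers; an empty confusion matrix is an
error. Seeds fully determine generator and calibration output;
per-component seeds derive from one integer via `numpy` seed sequences.
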