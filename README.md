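# sepsalert

An electronic severe-sepsis / septic-shock screening alert for emergency
departments, re-implemented as a reusable, testable engine.

Early recognition of severe sepsis in a crowded ED is hard: the presentation
is heterogeneous, prevalence among all comers is low (~0.4 %), and delays in
recognition translate directly into delayed resuscitation. One pragmatic
answer is a rule-based alert that continuously scans the most recent charted
vitals, labs and therapy orders and pages the care team when a sepsis
pattern appears. `sepsalert` packages that idea end to end for researchers
and CDS engineers who want to study such alerts — their logic, their
suppression behaviour, and their diagnostic accuracy — without access to
clinical data.

## The screening rule

A patient screens positive at time *t* when the most recent non-stale
values satisfy

**(≥ 2 SIRS criteria AND ≥ 1 organ dysfunction) OR ≥ 2 organ dysfunctions**

SIRS criteria: temperature > 38 °C or < 36 °C · pulse > 90 /min ·
respiratory rate > 20 /min · WBC > 12 or < 4 (10³/µL).

Organ dysfunction: SBP < 86 mm Hg (or 86–89 with an IV-fluid bolus
ordered) · SpO₂ < 85 % (or 85–89 % on supplemental oxygen) ·
lactate > 2 mmol/L.

All comparisons are strict; all criteria must be aligned at the same
snapshot. After an alert, the patient is deactivated for 48 h (suspected
sepsis), 24 h (not sepsis), or indefinitely (code status precludes ICU
care), anchored at the alert time.

The accuracy suite computes sensitivity, specificity, PPV, NPV (Wilson
score intervals with continuity correction; exact Clopper–Pearson also
available), LR± = sens/(1−spec), (1−sens)/spec with log-method intervals,
and the alert-to-ICU-referral lead-time median and quartiles.

The synthetic-cohort module simulates a low-prevalence ED (charting cadence
1 h / 2 h by triage area, ~1 h lab turnaround) and can calibrate stratum
severity so the engine's patient-level alert rates reproduce published
stratum proportions.

## Worked example

Feeding the patient-level 2×2 counts of a 49,838-patient ED cohort
(tp = 205, fp = 772, fn = 15, tn = 48,846) to the accuracy suite
(`examples/02_diagnostic_accuracy.py`):

```
n = 49838, prevalence = 0.44% (severe sepsis / septic shock is rare among all ED arrivals)
sensitivity   93.18%  95% CI (88.78%, 96.00%)
specificity   98.44%  95% CI (98.33%, 98.55%)
PPV           20.98%  95% CI (18.50%, 23.70%)
NPV           99.97%  95% CI (99.95%, 99.98%)
LR+            59.89  95% CI (55.36, 64.79)
LR-            0.069  95% CI (0.042, 0.113)
```

The alert misses few septic patients (sensitivity 93 %) and a silent screen
all but excludes severe sepsis (NPV 99.97 %); the low PPV is the price of
screening every ED arrival at 0.44 % prevalence.

`examples/` contains one short script per capability: screening a single
hand-built stay, the accuracy suite, cohort simulation, and the calibrated
full pipeline. A thin CLI wraps the same library functions:

```sh
sepsalert simulate --n 5000 --seed 7 --out events.csv --labels labels.csv --dispositions disp.csv
sepsalert screen --events events.csv --dispositions disp.csv --out alerts.jsonl
sepsalert evaluate --alerts alerts.jsonl --labels labels.csv --out report.json
sepsalert report report.json
```

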