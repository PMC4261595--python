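"""Screen a single hand-built ED stay and inspect the fired alert.

A patient arrives tachycardic and tachypneic with a soft blood pressure.
The first vitals round already satisfies two SIRS criteria plus one organ
dysfunction, so the engine fires immediately; a second qualifying round two
hours later stays silent because the alert is deactivated for 24 h.
"""

from sepsalert import (
    Observation,
    ParameterKind,
    PatientTimeline,
    alert_lead_time,
    format_time,
    run_screening,
)

ARRIVAL = 1_735_689_600.0  # 2025-01-01T00:00:00+00:00, seconds since epoch

vitals_rounds = {
    0.0: {"pulse": 118, "respiratory_rate": 26, "sbp": 84, "spo2": 95,
          "temperature": 37.4},
    2.0: {"pulse": 121, "respiratory_rate": 28, "sbp": 82, "spo2": 94,
          "temperature": 38.3},
}
observations = sorted(
    (Observation("ed-0042", ARRIVAL + h * 3600, ParameterKind(k), v)
     for h, vals in vitals_rounds.items() for k, v in vals.items()),
    key=lambda o: (o.time, o.kind.value))

patient = PatientTimeline(
    patient_id="ed-0042", triage_area="critical",
    ed_arrival=ARRIVAL, ed_departure=ARRIVAL + 10 * 3600,
    observations=observations,
    icu_referral_time=ARRIVAL + 4.5 * 3600,
)
patient.validate()

alerts = run_screening(patient)
for alert in alerts:
    print(f"ALERT at {format_time(alert.time)}  "
          f"SIRS met: {alert.sirs_met}  organ dysfunction: {alert.od_met}  "
          f"branch: {alert.rationale}")
print(f"alerts fired: {len(alerts)} (second round suppressed for 24 h)")
lead = alert_lead_time(alerts, patient.icu_referral_time)
print(f"lead time to ICU referral: {lead:.2f} h "
      "(how far the alert preceded the ICU referral)")
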