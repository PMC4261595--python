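"""Alert firing, deactivation windows, and replay determinism."""

from __future__ import annotations

import random

import pytest

from sepsalert.criteria import evaluate_snapshot
from sepsalert.engine import (
    CODE_STATUS_PRECLUDES,
    DEFAULT_ENGINE_CONFIG,
    NOT_SEPSIS,
    SUSPECTED_SEPSIS,
    DispositionEvent,
    EngineConfig,
    ScreeningSession,
    SuppressionWindows,
    alert_lead_time,
    patient_alert_status,
    run_screening,
    timeline_events,
)
from sepsalert.events import HOUR, ValidationError, snapshot_at

from conftest import SEPTIC_VITALS, hours, make_timeline


def septic_burst(at_h):
    """A full vitals round at `at_h` that satisfies 2 SIRS + 1 OD."""
    return [(at_h, kind, value) for _, kind, value in SEPTIC_VITALS]


def disp(h, category, pid="p1"):
    return DispositionEvent(pid, hours(h), category)


class TestSuppression:
    def test_second_qualifying_event_suppressed_by_default(self):
        tl = make_timeline(obs=septic_burst(0) + septic_burst(2))
        alerts = run_screening(tl)
        assert len(alerts) == 1 and alerts[0].time == hours(0)

    def test_default_window_expires_after_24h(self):
        tl = make_timeline(obs=septic_burst(0) + septic_burst(25), departure_h=30)
        assert len(run_screening(tl)) == 2

    def test_suspected_sepsis_holds_48h(self):
        tl = make_timeline(obs=septic_burst(0) + septic_burst(25) + septic_burst(49),
                           departure_h=60)
        alerts = run_screening(tl, [disp(1 / 6, SUSPECTED_SEPSIS)])
        assert [a.time for a in alerts] == [hours(0), hours(49)]

    def test_not_sepsis_holds_24h(self):
        tl = make_timeline(obs=septic_burst(0) + septic_burst(12) + septic_burst(25),
                           departure_h=30)
        alerts = run_screening(tl, [disp(0.5, NOT_SEPSIS)])
        assert [a.time for a in alerts] == [hours(0), hours(25)]

    def test_code_status_disposition_suppresses_forever(self):
        tl = make_timeline(obs=septic_burst(0) + septic_burst(30) + septic_burst(60)
                           + septic_burst(100), departure_h=120)
        alerts = run_screening(tl, [disp(0.5, CODE_STATUS_PRECLUDES)])
        assert len(alerts) == 1

    def test_latest_disposition_overwrites_window(self):
        # not_sepsis (24 h) then suspected (48 h): second burst at 30 h stays quiet
        tl = make_timeline(obs=septic_burst(0) + septic_burst(30), departure_h=60)
        alerts = run_screening(tl, [disp(0.5, NOT_SEPSIS), disp(1.0, SUSPECTED_SEPSIS)])
        assert len(alerts) == 1

    def test_disposition_before_any_alert_rejected(self):
        tl = make_timeline(obs=septic_burst(10), departure_h=20)
        with pytest.raises(ValidationError, match="precedes any alert"):
            run_screening(tl, [disp(1, NOT_SEPSIS)])

    def test_code_status_event_gates_alerts(self):
        tl = make_timeline(obs=septic_burst(2), code=[(1, True)], departure_h=20)
        assert run_screening(tl) == []
        cleared = make_timeline(obs=septic_burst(2), code=[(1, True), (1.5, False)],
                                departure_h=20)
        assert len(run_screening(cleared)) == 1


class TestAlertContents:
    def test_alert_records_met_criteria(self):
        tl = make_timeline(obs=septic_burst(0))
        (alert,) = run_screening(tl)
        assert alert.sirs_met == ("pulse", "respiratory_rate")
        assert alert.od_met == ("hypotension",)
        assert alert.rationale == "sirs_plus_od"

    def test_double_od_branch(self):
        tl = make_timeline(obs=[(0, "sbp", 80), (0, "spo2", 80)])
        (alert,) = run_screening(tl)
        assert alert.rationale == "double_od" and alert.sirs_met == ()

    def test_band_criteria_need_active_therapy(self):
        obs = [(0, "pulse", 100), (0, "respiratory_rate", 25), (0, "sbp", 88)]
        assert run_screening(make_timeline(obs=obs)) == []
        with_fluids = make_timeline(obs=obs, therapies=[("iv_fluid_bolus", 0, None)])
        assert len(run_screening(with_fluids)) == 1


class TestStatusAndLeadTime:
    def test_patient_alert_status(self):
        assert not patient_alert_status([])
        tl = make_timeline(obs=septic_burst(0))
        assert patient_alert_status(run_screening(tl))

    @pytest.mark.parametrize("alert_h,referral_h", [
        (8.0, 12.02),   # alert 08:00, referral 12:01:12 -> 4.02 h
        (8.0, 8.0),     # simultaneous -> 0
        (10.0, 9.0),    # referral preceded the alert -> -1, reported as-is
    ])
    def test_signed_lead_time(self, alert_h, referral_h):
        tl = make_timeline(obs=septic_burst(alert_h), departure_h=24,
                           referral_h=referral_h)
        alerts = run_screening(tl)
        assert alert_lead_time(alerts, tl.icu_referral_time) == pytest.approx(
            referral_h - alert_h, abs=1e-9)

    def test_lead_time_requires_alert_and_referral(self):
        tl = make_timeline(obs=septic_burst(1), referral_h=5)
        alerts = run_screening(tl)
        with pytest.raises(ValidationError):
            alert_lead_time([], tl.icu_referral_time)
        with pytest.raises(ValidationError):
            alert_lead_time(alerts, None)

    def test_lead_time_uses_first_alert(self):
        tl = make_timeline(obs=septic_burst(0) + septic_burst(25), departure_h=30,
                           referral_h=26)
        alerts = run_screening(tl)
        assert len(alerts) == 2
        assert alert_lead_time(alerts, tl.icu_referral_time) == pytest.approx(26.0)


# ---------------------------------------------------------------------------
# randomized properties

KIND_POOLS = {
    "temperature": [35.0, 36.5, 37.0, 38.5, 39.5],
    "pulse": [70, 85, 95, 120],
    "respiratory_rate": [14, 18, 22, 30],
    "wbc": [3.0, 7.0, 13.0],
    "sbp": [80, 87, 95, 120],
    "spo2": [82, 87, 93, 98],
    "lactate": [0.8, 1.5, 2.5, 4.0],
}


def random_timeline(rng: random.Random, pid="p1", max_h=72.0):
    obs = []
    for _ in range(rng.randint(0, 40)):
        kind = rng.choice(list(KIND_POOLS))
        obs.append((round(rng.uniform(0, max_h), 3), kind,
                    rng.choice(KIND_POOLS[kind])))
    therapies = []
    for kind in ("iv_fluid_bolus", "supplemental_oxygen"):
        if rng.random() < 0.5:
            s = round(rng.uniform(0, max_h - 1), 3)
            e = None if rng.random() < 0.4 else round(rng.uniform(s + 0.01, max_h), 3)
            therapies.append((kind, s, e))
    return make_timeline(obs=obs, therapies=therapies, departure_h=max_h, pid=pid)


def brute_force_alert_times(tl):
    """Per-event-time oracle: evaluate the snapshot at every event arrival."""
    times = {o.time for o in tl.observations}
    for th in tl.therapies:
        times.add(th.start)
        if th.end is not None:
            times.add(th.end)
    return [t for t in sorted(times)
            if evaluate_snapshot(snapshot_at(tl, t)).fire]


def test_engine_matches_per_event_oracle_with_suppression_off():
    """With zero-length windows the engine fires at exactly the event times
    whose snapshot satisfies the decision rule."""
    config = EngineConfig(suppression=SuppressionWindows(0.0, 0.0, 0.0))
    rng = random.Random(20240101)
    checked_fires = 0
    for _ in range(150):
        tl = random_timeline(rng)
        engine_times = [a.time for a in run_screening(tl, (), config)]
        assert engine_times == brute_force_alert_times(tl)
        checked_fires += len(engine_times)
    assert checked_fires > 50  # the scenario pool does exercise the rule


def test_streaming_equals_batch_replay():
    """Chunked feeding reproduces the whole-stream alert list exactly."""
    rng = random.Random(99)
    for _ in range(100):
        tl = random_timeline(rng)
        whole = run_screening(tl)
        events = timeline_events(tl)
        session = ScreeningSession(tl.patient_id)
        i = 0
        while i < len(events):
            j = min(len(events), i + rng.randint(1, 7))
            session.feed(events[i:j])
            i = j
        assert session.finish() == whole


def test_no_two_alerts_within_suppression_window():
    rng = random.Random(4242)
    pairs_checked = 0
    for _ in range(200):
        tl = random_timeline(rng)
        alerts = run_screening(tl)  # no dispositions: default 24 h window
        for a, b in zip(alerts, alerts[1:]):
            assert b.time - a.time >= DEFAULT_ENGINE_CONFIG.suppression.pending_default
            pairs_checked += 1
    assert pairs_checked > 5


def test_truncation_after_first_alert_is_irrelevant():
    rng = random.Random(7)
    checked = 0
    for _ in range(100):
        tl = random_timeline(rng)
        alerts = run_screening(tl)
        if not alerts:
            continue
        first = alerts[0]
        truncated = make_timeline(
            obs=[((o.time - tl.ed_arrival) / HOUR, o.kind.value, o.value)
                 for o in tl.observations if o.time <= first.time],
            therapies=[(th.kind.value, (th.start - tl.ed_arrival) / HOUR,
                        None if th.end is None else (th.end - tl.ed_arrival) / HOUR)
                       for th in tl.therapies if th.start <= first.time],
            departure_h=72.0, pid=tl.patient_id)
        re_alerts = run_screening(truncated)
        assert re_alerts and re_alerts[0] == first
        checked += 1
    assert checked > 20
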