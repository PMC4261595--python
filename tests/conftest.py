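"""Shared fixtures: a compact timeline builder and hypothesis settings."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from sepsalert.events import (
    HOUR,
    CodeStatusEvent,
    Observation,
    ParameterKind,
    PatientTimeline,
    TherapyInterval,
    TherapyKind,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASE = 1_700_000_000.0  # arbitrary epoch anchor for hand-built timelines


def hours(h: float) -> float:
    return BASE + h * HOUR


def make_timeline(obs=(), therapies=(), code=(), arrival_h=0.0, departure_h=48.0,
                  referral_h=None, label=False, area="other", pid="p1",
                  validate=True) -> PatientTimeline:
    """Build a timeline from (hour, kind, value) tuples relative to BASE.

    ``therapies``: (kind, start_h, end_h-or-None); ``code``: (hour, precludes).
    """
    observations = sorted(
        (Observation(pid, hours(h), ParameterKind(k), float(v)) for h, k, v in obs),
        key=lambda o: (o.time, o.kind.value))
    tl = PatientTimeline(
        patient_id=pid,
        triage_area=area,
        ed_arrival=hours(arrival_h),
        ed_departure=hours(departure_h),
        observations=observations,
        therapies=[TherapyInterval(pid, TherapyKind(k), hours(s),
                                   None if e is None else hours(e))
                   for k, s, e in therapies],
        code_status=[CodeStatusEvent(pid, hours(h), bool(p)) for h, p in code],
        icu_referral_time=None if referral_h is None else hours(referral_h),
        reference_label=label,
    )
    if validate:
        tl.validate()
    return tl


@pytest.fixture
def timeline_factory():
    return make_timeline


#: A snapshot-worth of clearly septic vitals: 2 SIRS (pulse, RR) + hypotension.
SEPTIC_VITALS = [
    (0.0, "temperature", 37.2),
    (0.0, "pulse", 120),
    (0.0, "respiratory_rate", 28),
    (0.0, "sbp", 80),
    (0.0, "spo2", 96),
]

#: Unremarkable vitals that satisfy no criterion.
NORMAL_VITALS = [
    (0.0, "temperature", 37.0),
    (0.0, "pulse", 80),
    (0.0, "respiratory_rate", 16),
    (0.0, "sbp", 120),
    (0.0, "spo2", 98),
]
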