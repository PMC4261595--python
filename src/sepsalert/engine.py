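"""Stateful replay of patient timelines: fire alerts, enforce suppression.

The engine re-evaluates the screening rule at every event arrival
(observation, therapy boundary, code-status change) — evaluation is
data-driven, not clock-driven, which makes replay deterministic.  After an
alert fires, further alerts are suppressed ("deactivated"):

* 48 h when the responding clinician suspects severe sepsis / septic shock,
* 24 h when they rule it out,
* indefinitely when the code status precludes ICU management of sepsis,
* 24 h by default while no disposition has been recorded.

Suppression windows are anchored at the alert time, not the disposition
time; the latest disposition answering an alert overwrites the window.  A
code-status event with ``precludes_sepsis_icu_care=True`` additionally gates
all further alerts from its own time onward until a later event clears it.

Multiple events sharing one timestamp are applied first and evaluated once.
Within a timestamp, dispositions are applied after the evaluation, so a
disposition may legally coincide with the alert it answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .criteria import DOUBLE_OD, SIRS_PLUS_OD, DEFAULT_THRESHOLDS, Thresholds
from .events import (
    DEFAULT_STALENESS,
    HOUR,
    KIND_INDEX,
    ParameterKind,
    PatientTimeline,
    TherapyKind,
    ValidationError,
    format_time,
)

SUSPECTED_SEPSIS = "suspected_sepsis"
NOT_SEPSIS = "not_sepsis"
CODE_STATUS_PRECLUDES = "code_status_precludes"
DISPOSITION_CATEGORIES = (SUSPECTED_SEPSIS, NOT_SEPSIS, CODE_STATUS_PRECLUDES)

_IDX_TEMP = KIND_INDEX[ParameterKind.TEMPERATURE]
_IDX_PULSE = KIND_INDEX[ParameterKind.PULSE]
_IDX_RR = KIND_INDEX[ParameterKind.RESPIRATORY_RATE]
_IDX_WBC = KIND_INDEX[ParameterKind.WBC]
_IDX_SBP = KIND_INDEX[ParameterKind.SBP]
_IDX_SPO2 = KIND_INDEX[ParameterKind.SPO2]
_IDX_LACTATE = KIND_INDEX[ParameterKind.LACTATE]

# event tags for the low-level stream
OBS = 0
THERAPY = 1
CODE = 2
DISPOSITION = 3

_SIRS_NAMES = ("temperature", "pulse", "respiratory_rate", "wbc")
_OD_NAMES = ("hypotension", "hypoxemia", "lactic_acidosis")


@dataclass(frozen=True)
class SuppressionWindows:
    """Deactivation durations in seconds, anchored at the alert time."""

    suspected_sepsis: float = 48 * HOUR
    not_sepsis: float = 24 * HOUR
    pending_default: float = 24 * HOUR  # no disposition recorded yet


@dataclass(frozen=True)
class EngineConfig:
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    staleness: dict[ParameterKind, float] = field(
        default_factory=lambda: dict(DEFAULT_STALENESS))
    suppression: SuppressionWindows = SuppressionWindows()
    alpha: float = 0.05
    quartile_method: str = "linear"

    def staleness_vector(self) -> tuple[float, ...]:
        return tuple(self.staleness[k] for k in ParameterKind)


DEFAULT_ENGINE_CONFIG = EngineConfig()


@dataclass(slots=True)
class AlertEvent:
    patient_id: str
    time: float
    sirs_met: tuple[str, ...]
    od_met: tuple[str, ...]
    rationale: str


@dataclass(slots=True)
class DispositionEvent:
    patient_id: str
    time: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in DISPOSITION_CATEGORIES:
            raise ValidationError(f"unknown disposition category {self.category!r}")


@dataclass(slots=True)
class SuppressionState:
    suppressed_until: float  # math.inf for indefinite
    reason: Optional[str]    # suspected_sepsis_48h | not_sepsis_24h |
                             # code_status_indefinite | pending_disposition_default


class ScreeningSession:
    """Incremental screening over one patient's event stream.

    Feed events in non-decreasing time order (any chunking); call
    :meth:`finish` to flush the final timestamp group and obtain the alerts.
    Low-level events are tuples ``(time, tag, a, b)``:

    ==========  =======================  ==============================
    tag         a                        b
    ==========  =======================  ==============================
    OBS         kind index (0..6)        value
    THERAPY     therapy kind index       +1 start / -1 end
    CODE        1 precludes / 0 clears   --
    DISPOSITION category string          --
    ==========  =======================  ==============================
    """

    def __init__(self, patient_id: str, config: EngineConfig = DEFAULT_ENGINE_CONFIG):
        self.patient_id = patient_id
        self.config = config
        t = config.thresholds
        self._thr = (t.temp_high, t.temp_low, t.pulse_high, t.rr_high,
                     t.wbc_high, t.wbc_low, t.sbp_low, t.sbp_band_high,
                     t.spo2_low, t.spo2_band_high, t.lactate_high)
        self._stal = config.staleness_vector()
        self._vals = [math.nan] * 7
        self._times = [-math.inf] * 7
        self._therapy_depth = [0, 0]  # fluids, oxygen
        self._code_precludes = False
        self._suppressed_until = -math.inf
        self._suppress_reason: Optional[str] = None
        self._last_alert_time: Optional[float] = None
        self._pending_time: Optional[float] = None
        self._pending_eval = False
        self._pending_disp: list[str] = []
        self.alerts: list[AlertEvent] = []

    # -- state inspection ---------------------------------------------------

    @property
    def suppression_state(self) -> SuppressionState:
        return SuppressionState(self._suppressed_until, self._suppress_reason)

    # -- event feeding ------------------------------------------------------

    def feed(self, events: Iterable[tuple]) -> None:
        for ev in events:
            t = ev[0]
            pending = self._pending_time
            if pending is not None and t < pending:
                raise ValidationError("events fed out of time order")
            if pending is None or t > pending:
                self._flush()
                self._pending_time = t
            tag = ev[1]
            if tag == OBS:
                self._vals[ev[2]] = ev[3]
                self._times[ev[2]] = t
                self._pending_eval = True
            elif tag == THERAPY:
                self._therapy_depth[ev[2]] += ev[3]
                self._pending_eval = True
            elif tag == CODE:
                self._code_precludes = bool(ev[2])
                self._pending_eval = True
            elif tag == DISPOSITION:
                self._pending_disp.append(ev[2])
            else:
                raise ValidationError(f"unknown event tag {tag!r}")

    def finish(self) -> list[AlertEvent]:
        self._flush()
        self._pending_time = None
        return self.alerts

    # -- internals ----------------------------------------------------------

    def _flush(self) -> None:
        t = self._pending_time
        if t is None:
            return
        if self._pending_eval:
            self._evaluate(t)
            self._pending_eval = False
        if self._pending_disp:
            for category in self._pending_disp:
                self._apply_disposition(t, category)
            self._pending_disp.clear()

    def _apply_disposition(self, t: float, category: str) -> None:
        anchor = self._last_alert_time
        if anchor is None:
            raise ValidationError(
                f"patient {self.patient_id}: disposition at {format_time(t)} "
                "precedes any alert")
        w = self.config.suppression
        if category == SUSPECTED_SEPSIS:
            self._suppressed_until = anchor + w.suspected_sepsis
            self._suppress_reason = "suspected_sepsis_48h"
        elif category == NOT_SEPSIS:
            self._suppressed_until = anchor + w.not_sepsis
            self._suppress_reason = "not_sepsis_24h"
        elif category == CODE_STATUS_PRECLUDES:
            self._suppressed_until = math.inf
            self._suppress_reason = "code_status_indefinite"
        else:
            raise ValidationError(f"unknown disposition category {category!r}")

    def _evaluate(self, t: float) -> None:
        if self._code_precludes or t < self._suppressed_until:
            return
        vals, times, stal = self._vals, self._times, self._stal
        (temp_hi, temp_lo, pulse_hi, rr_hi, wbc_hi, wbc_lo,
         sbp_lo, sbp_band, spo2_lo, spo2_band, lac_hi) = self._thr

        v = vals[_IDX_TEMP]
        b_temp = (t - times[_IDX_TEMP] < stal[_IDX_TEMP]) and (v > temp_hi or v < temp_lo)
        v = vals[_IDX_PULSE]
        b_pulse = (t - times[_IDX_PULSE] < stal[_IDX_PULSE]) and v > pulse_hi
        v = vals[_IDX_RR]
        b_rr = (t - times[_IDX_RR] < stal[_IDX_RR]) and v > rr_hi
        v = vals[_IDX_WBC]
        b_wbc = (t - times[_IDX_WBC] < stal[_IDX_WBC]) and (v > wbc_hi or v < wbc_lo)
        sirs = b_temp + b_pulse + b_rr + b_wbc

        v = vals[_IDX_SBP]
        b_sbp = (t - times[_IDX_SBP] < stal[_IDX_SBP]) and (
            v < sbp_lo or (v < sbp_band and self._therapy_depth[0] > 0))
        v = vals[_IDX_SPO2]
        b_spo2 = (t - times[_IDX_SPO2] < stal[_IDX_SPO2]) and (
            v < spo2_lo or (v < spo2_band and self._therapy_depth[1] > 0))
        v = vals[_IDX_LACTATE]
        b_lac = (t - times[_IDX_LACTATE] < stal[_IDX_LACTATE]) and v > lac_hi
        od = b_sbp + b_spo2 + b_lac

        if sirs >= 2 and od >= 1:
            rationale = SIRS_PLUS_OD
        elif od >= 2:
            rationale = DOUBLE_OD
        else:
            return
        self.alerts.append(AlertEvent(
            patient_id=self.patient_id,
            time=t,
            sirs_met=tuple(n for n, b in zip(_SIRS_NAMES, (b_temp, b_pulse, b_rr, b_wbc)) if b),
            od_met=tuple(n for n, b in zip(_OD_NAMES, (b_sbp, b_spo2, b_lac)) if b),
            rationale=rationale,
        ))
        self._last_alert_time = t
        self._suppressed_until = t + self.config.suppression.pending_default
        self._suppress_reason = "pending_disposition_default"


_THERAPY_IDX = {TherapyKind.IV_FLUID_BOLUS: 0, TherapyKind.SUPPLEMENTAL_OXYGEN: 1}


def timeline_events(timeline: PatientTimeline,
                    dispositions: Sequence[DispositionEvent] = (),
                    ) -> list[tuple]:
    """Lower a timeline (+ dispositions) to the sorted low-level event stream."""
    ev: list[tuple] = []
    for obs in timeline.observations:
        ev.append((obs.time, OBS, KIND_INDEX[obs.kind], obs.value))
    for th in timeline.therapies:
        idx = _THERAPY_IDX[th.kind]
        ev.append((th.start, THERAPY, idx, 1))
        if th.end is not None:
            ev.append((th.end, THERAPY, idx, -1))
    for cs in timeline.code_status:
        ev.append((cs.time, CODE, int(cs.precludes_sepsis_icu_care), 0))
    for d in dispositions:
        if d.patient_id != timeline.patient_id:
            raise ValidationError("disposition for a different patient")
        ev.append((d.time, DISPOSITION, d.category, 0))
    ev.sort(key=lambda e: (e[0], e[1] == DISPOSITION))
    return ev


def run_screening(timeline: PatientTimeline,
                  dispositions: Sequence[DispositionEvent] = (),
                  config: EngineConfig = DEFAULT_ENGINE_CONFIG,
                  ) -> list[AlertEvent]:
    """Replay one patient's ED stay and return the fired alerts.

    Deterministic: identical timeline + dispositions yield the identical
    alert list regardless of how the stream would have been chunked.
    """
    session = ScreeningSession(timeline.patient_id, config)
    session.feed(timeline_events(timeline, dispositions))
    return session.finish()


def patient_alert_status(alerts: Sequence[AlertEvent]) -> bool:
    """Patient-level test positivity: did at least one alert fire?"""
    return len(alerts) > 0


def alert_lead_time(alerts: Sequence[AlertEvent],
                    icu_referral_time: Optional[float]) -> float:
    """Hours from the first alert to ICU referral (negative if referral first)."""
    if not alerts:
        raise ValidationError("no alerts: lead time undefined")
    if icu_referral_time is None:
        raise ValidationError("no ICU referral time: lead time undefined")
    return (icu_referral_time - alerts[0].time) / HOUR
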