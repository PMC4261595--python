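"""Patient timelines and "most recent values" snapshot semantics.

The screening rule is evaluated against a :class:`Snapshot`: the most recent
non-stale value of each physiologic/lab parameter at a point in time, plus
flags for whether an IV-fluid bolus or supplemental-oxygen order is active.
All criteria must therefore be aligned at the same instant, which is the
defining (and limiting) property of this class of alert.

Timestamps are floats — seconds since the Unix epoch, UTC.  ISO-8601 strings
with an explicit offset are converted at the I/O boundary (:func:`parse_time`,
:func:`format_time`); all internal arithmetic is plain seconds.  Time
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Iterable, Mapping, Optional

logger = logging.getLogger(__name__)

HOUR = 3600.0


class ParameterKind(str, Enum):
    """The seven screened parameters, each with a fixed unit."""

    TEMPERATURE = "temperature"        # °C
    PULSE = "pulse"                    # beats/min
    RESPIRATORY_RATE = "respiratory_rate"  # breaths/min
    WBC = "wbc"                        # 10^3 cells/µL
    SBP = "sbp"                        # mm Hg
    SPO2 = "spo2"                      # % saturation
    LACTATE = "lactate"                # mmol/L


VITAL_KINDS = (
    ParameterKind.TEMPERATURE,
    ParameterKind.PULSE,
    ParameterKind.RESPIRATORY_RATE,
    ParameterKind.SBP,
    ParameterKind.SPO2,
)
LAB_KINDS = (ParameterKind.WBC, ParameterKind.LACTATE)

#: Index of each kind in the engine's internal arrays (stable order).
KIND_INDEX: dict[ParameterKind, int] = {k: i for i, k in enumerate(ParameterKind)}
KIND_BY_INDEX: tuple[ParameterKind, ...] = tuple(ParameterKind)

#: Physiologic plausibility bounds per kind (inclusive).  Values outside are
#: rejected at timeline construction — they are charting errors, not data.
DEFAULT_PLAUSIBLE_RANGES: dict[ParameterKind, tuple[float, float]] = {
    ParameterKind.TEMPERATURE: (25.0, 45.0),
    ParameterKind.PULSE: (0.0, 300.0),
    ParameterKind.RESPIRATORY_RATE: (0.0, 80.0),
    ParameterKind.WBC: (0.0, 200.0),
    ParameterKind.SBP: (0.0, 300.0),
    ParameterKind.SPO2: (0.0, 100.0),
    ParameterKind.LACTATE: (0.0, 50.0),
}

#: How long a "most recent" value stays usable.  Vitals: 4 h (twice the
#: slowest charting cadence); labs: 24 h.  Configurable everywhere.
DEFAULT_STALENESS: dict[ParameterKind, float] = {
    **{k: 4 * HOUR for k in VITAL_KINDS},
    **{k: 24 * HOUR for k in LAB_KINDS},
}


class TherapyKind(str, Enum):
    IV_FLUID_BOLUS = "iv_fluid_bolus"
    SUPPLEMENTAL_OXYGEN = "supplemental_oxygen"


class ValidationError(ValueError):
    """An event stream violates a timeline invariant."""


def parse_time(text: str) -> float:
    """Parse an ISO-8601 timestamp with explicit offset into epoch seconds."""
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        raise ValidationError(f"timestamp {text!r} lacks a UTC offset")
    return dt.timestamp()


def format_time(ts: float) -> str:
    """Render epoch seconds as an ISO-8601 UTC timestamp."""
    return datetime.fromtimestamp(ts, tz=timezone.utc).isoformat()


@dataclass(slots=True)
class Observation:
    """One time-stamped measurement of one parameter for one patient."""

    patient_id: str
    time: float
    kind: ParameterKind
    value: float


@dataclass(slots=True)
class TherapyInterval:
    """A therapy order active over the half-open interval [start, end).

    ``end is None`` means the order was never discontinued; it is treated as
    active until ED departure.
    """

    patient_id: str
    kind: TherapyKind
    start: float
    end: Optional[float] = None


@dataclass(slots=True)
class CodeStatusEvent:
    patient_id: str
    time: float
    precludes_sepsis_icu_care: bool


@dataclass(slots=True)
class Snapshot:
    """Most-recent non-stale value per parameter at time ``at``."""

    at: float
    latest: dict[ParameterKind, tuple[float, float]]  # kind -> (value, obs time)
    fluids_active: bool = False
    oxygen_active: bool = False


@dataclass(slots=True)
class PatientTimeline:
    patient_id: str
    triage_area: str  # "critical" or "other"
    ed_arrival: float
    ed_departure: float
    observations: list[Observation] = field(default_factory=list)
    therapies: list[TherapyInterval] = field(default_factory=list)
    code_status: list[CodeStatusEvent] = field(default_factory=list)
    icu_referral_time: Optional[float] = None
    reference_label: bool = False

    def validate(self, ranges: Mapping[ParameterKind, tuple[float, float]] | None = None) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        ranges = DEFAULT_PLAUSIBLE_RANGES if ranges is None else ranges
        if self.triage_area not in ("critical", "other"):
            raise ValidationError(f"unknown triage area {self.triage_area!r}")
        if not self.ed_departure > self.ed_arrival:
            raise ValidationError("ED departure must follow arrival")
        prev: tuple[float, str] | None = None
        for obs in self.observations:
            _check_value(obs.kind, obs.value, ranges)
            if not self.ed_arrival <= obs.time <= self.ed_departure:
                raise ValidationError(
                    f"observation at {format_time(obs.time)} outside ED stay "
                    f"for patient {self.patient_id}"
                )
            key = (obs.time, obs.kind.value)
            if prev is not None and key < prev:
                raise ValidationError("observations not sorted by (time, kind)")
            prev = key
        for th in self.therapies:
            if not self.ed_arrival <= th.start <= self.ed_departure:
                raise ValidationError("therapy start outside ED stay")
            if th.end is not None and not th.end > th.start:
                raise ValidationError("therapy end must follow start")
            if th.end is not None and th.end > self.ed_departure:
                raise ValidationError("therapy end after ED departure")
        for cs in self.code_status:
            if not self.ed_arrival <= cs.time <= self.ed_departure:
                raise ValidationError("code-status event outside ED stay")
        if self.icu_referral_time is not None and self.icu_referral_time < self.ed_arrival:
            raise ValidationError("ICU referral before ED arrival")


def _check_value(kind: ParameterKind, value: float,
                 ranges: Mapping[ParameterKind, tuple[float, float]]) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"non-finite {kind.value} value {value!r}")
    lo, hi = ranges[kind]
    if not lo <= value <= hi:
        raise ValidationError(
            f"{kind.value} value {value} outside plausible range [{lo}, {hi}]"
        )


@dataclass(slots=True)
class EventRecord:
    """One parsed row of the event-stream dialect (see :mod:`sepsalert.io`).

    ``event_type`` is one of obs, therapy_start, therapy_end, code_status,
    arrival, departure, icu_referral, label.
    """

    patient_id: str
    time: float
    event_type: str
    kind: Optional[str] = None
    value: Optional[float] = None
    extra: Optional[str] = None


_EVENT_TYPES = frozenset({
    "obs", "therapy_start", "therapy_end", "code_status",
    "arrival", "departure", "icu_referral", "label",
})


def build_timeline(records: Iterable[EventRecord],
                   ranges: Mapping[ParameterKind, tuple[float, float]] | None = None,
                   ) -> PatientTimeline:
    """Assemble and validate one patient's timeline from parsed event records.

    Records may arrive in any order.  Exact duplicate records are dropped;
    simultaneous observations of the same kind are resolved by keeping the
    last one in input order (logged).  Therapy start/end rows of the same
    kind are paired sequentially in time; a start without an end yields an
    open interval.
    """
    records = list(records)
    if not records:
        raise ValidationError("no event records")
    pids = {r.patient_id for r in records}
    if len(pids) != 1:
        raise ValidationError(f"records span multiple patients: {sorted(pids)}")
    pid = records[0].patient_id

    arrival = departure = referral = None
    triage_area = "other"
    label = False
    obs: list[tuple[int, Observation]] = []
    starts: dict[TherapyKind, list[float]] = {k: [] for k in TherapyKind}
    ends: dict[TherapyKind, list[float]] = {k: [] for k in TherapyKind}
    code: list[CodeStatusEvent] = []

    seen: set[tuple] = set()
    for i, r in enumerate(records):
        if r.event_type not in _EVENT_TYPES:
            raise ValidationError(f"unknown event_type {r.event_type!r}")
        dedupe_key = (r.time, r.event_type, r.kind, r.value, r.extra)
        if dedupe_key in seen:
            continue
        seen.add(dedupe_key)
        if r.event_type == "arrival":
            arrival = r.time
            if r.extra in ("critical", "other"):
                triage_area = r.extra
        elif r.event_type == "departure":
            departure = r.time
        elif r.event_type == "icu_referral":
            referral = r.time
        elif r.event_type == "label":
            label = bool(r.value)
        elif r.event_type == "obs":
            try:
                kind = ParameterKind(r.kind)
            except ValueError:
                raise ValidationError(f"unknown parameter kind {r.kind!r}") from None
            obs.append((i, Observation(pid, r.time, kind, float(r.value))))
        elif r.event_type in ("therapy_start", "therapy_end"):
            try:
                tkind = TherapyKind(r.kind)
            except ValueError:
                raise ValidationError(f"unknown therapy kind {r.kind!r}") from None
            (starts if r.event_type == "therapy_start" else ends)[tkind].append(r.time)
        elif r.event_type == "code_status":
            code.append(CodeStatusEvent(pid, r.time, bool(r.value)))

    if arrival is None or departure is None:
        raise ValidationError(f"patient {pid}: missing arrival or departure event")

    # stable sort by (time, kind), then input order: last-in-input wins ties
    obs.sort(key=lambda t: (t[1].time, t[1].kind.value, t[0]))
    deduped: list[Observation] = []
    for _, o in obs:
        if deduped and deduped[-1].time == o.time and deduped[-1].kind == o.kind:
            logger.warning(
                "patient %s: simultaneous %s observations at %s; keeping last",
                pid, o.kind.value, format_time(o.time))
            deduped[-1] = o
        else:
            deduped.append(o)

    therapies: list[TherapyInterval] = []
    for tkind in TherapyKind:
        st, en = sorted(starts[tkind]), sorted(ends[tkind])
        if len(en) > len(st):
            raise ValidationError(f"therapy_end without matching start for {tkind.value}")
        for j, s in enumerate(st):
            e = en[j] if j < len(en) else None
            therapies.append(TherapyInterval(pid, tkind, s, e))
    therapies.sort(key=lambda t: t.start)
    code.sort(key=lambda c: c.time)

    tl = PatientTimeline(
        patient_id=pid, triage_area=triage_area,
        ed_arrival=arrival, ed_departure=departure,
        observations=deduped, therapies=therapies, code_status=code,
        icu_referral_time=referral, reference_label=label,
    )
    tl.validate(ranges)
    return tl


def therapy_active(timeline: PatientTimeline, kind: TherapyKind, at: float) -> bool:
    """True iff ``at`` lies inside some [start, end) interval of ``kind``.

    Open-ended intervals run until ED departure (exclusive of nothing: the
    stay itself ends there).
    """
    for th in timeline.therapies:
        if th.kind is not kind:
            continue
        end = timeline.ed_departure if th.end is None else th.end
        if th.start <= at < end:
            return True
        if th.end is None and at == timeline.ed_departure and th.start <= at:
            return True
    return False


def snapshot_at(timeline: PatientTimeline, at: float,
                staleness: Mapping[ParameterKind, float] | None = None) -> Snapshot:
    """Most-recent non-stale value per parameter at time ``at``.

    A value observed at time ``t`` is usable when ``t <= at`` and
    ``at - t < staleness(kind)`` (strict: a value exactly at the staleness
    horizon has expired).  Parameters with no usable value are absent.
    """
    if not timeline.ed_arrival <= at <= timeline.ed_departure:
        raise ValidationError(
            f"snapshot time {format_time(at)} outside ED stay of {timeline.patient_id}")
    staleness = DEFAULT_STALENESS if staleness is None else staleness
    latest: dict[ParameterKind, tuple[float, float]] = {}
    for obs in timeline.observations:  # sorted: later entries overwrite
        if obs.time > at:
            break
        latest[obs.kind] = (obs.value, obs.time)
    latest = {k: v for k, v in latest.items() if at - v[1] < staleness[k]}
    return Snapshot(
        at=at,
        latest=latest,
        fluids_active=therapy_active(timeline, TherapyKind.IV_FLUID_BOLUS, at),
        oxygen_active=therapy_active(timeline, TherapyKind.SUPPLEMENTAL_OXYGEN, at),
    )
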