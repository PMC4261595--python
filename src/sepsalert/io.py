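"""Readers/writers for the event-stream, config and report formats.

Event-stream dialect (CSV with header, or JSON-lines with the same field
names)::

    patient_id,time,event_type,kind,value,extra

``event_type`` ∈ {obs, therapy_start, therapy_end, code_status, arrival,
departure, icu_referral, label}; timestamps are ISO-8601 with an explicit
UTC offset.  The arrival row's ``extra`` column carries the triage area
(``critical`` / ``other``).  Malformed rows are collected with their line
numbers; more than 10 % malformed aborts the read.

Reports are schema-versioned JSON; undefined statistics serialize as
``null`` estimates with a reason string.  Engine configuration round-trips
through YAML with durations in integer minutes.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .criteria import Thresholds
from .diagnostics import (
    ConfusionMatrix,
    DiagnosticReport,
    ProportionCI,
    RatioCI,
    Undefined,
)
from .engine import (
    AlertEvent,
    DispositionEvent,
    EngineConfig,
    SuppressionWindows,
)
from .events import (
    EventRecord,
    ParameterKind,
    PatientTimeline,
    ValidationError,
    build_timeline,
    format_time,
    parse_time,
)

REPORT_SCHEMA_VERSION = "1"
CSV_COLUMNS = ("patient_id", "time", "event_type", "kind", "value", "extra")

PathLike = Union[str, Path]


@dataclasses.dataclass(frozen=True)
class RowError:
    line: int
    message: str


# ---------------------------------------------------------------------------
# event streams

def _record_from_row(row: dict) -> EventRecord:
    et = (row.get("event_type") or "").strip()
    if not et:
        raise ValidationError("missing event_type")
    value = row.get("value")
    if value in ("", None):
        parsed_value = None
    else:
        try:
            parsed_value = float(value)
        except (TypeError, ValueError):
            raise ValidationError(f"unparseable value {value!r}") from None
    time_field = row.get("time")
    if time_field in ("", None):
        raise ValidationError("missing time")
    t = parse_time(time_field) if isinstance(time_field, str) else float(time_field)
    kind = row.get("kind") or None
    pid = (row.get("patient_id") or "").strip()
    if not pid:
        raise ValidationError("missing patient_id")
    if et == "obs":
        if kind is None:
            raise ValidationError("obs row lacks kind")
        ParameterKind(kind)  # raises ValueError on unknown kind
        if parsed_value is None:
            raise ValidationError("obs row lacks value")
    return EventRecord(patient_id=pid, time=t, event_type=et, kind=kind,
                       value=parsed_value, extra=(row.get("extra") or None))


def _iter_rows(path: PathLike, dialect: str):
    if dialect == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "event_type" not in reader.fieldnames:
                raise ValidationError(f"{path}: missing or invalid header row")
            for row in reader:
                yield reader.line_num, row
    elif dialect == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                yield i, json.loads(line)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_events(path: PathLike, dialect: str = "csv",
                max_malformed_fraction: float = 0.10,
                ) -> tuple[list[PatientTimeline], list[RowError]]:
    """Parse an event stream into validated per-patient timelines.

    Returns ``(timelines, row_errors)``.  Raises :class:`ValidationError`
    when more than ``max_malformed_fraction`` of rows are malformed, or when
    a patient's assembled timeline is itself invalid.
    """
    by_patient: dict[str, list[EventRecord]] = {}
    errors: list[RowError] = []
    total = 0
    for line_num, row in _iter_rows(path, dialect):
        total += 1
        try:
            rec = _record_from_row(row)
        except (ValidationError, ValueError, KeyError, json.JSONDecodeError) as exc:
            errors.append(RowError(line_num, str(exc)))
            continue
        by_patient.setdefault(rec.patient_id, []).append(rec)
    if total and len(errors) / total > max_malformed_fraction:
        raise ValidationError(
            f"{path}: {len(errors)}/{total} rows malformed "
            f"(first: line {errors[0].line}: {errors[0].message})")
    timelines = [build_timeline(records) for records in by_patient.values()]
    return timelines, errors


def _timeline_rows(tl: PatientTimeline) -> Iterable[dict]:
    yield {"patient_id": tl.patient_id, "time": format_time(tl.ed_arrival),
           "event_type": "arrival", "kind": "", "value": "", "extra": tl.triage_area}
    yield {"patient_id": tl.patient_id, "time": format_time(tl.ed_arrival),
           "event_type": "label", "kind": "", "value": int(tl.reference_label),
           "extra": ""}
    for obs in tl.observations:
        yield {"patient_id": tl.patient_id, "time": format_time(obs.time),
               "event_type": "obs", "kind": obs.kind.value, "value": repr(obs.value),
               "extra": ""}
    for th in tl.therapies:
        yield {"patient_id": tl.patient_id, "time": format_time(th.start),
               "event_type": "therapy_start", "kind": th.kind.value, "value": "",
               "extra": ""}
        if th.end is not None:
            yield {"patient_id": tl.patient_id, "time": format_time(th.end),
                   "event_type": "therapy_end", "kind": th.kind.value, "value": "",
                   "extra": ""}
    for cs in tl.code_status:
        yield {"patient_id": tl.patient_id, "time": format_time(cs.time),
               "event_type": "code_status", "kind": "",
               "value": int(cs.precludes_sepsis_icu_care), "extra": ""}
    if tl.icu_referral_time is not None:
        yield {"patient_id": tl.patient_id, "time": format_time(tl.icu_referral_time),
               "event_type": "icu_referral", "kind": "", "value": "", "extra": ""}
    yield {"patient_id": tl.patient_id, "time": format_time(tl.ed_departure),
           "event_type": "departure", "kind": "", "value": "", "extra": ""}


def write_events(timelines: Sequence[PatientTimeline], path: PathLike,
                 dialect: str = "csv") -> None:
    """Serialize timelines to the event-stream dialect (CSV or JSON-lines)."""
    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for tl in timelines:
                writer.writerows(_timeline_rows(tl))
    elif dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for tl in timelines:
                for row in _timeline_rows(tl):
                    fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# labels, dispositions, alerts

def write_labels(labels: dict[str, bool], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label"])
        for pid, lab in labels.items():
            writer.writerow([pid, int(lab)])


def read_labels(path: PathLike) -> dict[str, bool]:
    labels: dict[str, bool] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            labels[row["patient_id"]] = bool(int(row["label"]))
    return labels


def write_dispositions(dispositions: Sequence[DispositionEvent], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "time", "category"])
        for d in dispositions:
            writer.writerow([d.patient_id, format_time(d.time), d.category])


def read_dispositions(path: PathLike) -> list[DispositionEvent]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(DispositionEvent(row["patient_id"],
                                        parse_time(row["time"]), row["category"]))
    return out


def write_alerts(alerts: Sequence[AlertEvent], path: PathLike) -> None:
    """Write fired alerts as JSON-lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in alerts:
            fh.write(json.dumps({
                "patient_id": a.patient_id, "time": format_time(a.time),
                "sirs_met": list(a.sirs_met), "od_met": list(a.od_met),
                "rationale": a.rationale}) + "\n")


def read_alerts(path: PathLike) -> list[AlertEvent]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(AlertEvent(d["patient_id"], parse_time(d["time"]),
                                  tuple(d["sirs_met"]), tuple(d["od_met"]),
                                  d["rationale"]))
    return out


# ---------------------------------------------------------------------------
# engine configuration (YAML, durations in integer minutes)

def config_to_dict(config: EngineConfig) -> dict:
    return {
        "thresholds": dataclasses.asdict(config.thresholds),
        "staleness_minutes": {k.value: int(round(v / 60))
                              for k, v in config.staleness.items()},
        "suppression_minutes": {
            "suspected_sepsis": int(round(config.suppression.suspected_sepsis / 60)),
            "not_sepsis": int(round(config.suppression.not_sepsis / 60)),
            "pending_default": int(round(config.suppression.pending_default / 60)),
        },
        "alpha": config.alpha,
        "quartile_method": config.quartile_method,
    }


def config_from_dict(d: dict) -> EngineConfig:
    thresholds = Thresholds(**d.get("thresholds", {}))
    staleness = {ParameterKind(k): v * 60.0
                 for k, v in d.get("staleness_minutes", {}).items()}
    defaults = EngineConfig()
    full_staleness = dict(defaults.staleness)
    full_staleness.update(staleness)
    sup = d.get("suppression_minutes", {})
    suppression = SuppressionWindows(
        suspected_sepsis=sup.get("suspected_sepsis", 48 * 60) * 60.0,
        not_sepsis=sup.get("not_sepsis", 24 * 60) * 60.0,
        pending_default=sup.get("pending_default", 24 * 60) * 60.0,
    )
    return EngineConfig(thresholds=thresholds, staleness=full_staleness,
                        suppression=suppression,
                        alpha=d.get("alpha", 0.05),
                        quartile_method=d.get("quartile_method", "linear"))


def load_config(path: PathLike) -> EngineConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: EngineConfig, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# diagnostic reports (JSON)

def _stat_to_json(stat) -> dict:
    if isinstance(stat, Undefined):
        return {"estimate": None, "reason": stat.reason}
    d = {"estimate": stat.estimate, "ci": [stat.lower, stat.upper],
         "alpha": stat.alpha, "method": stat.method}
    return d


def _stat_from_json(d: dict, ratio: bool):
    if d.get("estimate") is None:
        return Undefined(d.get("reason", "undefined"))
    cls = RatioCI if ratio else ProportionCI
    return cls(d["estimate"], d["ci"][0], d["ci"][1], d["alpha"], method=d["method"])


def report_to_dict(report: DiagnosticReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "counts": {"tp": report.counts.tp, "fp": report.counts.fp,
                   "fn": report.counts.fn, "tn": report.counts.tn},
        "n": report.n,
        "prevalence": report.prevalence,
        "alpha": report.alpha,
        "ci_method": report.ci_method,
        "statistics": {
            "sensitivity": _stat_to_json(report.sensitivity),
            "specificity": _stat_to_json(report.specificity),
            "ppv": _stat_to_json(report.ppv),
            "npv": _stat_to_json(report.npv),
            "lr_pos": _stat_to_json(report.lr_pos),
            "lr_neg": _stat_to_json(report.lr_neg),
        },
    }


def report_from_dict(d: dict) -> DiagnosticReport:
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValidationError(f"unsupported report schema {d.get('schema_version')!r}")
    c = d["counts"]
    stats = d["statistics"]
    return DiagnosticReport(
        counts=ConfusionMatrix(c["tp"], c["fp"], c["fn"], c["tn"]),
        sensitivity=_stat_from_json(stats["sensitivity"], ratio=False),
        specificity=_stat_from_json(stats["specificity"], ratio=False),
        ppv=_stat_from_json(stats["ppv"], ratio=False),
        npv=_stat_from_json(stats["npv"], ratio=False),
        lr_pos=_stat_from_json(stats["lr_pos"], ratio=True),
        lr_neg=_stat_from_json(stats["lr_neg"], ratio=True),
        prevalence=d["prevalence"], n=d["n"], alpha=d["alpha"],
        ci_method=d["ci_method"],
    )


def write_report(report: DiagnosticReport, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
        fh.write("\n")


def read_report(path: PathLike) -> DiagnosticReport:
    with open(path, encoding="utf-8") as fh:
        return report_from_dict(json.load(fh))
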