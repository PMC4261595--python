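"""SIRS and organ-dysfunction predicates and the alert combination rule.

The alert fires when a snapshot shows at least two SIRS criteria together
with at least one organ dysfunction, OR at least two organ dysfunctions on
their own.  All threshold comparisons are strict, exactly as the screening
tool defines them; boundary values (38.0 °C, 90 bpm, 2.0 mmol/L, ...) do not
satisfy a criterion.

SIRS criteria (each needs its parameter present in the snapshot):
  - temperature > 38 °C or < 36 °C
  - pulse > 90 beats/min
  - respiratory rate > 20 breaths/min
  - WBC > 12 or < 4 (10^3 cells/µL)

Organ-dysfunction criteria (therapy-conditional bands):
  - hypotension: SBP < 86 mm Hg regardless of therapy, or 86 <= SBP < 90
    with an active IV-fluid bolus order
  - hypoxemia: SpO2 < 85 % regardless of therapy, or 85 <= SpO2 < 90
    with supplemental oxygen active
  - lactic acidosis: lactate > 2 mmol/L

The two printed band clauses are read as a clean partition: the half-open
band [86, 90) requires fluids, < 86 is unconditional (analogously [85, 90)
for SpO2).  Mean arterial pressure is not an alert input.

A parameter absent from the snapshot can never satisfy a criterion
(missing-data safety); the functions here are pure and total on valid
snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .events import ParameterKind, Snapshot

SIRS_PARAMS = ("temperature", "pulse", "respiratory_rate", "wbc")
OD_PARAMS = ("hypotension", "hypoxemia", "lactic_acidosis")

SIRS_PLUS_OD = "sirs_plus_od"
DOUBLE_OD = "double_od"
NO_FIRE = "none"


@dataclass(frozen=True)
class Thresholds:
    """Criterion thresholds; defaults are the screening tool's values.

    Exposed so sensitivity analyses can sweep them.  Directions are fixed by
    the rule (strict > for highs, strict < for lows).
    """

    temp_high: float = 38.0       # °C
    temp_low: float = 36.0
    pulse_high: float = 90.0      # beats/min
    rr_high: float = 20.0         # breaths/min
    wbc_high: float = 12.0        # 10^3 cells/µL
    wbc_low: float = 4.0
    sbp_low: float = 86.0         # mm Hg, unconditional
    sbp_band_high: float = 90.0   # [sbp_low, sbp_band_high) needs fluids
    spo2_low: float = 85.0        # %, unconditional
    spo2_band_high: float = 90.0  # [spo2_low, spo2_band_high) needs oxygen
    lactate_high: float = 2.0     # mmol/L


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class SirsResult:
    met: frozenset[str]
    evaluable: frozenset[str]

    def __post_init__(self) -> None:
        assert self.met <= self.evaluable

    @property
    def count(self) -> int:
        return len(self.met)


@dataclass(frozen=True)
class OrganDysfunctionResult:
    met: frozenset[str]
    evaluable: frozenset[str]

    def __post_init__(self) -> None:
        assert self.met <= self.evaluable

    @property
    def count(self) -> int:
        return len(self.met)


@dataclass(frozen=True)
class AlertDecision:
    fire: bool
    sirs_count: int
    od_count: int
    rationale: str  # sirs_plus_od | double_od | none


def _value(snapshot: Snapshot, kind: ParameterKind) -> float | None:
    entry = snapshot.latest.get(kind)
    return None if entry is None else entry[0]


def eval_sirs(snapshot: Snapshot, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> SirsResult:
    """Evaluate the four SIRS criteria on a snapshot."""
    t = thresholds
    met, evaluable = set(), set()
    v = _value(snapshot, ParameterKind.TEMPERATURE)
    if v is not None:
        evaluable.add("temperature")
        if v > t.temp_high or v < t.temp_low:
            met.add("temperature")
    v = _value(snapshot, ParameterKind.PULSE)
    if v is not None:
        evaluable.add("pulse")
        if v > t.pulse_high:
            met.add("pulse")
    v = _value(snapshot, ParameterKind.RESPIRATORY_RATE)
    if v is not None:
        evaluable.add("respiratory_rate")
        if v > t.rr_high:
            met.add("respiratory_rate")
    v = _value(snapshot, ParameterKind.WBC)
    if v is not None:
        evaluable.add("wbc")
        if v > t.wbc_high or v < t.wbc_low:
            met.add("wbc")
    return SirsResult(frozenset(met), frozenset(evaluable))


def eval_organ_dysfunction(snapshot: Snapshot,
                           thresholds: Thresholds = DEFAULT_THRESHOLDS,
                           ) -> OrganDysfunctionResult:
    """Evaluate the three organ-dysfunction criteria on a snapshot."""
    t = thresholds
    met, evaluable = set(), set()
    v = _value(snapshot, ParameterKind.SBP)
    if v is not None:
        evaluable.add("hypotension")
        if v < t.sbp_low or (v < t.sbp_band_high and snapshot.fluids_active):
            met.add("hypotension")
    v = _value(snapshot, ParameterKind.SPO2)
    if v is not None:
        evaluable.add("hypoxemia")
        if v < t.spo2_low or (v < t.spo2_band_high and snapshot.oxygen_active):
            met.add("hypoxemia")
    v = _value(snapshot, ParameterKind.LACTATE)
    if v is not None:
        evaluable.add("lactic_acidosis")
        if v > t.lactate_high:
            met.add("lactic_acidosis")
    return OrganDysfunctionResult(frozenset(met), frozenset(evaluable))


def alert_decision(sirs: SirsResult, od: OrganDysfunctionResult) -> AlertDecision:
    """Combine criteria counts into the fire/no-fire decision.

    Fires on (>=2 SIRS and >=1 organ dysfunction) or >=2 organ dysfunctions;
    when both branches hold, the SIRS branch is reported as the rationale.
    """
    s, o = sirs.count, od.count
    if s >= 2 and o >= 1:
        return AlertDecision(True, s, o, SIRS_PLUS_OD)
    if o >= 2:
        return AlertDecision(True, s, o, DOUBLE_OD)
    return AlertDecision(False, s, o, NO_FIRE)


def evaluate_snapshot(snapshot: Snapshot,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS) -> AlertDecision:
    """Convenience: SIRS + organ dysfunction + combination rule in one call."""
    return alert_decision(eval_sirs(snapshot, thresholds),
                          eval_organ_dysfunction(snapshot, thresholds))


# ---------------------------------------------------------------------------
# Vectorized evaluation (NaN marks a missing parameter)

def sirs_count_arrays(temperature, pulse, respiratory_rate, wbc,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Element-wise SIRS criterion count over arrays; NaN = parameter absent."""
    t = thresholds
    temperature = np.asarray(temperature, dtype=float)
    pulse = np.asarray(pulse, dtype=float)
    respiratory_rate = np.asarray(respiratory_rate, dtype=float)
    wbc = np.asarray(wbc, dtype=float)
    with np.errstate(invalid="ignore"):
        c = ((temperature > t.temp_high) | (temperature < t.temp_low)).astype(np.int8)
        c += (pulse > t.pulse_high)
        c += (respiratory_rate > t.rr_high)
        c += (wbc > t.wbc_high) | (wbc < t.wbc_low)
    return c


def od_count_arrays(sbp, spo2, lactate, fluids_active, oxygen_active,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Element-wise organ-dysfunction count over arrays; NaN = absent."""
    t = thresholds
    sbp = np.asarray(sbp, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)
    lactate = np.asarray(lactate, dtype=float)
    fluids_active = np.asarray(fluids_active, dtype=bool)
    oxygen_active = np.asarray(oxygen_active, dtype=bool)
    with np.errstate(invalid="ignore"):
        c = ((sbp < t.sbp_low) | ((sbp < t.sbp_band_high) & fluids_active)).astype(np.int8)
        c += (spo2 < t.spo2_low) | ((spo2 < t.spo2_band_high) & oxygen_active)
        c += lactate > t.lactate_high
    return c


def fire_arrays(temperature, pulse, respiratory_rate, wbc, sbp, spo2, lactate,
                fluids_active, oxygen_active,
                thresholds: Thresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Element-wise alert decision over parameter arrays (NaN = absent)."""
    s = sirs_count_arrays(temperature, pulse, respiratory_rate, wbc, thresholds)
    o = od_count_arrays(sbp, spo2, lactate, fluids_active, oxygen_active, thresholds)
    return ((s >= 2) & (o >= 1)) | (o >= 2)
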