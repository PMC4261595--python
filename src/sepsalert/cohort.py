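"""Seeded synthetic ED cohorts with the structure the alert evaluation assumes.

The generator emulates a low-prevalence emergency department: each patient
is septic or non-septic by a Bernoulli draw at the configured prevalence
(default 220/49,838 ≈ 0.44 %), is triaged to the critical area (vitals
charted hourly) or another area (every 2 hours), accumulates per-tick vital
draws from stratum-specific distributions, has WBC and lactate ordered on
arrival and resulted after the lab turnaround (~1 h), may carry IV-fluid
and supplemental-oxygen orders, and — in the septic stratum — receives an
ICU referral a log-normally distributed delay after arrival (median 4 h).

Septic-stratum per-draw abnormality rates are loosely matched to the
clinical frequencies reported for ICU-referred septic patients (~86 %
tachycardic, ~89 % tachypneic, ~70 % hypotensive, ~40 % hypoxic, ~45 %
leukocytosis, ~26 % hyperlactatemic).  Draws are independent across ticks
and parameters; no treatment response or autocorrelation is modelled.

:func:`calibrate_cohort_params` tunes a single per-stratum severity shift —
a 1-D location displacement applied to every parameter distribution — until
the engine-measured patient-level alert rate matches the published stratum
proportions (sensitivity 205/220 among septic patients, alert rate
772/49,618 among non-septic).  The search runs the same screening core used
by :func:`sepsalert.engine.run_screening`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .engine import (
    DEFAULT_ENGINE_CONFIG,
    NOT_SEPSIS,
    OBS,
    SUSPECTED_SEPSIS,
    THERAPY,
    DispositionEvent,
    EngineConfig,
    ScreeningSession,
    run_screening,
)
from .events import (
    HOUR,
    KIND_INDEX,
    LAB_KINDS,
    VITAL_KINDS,
    Observation,
    ParameterKind,
    PatientTimeline,
    TherapyInterval,
    TherapyKind,
)

SEPTIC = "septic"
NON_SEPTIC = "non_septic"

#: Direction and scale of the 1-D severity shift, per unit of shift ``s``.
#: Positive moves a parameter toward its abnormal range.  For log-normal
#: parameters the shift applies to the log-location.
SEVERITY_SHIFT_SCALE: dict[ParameterKind, float] = {
    ParameterKind.TEMPERATURE: 0.3,
    ParameterKind.PULSE: 8.0,
    ParameterKind.RESPIRATORY_RATE: 2.5,
    ParameterKind.WBC: 0.15,
    ParameterKind.SBP: -6.0,
    ParameterKind.SPO2: -2.0,
    ParameterKind.LACTATE: 0.2,
}

_BASE_TIME = 1704067200.0  # 2024-01-01T00:00:00+00:00


class CalibrationError(RuntimeError):
    """Severity-shift search failed; carries the best rates found."""

    def __init__(self, message: str, best: dict):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class DistSpec:
    """A clipped univariate distribution.

    family ``normal``: value = clip(loc + scale·z, lo, hi).
    family ``lognormal``: value = clip(exp(loc + scale·z), lo, hi) — ``loc``
    is the log-median.
    """

    family: str  # "normal" | "lognormal"
    loc: float
    scale: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.scale < 0 or not self.lo < self.hi:
            raise ValueError("invalid distribution parameters")

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        z = rng.standard_normal(size)
        if self.family == "normal":
            x = self.loc + self.scale * z
        else:
            x = np.exp(self.loc + self.scale * z)
        return np.clip(x, self.lo, self.hi)

    def shifted(self, delta: float) -> "DistSpec":
        return replace(self, loc=self.loc + delta)


def _logn(median: float, sigma: float, lo: float, hi: float) -> DistSpec:
    return DistSpec("lognormal", math.log(median), sigma, lo, hi)


@dataclass(frozen=True)
class StratumModel:
    """Per-parameter value distributions and therapy-order probabilities."""

    values: dict[ParameterKind, DistSpec]
    fluids_prob: float
    oxygen_prob: float

    def __post_init__(self) -> None:
        if set(self.values) != set(ParameterKind):
            raise ValueError("stratum model must cover all seven parameters")
        for p in (self.fluids_prob, self.oxygen_prob):
            if not 0 <= p <= 1:
                raise ValueError("therapy probability outside [0, 1]")

    def shifted(self, s: float) -> "StratumModel":
        values = {k: d.shifted(s * SEVERITY_SHIFT_SCALE[k])
                  for k, d in self.values.items()}
        return replace(self, values=values)


def default_septic_model() -> StratumModel:
    return StratumModel(
        values={
            ParameterKind.TEMPERATURE: DistSpec("normal", 37.5, 0.85, 33.0, 42.0),
            ParameterKind.PULSE: DistSpec("normal", 108.0, 17.0, 30.0, 220.0),
            ParameterKind.RESPIRATORY_RATE: DistSpec("normal", 26.0, 5.0, 8.0, 60.0),
            ParameterKind.WBC: _logn(11.5, 0.45, 0.3, 120.0),
            ParameterKind.SBP: DistSpec("normal", 84.0, 12.0, 40.0, 200.0),
            ParameterKind.SPO2: DistSpec("normal", 91.5, 4.5, 50.0, 100.0),
            ParameterKind.LACTATE: _logn(1.4, 0.55, 0.2, 25.0),
        },
        fluids_prob=0.75,
        oxygen_prob=0.45,
    )


def default_non_septic_model() -> StratumModel:
    return StratumModel(
        values={
            ParameterKind.TEMPERATURE: DistSpec("normal", 37.0, 0.45, 33.0, 42.0),
            ParameterKind.PULSE: DistSpec("normal", 82.0, 12.0, 30.0, 220.0),
            ParameterKind.RESPIRATORY_RATE: DistSpec("normal", 16.5, 2.5, 6.0, 60.0),
            ParameterKind.WBC: _logn(7.5, 0.28, 0.3, 120.0),
            ParameterKind.SBP: DistSpec("normal", 124.0, 14.0, 40.0, 240.0),
            ParameterKind.SPO2: DistSpec("normal", 97.3, 1.6, 50.0, 100.0),
            ParameterKind.LACTATE: _logn(1.1, 0.35, 0.2, 25.0),
        },
        fluids_prob=0.04,
        oxygen_prob=0.03,
    )


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a synthetic ED cohort; the seed fixes output."""

    n_patients: int
    seed: int
    prevalence: float = 220 / 49838
    stratum_models: dict[str, StratumModel] = field(default_factory=lambda: {
        SEPTIC: default_septic_model(), NON_SEPTIC: default_non_septic_model()})
    cadence: dict[str, float] = field(default_factory=lambda: {
        "critical": 1 * HOUR, "other": 2 * HOUR})
    lab_turnaround: float = 1 * HOUR
    p_critical: dict[str, float] = field(default_factory=lambda: {
        SEPTIC: 0.85, NON_SEPTIC: 0.25})
    ed_stay: dict[str, DistSpec] = field(default_factory=lambda: {
        SEPTIC: _logn(8 * HOUR, 0.40, 3 * HOUR, 20 * HOUR),
        NON_SEPTIC: _logn(4 * HOUR, 0.50, 1.5 * HOUR, 12 * HOUR)})
    icu_referral_delay: DistSpec = _logn(4 * HOUR, 1.1, 0.5 * HOUR, 30 * HOUR)
    therapy_start_delay: tuple[float, float] = (0.25 * HOUR, 1.5 * HOUR)
    start_time: float = _BASE_TIME
    arrival_window: float = 120 * 24 * HOUR
    make_dispositions: bool = True
    disposition_delay: float = 0.25 * HOUR
    calibration_info: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        for v in (*self.cadence.values(), self.lab_turnaround):
            if v <= 0:
                raise ValueError("cadences and turnaround must be positive")


@dataclass
class SyntheticCohort:
    timelines: list[PatientTimeline]
    labels: dict[str, bool]
    dispositions: list[DispositionEvent]
    params_echo: CohortParams


# ---------------------------------------------------------------------------
# batch generation

_VITAL_ALPHA = sorted(VITAL_KINDS, key=lambda k: k.value)
_LAB_ALPHA = sorted(LAB_KINDS, key=lambda k: k.value)


@dataclass
class _StratumBatch:
    """Vectorized draws for m same-stratum patients (times relative to arrival)."""

    m: int
    septic: bool
    cadence: np.ndarray        # (m,) seconds
    stay: np.ndarray           # (m,)
    n_ticks: np.ndarray        # (m,) int
    vitals: dict[ParameterKind, np.ndarray]  # (m, K_max)
    labs: dict[ParameterKind, np.ndarray]    # (m,)
    lab_time: float
    fluid_start: np.ndarray    # (m,) NaN = no order
    oxy_start: np.ndarray      # (m,)
    referral_delay: Optional[np.ndarray]
    critical: np.ndarray       # (m,) bool


def _draw_stratum(params: CohortParams, model: StratumModel, m: int,
                  rng: np.random.Generator, septic: bool) -> _StratumBatch:
    critical = rng.random(m) < params.p_critical[SEPTIC if septic else NON_SEPTIC]
    cadence = np.where(critical, params.cadence["critical"], params.cadence["other"])
    # whole-second times so ISO-8601 serialization round-trips exactly
    stay = np.round(params.ed_stay[SEPTIC if septic else NON_SEPTIC].draw(rng, m))
    n_ticks = (stay // cadence).astype(np.int64) + 1
    k_max = int(n_ticks.max()) if m else 1
    vitals = {k: model.values[k].draw(rng, (m, k_max)) for k in VITAL_KINDS}
    labs = {k: model.values[k].draw(rng, m) for k in LAB_KINDS}
    lo, hi = params.therapy_start_delay
    fluid_start = np.where(rng.random(m) < model.fluids_prob,
                           np.round(rng.uniform(lo, hi, m)), np.nan)
    oxy_start = np.where(rng.random(m) < model.oxygen_prob,
                         np.round(rng.uniform(lo, hi, m)), np.nan)
    # therapy orders must start within the stay
    fluid_start = np.where(fluid_start <= stay, fluid_start, np.nan)
    oxy_start = np.where(oxy_start <= stay, oxy_start, np.nan)
    referral = np.round(params.icu_referral_delay.draw(rng, m)) if septic else None
    return _StratumBatch(m=m, septic=septic, cadence=cadence, stay=stay,
                         n_ticks=n_ticks, vitals=vitals, labs=labs,
                         lab_time=params.lab_turnaround,
                         fluid_start=fluid_start, oxy_start=oxy_start,
                         referral_delay=referral, critical=critical)


def _batch_streams(batch: _StratumBatch):
    """Yield each patient's sorted low-level event list (times from arrival)."""
    vitals = [(KIND_INDEX[k], batch.vitals[k].tolist()) for k in VITAL_KINDS]
    labs = [(KIND_INDEX[k], batch.labs[k].tolist()) for k in LAB_KINDS]
    cadence = batch.cadence.tolist()
    stay = batch.stay.tolist()
    n_ticks = batch.n_ticks.tolist()
    fluid_start = batch.fluid_start.tolist()
    oxy_start = batch.oxy_start.tolist()
    lab_time = batch.lab_time
    for i in range(batch.m):
        ev: list[tuple] = []
        cad = cadence[i]
        for k in range(n_ticks[i]):
            t = k * cad
            for idx, rows in vitals:
                ev.append((t, OBS, idx, rows[i][k]))
        if lab_time <= stay[i]:
            for idx, vals in labs:
                ev.append((lab_time, OBS, idx, vals[i]))
        fs, os_ = fluid_start[i], oxy_start[i]
        if fs == fs:  # not NaN
            ev.append((fs, THERAPY, 0, 1))
        if os_ == os_:
            ev.append((os_, THERAPY, 1, 1))
        ev.sort(key=lambda e: e[0])
        yield ev


def _screen_positive(batch: _StratumBatch, config: EngineConfig) -> np.ndarray:
    """Patient-level alert positivity for a batch, via the engine core."""
    out = np.zeros(batch.m, dtype=bool)
    for i, stream in enumerate(_batch_streams(batch)):
        session = ScreeningSession(str(i), config)
        session.feed(stream)
        out[i] = bool(session.finish())
    return out


def _batch_to_timeline(batch: _StratumBatch, i: int, pid: str,
                       arrival: float) -> PatientTimeline:
    """Materialize patient ``i`` of a batch as a validated-shape timeline."""
    departure = arrival + float(batch.stay[i])
    obs: list[Observation] = []
    cad = float(batch.cadence[i])
    for k in range(int(batch.n_ticks[i])):
        t = arrival + k * cad
        for kind in VITAL_KINDS:
            obs.append(Observation(pid, t, kind, float(batch.vitals[kind][i, k])))
    if batch.lab_time <= batch.stay[i]:
        t = arrival + batch.lab_time
        for kind in LAB_KINDS:
            obs.append(Observation(pid, t, kind, float(batch.labs[kind][i])))
    obs.sort(key=lambda o: (o.time, o.kind.value))
    therapies: list[TherapyInterval] = []
    if not np.isnan(batch.fluid_start[i]):
        therapies.append(TherapyInterval(
            pid, TherapyKind.IV_FLUID_BOLUS, arrival + float(batch.fluid_start[i]), None))
    if not np.isnan(batch.oxy_start[i]):
        therapies.append(TherapyInterval(
            pid, TherapyKind.SUPPLEMENTAL_OXYGEN, arrival + float(batch.oxy_start[i]), None))
    therapies.sort(key=lambda th: th.start)
    return PatientTimeline(
        patient_id=pid,
        triage_area="critical" if batch.critical[i] else "other",
        ed_arrival=arrival, ed_departure=departure,
        observations=obs, therapies=therapies,
        icu_referral_time=None, reference_label=batch.septic,
    )


def simulate_cohort(params: CohortParams,
                    config: EngineConfig = DEFAULT_ENGINE_CONFIG) -> SyntheticCohort:
    """Generate a full synthetic cohort, bit-reproducible under the seed.

    When ``params.make_dispositions`` is set, each alerting patient gets a
    nurse disposition shortly after their first alert: ``suspected_sepsis``
    for labelled-septic patients, ``not_sepsis`` otherwise (the engine is
    run once here to locate first alerts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 11]))
    n = params.n_patients
    septic_mask = rng.random(n) < params.prevalence
    arrivals = params.start_time + np.round(rng.uniform(0, params.arrival_window, n))
    n_sep = int(septic_mask.sum())
    batches = {
        True: _draw_stratum(params, params.stratum_models[SEPTIC], n_sep, rng, True),
        False: _draw_stratum(params, params.stratum_models[NON_SEPTIC],
                             n - n_sep, rng, False),
    }
    index_in_batch = np.empty(n, dtype=np.int64)
    index_in_batch[septic_mask] = np.arange(n_sep)
    index_in_batch[~septic_mask] = np.arange(n - n_sep)

    timelines: list[PatientTimeline] = []
    labels: dict[str, bool] = {}
    dispositions: list[DispositionEvent] = []
    width = max(6, len(str(n)))
    for p in range(n):
        septic = bool(septic_mask[p])
        b = batches[septic]
        i = int(index_in_batch[p])
        pid = f"P{p:0{width}d}"
        timelines.append(_batch_to_timeline(b, i, pid, float(arrivals[p])))
        labels[pid] = septic

    # ICU referral follows the septic patient's deterioration: the referral
    # delay (log-normal, median 4 h) is anchored at the first alert when one
    # fires, else at arrival.  Dispositions answer each first alert.
    for p, tl in enumerate(timelines):
        septic = bool(septic_mask[p])
        need_alerts = params.make_dispositions or septic
        alerts = run_screening(tl, (), config) if need_alerts else []
        if septic:
            b = batches[True]
            anchor = alerts[0].time if alerts else tl.ed_arrival
            tl.icu_referral_time = anchor + float(b.referral_delay[int(index_in_batch[p])])
        if params.make_dispositions and alerts:
            category = SUSPECTED_SEPSIS if septic else NOT_SEPSIS
            dispositions.append(DispositionEvent(
                tl.patient_id, alerts[0].time + params.disposition_delay, category))
    return SyntheticCohort(timelines=timelines, labels=labels,
                           dispositions=dispositions, params_echo=params)


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class RateTargets:
    """Patient-level alert-rate targets per stratum (published proportions)."""

    septic: float = 205 / 220
    non_septic: float = 772 / 49618


def _stratum_rate(params: CohortParams, model: StratumModel, m: int,
                  seed_seq: list[int], septic: bool, config: EngineConfig) -> float:
    rng = np.random.default_rng(np.random.SeedSequence(seed_seq))
    batch = _draw_stratum(params, model, m, rng, septic)
    return float(_screen_positive(batch, config).mean())


def calibrate_cohort_params(n_patients: int, seed: int,
                            targets: RateTargets = RateTargets(),
                            config: EngineConfig = DEFAULT_ENGINE_CONFIG,
                            base: Optional[CohortParams] = None,
                            ) -> CohortParams:
    """Tune per-stratum severity shifts so engine-run alert rates hit targets.

    A deterministic bisection (common random numbers within each stage) on
    the 1-D severity shift, coarse stage first, then a refinement on a
    narrowed bracket with a larger Monte-Carlo sample.  Returns params whose
    stratum models embed the found shifts; ``calibration_info`` records the
    shifts and the achieved rates.
    """
    if n_patients < 1000:
        raise ValueError("calibration requires n_patients >= 1000")
    base = base if base is not None else CohortParams(n_patients=n_patients, seed=seed)
    info: dict = {"targets": {SEPTIC: targets.septic, NON_SEPTIC: targets.non_septic}}
    models: dict[str, StratumModel] = {}
    # sample sizes: the bisection locates the shift coarsely; the Newton
    # correction afterwards keeps the residual rate error well below the
    # binomial SE of the rates a 50k cohort can measure
    stages = {
        SEPTIC: ((2000, 9), (4000, 6)),
        NON_SEPTIC: ((6000, 9), (30000, 5)),
    }
    correction_m = {SEPTIC: (6000, 3000), NON_SEPTIC: (200000, 60000)}
    for stratum_id, (stratum, target) in enumerate(
            [(SEPTIC, targets.septic), (NON_SEPTIC, targets.non_septic)]):
        model0 = base.stratum_models[stratum]
        septic = stratum == SEPTIC
        lo, hi = -1.5, 2.5
        shift = 0.0
        for stage_id, (m, iters) in enumerate(stages[stratum]):
            sseq = [int(seed), 101 + stratum_id, stage_id]

            def rate(s: float) -> float:
                return _stratum_rate(base, model0.shifted(s), m, sseq, septic, config)

            if stage_id == 0:
                r_lo, r_hi = rate(lo), rate(hi)
                if not r_lo <= target <= r_hi:
                    raise CalibrationError(
                        f"{stratum}: target {target:.4g} outside achievable "
                        f"[{r_lo:.4g}, {r_hi:.4g}] for shift in [{lo}, {hi}]",
                        best={"stratum": stratum, "rate_lo": r_lo, "rate_hi": r_hi})
            for _ in range(iters):
                mid = 0.5 * (lo + hi)
                if rate(mid) < target:
                    lo = mid
                else:
                    hi = mid
            shift = 0.5 * (lo + hi)
            lo, hi = shift - 0.35, shift + 0.35  # narrowed bracket for refinement

        # one Newton step on fresh samples removes the residual bias of the
        # common-random-number bisection
        m_rate, m_slope = correction_m[stratum]
        r0 = _stratum_rate(base, model0.shifted(shift), m_rate,
                           [int(seed), 101 + stratum_id, 7], septic, config)
        h = 0.1
        slope_seq = [int(seed), 101 + stratum_id, 8]
        r_lo = _stratum_rate(base, model0.shifted(shift - h), m_slope,
                             slope_seq, septic, config)
        r_hi = _stratum_rate(base, model0.shifted(shift + h), m_slope,
                             slope_seq, septic, config)
        slope = (r_hi - r_lo) / (2 * h)
        if slope > 0:
            step = (target - r0) / slope
            shift += max(-0.2, min(0.2, step))

        models[stratum] = model0.shifted(shift)
        final_rate = _stratum_rate(base, models[stratum], m_rate,
                                   [int(seed), 101 + stratum_id, 99], septic, config)
        info[stratum] = {"shift": shift, "achieved_rate": final_rate}
    return replace(base, stratum_models=models, calibration_info=info)
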