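"""Patient-level diagnostic accuracy of the alert vs the clinician reference.

Provides the 2x2 confusion matrix, sensitivity / specificity / PPV / NPV
with binomial confidence intervals, likelihood ratios with log-method
intervals, and the alert-to-ICU-referral lead-time summary.

Two binomial interval methods are implemented:

* ``wilson_score_cc`` — Wilson score interval with continuity correction
  (Newcombe 1998).  This is the report default: it is the method that
  reproduces the published interval bounds of the alert-accuracy study this
  engine re-implements.
* ``clopper_pearson`` — exact (beta-quantile) interval, conservative by
  construction; available for users who prefer exact coverage.

Likelihood-ratio intervals use the standard log-normal approximation
(Simel, Samsa & Matchar 1991): ``exp(ln LR ± z · se(ln LR))`` with
``se²(ln LR+) = 1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)`` and
``se²(ln LR−) = 1/fn − 1/(tp+fn) + 1/tn − 1/(fp+tn)``.

Statistics whose margin is empty (or whose LR requires division by zero)
are reported as explicit :class:`Undefined` markers, never silently as 0/1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm

WILSON_CC = "wilson_score_cc"
CLOPPER_PEARSON = "clopper_pearson"
LOG_NORMAL = "log_normal"


class UndefinedStatisticError(ZeroDivisionError):
    """A requested statistic is undefined for these counts (empty margin)."""


@dataclass(frozen=True)
class Undefined:
    """Explicit marker for a statistic that cannot be computed."""

    reason: str


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-level 2x2 counts of alert positivity vs reference label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if not self.lower - 1e-12 <= self.estimate <= self.upper + 1e-12:
            raise ValueError("interval does not bracket the estimate")


@dataclass(frozen=True)
class RatioCI:
    estimate: float
    lower: float
    upper: float
    alpha: float
    method: str = LOG_NORMAL


@dataclass(frozen=True)
class LeadTimeSummary:
    median: float
    q1: float
    q3: float
    n: int


MaybeProportion = Union[ProportionCI, Undefined]
MaybeRatio = Union[RatioCI, Undefined]


@dataclass(frozen=True)
class DiagnosticReport:
    counts: ConfusionMatrix
    sensitivity: MaybeProportion
    specificity: MaybeProportion
    ppv: MaybeProportion
    npv: MaybeProportion
    lr_pos: MaybeRatio
    lr_neg: MaybeRatio
    prevalence: float
    n: int
    alpha: float
    ci_method: str


def build_confusion(status: Mapping[str, bool], labels: Mapping[str, bool]) -> ConfusionMatrix:
    """Cross-tabulate patient-level alert positivity against reference labels.

    ``status`` and ``labels`` must cover exactly the same patients.
    """
    s_ids, l_ids = set(status), set(labels)
    if s_ids != l_ids:
        diff = sorted(s_ids.symmetric_difference(l_ids))
        shown = ", ".join(map(str, diff[:10])) + ("..." if len(diff) > 10 else "")
        raise ValueError(f"patient id sets differ ({len(diff)} ids): {shown}")
    tp = fp = fn = tn = 0
    for pid, pos in status.items():
        if labels[pid]:
            tp, fn = tp + bool(pos), fn + (not pos)
        else:
            fp, tn = fp + bool(pos), tn + (not pos)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _check_counts(successes: int, trials: int, alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> ProportionCI:
    """Exact (Clopper–Pearson) binomial confidence interval.

    Obtained from beta quantiles, equivalently by inverting binomial tail
    probabilities.  ``successes=0`` pins the lower bound to 0 exactly;
    ``successes=trials`` pins the upper bound to 1.
    """
    _check_counts(successes, trials, alpha)
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k / n, lower, upper, alpha, CLOPPER_PEARSON)


def wilson_score_cc(successes: int, trials: int, alpha: float = 0.05) -> ProportionCI:
    """Wilson score interval with continuity correction (Newcombe 1998)."""
    _check_counts(successes, trials, alpha)
    k, n = successes, trials
    p = k / n
    z = float(norm.ppf(1 - alpha / 2))
    z2 = z * z
    if k == 0:
        lower = 0.0
    else:
        lower = (2 * n * p + z2 - 1 - z * math.sqrt(
            z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / (2 * (n + z2))
    if k == n:
        upper = 1.0
    else:
        upper = (2 * n * p + z2 + 1 + z * math.sqrt(
            z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / (2 * (n + z2))
    return ProportionCI(p, max(0.0, lower), min(1.0, upper), alpha, WILSON_CC)


_PROPORTION_METHODS = {WILSON_CC: wilson_score_cc, CLOPPER_PEARSON: clopper_pearson}


def likelihood_ratios(cm: ConfusionMatrix, alpha: float = 0.05) -> tuple[RatioCI, RatioCI]:
    """LR+ and LR− with log-method confidence intervals.

    Raises :class:`UndefinedStatisticError` when a zero cell makes a ratio
    undefined — no silent continuity correction is applied.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    if tp + fn == 0 or fp + tn == 0:
        raise UndefinedStatisticError("empty diseased or non-diseased margin")
    if fp == 0:
        raise UndefinedStatisticError("LR+ undefined: no false positives (specificity 1)")
    if tp == 0:
        raise UndefinedStatisticError("LR+ undefined: no true positives")
    if fn == 0:
        raise UndefinedStatisticError("LR- undefined: no false negatives (sensitivity 1)")
    if tn == 0:
        raise UndefinedStatisticError("LR- undefined: no true negatives (specificity 0)")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    z = float(norm.ppf(1 - alpha / 2))

    lr_pos = sens / (1 - spec)
    se_pos = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    ci_pos = RatioCI(lr_pos,
                     math.exp(math.log(lr_pos) - z * se_pos),
                     math.exp(math.log(lr_pos) + z * se_pos),
                     alpha)

    lr_neg = (1 - sens) / spec
    se_neg = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    ci_neg = RatioCI(lr_neg,
                     math.exp(math.log(lr_neg) - z * se_neg),
                     math.exp(math.log(lr_neg) + z * se_neg),
                     alpha)
    return ci_pos, ci_neg


def diagnostic_report(cm: ConfusionMatrix, alpha: float = 0.05,
                      ci_method: str = WILSON_CC) -> DiagnosticReport:
    """All six test characteristics with intervals, from the 2x2 counts.

    Per-statistic empty margins yield :class:`Undefined` markers; the report
    itself is always returned.
    """
    if ci_method not in _PROPORTION_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    interval = _PROPORTION_METHODS[ci_method]
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")

    def prop(k: int, m: int, what: str) -> MaybeProportion:
        if m == 0:
            return Undefined(f"{what} undefined: empty margin")
        return interval(k, m, alpha)

    sens = prop(tp, tp + fn, "sensitivity")
    spec = prop(tn, fp + tn, "specificity")
    ppv = prop(tp, tp + fp, "PPV")
    npv = prop(tn, fn + tn, "NPV")
    try:
        lr_pos, lr_neg = likelihood_ratios(cm, alpha)
    except UndefinedStatisticError as exc:
        lr_pos = lr_neg = Undefined(str(exc))
    return DiagnosticReport(
        counts=cm, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg,
        prevalence=(tp + fn) / n, n=n, alpha=alpha, ci_method=ci_method,
    )


def lead_time_summary(lead_times: Sequence[float]) -> LeadTimeSummary:
    """Median and quartiles of alert-to-referral lead times (hours).

    Quartiles use linear interpolation between order statistics (the common
    statistical-package default).
    """
    if len(lead_times) == 0:
        raise ValueError("empty lead-time list")
    q1, med, q3 = np.percentile(np.asarray(lead_times, dtype=float),
                                [25, 50, 75], method="linear")
    return LeadTimeSummary(median=float(med), q1=float(q1), q3=float(q3),
                           n=len(lead_times))
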