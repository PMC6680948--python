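"""Chance-predictor-corrected evaluation of advisory timelines.

An alarm system that spends a long-run fraction ``rho`` of time under
warning captures, by chance alone, a fraction ``rho`` of seizure onsets
when warnings and seizures are independent processes.  Performance is
therefore reported as the difference between observed sensitivity and
``rho``, with a conditional binomial hypothesis test: given ``n`` onsets
and time-under-warning ``rho``, the number captured is Binomial(n, rho)
under independence.  The red (high-likelihood) gate additionally demands
sensitivity above a 65% floor; the blue (low-likelihood) gate demands a
false-negative rate significantly *below* chance (lower binomial tail).

The likelihood-ratio statistic compares seizure rates between the high and
moderate advisory states; when no seizure falls in the moderate state the
ratio is infinite and reported with the ``ALL`` sentinel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy.stats import binom

from .advisory import RED, WHITE, BLUE, STATES, AdvisoryTimeline

ALL = "ALL"   # sentinel: every event occurred under the high advisory


@dataclass(frozen=True)
class ValidationCriteria:
    red_floor: float = 0.65
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.red_floor < 1:
            raise ValueError("red_floor must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class RedPerformance:
    n_events: int
    n_in_red: int
    sensitivity: float                  # nan when n_events == 0 (flagged)
    time_fraction_red: float
    advance_warning_min: list[float]
    p_value_vs_chance: float | None = None
    undefined: bool = False


@dataclass
class BluePerformance:
    n_events: int
    n_in_blue: int
    fnr: float
    time_fraction_blue: float
    npv: float | None                   # None when no blue episodes
    p_value_vs_chance: float | None = None
    undefined: bool = False


@dataclass
class LikelihoodRatioResult:
    events_high: int
    time_high: float
    events_moderate: int
    time_moderate: float
    value: float                        # inf when events_moderate == 0

    @property
    def is_all(self) -> bool:
        return np.isinf(self.value)

    def display(self) -> str:
        return ALL if self.is_all else f"{self.value:.2f}"


def time_fractions(timeline: AdvisoryTimeline) -> dict[str, Fraction]:
    """Per-state fraction of the monitored span; sums to 1 exactly.

    Durations are accumulated as exact rationals so that
    ``sum(result.values()) == 1`` holds identically.
    """
    if len(timeline) == 0:
        raise ValueError("empty timeline")
    totals = {s: Fraction(0) for s in STATES}
    for s, e, st in zip(timeline.starts, timeline.ends, timeline.states):
        totals[st] += Fraction(float(e)) - Fraction(float(s))
    grand = sum(totals.values())
    return {s: totals[s] / grand for s in STATES}


def red_sensitivity(events: np.ndarray, timeline: AdvisoryTimeline
                    ) -> RedPerformance:
    """Event credited iff its onset lies inside a red interval.

    Advance warning per credited event: onset minus the start of its
    enclosing red interval, in minutes.
    """
    events = np.asarray(events, dtype=float)
    t0, t1 = timeline.span
    if events.size and (events.min() < t0 or events.max() >= t1):
        raise ValueError("events must lie within the monitored span")
    rho = float(time_fractions(timeline)[RED])
    n_in_red = 0
    warnings_min: list[float] = []
    for t in events:
        i = timeline.interval_index_at(t)
        if i is not None and timeline.states[i] == RED:
            n_in_red += 1
            warnings_min.append((t - float(timeline.starts[i])) / 60.0)
    n = len(events)
    return RedPerformance(
        n_events=n, n_in_red=n_in_red,
        sensitivity=(n_in_red / n) if n else float("nan"),
        time_fraction_red=rho, advance_warning_min=warnings_min,
        undefined=(n == 0))


def blue_performance(events: np.ndarray, timeline: AdvisoryTimeline
                     ) -> BluePerformance:
    """False-negative rate (events under blue) and episode-based NPV."""
    events = np.asarray(events, dtype=float)
    rho_blue = float(time_fractions(timeline)[BLUE])
    episodes = timeline.episodes(BLUE)
    n_in_blue = 0
    for t in events:
        i = timeline.interval_index_at(t)
        if i is not None and timeline.states[i] == BLUE:
            n_in_blue += 1
    npv = None
    if episodes:
        clean = sum(1 for s, e in episodes
                    if not np.any((events >= s) & (events < e)))
        npv = clean / len(episodes)
    n = len(events)
    return BluePerformance(
        n_events=n, n_in_blue=n_in_blue,
        fnr=(n_in_blue / n) if n else float("nan"),
        time_fraction_blue=rho_blue, npv=npv, undefined=(n == 0))


def chance_sensitivity(rho: float) -> float:
    """Expected sensitivity of a chance predictor at time-under-warning rho.

    Warnings independent of onsets: the probability an onset falls under
    warning equals the long-run warning time fraction.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    return rho


def improvement_over_chance(sensitivity: float, rho: float) -> float:
    """Observed sensitivity minus chance sensitivity at equal warning time."""
    if not 0.0 <= sensitivity <= 1.0 or not 0.0 <= rho <= 1.0:
        raise ValueError("inputs must lie in [0, 1]")
    return sensitivity - chance_sensitivity(rho)


def chance_test_red(n_events: int, n_in_red: int, rho: float,
                    alpha: float = 0.05) -> tuple[float, bool]:
    """Upper-tail binomial test: P(K >= n_in_red), K ~ Binomial(n, rho)."""
    if n_events == 0:
        raise ValueError("chance test undefined for zero events")
    if n_in_red > n_events:
        raise ValueError("n_in_red cannot exceed n_events")
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    p = float(binom.sf(n_in_red - 1, n_events, rho))
    return p, p < alpha


def chance_test_blue(n_events: int, n_in_blue: int, rho_blue: float,
                     alpha: float = 0.05) -> tuple[float, bool]:
    """Lower-tail binomial test: P(K <= n_in_blue), K ~ Binomial(n, rho)."""
    if n_events == 0:
        raise ValueError("chance test undefined for zero events")
    if n_in_blue > n_events:
        raise ValueError("n_in_blue cannot exceed n_events")
    if not 0 < rho_blue < 1:
        raise ValueError("rho_blue must lie in (0, 1)")
    p = float(binom.cdf(n_in_blue, n_events, rho_blue))
    return p, p < alpha


def likelihood_ratio(events_high: int, time_high: float, events_moderate: int,
                     time_moderate: float) -> LikelihoodRatioResult:
    """Seizure rate under high advisory over rate under moderate advisory."""
    if time_high <= 0 or time_moderate <= 0:
        raise ValueError("state times must be positive")
    if events_high < 0 or events_moderate < 0:
        raise ValueError("event counts must be non-negative")
    if events_moderate == 0:
        value = float("inf")
    else:
        value = (events_high / time_high) / (events_moderate / time_moderate)
    return LikelihoodRatioResult(events_high=events_high, time_high=time_high,
                                 events_moderate=events_moderate,
                                 time_moderate=time_moderate, value=value)


@dataclass
class ValidationReport:
    red_pass: bool | None               # None: not evaluable
    blue_pass: bool | None
    advances: bool
    reasons: list[str] = field(default_factory=list)


def validate_algorithm(red: RedPerformance | None,
                       blue: BluePerformance | None,
                       criteria: ValidationCriteria = ValidationCriteria()
                       ) -> ValidationReport:
    """Red: sensitivity above chance (binomial) AND above the 65% floor.
    Blue: FNR significantly below chance.  The patient advances if either
    gate passes."""
    reasons: list[str] = []
    red_pass: bool | None = None
    blue_pass: bool | None = None
    if red is None or red.undefined or not 0 < red.time_fraction_red < 1:
        reasons.append("red performance not evaluable")
    else:
        p, sig = chance_test_red(red.n_events, red.n_in_red,
                                 red.time_fraction_red, criteria.alpha)
        red.p_value_vs_chance = p
        floor_ok = red.sensitivity > criteria.red_floor
        red_pass = bool(sig and floor_ok)
        if not floor_ok:
            reasons.append(f"red sensitivity {red.sensitivity:.2f} not above "
                           f"floor {criteria.red_floor}")
        if not sig:
            reasons.append(f"red not above chance (p={p:.3g})")
    if blue is None or blue.undefined or not 0 < blue.time_fraction_blue < 1:
        reasons.append("blue performance not evaluable")
    else:
        p, sig = chance_test_blue(blue.n_events, blue.n_in_blue,
                                  blue.time_fraction_blue, criteria.alpha)
        blue.p_value_vs_chance = p
        blue_pass = bool(sig)
        if not sig:
            reasons.append(f"blue FNR not below chance (p={p:.3g})")
    advances = bool(red_pass) or bool(blue_pass)
    return ValidationReport(red_pass=red_pass, blue_pass=blue_pass,
                            advances=advances, reasons=reasons)


def performance_report(events: np.ndarray, timeline: AdvisoryTimeline,
                       criteria: ValidationCriteria = ValidationCriteria()
                       ) -> dict:
    """Full JSON-serializable performance bundle for one timeline."""
    red = red_sensitivity(events, timeline)
    blue = blue_performance(events, timeline)
    verdict = validate_algorithm(red if red.n_events else None,
                                 blue if blue.n_events else None, criteria)
    fr = {s: float(v) for s, v in time_fractions(timeline).items()}
    ev = np.asarray(events, dtype=float)
    states = [timeline.state_at(t) for t in ev]
    n_white = sum(1 for s in states if s == WHITE)
    lr = None
    if fr[RED] > 0 and fr[WHITE] > 0:
        lr_res = likelihood_ratio(red.n_in_red, fr[RED], n_white, fr[WHITE])
        lr = lr_res.display()
    return {
        "n_events": red.n_events,
        "red": asdict(red),
        "blue": asdict(blue),
        "time_fractions": fr,
        "improvement_over_chance": (
            improvement_over_chance(red.sensitivity, red.time_fraction_red)
            if red.n_events else None),
        "likelihood_ratio": lr,
        "validation": asdict(verdict),
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
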