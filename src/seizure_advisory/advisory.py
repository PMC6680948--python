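"""Red/white/blue advisory timelines and trial event-handling rules.

The advisory indicator discretizes a continuous seizure likelihood into
high (red), moderate (white), and low (blue) states with two thresholds and
an optional minimum dwell time.  This module also implements the trial's
event bookkeeping: collapsing seizure clusters (events closer than eight
hours belong to one cluster, counted once), the 2-12 seizures/month and
45-day seizure-free-interval eligibility screen, leading seizures (at least
eight hours of continuous seizure-free recording before onset), and the
data-collection completion rule (five leading seizures within 30 days).

A month is 30 days; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

RED, WHITE, BLUE = "red", "white", "blue"
STATES = (RED, WHITE, BLUE)

HOUR = 3600.0
DAY = 86400.0
MONTH = 30.0 * DAY


@dataclass(frozen=True)
class ScreeningRules:
    min_monthly: float = 2.0
    max_monthly: float = 12.0
    max_seizure_free_days: float = 45.0
    cluster_gap_hours: float = 8.0

    def __post_init__(self) -> None:
        if not 0 < self.min_monthly <= self.max_monthly:
            raise ValueError("need 0 < min_monthly <= max_monthly")
        if self.max_seizure_free_days <= 0 or self.cluster_gap_hours <= 0:
            raise ValueError("rule parameters must be positive")


@dataclass
class AdvisoryTimeline:
    """Sorted, disjoint, exhaustive state intervals over the monitored span."""

    starts: np.ndarray
    ends: np.ndarray
    states: list[str]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.states)):
            raise ValueError("misaligned timeline arrays")
        if len(self.starts):
            if np.any(self.ends <= self.starts):
                raise ValueError("empty or inverted interval")
            if np.any(self.starts[1:] != self.ends[:-1]):
                raise ValueError("timeline must be contiguous and exhaustive")
        for s in self.states:
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def span(self) -> tuple[float, float]:
        return (float(self.starts[0]), float(self.ends[-1]))

    def duration_by_state(self) -> dict[str, float]:
        out = {s: 0.0 for s in STATES}
        for s, e, st in zip(self.starts, self.ends, self.states):
            out[st] += e - s
        return out

    def state_at(self, t: float) -> str | None:
        i = np.searchsorted(self.ends, t, side="right")
        if i >= len(self.starts) or t < self.starts[i]:
            return None
        return self.states[i]

    def interval_index_at(self, t: float) -> int | None:
        i = np.searchsorted(self.ends, t, side="right")
        if i >= len(self.starts) or t < self.starts[i]:
            return None
        return int(i)

    def episodes(self, state: str) -> list[tuple[float, float]]:
        return [(float(s), float(e)) for s, e, st in
                zip(self.starts, self.ends, self.states) if st == state]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"start_s": self.starts, "end_s": self.ends,
                      "state": self.states}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AdvisoryTimeline":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(starts=df["start_s"].to_numpy(dtype=float),
                   ends=df["end_s"].to_numpy(dtype=float),
                   states=list(df["state"]))


def _smooth_runs(states: list[str], lengths: list[int], min_dwell: int
                 ) -> tuple[list[str], list[int]]:
    """Merge runs shorter than min_dwell into the dominant neighbor.

    The shortest run (leftmost on ties) is merged first; the longer adjacent
    run absorbs it (tie -> the earlier neighbor persists).
    """
    states, lengths = list(states), list(lengths)
    while len(states) > 1:
        short = [i for i, n in enumerate(lengths) if n < min_dwell]
        if not short:
            break
        i = min(short, key=lambda j: (lengths[j], j))
        left = i - 1 if i > 0 else None
        right = i + 1 if i < len(states) - 1 else None
        if left is None:
            tgt = right
        elif right is None:
            tgt = left
        else:
            tgt = left if lengths[left] >= lengths[right] else right
        lengths[tgt] += lengths[i]
        del states[i], lengths[i]
        # adjacent equal states may now touch; merge them
        j = 0
        while j < len(states) - 1:
            if states[j] == states[j + 1]:
                lengths[j] += lengths[j + 1]
                del states[j + 1], lengths[j + 1]
            else:
                j += 1
    return states, lengths


def hold_red_mask(red_now: np.ndarray, red_hold: int) -> np.ndarray:
    """Extend each supra-threshold epoch forward by ``red_hold`` epochs.

    A raised warning persists: epoch ``i`` is red when any of epochs
    ``i - red_hold .. i`` crossed the high threshold.
    """
    red_now = np.asarray(red_now, dtype=bool)
    if red_hold <= 0 or not red_now.any():
        return red_now.copy()
    bump = np.zeros(len(red_now) + 1, dtype=int)
    idx = np.flatnonzero(red_now)
    np.add.at(bump, idx, 1)
    np.add.at(bump, np.minimum(idx + red_hold + 1, len(red_now)), -1)
    return np.cumsum(bump[:-1]) > 0


def advisory_from_likelihood(likelihood: np.ndarray, epoch_starts: np.ndarray,
                             epoch_length: float, theta_high: float,
                             theta_low: float, min_dwell: int = 1,
                             red_hold: int = 0) -> AdvisoryTimeline:
    """Threshold an epoch-gridded likelihood series into a state timeline.

    Epoch state: red if likelihood >= theta_high, blue if <= theta_low,
    else white.  A red warning persists for ``red_hold`` further epochs
    after the last supra-threshold epoch (it outranks blue while held).
    Runs shorter than ``min_dwell`` epochs are merged into the neighboring
    dominant state.  The result covers the epoch span exactly.
    """
    if not theta_high > theta_low:
        raise ValueError("theta_high must exceed theta_low")
    likelihood = np.asarray(likelihood, dtype=float)
    if likelihood.size == 0:
        return AdvisoryTimeline(np.empty(0), np.empty(0), [])
    red = hold_red_mask(likelihood >= theta_high, red_hold)
    per_epoch = np.where(red, RED,
                         np.where(likelihood <= theta_low, BLUE, WHITE))
    # run-length encode
    states: list[str] = [str(per_epoch[0])]
    lengths: list[int] = [1]
    for s in per_epoch[1:]:
        if s == states[-1]:
            lengths[-1] += 1
        else:
            states.append(str(s))
            lengths.append(1)
    if min_dwell > 1:
        states, lengths = _smooth_runs(states, lengths, min_dwell)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    t0 = float(epoch_starts[0])
    starts = t0 + bounds[:-1] * epoch_length
    ends = t0 + bounds[1:] * epoch_length
    return AdvisoryTimeline(starts=starts, ends=ends, states=states)


def collapse_clusters(event_times: np.ndarray, gap: float = 8 * HOUR
                      ) -> np.ndarray:
    """Greedy left-to-right cluster collapsing; a cluster counts once.

    An event within strictly less than ``gap`` of the previous cluster
    member joins that cluster; each cluster is represented by its first
    event.  A separation of exactly ``gap`` starts a new cluster.
    Idempotent.
    """
    times = np.sort(np.asarray(event_times, dtype=float))
    if times.size == 0:
        return times
    heads = [times[0]]
    last_member = times[0]
    for t in times[1:]:
        if t - last_member < gap:
            last_member = t
        else:
            heads.append(t)
            last_member = t
    return np.asarray(heads)


@dataclass
class EligibilityVerdict:
    eligible: bool
    reasons: list[str]
    monthly_rate: float
    max_gap_days: float
    n_collapsed: int


def eligibility_screen(events: np.ndarray, span: tuple[float, float],
                       rules: ScreeningRules = ScreeningRules()
                       ) -> EligibilityVerdict:
    """2-12 collapsed seizures/month on average; no 45-day seizure-free gap.

    Cluster collapsing is applied first.  The seizure-free-gap check
    includes the span boundaries (a long initial silence fails).
    """
    t0, t1 = span
    if not t1 > t0:
        raise ValueError("empty span")
    if t1 - t0 < 3 * MONTH:
        raise ValueError("screening span must cover at least three months")
    ev = np.asarray(events, dtype=float)
    ev = ev[(ev >= t0) & (ev < t1)]
    collapsed = collapse_clusters(ev, rules.cluster_gap_hours * HOUR)
    months = (t1 - t0) / MONTH
    rate = len(collapsed) / months
    boundary_pts = np.concatenate([[t0], collapsed, [t1]])
    max_gap_days = float(np.max(np.diff(boundary_pts)) / DAY)
    reasons = []
    if rate < rules.min_monthly:
        reasons.append(f"mean monthly seizure count {rate:.2f} below "
                       f"{rules.min_monthly}")
    if rate > rules.max_monthly:
        reasons.append(f"mean monthly seizure count {rate:.2f} above "
                       f"{rules.max_monthly}")
    if max_gap_days > rules.max_seizure_free_days:
        reasons.append(f"seizure-free interval {max_gap_days:.1f} d exceeds "
                       f"{rules.max_seizure_free_days} d")
    return EligibilityVerdict(eligible=not reasons, reasons=reasons,
                              monthly_rate=rate, max_gap_days=max_gap_days,
                              n_collapsed=len(collapsed))


def leading_seizures(events: np.ndarray,
                     coverage: list[tuple[float, float]] | None = None,
                     min_preictal_record: float = 8 * HOUR,
                     span: tuple[float, float] | None = None) -> np.ndarray:
    """Events preceded by >= 8 h of continuous, seizure-free recording.

    ``coverage`` lists recorded intervals (sorted, non-overlapping); if
    omitted, ``span`` (or the events' own range from 0) is taken as fully
    recorded.
    """
    ev = np.sort(np.asarray(events, dtype=float))
    if coverage is None:
        if span is None:
            span = (0.0, float(ev[-1]) + 1.0 if ev.size else 1.0)
        coverage = [span]
    out = []
    for i, t in enumerate(ev):
        window = (t - min_preictal_record, t)
        covered = any(s <= window[0] and e >= window[1] for s, e in coverage)
        quiet = not np.any((ev > window[0]) & (ev < t))
        if covered and quiet:
            out.append(t)
    return np.asarray(out)


def data_collection_complete(events: np.ndarray,
                             coverage: list[tuple[float, float]] | None = None,
                             span: tuple[float, float] | None = None,
                             min_leading: int = 5,
                             window: float = MONTH) -> bool:
    """True iff some 30-day sliding window holds >= 5 leading seizures."""
    lead = leading_seizures(events, coverage=coverage, span=span)
    if len(lead) < min_leading:
        return False
    return bool(np.any(lead[min_leading - 1:] - lead[:len(lead) - min_leading + 1]
                       <= window))


def verdict_to_json(verdict) -> str:
    from dataclasses import asdict

    return json.dumps(asdict(verdict), indent=2)
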