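"""Behavioral statistics of chase/escape trial sets.

Direction changes are zero crossings of an agent's horizontal velocity,
detected at the native recording rate. A velocity sample equal to zero
inherits the previous nonzero sign, so touching zero without crossing is
not an event. Defender responses are matched to attacker direction
changes greedily in time order (same sign, latency within [0, 500] ms,
one-to-one); matches faster than 150 ms count as short latency.

Heading-change histograms and their entropy are computed on data
decimated to the analysis rate (20 Hz by default). Angles are signed,
positive = counterclockwise (leftward turn), wrapped to (-180, 180].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    ANALYSIS_RATE_HZ,
    MAX_RESPONSE_LATENCY_S,
    SHORT_LATENCY_S,
    Condition,
    PitchGeometry,
    n_columns_for,
)
from .trajectory_io import Agent, Trial, TrialSet, downsample, velocities


# ---------------------------------------------------------------------------
# direction-change events and response matching


@dataclass(frozen=True)
class ChangeEvent:
    """A zero crossing of an agent's horizontal velocity."""

    agent: str
    time: float  # s from trial start (velocity-sample index / rate)
    sign: str  # "pos_to_neg" | "neg_to_pos"
    x_at_change: float  # agent's x position at the event sample (cm)
    trial_id: str

    @property
    def new_sign(self) -> int:
        return -1 if self.sign == "pos_to_neg" else 1


@dataclass(frozen=True)
class ResponseRecord:
    """A matched attacker/defender direction-change pair."""

    attacker_event: ChangeEvent
    defender_event: ChangeEvent
    latency: float  # seconds, in [0, MAX_RESPONSE_LATENCY_S]

    @property
    def latency_ms(self) -> float:
        return self.latency * 1000.0

    @property
    def is_short(self) -> bool:
        return self.latency < SHORT_LATENCY_S


def detect_direction_changes(trial: Trial, agent: Agent) -> list[ChangeEvent]:
    """Strict sign flips of vx; zero samples inherit the previous sign."""
    vel = velocities(trial, agent)
    pos = trial.positions(agent)
    signs = np.sign(vel.vx)
    events: list[ChangeEvent] = []
    prev = 0.0
    for i, s in enumerate(signs):
        if s == 0.0:
            continue
        if prev != 0.0 and s != prev:
            events.append(
                ChangeEvent(
                    agent=agent,
                    time=i / trial.sample_rate,
                    sign="pos_to_neg" if s < 0 else "neg_to_pos",
                    x_at_change=float(pos[i, 0]),
                    trial_id=trial.trial_id,
                )
            )
        prev = s
    return events


def match_responses(
    attacker_events: Sequence[ChangeEvent],
    defender_events: Sequence[ChangeEvent],
    max_latency: float = MAX_RESPONSE_LATENCY_S,
) -> list[ResponseRecord]:
    """Greedy one-to-one matching of same-signed events in time order.

    Each attacker event takes the earliest unmatched defender event of
    the same sign with 0 <= latency <= ``max_latency``; unmatched events
    are dropped.
    """
    used = [False] * len(defender_events)
    records = []
    for a in sorted(attacker_events, key=lambda e: e.time):
        for j, d in enumerate(defender_events):
            if used[j] or d.sign != a.sign:
                continue
            lat = d.time - a.time
            if lat < 0:
                continue
            if lat > max_latency:
                break  # defender events are time-ordered; later ones only worse
            used[j] = True
            records.append(ResponseRecord(a, d, lat))
            break
    return records


def trialset_events(
    ts: TrialSet, agent: Agent
) -> dict[str, list[ChangeEvent]]:
    """Direction-change events per trial_id."""
    return {t.trial_id: detect_direction_changes(t, agent) for t in ts}


def trialset_responses(ts: TrialSet) -> dict[str, list[ResponseRecord]]:
    """Matched responses per trial_id."""
    out = {}
    for t in ts:
        a = detect_direction_changes(t, "attacker")
        d = detect_direction_changes(t, "defender")
        out[t.trial_id] = match_responses(a, d)
    return out


def short_latency_proportion(
    records: Iterable[ResponseRecord],
    participants: dict[str, str] | None = None,
) -> float:
    """Fraction of matched responses with latency < 150 ms.

    If ``participants`` maps trial_id -> defender participant, the
    proportion is computed per participant and then averaged; otherwise
    it is pooled. NaN when there are no records.
    """
    records = list(records)
    if not records:
        return math.nan
    if participants is None:
        return sum(r.is_short for r in records) / len(records)
    by_p: dict[str, list[ResponseRecord]] = {}
    for r in records:
        p = participants[r.attacker_event.trial_id]
        by_p.setdefault(p, []).append(r)
    props = [sum(r.is_short for r in rs) / len(rs) for rs in by_p.values()]
    return float(np.mean(props))


# ---------------------------------------------------------------------------
# heading-change histogram and entropy


def wrap_angle_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into (-180, 180]."""
    r = np.mod(np.asarray(a, dtype=float) + 180.0, 360.0)
    r = np.where(r == 0.0, 360.0, r)
    out = r - 180.0
    return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out


@dataclass
class HeadingChangeHistogram:
    """Histogram of per-step heading changes over (-180, 180]."""

    bin_width: float
    counts: np.ndarray
    n_total: int
    n_skipped: int = 0  # zero-speed steps that contributed no angle

    @property
    def edges(self) -> np.ndarray:
        n = len(self.counts)
        return -180.0 + self.bin_width * np.arange(n + 1)

    @property
    def relative_frequencies(self) -> np.ndarray:
        if self.n_total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_total


def heading_changes_deg(trial: Trial, agent: Agent = "attacker") -> np.ndarray:
    """Signed heading change per consecutive step, degrees in (-180, 180].

    Movement direction is defined only where speed > 0; a change is
    produced only for consecutive steps that are both moving.
    """
    vel = velocities(trial, agent)
    moving = vel.speed > 0
    theta = np.degrees(np.arctan2(vel.vy, vel.vx))
    valid = moving[:-1] & moving[1:]
    d = theta[1:][valid] - theta[:-1][valid]
    return wrap_angle_deg(d)


def heading_change_histogram(
    ts: TrialSet | Iterable[Trial],
    agent: Agent = "attacker",
    bin_width: float = 5.0,
    rate: float = ANALYSIS_RATE_HZ,
) -> HeadingChangeHistogram:
    """Pooled heading-change histogram at the analysis rate."""
    n_bins = int(round(360.0 / bin_width))
    if abs(n_bins * bin_width - 360.0) > 1e-9:
        raise ValueError("bin_width must divide 360")
    counts = np.zeros(n_bins, dtype=np.int64)
    n_total = 0
    n_skipped = 0
    for trial in ts:
        t20 = downsample(trial, rate)
        vel = velocities(t20, agent)
        n_skipped += int(np.sum(vel.speed == 0))
        d = heading_changes_deg(t20, agent)
        if len(d):
            # right-inclusive bins over (-180, 180]
            idx = np.ceil((d + 180.0) / bin_width).astype(int) - 1
            idx = np.clip(idx, 0, n_bins - 1)
            counts += np.bincount(idx, minlength=n_bins)
            n_total += len(d)
    return HeadingChangeHistogram(bin_width, counts, n_total, n_skipped)


def entropy(hist: HeadingChangeHistogram) -> float:
    """Shannon entropy (bits) of the heading-change distribution."""
    if hist.n_total == 0:
        return math.nan
    p = hist.relative_frequencies
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# spatial (column) statistics


@dataclass
class ColumnStats:
    """Per-column occupancy and direction-change statistics."""

    n_columns: int
    edges: np.ndarray  # column boundaries, cm
    time_spent_s: np.ndarray
    n_changes: np.ndarray
    freq_per_s: np.ndarray  # NaN where missing
    mean_response_time_ms: np.ndarray  # NaN where no responses
    missing: np.ndarray  # True where the column was never visited


def column_stats(
    ts: TrialSet,
    agent: Agent = "attacker",
    events: dict[str, list[ChangeEvent]] | None = None,
    records: dict[str, list[ResponseRecord]] | None = None,
) -> ColumnStats:
    """Columnwise time spent, change counts, frequency and response times.

    All trials must share one condition (it fixes the column count:
    narrow=4, square=8, wide=16). Response times are attributed to the
    defender's own x position at its change event.
    """
    conds = ts.conditions()
    if len(conds) != 1:
        raise ValueError("column_stats requires a single-condition TrialSet")
    cond = conds[0]
    geom = PitchGeometry.for_condition(cond)
    n_cols = n_columns_for(cond)
    edges = np.linspace(-geom.half_width, geom.half_width, n_cols + 1)

    if events is None:
        events = trialset_events(ts, agent)
    if records is None:
        records = trialset_responses(ts)

    time_spent = np.zeros(n_cols)
    n_changes = np.zeros(n_cols, dtype=np.int64)
    resp_sum = np.zeros(n_cols)
    resp_n = np.zeros(n_cols, dtype=np.int64)

    for trial in ts:
        x = trial.positions(agent)[:, 0]
        idx = _column_index(x, edges)
        time_spent += np.bincount(idx, minlength=n_cols) / trial.sample_rate
        for ev in events.get(trial.trial_id, []):
            n_changes[_column_index(np.array([ev.x_at_change]), edges)[0]] += 1
        for rec in records.get(trial.trial_id, []):
            c = _column_index(np.array([rec.defender_event.x_at_change]), edges)[0]
            resp_sum[c] += rec.latency_ms
            resp_n[c] += 1

    missing = time_spent == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(missing, np.nan, n_changes / np.where(missing, 1, time_spent))
        mean_rt = np.where(resp_n > 0, resp_sum / np.maximum(resp_n, 1), np.nan)
    return ColumnStats(n_cols, edges, time_spent, n_changes, freq, mean_rt, missing)


def _column_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, x, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


# ---------------------------------------------------------------------------
# direction-change ratio


@dataclass
class ChangeRatio:
    per_participant: pd.Series  # defender/attacker change counts per participant
    mean: float
    sem: float
    pooled: float


def change_ratio(ts: TrialSet) -> ChangeRatio:
    """Defender-vs-attacker direction-change ratio per defender participant."""
    rows = []
    tot_a = tot_d = 0
    for p in ts.defender_participants():
        sub = ts.by_defender(p)
        n_a = sum(len(detect_direction_changes(t, "attacker")) for t in sub)
        n_d = sum(len(detect_direction_changes(t, "defender")) for t in sub)
        tot_a += n_a
        tot_d += n_d
        rows.append((p, n_d / n_a if n_a > 0 else math.nan))
    per_p = pd.Series(dict(rows), name="change_ratio")
    vals = per_p.dropna()
    mean = float(vals.mean()) if len(vals) else math.nan
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
    pooled = tot_d / tot_a if tot_a > 0 else math.nan
    return ChangeRatio(per_p, mean, sem, pooled)


# ---------------------------------------------------------------------------
# inter-change interval analysis (memorylessness)


@dataclass
class IntervalAnalysis:
    intervals: np.ndarray  # s, pooled within-trial inter-event intervals
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    survival_t: np.ndarray  # sorted interval values
    survival_p: np.ndarray  # P(interval > t)
    tail_threshold: float
    tail_rate: float  # MLE exponential rate on intervals > threshold (1/s)
    n_tail: int
    low_confidence: bool  # fewer than 10 tail intervals


def interval_analysis(
    events_by_trial: dict[str, list[ChangeEvent]] | Iterable[Sequence[ChangeEvent]],
    bin_width: float = 0.05,
    tail_threshold: float = 0.5,
) -> IntervalAnalysis:
    """Within-trial inter-event intervals, histogram, survival and tail fit.

    The tail rate is the maximum-likelihood exponential rate of the
    excess beyond ``tail_threshold``: 1 / (mean(tail) - threshold). For
    a memoryless switching process with a refractory window shorter
    than the threshold this recovers the underlying hazard.
    """
    if isinstance(events_by_trial, dict):
        groups: Iterable[Sequence[ChangeEvent]] = events_by_trial.values()
    else:
        groups = events_by_trial
    ivals: list[float] = []
    for evs in groups:
        times = sorted(e.time for e in evs)
        ivals.extend(np.diff(times))
    intervals = np.asarray(ivals)

    if len(intervals):
        n_bins = max(1, int(math.ceil(intervals.max() / bin_width)))
        edges = bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(intervals, bins=edges)
        st = np.sort(intervals)
        sp = 1.0 - np.arange(1, len(st) + 1) / len(st)
    else:
        edges = np.array([0.0, bin_width])
        counts = np.zeros(1, dtype=np.int64)
        st = np.array([])
        sp = np.array([])

    tail = intervals[intervals > tail_threshold]
    if len(tail) and tail.mean() > tail_threshold:
        rate = 1.0 / (tail.mean() - tail_threshold)
    else:
        rate = math.nan
    return IntervalAnalysis(
        intervals=intervals,
        hist_edges=edges,
        hist_counts=counts,
        survival_t=st,
        survival_p=sp,
        tail_threshold=tail_threshold,
        tail_rate=rate,
        n_tail=len(tail),
        low_confidence=len(tail) < 10,
    )


# ---------------------------------------------------------------------------
# speed saturation and interpersonal-distance binning


def speed_saturation(ts: TrialSet, threshold: float = 0.9) -> dict[str, float]:
    """Per agent: fraction of samples with speed above threshold * cap."""
    out = {}
    for agent in ("attacker", "defender"):
        n_fast = 0
        n_all = 0
        for trial in ts:
            vel = velocities(trial, agent)
            cap = trial.geometry.max_speed
            n_fast += int(np.sum(vel.speed_cmps > threshold * cap))
            n_all += len(vel)
        out[agent] = n_fast / n_all if n_all else math.nan
    return out


@dataclass
class DistanceBinnedChanges:
    bin_width: float
    edges: np.ndarray
    time_spent_s: np.ndarray
    n_changes: np.ndarray
    freq_per_s: np.ndarray  # NaN for unoccupied bins


def distance_binned_changes(
    ts: TrialSet,
    agent: Agent = "attacker",
    bin_width: float = 0.1,
    events: dict[str, list[ChangeEvent]] | None = None,
) -> DistanceBinnedChanges:
    """Time spent and direction changes binned by interpersonal distance."""
    if events is None:
        events = trialset_events(ts, agent)
    max_dist = 0.0
    per_trial_dist = {}
    for trial in ts:
        d = np.hypot(
            trial.attacker_xy[:, 0] - trial.defender_xy[:, 0],
            trial.attacker_xy[:, 1] - trial.defender_xy[:, 1],
        )
        per_trial_dist[trial.trial_id] = d
        if len(d):
            max_dist = max(max_dist, float(d.max()))
    n_bins = max(1, int(math.ceil(max_dist / bin_width)) + 1)
    edges = bin_width * np.arange(n_bins + 1)
    time_spent = np.zeros(n_bins)
    n_changes = np.zeros(n_bins, dtype=np.int64)
    for trial in ts:
        d = per_trial_dist[trial.trial_id]
        idx = np.minimum((d / bin_width).astype(int), n_bins - 1)
        time_spent += np.bincount(idx, minlength=n_bins) / trial.sample_rate
        for ev in events.get(trial.trial_id, []):
            sample = int(round(ev.time * trial.sample_rate))
            sample = min(sample, len(d) - 1)
            n_changes[min(int(d[sample] / bin_width), n_bins - 1)] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(time_spent > 0, n_changes / np.where(time_spent > 0, time_spent, 1), np.nan)
    return DistanceBinnedChanges(bin_width, edges, time_spent, n_changes, freq)


# ---------------------------------------------------------------------------
# tidy per-participant summary (CLI output)


def participant_summary(ts: TrialSet) -> pd.DataFrame:
    """Per defender-participant behavioral statistics, tidy format."""
    rows = []
    for p in ts.defender_participants():
        sub = ts.by_defender(p)
        recs = [r for rs in trialset_responses(sub).values() for r in rs]
        att_events = trialset_events(sub, "attacker")
        n_att = sum(len(v) for v in att_events.values())
        n_def = sum(len(v) for v in trialset_events(sub, "defender").values())
        hist = heading_change_histogram(sub)
        sat = speed_saturation(sub)
        rows.append(
            {
                "defender_participant": p,
                "n_trials": len(sub),
                "n_attacker_changes": n_att,
                "n_defender_changes": n_def,
                "n_matched_responses": len(recs),
                "short_latency_proportion": (
                    sum(r.is_short for r in recs) / len(recs) if recs else math.nan
                ),
                "mean_latency_ms": (
                    float(np.mean([r.latency_ms for r in recs])) if recs else math.nan
                ),
                "change_ratio": n_def / n_att if n_att else math.nan,
                "heading_change_entropy_bits": entropy(hist),
                "speed_saturation_attacker": sat["attacker"],
                "speed_saturation_defender": sat["defender"],
            }
        )
    return pd.DataFrame(rows)
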