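"""Classification and quantification of fictive motor programs.

Operates on multichannel time-series tables — one column per hemisegment ROI,
either simulator voltages or imaging ΔF/F — and reproduces the analysis
pipeline used to score the model's output:

* per-channel peak detection with rise-onset and fall-offset locations
  (20 % of the rise, 80 % of the fall, by default);
* waves: progressive peaks spanning the whole channel chain in posterior ->
  anterior order (forwards) or the mirror (backwards), with the posterior
  initiating group allowed to co-peak;
* bursts: near-synchronous activity confined to the anterior or posterior
  group that fails to propagate;
* head sweeps: supra-threshold left-right differences;
* per-event metrics (duration, interval, instantaneous frequency), overlap
  annotation, transition matrices, and bilateral-asymmetry kernel density
  estimates.

Channel names must start with the segment label (``"A3"``, ``"A3_L"``,
``"T2_R"``); posterior -> anterior ordering is inferred from the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "Peak",
    "PeakTable",
    "FictiveEvent",
    "detect_peaks",
    "build_peak_table",
    "classify_waves",
    "classify_bursts",
    "classify_events",
    "detect_head_sweeps",
    "wave_metrics",
    "annotate_metrics",
    "detect_overlap",
    "transition_matrix",
    "asymmetry_kde",
    "linear_fit_r2",
    "event_frequencies",
    "roi_frame",
]

# canonical posterior -> anterior order of segment labels
_SEG_ORDER = ["A8", "A7", "A6", "A5", "A4", "A3", "A2", "A1", "T3", "T2", "T1"]

POSTERIOR_GROUP = ("A8", "A7", "A6")
ANTERIOR_GROUP = ("A1", "T3", "T2", "T1")

# Discrete head sweeps on membrane-potential input are scored against this
# fraction of the channels' peak-to-peak range (a fully one-sided episode
# reaches ~0.9 of the range; partial co-active asymmetries stay below it).
# ΔF/F input keeps the 5 % criterion via scale="dff".
VOLTAGE_SWEEP_THRESHOLD = 0.5

WAVE_KINDS = ("forwards_wave", "backwards_wave")
BURST_KINDS = ("posterior_burst", "anterior_burst")
SWEEP_KINDS = ("head_sweep_L", "head_sweep_R")
EVENT_KINDS = WAVE_KINDS + BURST_KINDS + SWEEP_KINDS


def _segment_of(channel: str) -> str:
    return channel.split("_")[0]


def _order_channels(channels: Iterable[str]) -> list[str]:
    rank = {s: i for i, s in enumerate(_SEG_ORDER)}
    chans = list(channels)
    unknown = [c for c in chans if _segment_of(c) not in rank]
    if unknown:
        raise ValueError(f"channels with unrecognised segment labels: {unknown}")
    return sorted(chans, key=lambda c: rank[_segment_of(c)])


@dataclass(frozen=True)
class Peak:
    """One detected activity peak with its rise onset and fall offset (ms)."""

    channel: str
    time: float
    height: float
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (self.onset < self.time < self.offset):
            raise ValueError("peak must satisfy onset < peak < offset")


@dataclass
class PeakTable:
    """Time-ordered peaks per channel, channels in posterior->anterior order."""

    peaks: dict[str, list[Peak]]

    @property
    def channels(self) -> list[str]:
        return list(self.peaks)

    def all_peaks(self) -> list[Peak]:
        return sorted((p for ps in self.peaks.values() for p in ps),
                      key=lambda p: p.time)


@dataclass
class FictiveEvent:
    """One classified motor-program event."""

    kind: str
    start: float  # ms, onset in the initiating channel
    end: float  # ms, offset in the final channel
    channels: list[str] = field(default_factory=list)
    peak_times: dict[str, float] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


def _cross_time(t: np.ndarray, y: np.ndarray, i_peak: int, level: float,
                direction: int) -> float:
    """Linear-interpolated crossing of ``level`` walking from a peak.

    ``direction`` -1 walks left (rise onset), +1 walks right (fall offset).
    Falls back to the trace edge when the trace never crosses the level.
    """
    i = i_peak
    while 0 < i < len(y) - 1:
        j = i + direction
        if y[j] <= level:
            # interpolate between j and i
            if y[i] == y[j]:
                return t[j]
            frac = (y[i] - level) / (y[i] - y[j])
            return t[i] + frac * (t[j] - t[i])
        i = j
    return t[0] if direction < 0 else t[-1]


def detect_peaks(
    trace: np.ndarray,
    time: np.ndarray,
    channel: str = "",
    min_prominence: float = 0.3,
    min_separation: float = 1000.0,
    min_height: float = 0.35,
    rise_fraction: float = 0.2,
    fall_fraction: float = 0.8,
    baseline_percentile: float = 10.0,
    min_range: float = 0.0,
) -> list[Peak]:
    """Detect activity peaks in one uniformly sampled channel.

    ``min_prominence`` and ``min_height`` are fractions of the channel's
    dynamic range (baseline to maximum); sub-threshold recovery bumps between
    events are rejected by both.  A channel whose whole dynamic range is
    below ``min_range`` (absolute trace units) is treated as quiescent —
    without this floor, a fraction-of-range criterion would happily report
    "peaks" in settling transients of a silent channel.  The rise onset is
    where the trace last crossed ``baseline + rise_fraction * (height -
    baseline)`` before the peak; the fall offset is where ``fall_fraction``
    of the fall back to baseline is complete.

    Returns an empty list for empty or flat traces.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if trace.size == 0:
        return []
    base = np.percentile(trace, baseline_percentile)
    rng = trace.max() - base
    if rng <= 0 or rng < min_range:
        return []
    dt = time[1] - time[0] if time.size > 1 else 1.0
    idx, _ = find_peaks(
        trace,
        prominence=min_prominence * rng,
        distance=max(int(round(min_separation / dt)), 1),
        height=base + min_height * rng,
    )
    out: list[Peak] = []
    for i in idx:
        h = trace[i]
        on_level = base + rise_fraction * (h - base)
        off_level = base + (1.0 - fall_fraction) * (h - base)
        onset = _cross_time(time, trace, i, on_level, -1)
        offset = _cross_time(time, trace, i, off_level, +1)
        onset = min(onset, time[i] - dt / 2)
        offset = max(offset, time[i] + dt / 2)
        out.append(Peak(channel, float(time[i]), float(h), float(onset),
                        float(offset)))
    return out


def build_peak_table(frame: pd.DataFrame, time_column: str = "time_ms",
                     **kwargs) -> PeakTable:
    """Peak table from a trace table (time column + one column per ROI)."""
    t = frame[time_column].to_numpy()
    channels = _order_channels(c for c in frame.columns if c != time_column)
    return PeakTable(
        {c: detect_peaks(frame[c].to_numpy(), t, channel=c, **kwargs)
         for c in channels}
    )


def _chain_peaks(
    ordered: list[str],
    peaks: dict[str, list[Peak]],
    used: set,
    sync_window: float,
    max_interseg_delay: float,
):
    """Greedy progressive chains starting from the first channel's peaks.

    Within each chain, successive peak times may precede the previous one by
    at most ``sync_window`` (near-synchronous initiation) and follow it by at
    most ``max_interseg_delay``.
    """
    chains = []
    for p0 in peaks[ordered[0]]:
        if id(p0) in used:
            continue
        chain = [p0]
        ok = True
        for ch in ordered[1:]:
            prev = chain[-1]
            cands = [
                p for p in peaks[ch]
                if id(p) not in used
                and prev.time - sync_window <= p.time <= prev.time + max_interseg_delay
            ]
            if not cands:
                ok = False
                break
            chain.append(min(cands, key=lambda p: abs(p.time - prev.time)))
        if ok:
            chains.append(chain)
            used.update(id(p) for p in chain)
    return chains


def classify_waves(
    table: PeakTable,
    sync_window: float = 500.0,
    max_interseg_delay: float = 2000.0,
    _used: set | None = None,
) -> list[FictiveEvent]:
    """Forwards and backwards waves: progressive peaks spanning every channel.

    A forwards wave runs posterior -> anterior (most-posterior channel peaks
    first); a backwards wave is the mirror.  Peaks in adjacent channels may
    co-occur within ``sync_window`` (the posterior group peaks
    near-synchronously in forwards waves) but the whole event must be
    genuinely progressive: the first-to-last peak spread must exceed
    ``sync_window``, otherwise the event is left for the burst classifier.
    Events spanning fewer than all channels are not waves.
    """
    ordered = _order_channels(table.channels)
    if len(ordered) < 2:
        raise ValueError("wave classification needs at least two channels")
    used = _used if _used is not None else set()
    events = []
    for direction, chans in (("forwards_wave", ordered),
                             ("backwards_wave", ordered[::-1])):
        # trial chains without committing, then commit progressive ones
        trial_used = set(used)
        for chain in _chain_peaks(chans, table.peaks, trial_used,
                                  sync_window, max_interseg_delay):
            times = [p.time for p in chain]
            if times[-1] - times[0] <= sync_window:
                continue  # synchronous event, not a wave
            used.update(id(p) for p in chain)
            events.append(
                FictiveEvent(
                    kind=direction,
                    start=chain[0].onset,
                    end=chain[-1].offset,
                    channels=[p.channel for p in chain],
                    peak_times={p.channel: p.time for p in chain},
                )
            )
    events.sort(key=lambda e: e.start)
    return events


def _cluster_remaining(table: PeakTable, used: set, gap: float):
    rest = [p for p in table.all_peaks() if id(p) not in used]
    clusters: list[list[Peak]] = []
    for p in rest:
        if clusters and p.time - clusters[-1][-1].time <= gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def classify_bursts(
    table: PeakTable,
    sync_window: float = 500.0,
    posterior_group: Sequence[str] = POSTERIOR_GROUP,
    anterior_group: Sequence[str] = ANTERIOR_GROUP,
    _used: set | None = None,
) -> list[FictiveEvent]:
    """Anterior and posterior bursts: confined near-synchronous activity.

    A posterior burst is a co-peak (within ``sync_window``) of every available
    posterior-group channel with no concurrent peak anywhere else; an
    anterior burst is the mirror.  Synchronous activity across *all* channels
    is flagged ``synchronous_network_event`` (neither wave nor burst).  Waves
    and bursts are mutually exclusive labels for the same peaks: peaks
    already claimed by the wave classifier (via ``classify_events``) are not
    reconsidered.
    """
    chans = set(table.channels)
    post = [c for c in _order_channels(chans) if _segment_of(c) in posterior_group]
    ant = [c for c in _order_channels(chans) if _segment_of(c) in anterior_group]
    used = _used if _used is not None else set()
    events = []
    for cluster in _cluster_remaining(table, used, sync_window):
        cluster_chans = {p.channel for p in cluster}
        times = [p.time for p in cluster]
        synchronous = max(times) - min(times) <= sync_window
        kind = None
        if not synchronous:
            continue
        if cluster_chans == chans:
            kind = "synchronous_network_event"
        elif post and cluster_chans == set(post):
            kind = "posterior_burst"
        elif ant and cluster_chans == set(ant):
            kind = "anterior_burst"
        elif post and cluster_chans <= set(post):
            kind = "posterior_burst" if len(cluster_chans) > 1 else None
        elif ant and cluster_chans <= set(ant):
            kind = "anterior_burst" if len(cluster_chans) > 1 else None
        if kind is None:
            continue
        used.update(id(p) for p in cluster)
        events.append(
            FictiveEvent(
                kind=kind,
                start=min(p.onset for p in cluster),
                end=max(p.offset for p in cluster),
                channels=sorted(cluster_chans, key=_order_channels([*chans]).index),
                peak_times={p.channel: p.time for p in cluster},
            )
        )
    events.sort(key=lambda e: e.start)
    return events


def classify_events(
    table: PeakTable,
    sync_window: float = 500.0,
    max_interseg_delay: float = 2000.0,
    posterior_group: Sequence[str] = POSTERIOR_GROUP,
    anterior_group: Sequence[str] = ANTERIOR_GROUP,
) -> list[FictiveEvent]:
    """Waves first, then bursts, over one shared peak pool."""
    used: set = set()
    events = classify_waves(table, sync_window, max_interseg_delay, _used=used)
    events += classify_bursts(table, sync_window, posterior_group,
                              anterior_group, _used=used)
    events.sort(key=lambda e: e.start)
    return events


def detect_head_sweeps(
    left: np.ndarray,
    right: np.ndarray,
    time: np.ndarray,
    threshold: float = 0.05,
    refractory: float = 2000.0,
    scale: str = "range",
    merge_same_side: bool = True,
) -> list[FictiveEvent]:
    """Head sweeps: supra-threshold left-right asymmetry excursions.

    The difference trace (left - right) is scanned for excursions whose peak
    magnitude exceeds ``threshold`` times a reference scale: the larger
    peak-to-peak range of the two traces (``scale="range"``, voltage input)
    or 100 (``scale="dff"``, traces in ΔF/F percent, i.e. a 5 % peak
    difference at the default threshold).  Positive excursions are left
    sweeps.

    With ``merge_same_side`` (default), consecutive same-side excursions with
    no intervening opposite-side excursion merge into one discrete sweep
    event — a bout of one-sided dominance is scored once, and each change of
    side starts a new event.  Alternating supra-threshold excursions
    therefore still yield alternating L/R events.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    time = np.asarray(time, dtype=float)
    if left.shape != right.shape or left.shape != time.shape:
        raise ValueError("left, right and time must share one grid")
    diff = left - right
    if scale == "range":
        ref = max(np.ptp(left), np.ptp(right))
    elif scale == "dff":
        ref = 100.0
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if ref <= 0:
        return []
    level = threshold * ref
    dt = time[1] - time[0] if time.size > 1 else 1.0
    dist = max(int(round(refractory / dt)), 1)
    events = []
    for sign, kind in ((1.0, "head_sweep_L"), (-1.0, "head_sweep_R")):
        idx, _ = find_peaks(sign * diff, height=level, distance=dist,
                            prominence=level / 2)
        for i in idx:
            onset = _cross_time(time, sign * diff, i, level, -1)
            offset = _cross_time(time, sign * diff, i, level, +1)
            onset = min(onset, time[i] - dt / 2)
            offset = max(offset, time[i] + dt / 2)
            events.append(
                FictiveEvent(kind=kind, start=onset, end=offset,
                             peak_times={"diff": float(time[i])},
                             metrics={"magnitude": float(sign * diff[i])})
            )
    events.sort(key=lambda e: e.start)
    if merge_same_side:
        merged: list[FictiveEvent] = []
        for e in events:
            if merged and merged[-1].kind == e.kind:
                prev = merged[-1]
                prev.end = max(prev.end, e.end)
                prev.metrics["magnitude"] = max(
                    prev.metrics["magnitude"], e.metrics["magnitude"]
                )
            else:
                merged.append(e)
        events = merged
    return events


def wave_metrics(event: FictiveEvent,
                 previous: FictiveEvent | None = None) -> dict:
    """Duration/interval/frequency of one wave.

    Duration runs from 20 % of the rise in the first channel to 80 % of the
    fall in the last channel — exactly the event's ``start``/``end``.  The
    interval is measured between equivalent points (starts) of consecutive
    same-kind events; a lone event has no interval (absent, not zero).
    """
    m = {"duration_ms": event.end - event.start}
    if previous is not None:
        if previous.kind != event.kind:
            raise ValueError("interval is defined between same-kind events")
        interval = event.start - previous.start
        m["interval_ms"] = interval
        m["frequency_hz"] = 1000.0 / interval
    return m


def annotate_metrics(events: list[FictiveEvent]) -> list[FictiveEvent]:
    """Attach duration, same-kind interval and instantaneous frequency."""
    last_of_kind: dict[str, FictiveEvent] = {}
    for e in events:
        e.metrics.update(wave_metrics(e, last_of_kind.get(e.kind)))
        last_of_kind[e.kind] = e
    return events


def detect_overlap(events: list[FictiveEvent]) -> pd.DataFrame:
    """Same-program and opposite-program overlap annotation.

    Same-program overlap: two waves of the same direction propagating
    concurrently (their event windows intersect).  Opposite-program overlap
    (collision): a forwards wave and a backwards wave active at the same
    time.  Returns one row per event with boolean flags; the window used is
    the event's 20 %-rise to 80 %-fall span.
    """
    rows = []
    waves = [e for e in events if e.kind in WAVE_KINDS]
    for e in events:
        same = opposite = False
        if e.kind in WAVE_KINDS:
            for o in waves:
                if o is e:
                    continue
                if o.start < e.end and e.start < o.end:
                    if o.kind == e.kind:
                        same = True
                    else:
                        opposite = True
        rows.append({"kind": e.kind, "start": e.start, "end": e.end,
                     "same_program_overlap": same,
                     "opposite_program_overlap": opposite})
    return pd.DataFrame(rows)


def transition_matrix(kinds: Sequence[str]) -> pd.DataFrame:
    """Row-normalised first-order transition probabilities between kinds.

    Rows are the preceding kind, columns the following; every row with at
    least one outgoing transition sums to 1.  Fewer than two events give an
    empty matrix.
    """
    kinds = list(kinds)
    if len(kinds) < 2:
        return pd.DataFrame()
    pairs = pd.DataFrame({"preceding": kinds[:-1], "following": kinds[1:]})
    counts = pd.crosstab(pairs["preceding"], pairs["following"])
    return counts.div(counts.sum(axis=1), axis=0)


def asymmetry_kde(
    left: np.ndarray,
    right: np.ndarray,
    bandwidth_factor: float = 4.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of the left-right difference distribution.

    Scott's rule bandwidth multiplied by ``bandwidth_factor`` (default 4);
    returns (grid, density), density integrating to 1 on an unbounded grid.
    """
    diff = np.asarray(left, dtype=float) - np.asarray(right, dtype=float)
    kde = stats.gaussian_kde(diff)
    kde.set_bandwidth(kde.factor * bandwidth_factor)
    if grid is None:
        bw = np.sqrt(kde.covariance[0, 0])
        lo, hi = diff.min() - 4 * bw, diff.max() + 4 * bw
        grid = np.linspace(lo, hi, 512)
    return grid, kde(grid)


def linear_fit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares fit; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def progression_metrics(
    table: PeakTable,
    first_channel: str,
    last_channel: str,
    max_delay: float = 4000.0,
) -> pd.DataFrame:
    """Per-cycle duration and period of wave progression along a chain.

    Implements the chain-progression measurement used in the segment-block
    experiments: each cycle is anchored on a peak in the initiating
    (``first``) channel; its duration runs from 20 % of the rise there to
    80 % of the fall of the matching peak in the final intact (``last``)
    channel (the nearest one within ``max_delay``); the cycle period is the
    time between equivalent points (onsets) of consecutive cycles.  Works for
    full waves and for truncated progressions alike.
    """
    first = table.peaks[first_channel]
    last = table.peaks[last_channel]
    rows = []
    prev_onset = None
    for p0 in first:
        cands = [p for p in last if p0.time - 500.0 <= p.time <= p0.time + max_delay]
        if not cands:
            continue
        p1 = min(cands, key=lambda p: abs(p.time - p0.time))
        rows.append({
            "onset_ms": p0.onset,
            "duration_ms": p1.offset - p0.onset,
            "period_ms": p0.onset - prev_onset if prev_onset is not None else np.nan,
        })
        prev_onset = p0.onset
    return pd.DataFrame(rows)


def event_frequencies(events: list[FictiveEvent], duration_ms: float,
                      kinds: Sequence[str] = EVENT_KINDS) -> pd.Series:
    """Events per minute by kind over the record length."""
    minutes = duration_ms / 60000.0
    counts = {k: 0 for k in kinds}
    for e in events:
        if e.kind in counts:
            counts[e.kind] += 1
    s = pd.Series(counts, dtype=float) / minutes
    s["total"] = s.sum()
    return s


def roi_frame(recording, blueprint, side: str | None = None,
              segments: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-hemisegment ROI traces from a recording.

    Each ROI channel is the pointwise maximum over the hemisegment's excitor
    voltages — the model analogue of an imaging ROI over the motor region,
    which lights up whichever excitor population is active.
    """
    chans = blueprint.roi_channels(side=side)
    if segments is not None:
        chans = {k: v for k, v in chans.items()
                 if _segment_of(k) in set(segments)}
    data = {"time_ms": recording.time}
    for label, cells in chans.items():
        data[label] = np.max(
            np.stack([recording.channel(c) for c in cells]), axis=0
        )
    return pd.DataFrame(data)
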