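"""Contraction events, postural-engagement states and their statistics.

Contraction events are detected per channel as prominent minima of the
Savitzky–Golay-smoothed z-scored trend (all six metrics shrink during a
contraction, so peak finding runs on the negated trend).  Events are
graded major/minor by the 70%-of-maximum rule, and frames are classified:

* DPE  — covered by temporally overlapping *major* events in all three
  informative channels (trunk area, OS width, AS width): a synchronized,
  full-body contraction;
* SePE — covered by any event span that does not meet the DPE criterion:
  a selective, partial engagement;
* StaPE — no event coverage and sub-threshold |z-trend| in all three
  informative channels: postural quiescence.

Transient bouts shorter than 2 s are merged into their longer neighbor
before any temporal statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .morphometry import INFORMATIVE_CHANNELS, TrendSeries

__all__ = [
    "ContractionEvent", "Ethogram", "TransitionMatrix",
    "detect_events", "grade_events", "classify_states", "clean_states",
    "event_kinematics", "temporal_stats", "transition_matrix",
    "state_probability_timecourse", "STATE_ORDER",
]

STATE_ORDER = ("DPE", "SePE", "StaPE")


@dataclass
class ContractionEvent:
    channel: str
    onset: int
    peak: int
    offset: int
    prominence: float
    grade: str = "major"          # {"major", "minor"}
    amplitude: float = np.nan     # µm or µm²
    contraction_speed: float = np.nan
    relaxation_speed: float = np.nan

    def __post_init__(self) -> None:
        if not self.onset < self.peak < self.offset:
            raise ValueError("event must satisfy onset < peak < offset")


@dataclass
class Ethogram:
    frame_labels: np.ndarray      # (T,) of {"DPE","SePE","StaPE"}
    fps: float
    animal_id: str = ""
    condition: str = ""
    stimulus_onset: int | None = None

    @property
    def bouts(self) -> list[tuple[str, int, int, float]]:
        """(state, start, end_exclusive, duration_s) run-length bouts."""
        out = []
        labels = self.frame_labels
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                out.append((str(labels[start]), start, i, (i - start) / self.fps))
                start = i
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bouts,
                            columns=["state", "start_frame", "end_frame", "duration_s"])


@dataclass
class TransitionMatrix:
    states: tuple
    counts: np.ndarray
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        rows = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(rows > 0, counts / rows, 0.0)
        self.counts = counts
        self.probabilities = probs


# --------------------------------------------------------------------------
# event detection

def detect_events(trend: np.ndarray, channel: str = "", *,
                  prominence: float = 0.7, min_width: int = 5,
                  sg_window: int = 11, sg_order: int = 3,
                  max_halfspan: int = 50, span_shrink: int = 18,
                  valid_bounds: tuple[int, int] | None = None,
                  ) -> list[ContractionEvent]:
    """Prominence-based minima of a smoothed z-scored trend.

    The trend is Savitzky–Golay smoothed and negated; peaks need
    prominence >= 0.7 z-units and width >= 5 frames.  Onset and offset are
    placed at the half-prominence crossings on each side of the peak,
    bounded by the nearest prominent flanking trend maximum and by
    ``max_halfspan``, then pulled in by ``span_shrink`` frames to undo the
    widening introduced by the decomposition's centered moving average.
    """
    x = np.asarray(trend, dtype=float)
    if sg_window > len(x):
        raise ValueError("Savitzky-Golay window longer than the series")
    if sg_window % 2 == 0:
        sg_window += 1
    filled = pd.Series(x).interpolate(limit_direction="both").to_numpy()
    if np.any(~np.isfinite(filled)):
        return []
    smoothed = savgol_filter(filled, sg_window, sg_order)
    neg = -smoothed
    peaks, props = find_peaks(neg, prominence=prominence, width=min_width)
    if len(peaks) == 0:
        return []
    # onset/offset: the half-prominence crossings on each side of the
    # peak (the dip's shoulders), bounded by the nearest *prominent*
    # flanking local maximum of the trend — so a run of incompletely
    # relaxed contractions yields adjacent event spans while micro-wiggles
    # inside a dip cannot truncate one — and capped at the finite
    # footprint a single contraction can have in the moving-average trend
    # (slow baseline drift cannot stretch a span indefinitely)
    left, right = peak_widths(neg, peaks, rel_height=0.5,
                              prominence_data=(props["prominences"],
                                               props["left_bases"],
                                               props["right_bases"]))[2:]
    trend_maxima = find_peaks(smoothed, prominence=prominence / 2)[0]
    lo, hi = (0, len(x) - 1) if valid_bounds is None else valid_bounds
    events = []
    for p, prom, l, r in zip(peaks, props["prominences"], left, right):
        before = trend_maxima[trend_maxima < p]
        after = trend_maxima[trend_maxima > p]
        onset = max(int(np.floor(l)), lo, p - max_halfspan,
                    int(before[-1]) if len(before) else lo)
        offset = min(int(np.ceil(r)), hi, p + max_halfspan,
                     int(after[0]) if len(after) else hi)
        # compensate the moving-average shoulder: the decomposition trend
        # widens every dip by about a third of its window on each side, so
        # the span is pulled in toward the peak by that allowance
        onset = min(p - 1, onset + span_shrink)
        offset = max(p + 1, offset - span_shrink)
        if onset < p < offset:
            events.append(ContractionEvent(channel=channel, onset=onset,
                                           peak=int(p), offset=offset,
                                           prominence=float(prom)))
    return events


def grade_events(events: list[ContractionEvent],
                 major_fraction: float = 0.70) -> list[ContractionEvent]:
    """Major/minor grading by the 70%-of-maximum-prominence rule.

    The maximum is taken over this animal's events in the channel, so a
    single event is always major.
    """
    if not events:
        return []
    max_prom = max(ev.prominence for ev in events)
    return [replace(ev, grade="major" if ev.prominence >= major_fraction * max_prom
                    else "minor") for ev in events]


# --------------------------------------------------------------------------
# state classification

def _coverage(events, T: int, major_only: bool = False) -> np.ndarray:
    cov = np.zeros(T, dtype=bool)
    for ev in events:
        if major_only and ev.grade != "major":
            continue
        cov[ev.onset:ev.offset + 1] = True
    return cov


def classify_states(events_by_channel: dict, trend: TrendSeries, *,
                    quiescence_z: float = 0.5) -> Ethogram:
    """Raw frame labels from the three informative channels.

    ``events_by_channel`` maps channel name to its graded event list.
    Frames meeting none of the three rules inherit the nearest preceding
    label (leading frames take the first assigned label).
    """
    T = trend.n_frames
    missing = [c for c in INFORMATIVE_CHANNELS if c not in events_by_channel]
    if missing:
        raise ValueError(f"events missing for informative channel(s): {missing}")
    major_cov = np.ones(T, dtype=bool)
    any_cov = np.zeros(T, dtype=bool)
    quiet = np.ones(T, dtype=bool)
    for ch in INFORMATIVE_CHANNELS:
        evs = events_by_channel[ch]
        major_cov &= _coverage(evs, T, major_only=True)
        any_cov |= _coverage(evs, T)
        z = np.asarray(trend.channels[ch], dtype=float)
        # quiescence is judged against the channel's quiescent baseline
        # (the trend median): z-scoring centers on the mean, which
        # contraction dips drag below the resting level
        baseline = np.nanmedian(z)
        quiet &= np.abs(np.nan_to_num(z, nan=np.inf) - baseline) < quiescence_z

    labels = np.empty(T, dtype=object)
    labels[:] = None
    labels[major_cov] = "DPE"
    sepe = any_cov & ~major_cov
    labels[sepe] = "SePE"
    stape = ~any_cov & quiet
    labels[stape] = "StaPE"
    # nearest preceding label; leading gap takes the first assigned label
    last = None
    first = next((l for l in labels if l is not None), "StaPE")
    for i in range(T):
        if labels[i] is None:
            labels[i] = last if last is not None else first
        else:
            last = labels[i]
    return Ethogram(frame_labels=labels, fps=trend.fps,
                    animal_id=trend.animal_id, condition=trend.condition,
                    stimulus_onset=trend.stimulus_onset)


def clean_states(ethogram: Ethogram, min_bout_s: float = 2.0) -> Ethogram:
    """Merge transient bouts (< 2 s) into the longer adjacent bout.

    The shortest offending bout is absorbed first (leftmost on ties); the
    absorbing neighbor is the longer one (preceding on ties).  Repeats
    until no interior bout is below threshold; a short bout at a record
    edge with a single neighbor is absorbed into it.
    """
    min_frames = min_bout_s * ethogram.fps
    runs = [[s, b - a] for s, a, b, _ in ethogram.bouts]
    while True:
        short = [(length, i) for i, (_, length) in enumerate(runs)
                 if length < min_frames]
        if not short or len(runs) == 1:
            break
        _, i = min(short, key=lambda t: (t[0], t[1]))
        left = runs[i - 1][1] if i > 0 else -1
        right = runs[i + 1][1] if i < len(runs) - 1 else -1
        target = i - 1 if left >= right else i + 1
        runs[target][1] += runs[i][1]
        del runs[i]
        # merge neighbors that became identical
        j = 1
        while j < len(runs):
            if runs[j][0] == runs[j - 1][0]:
                runs[j - 1][1] += runs[j][1]
                del runs[j]
            else:
                j += 1
    labels = np.empty(len(ethogram.frame_labels), dtype=object)
    pos = 0
    for state, length in runs:
        labels[pos:pos + length] = state
        pos += length
    return Ethogram(frame_labels=labels, fps=ethogram.fps,
                    animal_id=ethogram.animal_id, condition=ethogram.condition,
                    stimulus_onset=ethogram.stimulus_onset)


# --------------------------------------------------------------------------
# kinematics and temporal statistics

def event_kinematics(event: ContractionEvent, metric: np.ndarray,
                     fps: float) -> ContractionEvent:
    """Amplitude (µm or µm²) and contraction/relaxation speeds of an event.

    amplitude = metric(onset) − metric(peak), positive for a contraction;
    speeds divide by the respective segment duration in seconds.
    """
    m = np.asarray(metric, dtype=float)
    amp = m[event.onset] - m[event.peak]
    dt_c = (event.peak - event.onset) / fps
    dt_r = (event.offset - event.peak) / fps
    c_speed = amp / dt_c if dt_c > 0 else np.nan
    r_speed = (m[event.offset] - m[event.peak]) / dt_r if dt_r > 0 else np.nan
    return replace(event, amplitude=float(amp),
                   contraction_speed=float(c_speed),
                   relaxation_speed=float(r_speed))


def temporal_stats(ethogram: Ethogram, window_s: float | None = None) -> dict:
    """Per-state bout durations, inter-state intervals and frequencies.

    Frequency is bouts per minute over the analysis window (the labeled
    recording length unless ``window_s`` is given).  Also returns the
    empirical survival function of bout durations per state.
    """
    bouts = ethogram.bouts
    total_s = window_s if window_s is not None else len(ethogram.frame_labels) / ethogram.fps
    stats: dict = {}
    for state in STATE_ORDER:
        sb = [(a, b, d) for s, a, b, d in bouts if s == state]
        durations = np.array([d for _, _, d in sb])
        isi = np.array([(sb[i + 1][0] - sb[i][1]) / ethogram.fps
                        for i in range(len(sb) - 1)])
        if len(durations):
            ts = np.sort(durations)
            survival = (ts, 1.0 - np.arange(1, len(ts) + 1) / len(ts))
        else:
            survival = (np.array([]), np.array([]))
        stats[state] = {
            "durations_s": durations,
            "isi_s": isi,
            "n_bouts": len(durations),
            "frequency_per_min": 60.0 * len(durations) / total_s if total_s > 0 else 0.0,
            "survival": survival,
        }
    return stats


def transition_matrix(ethogram: Ethogram,
                      states: tuple = STATE_ORDER) -> TransitionMatrix:
    """Bout-to-bout transition counts and row-normalized probabilities.

    Self-transitions cannot occur at the bout level (consecutive bouts
    differ by construction), so the diagonal is zero.
    """
    bouts = ethogram.bouts
    if len(bouts) < 2:
        return TransitionMatrix(states=states,
                                counts=np.zeros((len(states), len(states))))
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for (s1, *_), (s2, *_) in zip(bouts[:-1], bouts[1:]):
        counts[index[s1], index[s2]] += 1
    return TransitionMatrix(states=states, counts=counts)


def pool_transitions(ethograms: list[Ethogram],
                     states: tuple = STATE_ORDER) -> TransitionMatrix:
    """Cohort-pooled bout-to-bout transition matrix."""
    counts = np.zeros((len(states), len(states)))
    for eth in ethograms:
        counts += transition_matrix(eth, states).counts
    return TransitionMatrix(states=states, counts=counts)


def state_probability_timecourse(ethograms: list[Ethogram],
                                 bin_width_s: float = 30.0,
                                 align_to_onset: bool = True) -> pd.DataFrame:
    """Fraction of animals per state over time, mean ± SEM across animals.

    With ``align_to_onset``, time 0 is each recording's stimulus-onset
    frame (recordings without an onset align to frame 0).  Returns a tidy
    frame (time_s, state, mean, sem, n).
    """
    fps = {eth.fps for eth in ethograms}
    if len(fps) != 1:
        raise ValueError("all recordings must share one sampling rate")
    fps = fps.pop()
    bin_frames = max(1, int(round(bin_width_s * fps)))

    rel_ranges = []
    for eth in ethograms:
        onset = eth.stimulus_onset if (align_to_onset and eth.stimulus_onset is not None) else 0
        rel_ranges.append((-onset, len(eth.frame_labels) - onset))
    lo = min(r[0] for r in rel_ranges)
    hi = max(r[1] for r in rel_ranges)
    edges = np.arange(lo, hi + bin_frames, bin_frames)

    rows = []
    for b in range(len(edges) - 1):
        fracs = {s: [] for s in STATE_ORDER}
        for eth, (r0, _) in zip(ethograms, rel_ranges):
            a = max(edges[b] - r0, 0)
            bnd = min(edges[b + 1] - r0, len(eth.frame_labels))
            if bnd <= a:
                continue
            seg = eth.frame_labels[a:bnd]
            for s in STATE_ORDER:
                fracs[s].append(np.mean(seg == s))
        n = len(fracs[STATE_ORDER[0]])
        if n == 0:
            continue
        for s in STATE_ORDER:
            vals = np.asarray(fracs[s])
            sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows.append({"time_s": edges[b] / fps, "state": s,
                         "mean": vals.mean(), "sem": sem, "n": n})
    return pd.DataFrame(rows)
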