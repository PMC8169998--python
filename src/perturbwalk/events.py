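"""Touchdown and toe-off detection from force plates, with a marker fallback.

The primary detector thresholds each belt's vertical ground-reaction force:
touchdown is an upward crossing of the threshold sustained for at least
``min_contact`` seconds; toe-off is the corresponding downward crossing.
Brief dropouts shorter than the debounce window are merged into the
surrounding contact.

The fallback detector uses the anteroposterior hallux extrema: on a
treadmill the foot is carried backward during stance and swung forward
during swing, so the hallux AP maximum marks touchdown and the minimum
marks toe-off.  It is preferred for the perturbed side when cross-belt
stepping makes the force signal ambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .preprocessing import FilterSpec, butterworth_zero_phase

__all__ = [
    "GaitEvents",
    "detect_events_force",
    "detect_events_marker",
    "reconcile_events",
]

log = logging.getLogger(__name__)

_OTHER = {"L": "R", "R": "L"}


@dataclass
class GaitEvents:
    """Ordered touchdown / toe-off instants with foot side ('L' or 'R')."""

    touchdowns: list = field(default_factory=list)  # [(time, side), ...]
    toeoffs: list = field(default_factory=list)

    def td_times(self, side: str | None = None) -> np.ndarray:
        return np.array(
            [t for t, s in self.touchdowns if side is None or s == side], dtype=float
        )

    def td_sides(self) -> list:
        return [s for _, s in self.touchdowns]

    def to_times(self, side: str | None = None) -> np.ndarray:
        return np.array(
            [t for t, s in self.toeoffs if side is None or s == side], dtype=float
        )

    def toeoff_after(self, t: float, side: str) -> float:
        """First toe-off of ``side`` at or after time ``t`` (raises if none)."""
        times = self.to_times(side)
        later = times[times >= t]
        if later.size == 0:
            raise ValueError(f"no {side} toe-off after t={t:.3f} s")
        return float(later[0])

    def validate(self, max_stance: float = 2.0) -> None:
        """Check ordering, alternation and stance-duration invariants."""
        td = self.touchdowns
        for seq, name in ((td, "touchdowns"), (self.toeoffs, "toeoffs")):
            times = [t for t, _ in seq]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} not strictly increasing")
        for (t0, s0), (t1, s1) in zip(td, td[1:]):
            if s0 == s1:
                raise ValueError(
                    f"consecutive {s0} touchdowns at {t0:.3f} and {t1:.3f} s"
                )
        for t, s in td:
            later = [tt for tt, ss in self.toeoffs if ss == s and tt > t]
            if later:
                stance = later[0] - t
                if not (0.0 < stance < max_stance):
                    raise ValueError(
                        f"stance of {stance:.3f} s at t={t:.3f} s out of range"
                    )

    def merged_sorted(self) -> "GaitEvents":
        return GaitEvents(
            touchdowns=sorted(self.touchdowns), toeoffs=sorted(self.toeoffs)
        )


def _contact_segments(
    above: np.ndarray, rate: float, min_contact: float, debounce: float
) -> list:
    """(start, end) index pairs of sustained above-threshold contact."""
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    # merge contacts separated by gaps shorter than the debounce window
    merged = [[starts[0], ends[0]]]
    gap = int(round(debounce * rate))
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = int(round(min_contact * rate))
    return [(s, e) for s, e in merged if e - s >= min_len]


def _cross_time(
    f: np.ndarray, time: np.ndarray, i: int, threshold: float, rising: bool
) -> float:
    """Linear-interpolated threshold-crossing time at segment edge index i."""
    if rising:
        if i == 0:
            return float(time[0])
        f0, f1 = f[i - 1], f[i]
        t0, t1 = time[i - 1], time[i]
    else:
        if i >= len(f):
            return float(time[-1])
        f0, f1 = f[i - 1], f[i]
        t0, t1 = time[i - 1], time[i]
    if f1 == f0:
        return float(t1)
    frac = (threshold - f0) / (f1 - f0)
    return float(t0 + np.clip(frac, 0.0, 1.0) * (t1 - t0))


def detect_events_force(
    forces,
    rate: float = 1000.0,
    threshold: float = 50.0,
    min_contact: float = 0.02,
    debounce: float = 0.05,
    t0: float = 0.0,
) -> GaitEvents:
    """Detect gait events from per-belt vertical forces ``{'L': ..., 'R': ...}``.

    A contact that is already loaded at the first sample yields no touchdown
    (only its toe-off), and symmetrically at the end of the record.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    events = GaitEvents()
    any_contact = False
    for side in ("L", "R"):
        f = np.asarray(forces[side], dtype=float)
        time = t0 + np.arange(f.size) / rate
        segs = _contact_segments(f >= threshold, rate, min_contact, debounce)
        if segs:
            any_contact = True
        for s, e in segs:
            if s > 0:
                events.touchdowns.append(
                    (_cross_time(f, time, s, threshold, rising=True), side)
                )
            if e < f.size:
                events.toeoffs.append(
                    (_cross_time(f, time, e, threshold, rising=False), side)
                )
    if not any_contact:
        warnings.warn("no force contact above threshold; returning empty events")
    return events.merged_sorted()


def detect_events_marker(
    session, filter_spec: FilterSpec | None = None, min_cycles: int = 2
) -> GaitEvents:
    """Detect events from hallux AP extrema (maxima = touchdown, minima = toe-off)."""
    events = GaitEvents()
    rate = session.sampling_rate_markers
    for side, label in (("L", "LHLX"), ("R", "RHLX")):
        x = butterworth_zero_phase(
            session.markers[label][:, 0], filter_spec or FilterSpec(), rate
        )
        span = np.percentile(x, 95) - np.percentile(x, 5)
        if span < 1e-4:
            raise ValueError(f"no gait cycles detectable on side {side}")
        prominence = 0.25 * span
        min_dist = int(0.4 * rate)  # two same-side events > ~0.4 s apart
        peaks, _ = find_peaks(x, prominence=prominence, distance=min_dist)
        troughs, _ = find_peaks(-x, prominence=prominence, distance=min_dist)
        if len(peaks) < min_cycles:
            raise ValueError(
                f"only {len(peaks)} gait cycles detected on side {side} "
                f"(need >= {min_cycles})"
            )
        for i in peaks:
            events.touchdowns.append((float(session.time[i]), side))
        for i in troughs:
            events.toeoffs.append((float(session.time[i]), side))
    return events.merged_sorted()


def reconcile_events(
    primary: GaitEvents, fallback: GaitEvents, match_tol: float = 0.05
) -> GaitEvents:
    """Merge force (primary) and marker (fallback) event streams.

    Fallback touchdowns are inserted only where they restore the left/right
    alternation the primary stream is missing; fallback events that would
    break alternation are dropped and logged.
    """
    merged = [list(e) for e in sorted(primary.touchdowns)]
    for t, s in sorted(fallback.touchdowns):
        near = any(abs(t - mt) < match_tol for mt, _ in merged)
        if near:
            continue
        candidate = sorted(merged + [[t, s]])
        i = candidate.index([t, s])
        ok = True
        if i > 0 and candidate[i - 1][1] == s:
            ok = False
        if i < len(candidate) - 1 and candidate[i + 1][1] == s:
            ok = False
        if ok:
            merged = candidate
        else:
            log.info("dropping marker touchdown (%s, %.3f s): breaks alternation", s, t)
    # drop any residual alternation violations, preferring the earlier event
    cleaned = []
    for t, s in merged:
        if cleaned and cleaned[-1][1] == s:
            log.info("dropping touchdown (%s, %.3f s): duplicate side", s, t)
            continue
        cleaned.append([t, s])
    toeoffs = sorted(set(tuple(e) for e in primary.toeoffs + fallback.toeoffs))
    # toe-offs: keep primary; add fallback ones not near a primary same-side event
    to_merged = sorted(primary.toeoffs)
    for t, s in sorted(fallback.toeoffs):
        if not any(abs(t - mt) < match_tol and ms == s for mt, ms in to_merged):
            to_merged = sorted(to_merged + [(t, s)])
    return GaitEvents(
        touchdowns=[(t, s) for t, s in cleaned], toeoffs=to_merged
    )
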