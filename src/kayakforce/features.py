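"""The five leg-force characteristics of a processed bout.

For each paddler-bout the analysis reports velocity plus five force
characteristics: stroke rate (peaks counted on both sides), mean push
force, peak push force, force impulse over one stroke cycle, and force
impulse over 10 s.  Impulses use trapezoidal integration and sum the
left and right channels; mean force averages the two channels (so that
twice the mean force times the cycle duration equals the per-cycle
impulse); peak force is the mean over analysed cycles of each cycle's
per-side maxima, both sides pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ForceTrace, VelocityTrace, FeatureRecord, InsufficientDataError
from .preprocess import (
    PeakSet,
    StrokeCycle,
    detect_peaks,
    lowpass_filter,
    segment_cycles,
    select_cycles,
)

__all__ = [
    "AnalysisWindow",
    "stroke_rate",
    "mean_force",
    "peak_force",
    "impulse",
    "extract_features",
]

WINDOW_RULES = ("first-10s", "last-10s", "explicit")


@dataclass(frozen=True)
class AnalysisWindow:
    """A fixed-length time window of a bout, in seconds from bout start."""

    start: float
    end: float
    rule: str = "explicit"

    def __post_init__(self) -> None:
        if self.rule not in WINDOW_RULES:
            raise ValueError(f"unknown window rule {self.rule!r}")
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} must exceed start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @classmethod
    def from_rule(cls, trace: ForceTrace, rule: str = "last-10s",
                  length: float = 10.0) -> "AnalysisWindow":
        """Place a ``length``-second window at the start or end of a trace."""
        t0, t1 = float(trace.time[0]), float(trace.time[-1])
        if t1 - t0 < length:
            raise InsufficientDataError(
                f"trace spans {t1 - t0:.3f} s, shorter than the "
                f"{length} s analysis window"
            )
        if rule == "first-10s":
            return cls(t0, t0 + length, rule=rule)
        if rule == "last-10s":
            return cls(t1 - length, t1, rule=rule)
        raise ValueError(f"rule must be 'first-10s' or 'last-10s', got {rule!r}")


def stroke_rate(peaks: PeakSet, window: AnalysisWindow) -> float:
    """Strokes per minute: left + right peaks in the window, per minute."""
    if window.duration <= 0:
        raise ValueError("zero-length analysis window")
    n = peaks.count_in_window(window.start, window.end)
    return n * 60.0 / window.duration


def mean_force(trace: ForceTrace, window: AnalysisWindow) -> float:
    """Time-average of (left + right) / 2 over the analysis window."""
    mask = (trace.time >= window.start) & (trace.time <= window.end)
    if not mask.any():
        raise InsufficientDataError("analysis window contains no samples")
    return float(np.mean(0.5 * (trace.left[mask] + trace.right[mask])))


def peak_force(cycles: list[StrokeCycle]) -> float:
    """Mean over cycles of each cycle's per-side maxima, both sides pooled."""
    if not cycles:
        raise InsufficientDataError("no stroke cycles for peak force")
    maxima = []
    for cyc in cycles:
        maxima.append(float(np.max(cyc.left)))
        maxima.append(float(np.max(cyc.right)))
    return float(np.mean(maxima))


def impulse(trace: ForceTrace, start: float, end: float) -> float:
    """Trapezoid-rule force impulse (N·s), left + right summed.

    ``start`` and ``end`` are times in seconds and must lie within the
    trace.  Integration runs over the samples inside [start, end].
    """
    if end <= start:
        raise ValueError(f"interval end {end} must exceed start {start}")
    if start < trace.time[0] - 1e-9 or end > trace.time[-1] + 1e-9:
        raise ValueError(
            f"interval [{start}, {end}] s outside trace span "
            f"[{trace.time[0]}, {trace.time[-1]}] s"
        )
    mask = (trace.time >= start - 1e-12) & (trace.time <= end + 1e-12)
    t = trace.time[mask]
    if len(t) < 2:
        raise InsufficientDataError("interval contains fewer than 2 samples")
    return float(np.trapezoid(trace.left[mask], t)
                 + np.trapezoid(trace.right[mask], t))


def cycle_impulse(trace: ForceTrace, cycles: list[StrokeCycle]) -> float:
    """Mean per-cycle impulse (N·s) over the analysed cycles."""
    if not cycles:
        raise InsufficientDataError("no stroke cycles for cycle impulse")
    vals = [
        impulse(trace, cyc.start / cyc.sampling_rate, cyc.end / cyc.sampling_rate)
        for cyc in cycles
    ]
    return float(np.mean(vals))


def extract_features(
    trace: ForceTrace,
    velocity_trace: VelocityTrace | None = None,
    *,
    paddler_id: str = "P00000",
    group: str = "senior men",
    bout: str = "maximal",
    cutoff_hz: float = 20.0,
    filter_order: int = 4,
    min_separation: float | None = None,
    min_prominence: float | None = None,
    n_cycles: int = 15,
    window_rule: str = "last-10s",
    window: AnalysisWindow | None = None,
    velocity_kmh: float | None = None,
) -> FeatureRecord:
    """Run the full descriptive chain on one bout and return its record.

    Filters the raw trace, detects per-side peaks, segments left-anchored
    cycles, selects the analysed cycles (last ``n_cycles`` by default),
    places the 10-s analysis window (last 10 s by default), and computes
    the five force characteristics.  Velocity is the mean of the velocity
    trace over the analysis window, or ``velocity_kmh`` if given directly.
    """
    filtered = lowpass_filter(trace, cutoff=cutoff_hz, order=filter_order)
    peaks = detect_peaks(filtered, min_separation=min_separation,
                         min_prominence=min_prominence)
    if peaks.n_total == 0:
        raise InsufficientDataError("no push peaks detected: no strokes in trace")
    cycles = segment_cycles(peaks, filtered)
    analysed = select_cycles(cycles, n_cycles=n_cycles)

    if window is None:
        window = AnalysisWindow.from_rule(filtered, rule=window_rule)

    if velocity_kmh is None:
        if velocity_trace is None:
            raise ValueError("provide either velocity_trace or velocity_kmh")
        velocity_kmh = velocity_trace.mean_over(window.start, window.end)

    return FeatureRecord(
        paddler_id=paddler_id,
        group=group,
        bout=bout,
        velocity_kmh=float(velocity_kmh),
        stroke_rate_spm=stroke_rate(peaks, window),
        mean_force_n=mean_force(filtered, window),
        peak_force_n=peak_force(analysed),
        impulse_cycle_ns=cycle_impulse(filtered, analysed),
        impulse_10s_ns=impulse(filtered, window.start, window.end),
    )
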