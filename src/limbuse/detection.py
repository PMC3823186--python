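"""Movement-event detection from smoothed tri-axial accelerometry.

The processing chain mirrors how habitual limb use is quantified from
wrist/upper-arm activity monitors in one-handed cohorts:

1. each axis is smoothed with a 500 ms centred moving average to discard
   high-frequency noise;
2. the range (max − min) of each axis is computed within a 400 ms sliding
   window, stride one sample;
3. a movement is a maximal run of window positions whose range exceeds
   0.2 m/s² on at least one axis, accepted only if it is immediately
   preceded and followed by a quiescent period — windows whose range is
   below threshold on *all* axes.

The range statistic cancels any constant offset (gravity, sensor bias),
so detection is offset-invariant per axis.  Windows are evaluated only
where they lie fully inside the trace; no padding is applied, because
padded samples would fabricate quiescence at the edges.

The quiescence duration, kernel shape and window stride are not part of
the published description; the defaults here (400 ms quiescence, boxcar
kernel, stride 1) are documented choices exposed as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .io import AccelTrace, ValidationError

__all__ = [
    "DetectorParams",
    "MovementEvent",
    "smooth_trace",
    "window_ranges",
    "detect_movements",
    "count_movements",
]

logger = logging.getLogger(__name__)

AXIS_NAMES = ("x", "y", "z")


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detector parameters (durations in ms, threshold in m/s²)."""

    smooth_ms: float = 500.0
    window_ms: float = 400.0
    threshold: float = 0.2
    quiescence_ms: float = 400.0

    def __post_init__(self) -> None:
        for name in ("smooth_ms", "window_ms", "quiescence_ms"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.threshold > 0:
            raise ValidationError(f"threshold must be > 0, got {self.threshold}")

    def smooth_span(self, sample_rate: float) -> int:
        """Smoothing kernel span in samples (≥ 1)."""
        return max(1, int(round(self.smooth_ms * sample_rate / 1000.0)))

    def window_span(self, sample_rate: float) -> int:
        span = int(round(self.window_ms * sample_rate / 1000.0))
        if span < 2:
            raise ValidationError(
                f"window_ms={self.window_ms} spans {span} sample(s) at "
                f"{sample_rate} Hz; at least 2 are required"
            )
        return span

    def quiescence_span(self, sample_rate: float) -> int:
        return max(1, int(round(self.quiescence_ms * sample_rate / 1000.0)))


@dataclass(frozen=True)
class MovementEvent:
    """A detected movement over a half-open sample interval.

    ``per_axis_range`` is max − min per axis within the event span;
    ``triggering_axes`` is the subset of axes whose window range exceeded
    the threshold somewhere in the run.
    """

    start_sample: int
    end_sample: int
    per_axis_range: tuple[float, float, float]
    triggering_axes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.start_sample < self.end_sample:
            raise ValidationError("event must satisfy start_sample < end_sample")
        if not self.triggering_axes:
            raise ValidationError("event must have at least one triggering axis")

    def interval_s(self, sample_rate: float) -> tuple[float, float]:
        return self.start_sample / sample_rate, self.end_sample / sample_rate


def smooth_trace(trace: AccelTrace, params: DetectorParams) -> AccelTrace:
    """Centred moving average per axis; output length equals input length.

    The nominal kernel spans ``smooth_ms``.  Near the edges the window
    shrinks symmetrically (half-width ``min(h, i, n-1-i)``), so a constant
    trace is reproduced exactly and no samples are fabricated.
    """
    n = trace.n_samples
    span = params.smooth_span(trace.sample_rate)
    if span > n:
        raise ValidationError(f"smoothing kernel ({span} samples) exceeds trace length ({n})")
    half = span // 2
    if half == 0:
        return trace
    idx = np.arange(n)
    m = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.vstack([np.zeros((1, 3)), np.cumsum(trace.data, axis=0)])
    out = (csum[idx + m + 1] - csum[idx - m]) / (2 * m + 1)[:, None]
    return trace.replace_data(out)


def window_ranges(trace: AccelTrace, params: DetectorParams) -> np.ndarray:
    """Per-axis max − min within every fully-interior sliding window.

    Returns an array of shape ``(n_samples - span + 1, 3)``; row ``j`` is
    the range of the window starting at sample ``j`` (stride 1).
    """
    w = params.window_span(trace.sample_rate)
    n = trace.n_samples
    if w > n:
        raise ValidationError(f"window span ({w} samples) exceeds trace length ({n})")
    # maximum_filter1d with default origin puts window start at i - w//2;
    # slicing at offset w//2 realigns output row j to window start j.
    mx = maximum_filter1d(trace.data, size=w, axis=0, mode="nearest")
    mn = minimum_filter1d(trace.data, size=w, axis=0, mode="nearest")
    lo = w // 2
    sel = slice(lo, lo + n - w + 1)
    return mx[sel] - mn[sel]


def detect_movements(trace: AccelTrace, params: DetectorParams) -> list[MovementEvent]:
    """Threshold-and-quiescence event detection on a *smoothed* trace.

    A candidate event is a maximal run of consecutive window positions
    whose range exceeds ``threshold`` on ≥ 1 axis.  It is accepted iff the
    ``quiescence_ms`` interval immediately before its first supra-threshold
    window and immediately after its last one lies inside the trace and
    contains only windows with range strictly below threshold on all axes.
    Accepted events are disjoint and ordered; each spans its run plus the
    window span of the last position.
    """
    fs = trace.sample_rate
    w = params.window_span(fs)
    q = params.quiescence_span(fs)
    n = trace.n_samples
    if n < w + 2 * q:
        logger.warning(
            "trace of %d samples is shorter than window + 2*quiescence (%d); "
            "no event can satisfy the quiescence condition",
            n,
            w + 2 * q,
        )
        return []
    ranges = window_ranges(trace, params)
    above = ranges > params.threshold  # per position, per axis
    above_any = above.any(axis=1)
    quiet_all = (ranges < params.threshold).all(axis=1)
    n_pos = ranges.shape[0]

    events: list[MovementEvent] = []
    # maximal runs of above_any
    padded = np.concatenate([[False], above_any, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1  # inclusive last position of each run
    for f, l in zip(starts, ends):
        if f - q < 0 or l + q > n_pos - 1:
            continue
        if not quiet_all[f - q : f].all():
            continue
        if not quiet_all[l + 1 : l + q + 1].all():
            continue
        seg = trace.data[f : l + w]
        rng = seg.max(axis=0) - seg.min(axis=0)
        trig = tuple(AXIS_NAMES[a] for a in range(3) if above[f : l + 1, a].any())
        events.append(
            MovementEvent(
                start_sample=int(f),
                end_sample=int(l + w),
                per_axis_range=(float(rng[0]), float(rng[1]), float(rng[2])),
                triggering_axes=trig,
            )
        )
    return events


def count_movements(trace: AccelTrace, params: DetectorParams | None = None) -> int:
    """Full-chain movement count for one limb: smooth → detect → count.

    Convenience wrapper used by the usage pipeline; accepts a *raw* trace.
    """
    params = params or DetectorParams()
    return len(detect_movements(smooth_trace(trace, params), params))
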