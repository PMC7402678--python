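"""dF/F conversion, baseline estimation, event detection, microdomain stats.

The baseline F0 of a trace is the 25th percentile (linear interpolation)
over all frames of a centred 100 s moving-window average of the raw
fluorescence, with shrinking windows at the edges.  dF/F = (F - F0)/F0.
A calcium transient is a run of frames whose dF/F exceeds three times
the baseline standard deviation; "baseline" frames are the frames whose
moving-average F lies at or below that 25th percentile (the same frames
that determine F0), which keeps the noise estimate uncontaminated by
transients.  The signal area is the sum of every suprathreshold dF/F
sample times the frame interval (the suprathreshold values themselves
are summed, not their excess over the threshold); a microdomain is
"active" when its signal area reaches 5 dF/F*s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rois import Roi
from .stack import ImageStack

__all__ = ["CalciumTrace", "CalciumEvent", "MicrodomainStats", "extract_trace",
           "moving_average", "estimate_baseline", "estimate_baseline_manual",
           "make_trace", "detect_events", "signal_area", "summarize_microdomain",
           "events_to_frame", "stats_to_frame"]

DEFAULT_BASELINE_WINDOW_S = 100.0
DEFAULT_SD_MULTIPLE = 3.0
DEFAULT_ACTIVE_THRESHOLD = 5.0     # dF/F * s
MANUAL_BASELINE_FRAMES = 200


@dataclass
class CalciumTrace:
    roi_id: str
    F: np.ndarray
    F0: float
    dff: np.ndarray
    sigma_baseline: float
    threshold: float
    frame_rate_hz: float
    baseline_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    kind: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.F)), "F": self.F, "dff": self.dff}
        )


@dataclass(frozen=True)
class CalciumEvent:
    roi_id: str
    onset_frame: int
    offset_frame: int          # inclusive
    peak_frame: int
    peak_dff: float
    area: float                # dF/F * s over the event's suprathreshold frames


@dataclass(frozen=True)
class MicrodomainStats:
    roi_id: str
    kind: str | None
    signal_area: float
    max_amplitude: float
    active: bool
    n_events: int


def extract_trace(stack: ImageStack, roi: Roi) -> np.ndarray:
    """Mean intensity over the ROI mask at each frame."""

    if roi.mask.shape != stack.data.shape[1:]:
        raise ValueError("ROI mask shape does not match stack frames")
    if not roi.mask.any():
        raise ValueError("empty ROI mask")
    return stack.data[:, roi.mask].mean(axis=1).astype(np.float64)


def moving_average(F: np.ndarray, window_frames: int) -> np.ndarray:
    """Centred moving average with shrinking (truncated) edge windows.

    Frame i averages F over [i - (w-1)//2, i + w//2], clipped to the
    trace; no values are fabricated at the boundaries.
    """

    F = np.asarray(F, dtype=np.float64)
    n = len(F)
    w = int(window_frames)
    if w < 1:
        raise ValueError("window must be >= 1 frame")
    half_lo, half_hi = (w - 1) // 2, w // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_lo)
    hi = np.minimum(n, idx + half_hi + 1)
    csum = np.concatenate([[0.0], np.cumsum(F)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def _baseline_from_smoothed(F, smoothed, baseline_mode: str):
    q25 = float(np.percentile(smoothed, 25))
    if baseline_mode == "lower_quartile":
        frames = np.nonzero(smoothed <= q25)[0]
    elif baseline_mode == "below_median":
        frames = np.nonzero(smoothed < np.median(smoothed))[0]
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if frames.size == 0:  # constant trace: every frame is baseline
        frames = np.arange(len(F))
    return q25, frames


def estimate_baseline(
    F: np.ndarray,
    frame_rate_hz: float,
    window_s: float = DEFAULT_BASELINE_WINDOW_S,
) -> float:
    """F0 = 25th percentile, across all frames, of the 100 s moving average."""

    F = np.asarray(F, dtype=np.float64)
    w = max(1, round(window_s * frame_rate_hz))
    if len(F) < w:
        raise ValueError(f"trace shorter than the {window_s} s baseline window")
    f0 = float(np.percentile(moving_average(F, w), 25))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0}; trace unusable for dF/F")
    return f0


def estimate_baseline_manual(F: np.ndarray, quiet_range: tuple[int, int]) -> float:
    """F0 from a user-selected 200-frame quiet period: its 25th percentile.

    Used when global activity (seizures, calcium waves) contaminates the
    moving-window estimate; no smoothing is applied.
    """

    F = np.asarray(F, dtype=np.float64)
    start, stop = quiet_range
    if stop - start != MANUAL_BASELINE_FRAMES:
        raise ValueError(
            f"quiet_range must span exactly {MANUAL_BASELINE_FRAMES} frames, "
            f"got {stop - start}"
        )
    if start < 0 or stop > len(F):
        raise ValueError("quiet_range outside the recording")
    f0 = float(np.percentile(F[start:stop], 25))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0}")
    return f0


def make_trace(
    roi_id: str,
    F: np.ndarray,
    frame_rate_hz: float,
    baseline: str = "moving",                 # "moving" | "manual"
    window_s: float = DEFAULT_BASELINE_WINDOW_S,
    quiet_range: tuple[int, int] | None = None,
    sd_multiple: float = DEFAULT_SD_MULTIPLE,
    baseline_mode: str = "lower_quartile",    # or "below_median"
    kind: str | None = None,
) -> CalciumTrace:
    """Build a dF/F trace with its event threshold (sd_multiple x sigma)."""

    F = np.asarray(F, dtype=np.float64)
    if baseline == "moving":
        w = max(1, round(window_s * frame_rate_hz))
        if len(F) < w:
            raise ValueError("trace shorter than the baseline window")
        smoothed = moving_average(F, w)
        f0, frames = _baseline_from_smoothed(F, smoothed, baseline_mode)
    elif baseline == "manual":
        if quiet_range is None:
            raise ValueError("manual baseline requires quiet_range")
        f0 = estimate_baseline_manual(F, quiet_range)
        frames = np.arange(quiet_range[0], quiet_range[1])
    else:
        raise ValueError(f"unknown baseline method {baseline!r}")
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0={f0}; trace unusable for dF/F")
    dff = (F - f0) / f0
    sigma = float(np.std(dff[frames]))
    return CalciumTrace(
        roi_id=roi_id,
        F=F,
        F0=float(f0),
        dff=dff,
        sigma_baseline=sigma,
        threshold=sd_multiple * sigma,
        frame_rate_hz=frame_rate_hz,
        baseline_frames=frames,
        kind=kind,
    )


def detect_events(
    trace: CalciumTrace,
    min_duration_frames: int = 2,
    merge_gap_frames: int = 0,
) -> list[CalciumEvent]:
    """Maximal runs of contiguous frames with dF/F above the threshold.

    Runs shorter than ``min_duration_frames`` are discarded (single-frame
    threshold crossings at 1 Hz are indistinguishable from shot noise);
    runs separated by at most ``merge_gap_frames`` subthreshold frames
    can optionally be merged (default: strict contiguity, no merging).
    """

    above = trace.dff > trace.threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1          # inclusive
    if merge_gap_frames > 0 and len(starts) > 1:
        merged = [[starts[0], ends[0]]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] - 1 <= merge_gap_frames:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
    dt = 1.0 / trace.frame_rate_hz
    events = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_duration_frames:
            continue
        seg = trace.dff[s : e + 1]
        sup = seg > trace.threshold
        peak_rel = int(np.argmax(seg))
        events.append(
            CalciumEvent(
                roi_id=trace.roi_id,
                onset_frame=int(s),
                offset_frame=int(e),
                peak_frame=int(s + peak_rel),
                peak_dff=float(seg[peak_rel]),
                area=float(seg[sup].sum() * dt),
            )
        )
    return events


def signal_area(trace: CalciumTrace) -> float:
    """Sum of every suprathreshold dF/F sample times the frame interval."""

    sup = trace.dff > trace.threshold
    return float(trace.dff[sup].sum() / trace.frame_rate_hz)


def summarize_microdomain(
    trace: CalciumTrace,
    events: list[CalciumEvent],
    active_threshold: float = DEFAULT_ACTIVE_THRESHOLD,
) -> MicrodomainStats:
    """Whole-recording stats; active iff signal_area >= active_threshold."""

    area = signal_area(trace)
    return MicrodomainStats(
        roi_id=trace.roi_id,
        kind=trace.kind,
        signal_area=area,
        max_amplitude=float(np.max(trace.dff)) if len(trace.dff) else 0.0,
        active=bool(area >= active_threshold),
        n_events=len(events),
    )


def events_to_frame(events: list[CalciumEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"roi_id": e.roi_id, "onset": e.onset_frame, "offset": e.offset_frame,
             "peak_frame": e.peak_frame, "peak_dff": e.peak_dff, "area": e.area}
            for e in events
        ],
        columns=["roi_id", "onset", "offset", "peak_frame", "peak_dff", "area"],
    )


def stats_to_frame(stats: list[MicrodomainStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"roi_id": s.roi_id, "kind": s.kind, "signal_area": s.signal_area,
             "max_amplitude": s.max_amplitude, "active": s.active,
             "n_events": s.n_events}
            for s in stats
        ],
        columns=["roi_id", "kind", "signal_area", "max_amplitude", "active", "n_events"],
    )
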