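"""Calcium-motility association: activity by motility class, nearest-event
latency, latency-bin fractions, and cohort-level tables.

Latency analysis: for each extending/retracting process, the calcium
events with peak dF/F >= 0.5 are searched for the nearest event peak
before and after the motility start; the smaller absolute latency is
binned into nested <30 s / <60 s / <120 s windows.  Processes with no
qualifying event stay in the bin denominators (fractions are "of all
processes of that class").  Group-level inferential statistics are out
of scope: outputs are counts, proportions, and mean +/- SEM tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motility import MotilityEvent
from .traces import CalciumEvent, MicrodomainStats

__all__ = ["LatencyRecord", "ClassActivity", "AssociationSummary",
           "activity_by_motility_class", "nearest_event_latency",
           "bin_latency_fractions", "latency_records_to_frame"]

QUALIFYING_PEAK_DFF = 0.5
LATENCY_BINS_S = (30.0, 60.0, 120.0)


@dataclass
class LatencyRecord:
    roi_id: str
    motility_class: str
    motility_start_frame: int
    nearest_before_s: float | None
    nearest_after_s: float | None
    nearest_abs_s: float | None
    bins: dict[str, bool] = field(default_factory=dict)


@dataclass
class ClassActivity:
    n_processes: int
    n_with_calcium: int
    fraction_active: float | None
    mean_signal_area: float | None
    sem_signal_area: float | None


@dataclass
class AssociationSummary:
    by_class: dict[str, ClassActivity]
    activity_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"class": k, "n": v.n_processes, "n_active": v.n_with_calcium,
                 "fraction_active": v.fraction_active,
                 "mean_signal_area": v.mean_signal_area,
                 "sem_signal_area": v.sem_signal_area}
                for k, v in self.by_class.items()
            ]
        )


def _mean_sem(values: np.ndarray) -> tuple[float | None, float | None]:
    if values.size == 0:
        return None, None
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else None
    return mean, sem


def activity_by_motility_class(
    motility_events: list[MotilityEvent],
    microdomain_stats: list[MicrodomainStats],
    activity_threshold: float = 5.0,
    classes: tuple[str, ...] = ("extension", "retraction", "stable"),
) -> AssociationSummary:
    """Per motility class: fraction of processes with suprathreshold signal
    area and the class's mean +/- SEM signal area (SEM over processes).

    Classes with zero members report fractions/means as None (undefined,
    not zero).
    """

    stats_by_roi = {s.roi_id: s for s in microdomain_stats}
    by_class: dict[str, ClassActivity] = {}
    for klass in classes:
        rois = [m.roi_id for m in motility_events if m.klass == klass]
        areas = np.array(
            [stats_by_roi[r].signal_area for r in rois if r in stats_by_roi]
        )
        n = len(rois)
        if n == 0:
            by_class[klass] = ClassActivity(0, 0, None, None, None)
            continue
        n_active = int(np.sum(areas >= activity_threshold))
        mean, sem = _mean_sem(areas)
        by_class[klass] = ClassActivity(n, n_active, n_active / n, mean, sem)
    return AssociationSummary(by_class=by_class, activity_threshold=activity_threshold)


def nearest_event_latency(
    events: list[CalciumEvent],
    motility_event: MotilityEvent,
    frame_rate_hz: float,
    peak_min: float = QUALIFYING_PEAK_DFF,
    bins_s: tuple[float, ...] = LATENCY_BINS_S,
) -> LatencyRecord:
    """Latency from the nearest qualifying event peak to the motility start.

    Only events with peak dF/F >= ``peak_min`` qualify.  Ties between the
    preceding and following event resolve to the preceding one.  With no
    qualifying event, latencies are None and no bin is set (the record
    still counts in bin denominators).
    """

    if motility_event.start_frame is None:
        raise ValueError("motility event has no start_frame; run bounds detection first")
    start_s = motility_event.start_frame / frame_rate_hz
    peaks_s = np.array(
        [e.peak_frame / frame_rate_hz for e in events if e.peak_dff >= peak_min]
    )
    before = peaks_s[peaks_s <= start_s]
    after = peaks_s[peaks_s > start_s]
    nearest_before = float(start_s - before.max()) if before.size else None
    nearest_after = float(after.min() - start_s) if after.size else None
    candidates = [v for v in (nearest_before, nearest_after) if v is not None]
    if not candidates:
        nearest_abs = None
    elif nearest_before is not None and (
        nearest_after is None or nearest_before <= nearest_after
    ):
        nearest_abs = nearest_before
    else:
        nearest_abs = nearest_after
    bins = {
        f"<{int(b)}s": (nearest_abs is not None and nearest_abs < b) for b in bins_s
    }
    return LatencyRecord(
        roi_id=motility_event.roi_id,
        motility_class=motility_event.klass,
        motility_start_frame=motility_event.start_frame,
        nearest_before_s=nearest_before,
        nearest_after_s=nearest_after,
        nearest_abs_s=nearest_abs,
        bins=bins,
    )


def bin_latency_fractions(
    records: list[LatencyRecord],
    bins_s: tuple[float, ...] = LATENCY_BINS_S,
    classes: tuple[str, ...] = ("extension", "retraction"),
) -> pd.DataFrame:
    """Per class and bin, the fraction of processes inside the bin.

    All processes of the class count in the denominator, including those
    without a qualifying event; empty classes give null fractions.
    """

    rows = []
    for klass in classes:
        recs = [r for r in records if r.motility_class == klass]
        for b in bins_s:
            key = f"<{int(b)}s"
            n = len(recs)
            count = sum(1 for r in recs if r.bins.get(key, False))
            rows.append(
                {"class": klass, "bin": key, "n": n, "count": count,
                 "fraction": count / n if n else None}
            )
    return pd.DataFrame(rows)


def latency_records_to_frame(records: list[LatencyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": r.roi_id, "class": r.motility_class,
                "start_frame": r.motility_start_frame,
                "nearest_before_s": r.nearest_before_s,
                "nearest_after_s": r.nearest_after_s,
                "nearest_abs_s": r.nearest_abs_s,
                **{k: v for k, v in r.bins.items()},
            }
            for r in records
        ]
    )
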