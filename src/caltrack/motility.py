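"""Process-area quantification, motility classification, and Sholl profiles.

Motility follows the two-projection protocol: average the first and the
last 100 frames of the series, threshold each within the process ROI at
the recording's uniform process threshold, and compare areas.  A process
qualifies only if its initial area exceeds 9 um^2; a >= +50% area change
is an extension, <= -50% a retraction, anything else stable.  The
dynamic phase is bounded on a windowed (default 15 s) area series: the
start is the first window of a sustained monotone run of area changes
beyond a noise tolerance, the end the first window of the subsequent
plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .rois import Roi
from .segmentation import soma_mask_union
from .stack import ImageStack, average_intensity_projection

__all__ = ["ProcessAreaSeries", "MotilityEvent", "Exclusion", "MotilityBounds",
           "TwoColorOverlay", "total_process_area", "two_color_overlay",
           "classify_motility", "process_area_series", "detect_motility_bounds",
           "ShollProfile", "sholl_profile"]

MIN_PROCESS_AREA_UM2 = 9.0      # strict inclusion rule: first area must exceed this
MOTILITY_FRACTION = 0.5         # >= 50% change classifies extension/retraction
OVERLAY_FRAMES = 100


@dataclass
class ProcessAreaSeries:
    """Process area per sub-stack averaging window (default 15 s)."""

    roi_id: str
    window_s: float
    frame_of_window: np.ndarray     # start frame of each window
    area_um2: np.ndarray


@dataclass
class MotilityEvent:
    roi_id: str
    klass: str                      # extension | retraction | stable
    area_first_um2: float
    area_last_um2: float
    fractional_change: float
    start_frame: int | None = None
    end_frame: int | None = None


@dataclass(frozen=True)
class Exclusion:
    roi_id: str
    reason: str


@dataclass(frozen=True)
class MotilityBounds:
    start_frame: int
    end_frame: int
    direction: str                  # extension | retraction


@dataclass
class TwoColorOverlay:
    first: np.ndarray
    last: np.ndarray
    rgb: np.ndarray                 # H x W x 3, red=first, green=last


def _uniform_threshold(projection, mask_out, method, fixed):
    vals = projection[~mask_out]
    if method == "fixed":
        return float(fixed)
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("cannot compute Otsu threshold on a flat projection")
    return float(threshold_otsu(vals))


def total_process_area(
    stack: ImageStack,
    soma_rois: list[Roi],
    period_ranges: list[tuple[int, int]],
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    soma_dilation_px: int = 2,
) -> tuple[list[float], float]:
    """Total process area (um^2) per period at ONE uniform threshold.

    The threshold is derived from the first (baseline) period's
    soma-masked projection and held fixed across all periods, so area
    changes reflect morphology rather than thresholding drift.
    Returns (areas per period, threshold used).
    """

    T = stack.n_frames
    for lo, hi in period_ranges:
        if lo < 0 or hi > T or hi <= lo:
            raise ValueError(f"period ({lo}, {hi}) outside the recording")
    somas = soma_mask_union(soma_rois, stack.data.shape[1:], soma_dilation_px)
    base_proj = average_intensity_projection(stack, np.arange(*period_ranges[0]))
    thr = _uniform_threshold(base_proj, somas, threshold_method, fixed_threshold)
    px_area = stack.pixel_size_um**2
    areas = []
    for lo, hi in period_ranges:
        proj = average_intensity_projection(stack, np.arange(lo, hi))
        fg = (proj > thr) & ~somas
        areas.append(float(fg.sum() * px_area))
    if areas[0] == 0:
        warnings.warn("baseline period has no suprathreshold process pixels")
    return areas, thr


def two_color_overlay(stack: ImageStack, n_frames: int = OVERLAY_FRAMES) -> TwoColorOverlay:
    """Red/green composite of the first- and last-100-frame projections.

    Red-only pixels flag retracted structure, green-only newly extended
    structure, yellow stable morphology; emitted for human review of
    candidate motile processes.
    """

    if stack.n_frames < 2 * n_frames:
        raise ValueError(
            f"need >= {2 * n_frames} frames for a first/last {n_frames}-frame overlay"
        )
    first = average_intensity_projection(stack, np.arange(n_frames))
    last = average_intensity_projection(
        stack, np.arange(stack.n_frames - n_frames, stack.n_frames)
    )
    scale = max(float(first.max()), float(last.max()), 1e-12)
    rgb = np.zeros(first.shape + (3,), dtype=np.float64)
    rgb[..., 0] = first / scale
    rgb[..., 1] = last / scale
    return TwoColorOverlay(first=first, last=last, rgb=rgb)


def classify_motility(
    roi: Roi,
    first_projection: np.ndarray,
    last_projection: np.ndarray,
    threshold: float,
    pixel_size_um: float,
    min_area_um2: float = MIN_PROCESS_AREA_UM2,
    motility_fraction: float = MOTILITY_FRACTION,
    soma_mask: np.ndarray | None = None,
) -> MotilityEvent | Exclusion:
    """Classify one process ROI from its first/last projection areas.

    Boundary handling: a change of exactly +/-50% counts as
    extension/retraction; the size rule is strict (first area must be
    > 9 um^2, otherwise the ROI is excluded with a reason).
    """

    keep = roi.mask if soma_mask is None else roi.mask & ~soma_mask
    px_area = pixel_size_um**2
    first_area = float(((first_projection > threshold) & keep).sum() * px_area)
    last_area = float(((last_projection > threshold) & keep).sum() * px_area)
    if first_area == 0:
        return Exclusion(roi.id, "zero baseline area after thresholding")
    if first_area <= min_area_um2:
        return Exclusion(
            roi.id, f"minimum size: first area {first_area:.2f} um^2 <= {min_area_um2} um^2"
        )
    frac = (last_area - first_area) / first_area
    if frac >= motility_fraction:
        klass = "extension"
    elif frac <= -motility_fraction:
        klass = "retraction"
    else:
        klass = "stable"
    return MotilityEvent(
        roi_id=roi.id,
        klass=klass,
        area_first_um2=first_area,
        area_last_um2=last_area,
        fractional_change=frac,
    )


def process_area_series(
    stack: ImageStack,
    roi: Roi,
    threshold: float,
    window_s: float = 15.0,
    soma_mask: np.ndarray | None = None,
) -> ProcessAreaSeries:
    """Windowed area series: per window, project, threshold, count in-ROI px."""

    w = max(1, round(window_s * stack.frame_rate_hz))
    keep = roi.mask if soma_mask is None else roi.mask & ~soma_mask
    px_area = stack.pixel_size_um**2
    starts = np.arange(0, stack.n_frames, w)
    areas = np.empty(len(starts))
    for i, lo in enumerate(starts):
        proj = stack.data[lo : min(lo + w, stack.n_frames)].mean(axis=0)
        areas[i] = ((proj > threshold) & keep).sum() * px_area
    return ProcessAreaSeries(
        roi_id=roi.id, window_s=window_s, frame_of_window=starts, area_um2=areas
    )


def detect_motility_bounds(
    series: ProcessAreaSeries,
    tolerance: float | None = None,
    min_run: int = 3,
    plateau_run: int = 2,
    rel_floor: float = 0.05,
) -> MotilityBounds | None:
    """Start/end of the dynamic phase of a windowed area series.

    Start: the first window of a run of >= ``min_run`` successive area
    changes, each beyond the noise tolerance and all in one direction.
    End: the first window at which the area has stopped changing (the
    incoming change and the next ``plateau_run - 1`` changes are all
    within tolerance); the final window if no plateau occurs.  The
    default tolerance is the larger of the SD of the first five window
    areas and ``rel_floor`` of their mean (clean projections have zero
    SD, so a purely SD-based tolerance would flag rounding noise).
    Returns None when no qualifying run exists.
    """

    a = np.asarray(series.area_um2, dtype=np.float64)
    if len(a) < 3:
        raise ValueError("need at least 3 windows")
    d = np.diff(a)
    if tolerance is None:
        head = a[: min(5, len(a))]
        tolerance = max(float(np.std(head)), rel_floor * float(np.mean(head)), 1e-9)

    start_w = direction = None
    for i in range(len(d) - min_run + 1):
        seg = d[i : i + min_run]
        if np.all(seg > tolerance):
            start_w, direction, run_start = i + 1, "extension", i
            break
        if np.all(seg < -tolerance):
            start_w, direction, run_start = i + 1, "retraction", i
            break
    if start_w is None:
        return None

    end_w = len(a) - 1
    for j in range(run_start + 1, len(d)):
        seg = np.abs(d[j : j + plateau_run])
        if len(seg) == plateau_run and np.all(seg < tolerance):
            end_w = j + 1
            break
    return MotilityBounds(
        start_frame=int(series.frame_of_window[start_w]),
        end_frame=int(series.frame_of_window[end_w]),
        direction=direction,
    )


# --- Sholl analysis -------------------------------------------------------


@dataclass
class ShollProfile:
    cell_id: str
    radii_um: np.ndarray
    intersections: np.ndarray
    center: tuple[float, float]     # (row, col) px


def _circle_runs(mask: np.ndarray, center, radius_px: float) -> int:
    """Number of contiguous foreground runs on a 1-px circle, by angular walk."""

    cy, cx = center
    n = max(16, int(np.ceil(2 * np.pi * radius_px * 2)))
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = np.round(cy + radius_px * np.sin(theta)).astype(int)
    cc = np.round(cx + radius_px * np.cos(theta)).astype(int)
    inb = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    vals = np.zeros(n, dtype=bool)
    vals[inb] = mask[rr[inb], cc[inb]]
    if not vals.any():
        return 0
    if vals.all():
        return 1
    rises = int(np.sum(vals & ~np.roll(vals, 1)))   # circular False->True edges
    return rises


def sholl_profile(
    morphology_mask: np.ndarray,
    soma_center: tuple[float, float],
    r_max_um: float,
    step_um: float = 2.0,
    pixel_size_um: float = 300.0 / 512.0,
    cell_id: str = "cell",
) -> ShollProfile:
    """Concentric-circle intersection counts around the soma centre.

    For each radius r = step, 2*step, ..., r_max (um), counts the
    connected runs of foreground pixels crossed by the 1-px-wide circle
    of radius r.
    """

    cy, cx = soma_center
    h, w = morphology_mask.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("soma_center outside image")
    radii = np.arange(step_um, r_max_um + 1e-9, step_um)
    counts = np.array(
        [_circle_runs(morphology_mask, (cy, cx), r / pixel_size_um) for r in radii],
        dtype=int,
    )
    return ShollProfile(
        cell_id=cell_id, radii_um=radii, intersections=counts, center=(cy, cx)
    )
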