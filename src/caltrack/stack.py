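"""Time-lapse stack container, multi-page TIFF I/O, and projections."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "StackFormatError", "read_stack", "write_stack",
           "average_intensity_projection"]


class StackFormatError(ValueError):
    """Unreadable or inconsistently shaped multi-page TIFF."""


@dataclass
class ImageStack:
    """A T x H x W fluorescence movie with acquisition metadata.

    ``provenance`` records the source path and processing history;
    registered stacks additionally carry the applied per-frame shifts.
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    registered: bool = False
    provenance: list[str] = field(default_factory=list)
    applied_shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("data must be T x H x W with T >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def to_tiff(self, path: str | Path, dtype=None) -> None:
        data = self.data
        if dtype is not None:
            info = np.iinfo(dtype) if np.issubdtype(np.dtype(dtype), np.integer) else None
            if info is not None:
                data = np.clip(np.round(data), info.min, info.max)
            data = data.astype(dtype)
        tifffile.imwrite(str(path), data)


def read_stack(path: str | Path, frame_rate_hz: float = 1.0,
               pixel_size_um: float = 300.0 / 512.0) -> ImageStack:
    """Load a multi-page TIFF, preserving frame order.

    Raises :class:`StackFormatError` on unreadable files, non-2-D pages,
    or pages of inconsistent shape.
    """

    try:
        with tifffile.TiffFile(str(path)) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackFormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise StackFormatError(f"{path}: no pages")
    shapes = {p.shape for p in pages}
    if any(p.ndim != 2 for p in pages):
        raise StackFormatError(f"{path}: pages must be 2-D, got shapes {shapes}")
    if len(shapes) != 1:
        raise StackFormatError(f"{path}: inconsistent page shapes {shapes}")
    return ImageStack(
        data=np.stack(pages),
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
        provenance=[f"read from {path}"],
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the pixel data as a multi-page TIFF (dtype preserved)."""

    stack.to_tiff(path)


def average_intensity_projection(stack: ImageStack, frame_range=None) -> np.ndarray:
    """Per-pixel temporal mean over ``frame_range`` (default: all frames).

    The constitutive morphology label dominates this mean, so the result
    approximates a static morphology image for ROI selection.
    """

    if frame_range is None:
        frames = np.arange(stack.n_frames)
    else:
        frames = np.asarray(frame_range)
        if frames.ndim == 0:
            frames = frames[None]
    if frames.size == 0:
        raise ValueError("frame_range is empty")
    if frames.min() < 0 or frames.max() >= stack.n_frames:
        raise ValueError("frame_range outside [0, T)")
    return stack.data[frames].mean(axis=0)
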