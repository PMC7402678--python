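"""Rigid frame-to-frame motion correction.

Each frame is aligned to a template (mean of the first K frames) by
cross-correlation with upsampled sub-pixel peak localisation, then
resampled by the recovered shift.  Out-of-frame pixels are filled with
the frame's median intensity so that projections stay NaN-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stack import ImageStack

__all__ = ["RegistrationError", "RegistrationResult", "register_stack"]


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationResult:
    """Per-frame displacement estimates.

    ``shifts[t]`` is the estimated (dy, dx) displacement of frame ``t``
    relative to the template, in px (sub-pixel); the corrected frame is
    the original resampled by ``-shifts[t]``.
    """

    shifts: np.ndarray                  # (T, 2)
    reference: str

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"frame": np.arange(len(self.shifts)),
             "dy": self.shifts[:, 0], "dx": self.shifts[:, 1]}
        ).to_csv(path, index=False)


def register_stack(
    stack: ImageStack,
    template_frames: int = 30,
    upsample_factor: int = 50,
) -> tuple[ImageStack, RegistrationResult]:
    """Align every frame to the mean of the first ``template_frames`` frames.

    Uses plain (un-normalised-spectrum) cross-correlation with upsampled
    peak interpolation; the "phase" spectral whitening misbehaves on
    smooth low-texture fluorescence frames.
    """

    if stack.n_frames < 2:
        raise RegistrationError("need at least 2 frames to register")
    k = int(min(max(template_frames, 1), stack.n_frames))
    template = stack.data[:k].mean(axis=0).astype(np.float64)
    if np.ptp(template) == 0:
        raise RegistrationError("flat (zero-variance) template")

    T = stack.n_frames
    shifts = np.zeros((T, 2))
    corrected = np.empty_like(stack.data, dtype=np.float32)
    for t in range(T):
        frame = stack.data[t].astype(np.float64)
        reg_shift, _, _ = phase_cross_correlation(
            template, frame, upsample_factor=upsample_factor, normalization=None
        )
        # reg_shift is what must be applied to the frame to match the
        # template, i.e. minus the frame's displacement
        shifts[t] = -reg_shift
        if np.any(reg_shift != 0):
            fill = float(np.median(frame))
            corrected[t] = ndimage.shift(
                frame, reg_shift, order=1, mode="constant", cval=fill
            ).astype(np.float32)
        else:
            corrected[t] = frame.astype(np.float32)

    result = RegistrationResult(
        shifts=shifts,
        reference=(f"frame {0}" if k == 1 else f"template=mean of first {k} frames"),
    )
    out = ImageStack(
        data=corrected,
        frame_rate_hz=stack.frame_rate_hz,
        pixel_size_um=stack.pixel_size_um,
        registered=True,
        provenance=stack.provenance + [f"registered to {result.reference}"],
        applied_shifts=shifts.copy(),
    )
    return out, result
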