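"""Threshold-based process-territory detection, grid parcellation, and
manual-segmentation rule checks.

Territory detection mirrors the semi-automated workflow used on average
intensity projections: mask the (dilated) somata, binarize the remainder
at a uniform threshold, and keep 8-connected components larger than a
minimum pixel area (default: strictly more than 50 px).  A territory
typically corresponds to a primary process with its secondary and
tertiary branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk as disk_footprint, skeletonize

from .rois import Roi

__all__ = ["SegmentationConfig", "RuleViolation", "threshold_territories",
           "grid_rois", "check_process_rules", "soma_mask_union",
           "skeleton_length_px"]


@dataclass
class SegmentationConfig:
    threshold_method: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_territory_px: int = 50              # strict: area must exceed this
    soma_dilation_px: int = 2
    connectivity: int = 8                   # 4 | 8
    grid_tile_px: int = 32

    def __post_init__(self) -> None:
        if self.min_territory_px < 1:
            raise ValueError("min_territory_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required for method 'fixed'")


@dataclass(frozen=True)
class RuleViolation:
    roi_id: str
    rule: str
    message: str


def soma_mask_union(soma_rois: list[Roi], shape: tuple[int, int],
                    dilation_px: int = 0) -> np.ndarray:
    """Union of soma masks, optionally dilated to suppress halo pixels."""

    union = np.zeros(shape, dtype=bool)
    for r in soma_rois:
        union |= r.mask
    if dilation_px > 0 and union.any():
        union = dilation(union, disk_footprint(dilation_px))
    return union


def threshold_territories(
    projection: np.ndarray,
    soma_rois: list[Roi],
    config: SegmentationConfig | None = None,
    pixel_size_um: float | None = None,
) -> list[Roi]:
    """Detect process territories on a soma-masked projection.

    Returns connected components whose pixel area strictly exceeds
    ``config.min_territory_px``, as ``process_territory`` ROIs.  An image
    with no suprathreshold pixels yields an empty list (not an error).
    """

    config = config or SegmentationConfig()
    somas = soma_mask_union(soma_rois, projection.shape, config.soma_dilation_px)
    outside = ~somas
    if config.threshold_method == "fixed":
        thr = float(config.fixed_threshold)
    else:
        vals = projection[outside]
        if vals.size == 0 or np.ptp(vals) == 0:
            return []
        thr = float(threshold_otsu(vals))
    binary = (projection > thr) & outside
    if not binary.any():
        return []
    labels = cc_label(binary, connectivity=2 if config.connectivity == 8 else 1)
    rois: list[Roi] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area > config.min_territory_px:
            rois.append(
                Roi(
                    id=f"territory_{len(rois):03d}",
                    kind="process_territory",
                    mask=mask,
                    source="threshold",
                    pixel_size_um=pixel_size_um,
                )
            )
    assert all(r.area_px > config.min_territory_px for r in rois)
    return rois


def grid_rois(image_shape: tuple[int, int], grid_tile_px: int,
              pixel_size_um: float | None = None) -> list[Roi]:
    """Non-overlapping tiles covering the frame; edge tiles may be smaller.

    Tile ids encode (row, col) of the tile grid.
    """

    if grid_tile_px < 1:
        raise ValueError("grid_tile_px must be >= 1")
    h, w = image_shape
    rois = []
    for i, top in enumerate(range(0, h, grid_tile_px)):
        for j, left in enumerate(range(0, w, grid_tile_px)):
            mask = np.zeros(image_shape, dtype=bool)
            mask[top : top + grid_tile_px, left : left + grid_tile_px] = True
            rois.append(
                Roi(
                    id=f"grid_r{i:02d}_c{j:02d}",
                    kind="grid_tile",
                    mask=mask,
                    source="grid",
                    pixel_size_um=pixel_size_um,
                )
            )
    return rois


def skeleton_length_px(mask: np.ndarray) -> int:
    """Process length as the pixel count of the mask's morphological skeleton."""

    return int(skeletonize(mask).sum())


def check_process_rules(
    rois: list[Roi],
    min_secondary_length_px: int = 15,
) -> list[RuleViolation]:
    """Advisory validation of manually segmented process ROIs.

    Flags (never drops): process ROIs without an associated soma in the
    set, and secondary branches whose skeleton length does not exceed
    ``min_secondary_length_px`` (the ~10 um rule).
    """

    soma_ids = {r.id for r in rois if r.kind in ("soma", "neuron_soma")}
    violations: list[RuleViolation] = []
    for r in rois:
        if r.kind != "process":
            continue
        if r.parent_cell is None or r.parent_cell not in soma_ids:
            violations.append(
                RuleViolation(r.id, "soma_association",
                              "process has no associated soma in the field of view")
            )
        if r.branch_order == 2:
            length = skeleton_length_px(r.mask)
            if length <= min_secondary_length_px:
                violations.append(
                    RuleViolation(
                        r.id, "secondary_branch_length",
                        f"secondary branch skeleton length {length} px <= "
                        f"{min_secondary_length_px} px",
                    )
                )
    return violations
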