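"""Regions of interest: container, ImageJ ``.roi``/``.zip`` and GeoJSON I/O.

ROIs are stored as boolean rasters at stack resolution.  Rasterization
follows the ImageJ convention that polygon vertices live on pixel
*corners*: a pixel belongs to a polygon when its centre (i + 0.5) falls
inside, so an axis-aligned 10x10 rectangle covers exactly 100 px.

The ImageJ codec implements the subset of the public binary format that
manual segmentation produces (polygon, freehand, rectangle, oval); ROI
names are taken from zip entry names (ImageJ's own convention) or the
embedded header-2 name field.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

__all__ = ["Roi", "RoiError", "load_manual_rois", "rasterize_polygon",
           "encode_imagej_roi", "decode_imagej_roi", "write_imagej_zip",
           "roi_catalogue"]

ROI_KINDS = ("soma", "process", "process_territory", "grid_tile", "neuron_soma")

#: default name-prefix -> kind mapping used when loading manual ROI files
DEFAULT_KIND_MAP = {
    "soma": "soma",
    "neuron": "neuron_soma",
    "terr": "process_territory",
    "grid": "grid_tile",
    "proc": "process",
}


class RoiError(ValueError):
    pass


@dataclass
class Roi:
    """A labelled 2-D region as a boolean mask with provenance."""

    id: str
    kind: str
    mask: np.ndarray
    parent_cell: str | None = None
    source: str = "manual"           # manual | threshold | grid
    pixel_size_um: float | None = None
    branch_order: int | None = None  # 1 = primary process, 2 = secondary branch

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ROI_KINDS:
            raise RoiError(f"unknown ROI kind {self.kind!r}")
        if not self.mask.any():
            raise RoiError(f"ROI {self.id!r}: empty mask")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float | None:
        if self.pixel_size_um is None:
            return None
        return self.area_px * self.pixel_size_um**2

    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())


def rasterize_polygon(vertices_xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon given in (x, y) pixel-corner coordinates."""

    v = np.asarray(vertices_xy, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise RoiError("polygon needs >= 3 (x, y) vertices")
    rr, cc = draw_polygon(v[:, 1] - 0.5, v[:, 0] - 0.5, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _rasterize_oval(top, left, bottom, right, shape) -> np.ndarray:
    h, w = bottom - top, right - left
    if h <= 0 or w <= 0:
        raise RoiError("degenerate oval bounding box")
    cy, cx = top + h / 2.0, left + w / 2.0
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy + 0.5 - cy) / (h / 2.0)) ** 2 + ((xx + 0.5 - cx) / (w / 2.0)) ** 2 <= 1.0


# --- ImageJ .roi binary codec (big-endian) --------------------------------

_HEADER_SIZE = 64
_TYPE_POLYGON, _TYPE_RECT, _TYPE_OVAL, _TYPE_FREEHAND = 0, 1, 2, 7


def encode_imagej_roi(name: str, roi_type: str, coords_xy=None, bbox=None) -> bytes:
    """Encode a polygon/rect/oval ROI in the ImageJ binary format.

    ``coords_xy`` (polygon/freehand): (N, 2) integer vertices; ``bbox``
    (rect/oval): (top, left, bottom, right).
    """

    type_code = {"polygon": _TYPE_POLYGON, "rect": _TYPE_RECT,
                 "oval": _TYPE_OVAL, "freehand": _TYPE_FREEHAND}[roi_type]
    if roi_type in ("polygon", "freehand"):
        c = np.asarray(coords_xy, dtype=int)
        top, left = int(c[:, 1].min()), int(c[:, 0].min())
        bottom, right = int(c[:, 1].max()), int(c[:, 0].max())
        n = len(c)
        xs = (c[:, 0] - left).astype(">i2")
        ys = (c[:, 1] - top).astype(">i2")
        coord_bytes = xs.tobytes() + ys.tobytes()
    else:
        top, left, bottom, right = (int(v) for v in bbox)
        n = 0
        coord_bytes = b""

    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)            # version
    header[6] = type_code
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    hdr2_offset = _HEADER_SIZE + len(coord_bytes)
    struct.pack_into(">i", header, 60, hdr2_offset)

    name_utf16 = name.encode("utf-16-be")
    hdr2 = bytearray(64)
    struct.pack_into(">i", hdr2, 16, hdr2_offset + 64)  # name offset
    struct.pack_into(">i", hdr2, 20, len(name))         # name length (chars)
    return bytes(header) + coord_bytes + bytes(hdr2) + name_utf16


def decode_imagej_roi(data: bytes, fallback_name: str = "roi") -> dict:
    """Decode one ``.roi`` blob to a geometry dict."""

    if data[0:4] != b"Iout":
        raise RoiError("not an ImageJ ROI file (missing 'Iout' magic)")
    type_code = data[6]
    top, left, bottom, right = struct.unpack_from(">4h", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    name = fallback_name
    (hdr2_offset,) = struct.unpack_from(">i", data, 60)
    if 0 < hdr2_offset <= len(data) - 24:
        name_off, name_len = struct.unpack_from(">2i", data, hdr2_offset + 16)
        if name_len > 0 and 0 < name_off <= len(data) - 2 * name_len:
            name = data[name_off : name_off + 2 * name_len].decode("utf-16-be")
    out = {"name": name, "bbox": (top, left, bottom, right)}
    if type_code in (_TYPE_POLYGON, _TYPE_FREEHAND):
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE)
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE + 2 * n)
        out["type"] = "polygon"
        out["coords_xy"] = np.stack([xs + left, ys + top], axis=1).astype(float)
    elif type_code == _TYPE_RECT:
        out["type"] = "rect"
    elif type_code == _TYPE_OVAL:
        out["type"] = "oval"
    else:
        raise RoiError(f"unsupported ImageJ ROI type code {type_code}")
    return out


def write_imagej_zip(path: str | Path, rois: list[dict]) -> None:
    """Write an ImageJ ROI archive; each dict as accepted by encode_imagej_roi."""

    with zipfile.ZipFile(path, "w") as zf:
        for r in rois:
            blob = encode_imagej_roi(
                r["name"], r["type"], r.get("coords_xy"), r.get("bbox")
            )
            zf.writestr(f"{r['name']}.roi", blob)


# --- loading --------------------------------------------------------------


def _kind_from_name(name: str, kind_map: dict[str, str]) -> str:
    low = name.lower()
    for prefix, kind in kind_map.items():
        if low.startswith(prefix):
            return kind
    return "process"


def _geometry_to_roi(geom: dict, shape, pixel_size_um, kind_map,
                     properties: dict | None = None) -> Roi:
    props = properties or {}
    name = props.get("name", geom["name"])
    if geom["type"] == "polygon":
        v = np.asarray(geom["coords_xy"], dtype=float)
        out_of_bounds = (
            (v[:, 0] < 0).any() or (v[:, 1] < 0).any()
            or (v[:, 0] > shape[1]).any() or (v[:, 1] > shape[0]).any()
        )
        if out_of_bounds:
            warnings.warn(f"ROI {name!r}: polygon extends outside image; clipped")
        mask = rasterize_polygon(v, shape)
    elif geom["type"] == "rect":
        top, left, bottom, right = geom["bbox"]
        mask = np.zeros(shape, dtype=bool)
        mask[max(top, 0) : bottom, max(left, 0) : right] = True
    elif geom["type"] == "oval":
        mask = _rasterize_oval(*geom["bbox"], shape)
    else:  # pragma: no cover - decode already rejects others
        raise RoiError(f"unsupported geometry {geom['type']}")
    if not mask.any():
        raise RoiError(f"ROI {name!r}: empty after clipping to image bounds")
    return Roi(
        id=name,
        kind=props.get("kind") or _kind_from_name(name, kind_map),
        mask=mask,
        parent_cell=props.get("parent_cell"),
        source="manual",
        pixel_size_um=pixel_size_um,
        branch_order=props.get("branch_order"),
    )


def load_manual_rois(
    path: str | Path,
    image_shape: tuple[int, int],
    pixel_size_um: float | None = None,
    kind_map: dict[str, str] | None = None,
) -> list[Roi]:
    """Load manually drawn ROIs from an ImageJ archive or GeoJSON file.

    Supported: single ``.roi``, ``.zip`` of ``.roi`` entries, or a GeoJSON
    FeatureCollection of Polygon features (properties: name, kind,
    parent_cell, branch_order).  ROI kind falls back to a name-prefix
    convention (soma*/proc*/terr*/grid*/neuron*).
    """

    path = Path(path)
    kind_map = kind_map or DEFAULT_KIND_MAP
    rois: list[Roi] = []
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith(".roi")]
            for n in sorted(names):
                geom = decode_imagej_roi(zf.read(n), fallback_name=Path(n).stem)
                geom["name"] = Path(n).stem  # zip entry name wins, as in ImageJ
                rois.append(_geometry_to_roi(geom, image_shape, pixel_size_um, kind_map))
    elif path.suffix.lower() == ".roi":
        geom = decode_imagej_roi(path.read_bytes(), fallback_name=path.stem)
        rois.append(_geometry_to_roi(geom, image_shape, pixel_size_um, kind_map))
    elif path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            fc = json.load(fh)
        for i, feat in enumerate(fc.get("features", [])):
            g = feat.get("geometry", {})
            if g.get("type") != "Polygon":
                warnings.warn(f"feature {i}: skipping non-Polygon geometry")
                continue
            props = feat.get("properties") or {}
            geom = {
                "type": "polygon",
                "name": props.get("name", f"roi{i}"),
                "coords_xy": np.asarray(g["coordinates"][0], dtype=float),
            }
            rois.append(
                _geometry_to_roi(geom, image_shape, pixel_size_um, kind_map, props)
            )
    else:
        raise RoiError(f"unsupported ROI file type: {path.suffix!r}")
    if not rois:
        warnings.warn(f"{path}: no ROIs found")
    return rois


def roi_catalogue(rois: list[Roi]) -> pd.DataFrame:
    """Tabular ROI summary (id, kind, areas, parent cell, source)."""

    return pd.DataFrame(
        [
            {
                "id": r.id,
                "kind": r.kind,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "parent_cell": r.parent_cell,
                "source": r.source,
            }
            for r in rois
        ]
    )
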