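"""File formats: depth.bin dialect, mask PNGs, polygon annotations, camera
JSON, measurement results and record CSVs.

The depth dialect is this package's own documented layout (the mobile app's
export format is unpublished): an 8-byte magic ``BDEPTH01``, two uint32
little-endian fields (height, width), then height*width float32
little-endian z-depths in row-major order.  Missing returns are stored as
the sentinel -1.0 (any non-positive value reads back as invalid).
Round-trips are bit-identical.

Masks are 8-bit PNGs, nonzero = wound.  Polygon annotations follow the
Labelme JSON layout (``shapes[*].points`` in image pixel coordinates plus
``imageHeight``/``imageWidth``); rasterization uses the even-odd rule with
pixel-center sampling, scaling vertices when the annotation resolution
differs from the depth grid.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .camera import CameraExtrinsics, CameraIntrinsics, DepthMap
from .errors import DepthFormatError

__all__ = [
    "DEPTH_MAGIC",
    "INVALID_DEPTH_SENTINEL",
    "PolygonLabel",
    "read_depth_bin",
    "write_depth_bin",
    "read_mask_png",
    "write_mask_png",
    "read_labelme",
    "rasterize_polygons",
    "read_intrinsics_json",
    "write_intrinsics_json",
    "read_extrinsics_json",
    "write_extrinsics_json",
    "measurement_to_dict",
    "write_measurement_json",
    "read_records_csv",
    "write_records_csv",
]

DEPTH_MAGIC = b"BDEPTH01"
INVALID_DEPTH_SENTINEL = -1.0


def write_depth_bin(path, depth: DepthMap) -> None:
    """Write a DepthMap in the package's depth.bin dialect (bit-exact)."""
    h, w = depth.shape
    values = np.where(depth.valid, depth.values, INVALID_DEPTH_SENTINEL)
    payload = values.astype("<f4").tobytes(order="C")
    with open(path, "wb") as fh:
        fh.write(DEPTH_MAGIC)
        fh.write(struct.pack("<II", h, w))
        fh.write(payload)


def read_depth_bin(path) -> DepthMap:
    """Read a depth.bin file; raises DepthFormatError on malformed input."""
    raw = Path(path).read_bytes()
    if len(raw) < 16 or raw[:8] != DEPTH_MAGIC:
        raise DepthFormatError(f"{path}: bad magic")
    h, w = struct.unpack("<II", raw[8:16])
    expected = 16 + h * w * 4
    if len(raw) != expected:
        raise DepthFormatError(
            f"{path}: payload length {len(raw) - 16} != {h}*{w}*4"
        )
    values = np.frombuffer(raw[16:], dtype="<f4").reshape(h, w).astype(float)
    return DepthMap(values)


def write_mask_png(path, mask) -> None:
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    """8-bit mask PNG -> boolean array; nonzero = wound."""
    return np.asarray(Image.open(path).convert("L")) > 0


@dataclass(frozen=True)
class PolygonLabel:
    """One labeled wound polygon in image pixel coordinates."""

    label: str
    points: np.ndarray  # (N, 2) float, (u, v)
    image_height: int
    image_width: int


def read_labelme(path) -> list[PolygonLabel]:
    """Parse a Labelme-style JSON annotation into polygon labels.

    Polygons with fewer than 3 vertices are skipped with a warning.
    """
    doc = json.loads(Path(path).read_text())
    h = int(doc.get("imageHeight", 0))
    w = int(doc.get("imageWidth", 0))
    out = []
    for shape in doc.get("shapes", []):
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or len(pts) < 3:
            warnings.warn(
                f"skipping shape {shape.get('label')!r}: fewer than 3 vertices",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out.append(
            PolygonLabel(
                label=str(shape.get("label", "")),
                points=pts,
                image_height=h,
                image_width=w,
            )
        )
    return out


def _even_odd_fill(vertices: np.ndarray, height: int, width: int) -> np.ndarray:
    # even-odd (crossing number) rule sampled at pixel centers (u, v) = ints
    U, V = np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))
    inside = np.zeros((height, width), dtype=bool)
    x0, y0 = vertices[:, 0], vertices[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for i in range(len(vertices)):
        if y0[i] == y1[i]:
            continue  # horizontal edges never cross a scanline
        crosses = ((y0[i] <= V) & (V < y1[i])) | ((y1[i] <= V) & (V < y0[i]))
        x_at = x0[i] + (V - y0[i]) * (x1[i] - x0[i]) / (y1[i] - y0[i])
        inside ^= crosses & (U < x_at)
    return inside


def rasterize_polygons(
    polygons: list[PolygonLabel], height: int, width: int
) -> np.ndarray:
    """Rasterize polygon labels to a depth-grid-resolution mask.

    Vertices are scaled by the resolution ratio when the annotation image
    size differs from ``(height, width)`` (polygons are typically drawn at
    RGB resolution while the depth grid is sensor-native).  Overlapping
    polygons are OR-combined; each polygon is filled with the even-odd rule
    at pixel centers.
    """
    mask = np.zeros((height, width), dtype=bool)
    for poly in polygons:
        pts = poly.points.astype(float).copy()
        if poly.image_width and poly.image_height:
            pts[:, 0] *= width / poly.image_width
            pts[:, 1] *= height / poly.image_height
        mask |= _even_odd_fill(pts, height, width)
    return mask


def write_intrinsics_json(path, intr: CameraIntrinsics) -> None:
    Path(path).write_text(
        json.dumps(
            {"fx": intr.fx, "fy": intr.fy, "ox": intr.ox, "oy": intr.oy},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def read_intrinsics_json(path) -> CameraIntrinsics:
    d = json.loads(Path(path).read_text())
    return CameraIntrinsics(fx=d["fx"], fy=d["fy"], ox=d["ox"], oy=d["oy"])


def write_extrinsics_json(path, ext: CameraExtrinsics) -> None:
    Path(path).write_text(
        json.dumps(
            {"R": ext.R.tolist(), "t": ext.t.tolist()}, indent=2, sort_keys=True
        )
        + "\n"
    )


def read_extrinsics_json(path) -> CameraExtrinsics:
    d = json.loads(Path(path).read_text())
    return CameraExtrinsics(np.asarray(d["R"], float), np.asarray(d["t"], float))


def measurement_to_dict(result) -> dict:
    """JSON-ready dict of a MeasurementResult; areas rounded to 2 decimals
    (output files only — internal values stay full precision)."""
    return {
        "area2d_cm2": round(result.total_area2d_cm2, 2),
        "area3d_cm2": round(result.total_area3d_cm2, 2),
        "ratio": round(result.total_ratio, 4),
        "warnings": list(result.warnings),
        "wounds": [
            {
                "label": w.label,
                "area2d_cm2": round(w.area2d_cm2, 2),
                "area3d_cm2": round(w.area3d_cm2, 2),
                "ratio": round(w.ratio, 4),
                "triangle_count": w.triangle_count,
                "coverage": round(w.coverage, 4),
                "pixel_count": w.pixel_count,
                "warnings": list(w.warnings),
            }
            for w in result.wounds
        ],
    }


def write_measurement_json(path, result) -> None:
    Path(path).write_text(
        json.dumps(measurement_to_dict(result), indent=2, sort_keys=True) + "\n"
    )


def read_records_csv(path):
    import pandas as pd

    return pd.read_csv(path)


def write_records_csv(path, records) -> None:
    from .analysis import records_frame

    records_frame(records).to_csv(path, index=False)
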