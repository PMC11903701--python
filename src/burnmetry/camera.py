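"""Pinhole camera model: pixels + LiDAR depth -> camera-frame and world-frame 3D points.

The sensor delivers a per-pixel *z-depth* map: each value is the distance of
the hit point along the optical axis, not the Euclidean ray range.  Under the
pinhole model with intrinsics ``K = [[fx, 0, ox], [0, fy, oy], [0, 0, 1]]``
a pixel ``(u, v)`` with depth ``z`` therefore unprojects in closed form to

    x = (u - ox) * z / fx,   y = (v - oy) * z / fy.

Extrinsics ``[R|t]`` map world coordinates into the camera frame
(``p_cam = R @ p_world + t``); world recovery uses the closed-form inverse
``p_world = R.T @ (p_cam - t)``.

Conventions fixed here and relied on everywhere else in the package:

* pixel indices are 0-based, ``(u, v) = (column, row)``, and refer to pixel
  centers;
* depth values are in meters; invalid returns are encoded by any
  non-positive (or non-finite) value and are never interpolated here —
  missing-data policy belongs to the measurement layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DimensionMismatchError,
    InvalidDepthError,
    InvalidExtrinsicsError,
)

__all__ = [
    "CameraIntrinsics",
    "CameraExtrinsics",
    "DepthMap",
    "PointGrid",
    "unproject_pixel",
    "project_point",
    "camera_to_world",
    "world_to_camera",
    "unproject_depth_map",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: pixel focal lengths and principal-point offsets.

    Parameters
    ----------
    fx, fy : float
        Pixel focal lengths (pixels); must be positive.
    ox, oy : float
        Principal-point offsets from the top-left pixel center, in pixels
        (column and row respectively).
    """

    fx: float
    fy: float
    ox: float
    oy: float

    def __post_init__(self) -> None:
        vals = (self.fx, self.fy, self.ox, self.oy)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("intrinsics must be finite")
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        """The 3x3 intrinsic matrix."""
        return np.array(
            [[self.fx, 0.0, self.ox], [0.0, self.fy, self.oy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class CameraExtrinsics:
    """Rigid world->camera transform ``p_cam = R @ p_world + t``.

    ``R`` must be a proper rotation (orthonormal, det +1) to within 1e-9;
    ``t`` is in meters.
    """

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidExtrinsicsError("R must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidExtrinsicsError("R is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise InvalidExtrinsicsError("R must have determinant +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "CameraExtrinsics":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def look_at(
        cls,
        camera_position,
        target,
        up=(0.0, 1.0, 0.0),
    ) -> "CameraExtrinsics":
        """Extrinsics for a camera at ``camera_position`` whose optical axis
        (+z in the camera frame) points at ``target``.

        ``up`` is a world-frame hint for the camera's +y (image-down) axis.
        """
        pos = np.asarray(camera_position, dtype=float)
        fwd = np.asarray(target, dtype=float) - pos
        n = np.linalg.norm(fwd)
        if n == 0:
            raise ValueError("camera_position and target coincide")
        z_c = fwd / n
        up = np.asarray(up, dtype=float)
        x_c = np.cross(up, z_c)
        nx = np.linalg.norm(x_c)
        if nx < 1e-12:
            raise ValueError("up vector is parallel to the viewing direction")
        x_c /= nx
        y_c = np.cross(z_c, x_c)
        R = np.stack([x_c, y_c, z_c])
        return cls(R, -R @ pos)

    @property
    def camera_position(self) -> np.ndarray:
        """Camera center in world coordinates, ``-R.T @ t``."""
        return -self.R.T @ self.t


@dataclass
class DepthMap:
    """H x W grid of per-pixel z-depth in meters.

    ``values`` may contain a non-positive sentinel (or NaN/inf) marking
    missing LiDAR returns; ``valid`` is derived as finite-and-positive.
    """

    values: np.ndarray
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise DimensionMismatchError("depth map must be at least 2x2")
        self.values = v
        self.valid = np.isfinite(v) & (v > 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class PointGrid:
    """Image-ordered H x W grid of world-frame 3D points with validity flags.

    Row/column order matches the source depth map, so 4/8-neighborhood in the
    image corresponds to adjacency on the reconstructed surface.
    """

    points: np.ndarray  # (H, W, 3) meters
    valid: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise DimensionMismatchError("points must have shape (H, W, 3)")
        if self.valid.shape != self.points.shape[:2]:
            raise DimensionMismatchError("valid mask must match point grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape


def unproject_pixel(u, v, depth, intr: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel ``(u, v)`` with z-depth ``depth`` into the camera frame.

    Returns the camera-frame point ``(x, y, z)`` with
    ``x = (u - ox) * depth / fx``, ``y = (v - oy) * depth / fy``, ``z = depth``.

    Raises
    ------
    InvalidDepthError
        If ``depth`` is non-positive or non-finite.
    """
    depth = float(depth)
    if not np.isfinite(depth) or depth <= 0:
        raise InvalidDepthError(f"depth must be finite and > 0, got {depth}")
    x = (u - intr.ox) * depth / intr.fx
    y = (v - intr.oy) * depth / intr.fy
    return np.array([x, y, depth])


def project_point(p, intr: CameraIntrinsics) -> tuple[float, float]:
    """Project a camera-frame point to pixel coordinates (the forward model)."""
    p = np.asarray(p, dtype=float)
    if p[2] <= 0:
        raise InvalidDepthError("point must lie in front of the camera (z > 0)")
    return (
        intr.fx * p[0] / p[2] + intr.ox,
        intr.fy * p[1] / p[2] + intr.oy,
    )


def camera_to_world(p, ext: CameraExtrinsics) -> np.ndarray:
    """Map camera-frame point(s) to the world frame, ``R.T @ (p - t)``.

    Accepts a single 3-vector or an (..., 3) array.
    """
    p = np.asarray(p, dtype=float)
    return (p - ext.t) @ ext.R  # row-vector form of R.T @ (p - t)


def world_to_camera(p, ext: CameraExtrinsics) -> np.ndarray:
    """Map world-frame point(s) into the camera frame, ``R @ p + t``."""
    p = np.asarray(p, dtype=float)
    return p @ ext.R.T + ext.t


def unproject_depth_map(
    depth: DepthMap,
    mask: np.ndarray,
    intr: CameraIntrinsics,
    ext: CameraExtrinsics | None = None,
) -> PointGrid:
    """Convert a masked depth map into an image-ordered grid of world points.

    A cell is valid iff its mask bit is set *and* its depth sample is valid;
    invalid cells carry zeros.  Grid ordering preserves image row/column
    order.

    Raises
    ------
    DimensionMismatchError
        If ``mask`` and ``depth`` shapes differ.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != depth.shape:
        raise DimensionMismatchError(
            f"mask shape {mask.shape} != depth shape {depth.shape}"
        )
    if ext is None:
        ext = CameraExtrinsics.identity()
    H, W = depth.shape
    v, u = np.mgrid[0:H, 0:W].astype(float)
    z = depth.values
    ok = depth.valid & mask
    zs = np.where(ok, z, 1.0)  # placeholder depth for invalid cells
    x = (u - intr.ox) * zs / intr.fx
    y = (v - intr.oy) * zs / intr.fy
    pts_cam = np.stack([x, y, zs], axis=-1)
    pts_world = camera_to_world(pts_cam, ext)
    pts_world[~ok] = 0.0
    return PointGrid(points=pts_world, valid=ok)
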