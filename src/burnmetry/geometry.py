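"""Wound area measurement: best-fit-plane 2D projection area and triangulated
3D surface area.

Two complementary quantities are computed for each wound:

* **2D projection area** — the wound's outer contour is lifted to 3D, a
  best-fit plane is obtained from the contour with Newell's method, the
  contour is projected onto that plane and its polygon area is evaluated in
  an in-plane orthonormal basis.  This is the planimetric area a flat
  tracing would report, made pose-independent by the best-fit plane.
* **3D surface area** — the depth-mapped wound region is triangulated by
  splitting every 2x2 pixel quad along its top-left -> bottom-right
  diagonal (matching the row-major scan order of the grid); the area is the
  sum of Heron-formula triangle areas.  A triangle contributes only when all
  three of its vertices are masked and depth-valid, so the estimate never
  extrapolates outside the segmented wound; the resulting boundary bias is
  surfaced through the ``coverage`` field.

Internally everything is in meters; reported areas are cm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

from .camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    DepthMap,
    PointGrid,
    unproject_depth_map,
)
from .errors import (
    DegenerateContourError,
    DimensionMismatchError,
    NoWoundError,
    UnmeasurableWoundError,
)

__all__ = [
    "Plane",
    "WoundMeasurement",
    "MeasurementResult",
    "heron_area",
    "newell_normal",
    "projection_area",
    "surface_area_3d",
    "trace_boundary",
    "measure",
]

M2_TO_CM2 = 1e4

#: 4-connectivity structuring element for wound components.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def heron_area(p1, p2, p3):
    """Triangle area from three 3D vertices via Heron's formula.

    Uses the numerically stabilized (sorted-side, Kahan) form
    ``A = sqrt((a+(b+c)) (c-(a-b)) (c+(a-b)) (a+(b-c))) / 4`` with
    ``a >= b >= c``, so near-degenerate triangles cannot produce a negative
    radicand; exactly degenerate triangles return 0.  Broadcasts over leading
    dimensions. Input in meters, output in m^2.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    sa = np.linalg.norm(p2 - p3, axis=-1)
    sb = np.linalg.norm(p1 - p3, axis=-1)
    sc = np.linalg.norm(p1 - p2, axis=-1)
    s = np.sort(np.stack([sa, sb, sc], axis=-1), axis=-1)
    c, b, a = s[..., 0], s[..., 1], s[..., 2]
    rad = (a + (b + c)) * (c - (a - b)) * (c + (a - b)) * (a + (b - c))
    return 0.25 * np.sqrt(np.maximum(rad, 0.0))


@dataclass(frozen=True)
class Plane:
    """Best-fit plane: unit normal plus a reference point (contour centroid)."""

    normal: np.ndarray
    centroid: np.ndarray


def newell_normal(contour) -> Plane:
    """Best-fit plane of an ordered 3D contour via Newell's method.

    The normal is the cyclic Newell summation over consecutive vertex pairs;
    its sign follows the contour orientation.  The reference point is the
    vertex centroid.

    Raises
    ------
    DegenerateContourError
        Fewer than 3 vertices, or vertices collinear/coincident.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateContourError("contour needs at least 3 points in 3D")
    nxt = np.roll(pts, -1, axis=0)
    n = np.array(
        [
            np.sum((pts[:, 1] - nxt[:, 1]) * (pts[:, 2] + nxt[:, 2])),
            np.sum((pts[:, 2] - nxt[:, 2]) * (pts[:, 0] + nxt[:, 0])),
            np.sum((pts[:, 0] - nxt[:, 0]) * (pts[:, 1] + nxt[:, 1])),
        ]
    )
    norm = np.linalg.norm(n)
    scale = max(1.0, float(np.ptp(pts)) ** 2)
    if norm <= 1e-12 * scale:
        raise DegenerateContourError("contour points are collinear or coincident")
    return Plane(normal=n / norm, centroid=pts.mean(axis=0))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # First axis: world x-axis projected into the plane; y-axis fallback when
    # x is nearly parallel to the normal. Any orthonormal pair gives the same
    # polygon area; fixing one makes outputs reproducible.
    seed = np.array([1.0, 0.0, 0.0])
    e1 = seed - np.dot(seed, normal) * normal
    if np.linalg.norm(e1) < 1e-6:
        seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - np.dot(seed, normal) * normal
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(normal, e1)


def projection_area(contour, plane: Plane | None = None) -> float:
    """Area (cm^2) of a 3D contour projected onto its best-fit plane.

    Vertices are projected orthogonally onto the plane, expressed in an
    in-plane orthonormal basis and fed to the shoelace formula; the absolute
    signed area is returned, which is exact for simple polygons whether
    convex or not (and agrees with a Heron fan on convex ones).  A
    self-intersecting contour triggers a ``RuntimeWarning`` but the signed
    value is still returned.
    """
    pts = np.asarray(contour, dtype=float)
    if plane is None:
        plane = newell_normal(pts)
    rel = pts - plane.centroid
    rel = rel - np.outer(rel @ plane.normal, plane.normal)
    e1, e2 = _plane_basis(plane.normal)
    x, y = rel @ e1, rel @ e2
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    ring = np.stack([x, y], axis=1)
    keep = np.any(ring != np.roll(ring, 1, axis=0), axis=1)
    ring = ring[keep]
    if len(ring) >= 3 and not LineString(np.vstack([ring, ring[:1]])).is_simple:
        warnings.warn("self-intersecting contour", RuntimeWarning, stacklevel=2)
    return float(area) * M2_TO_CM2


def surface_area_3d(grid: PointGrid, mask) -> tuple[float, int, float]:
    """Triangulated 3D surface area of a masked point grid.

    Every 2x2 quad of adjacent pixels is split along its top-left ->
    bottom-right diagonal into two triangles; a triangle contributes iff all
    three vertices are valid masked cells.  Returns
    ``(area_cm2, triangle_count, coverage)`` where coverage is the fraction
    of fully-masked quads that contributed both triangles (i.e. had complete
    depth data).

    Raises
    ------
    UnmeasurableWoundError
        If no triangle contributes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise DimensionMismatchError("mask shape must match grid shape")
    ok = grid.valid & mask
    P = grid.points
    A, B = P[:-1, :-1], P[:-1, 1:]
    C, D = P[1:, 1:], P[1:, :-1]
    okA, okB = ok[:-1, :-1], ok[:-1, 1:]
    okC, okD = ok[1:, 1:], ok[1:, :-1]
    t1 = okA & okB & okC  # upper triangle (TL, TR, BR)
    t2 = okA & okC & okD  # lower triangle (TL, BR, BL)
    area = heron_area(A, B, C)[t1].sum() + heron_area(A, C, D)[t2].sum()
    count = int(t1.sum() + t2.sum())
    if count < 1:
        raise UnmeasurableWoundError("no valid surface triangle in wound region")
    mq = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, 1:] & mask[1:, :-1]
    full = int(mq.sum())
    coverage = float((t1 & t2).sum() / full) if full else 0.0
    return float(area) * M2_TO_CM2, count, coverage


# Moore neighborhood in clockwise order starting due north, as (row, col).
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_boundary(mask) -> list[tuple[int, int]]:
    """Outer boundary of a single connected component by Moore tracing.

    Starts at the topmost-leftmost masked cell and walks the 8-neighborhood
    clockwise, stopping when the initial (cell, backtrack) state recurs.
    Returns boundary cell indices ``(row, col)`` ordered counter-clockwise in
    image coordinates (positive shoelace in ``(u, v)``).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoWoundError("empty mask")
    H, W = mask.shape
    start = (int(rows[0]), int(cols[0]))

    def masked(cell):
        r, c = cell
        return 0 <= r < H and 0 <= c < W and mask[r, c]

    state0 = (start, (start[0], start[1] - 1))
    cur, prev = state0
    contour: list[tuple[int, int]] = []
    while True:
        contour.append(cur)
        d = (prev[0] - cur[0], prev[1] - cur[1])
        i = _MOORE.index(d)
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(i + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if masked(cand):
                pr, pc = _MOORE[(i + k - 1) % 8]
                nxt, new_prev = cand, (cur[0] + pr, cur[1] + pc)
                break
        if nxt is None:  # isolated single cell
            break
        cur, prev = nxt, new_prev
        if (cur, prev) == state0:
            break
    # enforce counter-clockwise orientation (positive area in (u, v))
    u = np.array([c for _, c in contour], dtype=float)
    v = np.array([r for r, _ in contour], dtype=float)
    signed = 0.5 * (np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))
    if signed < 0:
        contour.reverse()
    return contour


@dataclass
class WoundMeasurement:
    """Per-component measurement: areas in cm^2, unitless 3D/2D ratio."""

    label: int
    area2d_cm2: float
    area3d_cm2: float
    ratio: float
    triangle_count: int
    coverage: float
    pixel_count: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class MeasurementResult:
    """Measurement of every wound in an image plus image-level totals.

    Totals are plain sums of the per-wound values; the total ratio is the
    ratio of total 3D to total 2D area.
    """

    wounds: list[WoundMeasurement]
    total_area2d_cm2: float
    total_area3d_cm2: float
    total_ratio: float
    warnings: list[str] = field(default_factory=list)


def measure(
    depth: DepthMap,
    mask,
    intr: CameraIntrinsics,
    ext: CameraExtrinsics | None = None,
    *,
    coverage_threshold: float = 0.95,
) -> MeasurementResult:
    """Measure every wound component in a masked depth map.

    The mask is split into 4-connected components; each component gets its
    own contour (Moore tracing), best-fit plane, 2D projection area and 3D
    triangulated area.  When an image contains multiple wounds the reported
    totals are the separate sums of the 2D and the 3D results.

    Components too small or too data-poor to measure are skipped with a
    warning; ``coverage < coverage_threshold`` flags a low-coverage warning
    in the result metadata rather than failing.

    Raises
    ------
    NoWoundError
        If the mask is empty or no component is measurable.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != depth.shape:
        raise DimensionMismatchError("mask shape must match depth shape")
    if not mask.any():
        raise NoWoundError("mask contains no wound pixels")
    if ext is None:
        ext = CameraExtrinsics.identity()
    grid = unproject_depth_map(depth, mask, intr, ext)
    labels, n_comp = ndimage.label(mask, structure=_CROSS)
    wounds: list[WoundMeasurement] = []
    global_warnings: list[str] = []
    for comp in range(1, n_comp + 1):
        cmask = labels == comp
        npix = int(cmask.sum())
        if npix < 3:
            global_warnings.append(
                f"component {comp}: fewer than 3 cells, skipped"
            )
            continue
        comp_warn: list[str] = []
        try:
            cells = trace_boundary(cmask)
            contour_pts = np.array(
                [grid.points[r, c] for r, c in cells if grid.valid[r, c]]
            )
            n_dropped = len(cells) - len(contour_pts)
            if n_dropped:
                comp_warn.append(
                    f"{n_dropped} contour vertices dropped (invalid depth)"
                )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                a2 = projection_area(contour_pts)
            comp_warn.extend(str(w.message) for w in caught)
            a3, tric, cov = surface_area_3d(grid, cmask)
        except (DegenerateContourError, UnmeasurableWoundError) as exc:
            global_warnings.append(f"component {comp}: {exc}, skipped")
            continue
        if cov < coverage_threshold:
            comp_warn.append(
                f"low depth coverage {cov:.3f} < {coverage_threshold}"
            )
        wounds.append(
            WoundMeasurement(
                label=comp,
                area2d_cm2=a2,
                area3d_cm2=a3,
                ratio=a3 / a2 if a2 > 0 else float("nan"),
                triangle_count=tric,
                coverage=cov,
                pixel_count=npix,
                warnings=comp_warn,
            )
        )
    if not wounds:
        raise NoWoundError("no measurable wound component")
    tot2 = sum(w.area2d_cm2 for w in wounds)
    tot3 = sum(w.area3d_cm2 for w in wounds)
    return MeasurementResult(
        wounds=wounds,
        total_area2d_cm2=tot2,
        total_area3d_cm2=tot3,
        total_ratio=tot3 / tot2 if tot2 > 0 else float("nan"),
        warnings=global_warnings,
    )
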