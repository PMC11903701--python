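"""Elliptical cross-section curvature model and the curvature -> 3D/2D ratio map.

Limb and trunk cross-sections are modelled as ellipses whose *full* axis
lengths ``a >= b`` (cm) are measured with a caliper.  In this convention the
flatter vertex (end of the minor axis) has curvature ``b / a**2`` and the
sharper vertex (end of the major axis) has curvature ``a / b**2``; for a
circular cross-section of full diameter ``d`` both reduce to ``1 / d``.

Note this is *half* the differential-geometry curvature of the ellipse: the
convention works with diameters rather than radii, so the osculating circle
at a vertex with curvature ``kappa`` has radius ``1 / (2 * kappa)``.  All
downstream code (phantom construction included) follows the same diameter
convention.

``predicted_ratio`` turns a curvature into the expected 3D-surface to
2D-projection area ratio of a round template: the template is modelled as a
geodesic disc wrapped on a circular cylinder with the vertex's osculating
radius, and the ratio of the disc area to the area of its orthogonal
projection onto the tangent plane at the disc center is computed by
deterministic numerical integration of the foreshortening factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.integrate import quad

from .errors import OutOfModelError

__all__ = [
    "EllipseSection",
    "CurvaturePair",
    "ellipse_curvature",
    "predicted_ratio",
    "truncate_reported",
]


@dataclass(frozen=True)
class EllipseSection:
    """Elliptical cross-section with full axis lengths in cm (long >= short > 0)."""

    long_axis: float
    short_axis: float

    def __post_init__(self) -> None:
        if not (self.long_axis >= self.short_axis > 0):
            raise ValueError("axes must satisfy long_axis >= short_axis > 0")


@dataclass(frozen=True)
class CurvaturePair:
    """Curvatures (1/cm, diameter convention) at the two vertices of a section."""

    flat_side: float
    curved_side: float

    def reported(self) -> "CurvaturePair":
        """Curvatures truncated (toward zero) to 3 decimals, as reported."""
        return CurvaturePair(
            truncate_reported(self.flat_side), truncate_reported(self.curved_side)
        )


def truncate_reported(x: float, decimals: int = 3) -> float:
    """Truncate toward zero at ``decimals`` places (reporting convention)."""
    f = 10.0**decimals
    return math.trunc(x * f) / f


def ellipse_curvature(sec: EllipseSection) -> CurvaturePair:
    """Curvature pair of an elliptical cross-section (full-axis convention).

    flat side: ``short / long**2``; curved side: ``long / short**2``.  For
    ``long == short == d`` both equal ``1 / d``.
    """
    a, b = sec.long_axis, sec.short_axis
    return CurvaturePair(flat_side=b / a**2, curved_side=a / b**2)


def predicted_ratio(curvature: float, template_area: float = 43.0) -> float:
    """Predicted 3D/2D area ratio of a round template on a surface of the
    given curvature (1/cm, diameter convention).

    A geodesic disc of the requested area (cm^2) is wrapped on a circular
    cylinder of radius ``1 / (2 * curvature)``; the function returns
    disc area / area of its orthogonal projection onto the tangent plane at
    the disc center.  In developed coordinates ``(s, y)`` the projection
    area is ``integral of cos(s / R)`` over the disc, evaluated with
    adaptive quadrature.  ``curvature = 0`` returns exactly 1.  Depends on
    ``curvature * sqrt(area)`` only.

    Raises
    ------
    OutOfModelError
        If the disc would wrap a quarter turn or more each way
        (``r_disc >= pi * R / 2``), where the projection folds over.
    """
    if curvature < 0:
        raise ValueError("curvature must be >= 0")
    if template_area <= 0:
        raise ValueError("template_area must be > 0")
    if curvature == 0:
        return 1.0
    r = math.sqrt(template_area / math.pi)
    R = 1.0 / (2.0 * curvature)
    if r >= math.pi * R / 2.0:
        raise OutOfModelError(
            f"disc radius {r:.3g} cm wraps beyond a quarter turn on "
            f"cylinder radius {R:.3g} cm"
        )
    proj, _ = quad(
        lambda s: 2.0 * math.sqrt(max(r * r - s * s, 0.0)) * math.cos(s / R),
        -r,
        r,
        limit=200,
    )
    return template_area / proj
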