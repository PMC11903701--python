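"""Cohort statistics and 3D-vs-2D regression machinery.

Measurement collections are plain pandas DataFrames with one row per
measured image ("record") and the columns

    location      anatomical-site label (str)
    area2d_cm2    2D projection area
    area3d_cm2    3D surface area
    gt_area_cm2   known template/ground-truth area (optional, NaN if absent)
    curvature     site curvature, 1/cm (optional)
    n_wounds      wound count in the image (optional, default 1)

``ratio_stats`` summarizes per-location mean +/- SD of 3D/GT, 3D/2D and
curvature.  ``fit_3d_vs_2d`` regresses the 3D surface area on the 2D
projection area by ordinary least squares: the slope says how many times
the 3D area is the 2D area on average, and R^2 how well the linear relation
explains the scatter.  ``ratio_vs_size`` regresses the 3D/2D ratio on the
3D area (the size-dependence of the underestimation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError

__all__ = [
    "MeasurementRecord",
    "RegressionFit",
    "records_frame",
    "ratio_stats",
    "fit_3d_vs_2d",
    "ratio_vs_size",
]

RECORD_COLUMNS = [
    "location",
    "area2d_cm2",
    "area3d_cm2",
    "gt_area_cm2",
    "curvature",
    "n_wounds",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured image."""

    location: str
    area2d_cm2: float
    area3d_cm2: float
    gt_area_cm2: float | None = None
    curvature: float | None = None
    n_wounds: int = 1

    def __post_init__(self) -> None:
        if self.area2d_cm2 <= 0 or self.area3d_cm2 <= 0:
            raise ValueError("areas must be positive")


def records_frame(records) -> pd.DataFrame:
    """Normalize a DataFrame or iterable of MeasurementRecord to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    for col in ("gt_area_cm2", "curvature"):
        if col not in df:
            df[col] = np.nan
    if "n_wounds" not in df:
        df["n_wounds"] = 1
    return df


def ratio_stats(records) -> pd.DataFrame:
    """Per-location sample mean and SD (n-1 denominator) of 3D/GT, 3D/2D
    and curvature — the cohort summary table.

    Locations with no records are omitted; a location with a single record
    gets NaN SDs with a warning.  Permutation-invariant in record order
    (rows are sorted by location name).
    """
    df = records_frame(records)
    if df.empty:
        warnings.warn("no records; empty summary", RuntimeWarning, stacklevel=2)
        return pd.DataFrame(
            columns=["location", "n", "ratio_3d_gt_mean", "ratio_3d_gt_sd",
                     "ratio_3d_2d_mean", "ratio_3d_2d_sd",
                     "curvature_mean", "curvature_sd"]
        ).set_index("location")
    df = df.assign(
        ratio_3d_gt=df["area3d_cm2"] / df["gt_area_cm2"],
        ratio_3d_2d=df["area3d_cm2"] / df["area2d_cm2"],
    )
    rows = []
    for loc, g in sorted(df.groupby("location"), key=lambda kv: kv[0]):
        if len(g) < 2:
            warnings.warn(
                f"location {loc!r} has fewer than 2 records; SD undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        rows.append(
            {
                "location": loc,
                "n": len(g),
                "ratio_3d_gt_mean": g["ratio_3d_gt"].mean(),
                "ratio_3d_gt_sd": g["ratio_3d_gt"].std(ddof=1),
                "ratio_3d_2d_mean": g["ratio_3d_2d"].mean(),
                "ratio_3d_2d_sd": g["ratio_3d_2d"].std(ddof=1),
                "curvature_mean": g["curvature"].mean(),
                "curvature_sd": g["curvature"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("location")


@dataclass(frozen=True)
class RegressionFit:
    """Simple OLS fit ``y = slope * x + intercept`` with coefficient of
    determination ``r_squared`` and sample size ``n``."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    if len(x) < 3:
        raise DegenerateFitError("need at least 3 records for a fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant abscissa; regression undefined")
    res = stats.linregress(x, y)
    rsq = float(res.rvalue**2)
    if np.isnan(rsq):  # zero-variance y: the flat line is an exact fit
        resid = y - (res.slope * x + res.intercept)
        rsq = 1.0 if np.allclose(resid, 0.0, atol=1e-12) else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=rsq,
        n=len(x),
    )


def fit_3d_vs_2d(records) -> RegressionFit:
    """OLS of 3D surface area (y) on 2D projection area (x), with intercept."""
    df = records_frame(records)
    return _ols(df["area2d_cm2"].to_numpy(float), df["area3d_cm2"].to_numpy(float))


def ratio_vs_size(records) -> RegressionFit:
    """OLS of the 3D/2D area ratio (y) on the 3D surface area (x)."""
    df = records_frame(records)
    x = df["area3d_cm2"].to_numpy(float)
    y = x / df["area2d_cm2"].to_numpy(float)
    return _ols(x, y)
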