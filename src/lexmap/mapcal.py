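"""Schematic-map calibration: digitized pixels -> calibrated frame -> distances.

Schematic transit diagrams are compared against geography by digitizing
station positions off the published map image (pixel X/Y exports), fitting an
affine transform from pixel space to a calibrated frame (typically the
geographic lon/lat frame, using a subset of stations as control points), and
then measuring distances and coordinate correlations in that frame.

An affine fit (rotation, anisotropic scale, shear, translation) absorbs the
arbitrary orientation and scale of the digitization — including the image
convention of a downward-pointing y axis, which simply shows up as a negative
axis coefficient. What it deliberately does *not* absorb is the schematic
distortion itself; that residual distortion is the object of study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .geography import EARTH_RADIUS_KM, haversine_km

__all__ = [
    "ControlPoint",
    "AffineTransform",
    "fit_affine",
    "map_distance",
    "pearson_r",
    "read_points_csv",
    "calibrate_points",
]


@dataclass(frozen=True)
class ControlPoint:
    """A digitized point with known location in the calibrated frame."""

    pixel: tuple[float, float]
    target: tuple[float, float]


@dataclass(frozen=True)
class AffineTransform:
    """``target = linear @ pixel + offset`` with a non-singular 2x2 linear part."""

    linear: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if self.linear.shape != (2, 2) or self.offset.shape != (2,):
            raise ValueError("linear must be 2x2 and offset length 2")
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine transform is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` (or a single) pixel point into the calibrated frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out


def fit_affine(controls: Sequence[ControlPoint]) -> AffineTransform:
    """Least-squares affine calibration from >= 3 non-collinear control points.

    With exactly three non-collinear controls the fit interpolates them; with
    more, it minimises the summed squared target residuals.
    """
    if len(controls) < 3:
        raise ValueError(f"need >= 3 control points, got {len(controls)}")
    P = np.array([c.pixel for c in controls], dtype=float)
    T = np.array([c.target for c in controls], dtype=float)
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("control points are collinear; affine calibration is degenerate")
    design = np.column_stack([P, np.ones(len(controls))])
    coef, *_ = np.linalg.lstsq(design, T, rcond=None)  # (3, 2)
    return AffineTransform(linear=coef[:2].T, offset=coef[2])


def map_distance(
    p: Sequence[float],
    q: Sequence[float],
    mode: str = "planar",
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Distance between two calibrated map points.

    ``planar``: Euclidean distance in the calibrated frame — the defensible
    metric for a flat schematic image. ``lonlat-compat``: treat the points as
    (x, y) = (lon, lat) and apply the spherical great-circle formula, mirroring
    the replication convention of feeding digitized map X/Y into a geographic
    distance routine; only standardized/correlational summaries of these
    values are meaningful.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if mode == "planar":
        return float(np.linalg.norm(p - q))
    if mode == "lonlat-compat":
        return float(haversine_km((p[1], p[0]), (q[1], q[0]), radius_km))
    raise ValueError(f"unknown mode {mode!r}; use 'planar' or 'lonlat-compat'")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; rejects constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 observations, got {len(x)}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def read_points_csv(path: str | Path) -> pd.DataFrame:
    """Read a digitizer export: CSV with header ``label,x,y``."""
    df = pd.read_csv(path, comment="#", dtype={"label": str})
    missing = [c for c in ("label", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[["label", "x", "y"]]


def calibrate_points(
    pixels: pd.DataFrame,
    targets: pd.DataFrame,
    control_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, AffineTransform]:
    """Calibrate digitized pixels onto a target frame via shared labels.

    ``pixels`` and ``targets`` are ``label,x,y`` tables; control points are
    the labels present in both (or the subset ``control_labels``). Returns the
    full pixel table with calibrated ``map_x, map_y`` columns plus the fitted
    transform.
    """
    merged = pixels.merge(targets, on="label", suffixes=("_px", "_t"))
    if control_labels is not None:
        merged = merged[merged["label"].isin(set(control_labels))]
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} shared control labels; need >= 3 for calibration"
        )
    controls = [
        ControlPoint(pixel=(r.x_px, r.y_px), target=(r.x_t, r.y_t))
        for r in merged.itertuples(index=False)
    ]
    transform = fit_affine(controls)
    calibrated = transform.apply(pixels[["x", "y"]].to_numpy())
    out = pixels.copy()
    out["map_x"] = calibrated[:, 0]
    out["map_y"] = calibrated[:, 1]
    return out, transform
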