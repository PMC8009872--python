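"""Rotation geometry about the tilt axis and per-ROI eucentric-height fitting.

Coordinate frame convention (used package-wide):

* ``x`` runs along the tilt axis and is invariant under tilting.
* ``y`` runs perpendicular to the tilt axis, in the specimen plane at zero
  tilt.
* ``z`` runs along the beam, toward the source.
* A positive tilt angle rotates ``+y`` toward ``+z``.

All angles are accepted in degrees at every interface; stage/targeting
lengths are micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RoiTarget",
    "EucentricFit",
    "rotate_point_about_tilt_axis",
    "fit_eucentric",
    "predict_roi_correction",
]

#: Largest beam-image-shift radius considered safe, in micrometres.
DEFAULT_MAX_BIS_RADIUS_UM = 8.0


class GeometryError(ValueError):
    """Invalid geometric input (non-finite values, out-of-range angles)."""


class UnderdeterminedFitError(GeometryError):
    """The eucentric fit design matrix is rank deficient."""


@dataclass(frozen=True)
class RoiTarget:
    """One region of interest addressed by beam-image shift.

    Parameters
    ----------
    id : str
        Free-form label.
    x, y : float
        In-plane position in micrometres; ``x`` along the tilt axis,
        ``y`` perpendicular to it at zero tilt.
    z : float
        Height offset (micrometres) from the tracking area's plane of
        rotation.
    bis_offset : tuple of float
        Beam-image-shift vector (micrometres) from the tracking area at
        zero tilt.
    """

    id: str
    x: float
    y: float
    z: float = 0.0
    bis_offset: tuple[float, float] = (0.0, 0.0)
    max_bis_radius: float = field(default=DEFAULT_MAX_BIS_RADIUS_UM, repr=False)

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.z, *self.bis_offset)
        if not all(math.isfinite(v) for v in vals):
            raise GeometryError(f"non-finite coordinate in ROI {self.id!r}")
        r = math.hypot(*self.bis_offset)
        if r > self.max_bis_radius + 1e-9:
            raise GeometryError(
                f"ROI {self.id!r} BIS offset {r:.3f} um exceeds the "
                f"{self.max_bis_radius:g} um radius limit"
            )


@dataclass(frozen=True)
class EucentricFit:
    """Result of fitting the axis-rotation model to targeting data.

    ``y0`` and ``z0`` are the in-plane offset and height offset (micrometres)
    of the target relative to the plane of rotation; ``rms_residual`` is the
    root-mean-square misfit of the observations in micrometres.
    """

    y0: float
    z0: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise GeometryError("eucentric fit requires at least 2 points")
        if self.rms_residual < 0:
            raise GeometryError("rms_residual must be non-negative")


def rotate_point_about_tilt_axis(
    y: float, z: float, theta: float
) -> tuple[float, float]:
    """Rotate the point ``(y, z)`` by ``theta`` degrees about the tilt axis.

    Returns ``(y', z')`` with ``y' = y cos(t) + z sin(t)`` and
    ``z' = -y sin(t) + z cos(t)``. ``y'`` is the new in-plane coordinate
    perpendicular to the axis and ``z'`` the new height along the beam.
    """
    if not (math.isfinite(y) and math.isfinite(z) and math.isfinite(theta)):
        raise GeometryError("rotate_point_about_tilt_axis: non-finite input")
    if abs(theta) > 90.0:
        raise GeometryError(f"|theta| must be <= 90 degrees, got {theta}")
    t = math.radians(theta)
    c, s = math.cos(t), math.sin(t)
    return (y * c + z * s, -y * s + z * c)


def fit_eucentric(
    observations: Iterable[tuple[float, float]],
    *,
    reject_outliers: bool = False,
    outlier_k: float = 3.0,
) -> EucentricFit:
    """Fit ``(y0, z0)`` so that ``y_obs(theta) = y0 cos(t) + z0 sin(t)``.

    ``observations`` is a sequence of ``(theta_degrees, y_observed_um)``
    pairs. The fit is ordinary (unweighted) linear least squares with a
    closed-form solution. With ``reject_outliers`` enabled, points whose
    residual exceeds ``outlier_k`` times the rms residual of a first pass
    are dropped and the model refit once.

    Raises
    ------
    UnderdeterminedFitError
        If fewer than two points are supplied or all tilt angles coincide.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise UnderdeterminedFitError(
            "fit_eucentric needs at least 2 (theta, y) observations"
        )
    if not np.all(np.isfinite(obs)):
        raise GeometryError("fit_eucentric: non-finite observation")
    theta, y_obs = obs[:, 0], obs[:, 1]
    if np.unique(theta).size < 2:
        raise UnderdeterminedFitError(
            "all observations share one tilt angle; (y0, z0) is under-determined"
        )

    def _solve(th: np.ndarray, yo: np.ndarray) -> tuple[float, float, np.ndarray]:
        t = np.radians(th)
        design = np.column_stack([np.cos(t), np.sin(t)])
        coef, _, rank, _ = np.linalg.lstsq(design, yo, rcond=None)
        if rank < 2:
            raise UnderdeterminedFitError("rank-deficient eucentric design matrix")
        return float(coef[0]), float(coef[1]), yo - design @ coef

    y0, z0, resid = _solve(theta, y_obs)
    if reject_outliers and theta.size > 2:
        rms = float(np.sqrt(np.mean(resid**2)))
        if rms > 0:
            keep = np.abs(resid) <= outlier_k * rms
            if keep.sum() >= 2 and np.unique(theta[keep]).size >= 2:
                y0, z0, resid = _solve(theta[keep], y_obs[keep])
                theta = theta[keep]
    rms = float(np.sqrt(np.mean(resid**2)))
    return EucentricFit(y0=y0, z0=z0, rms_residual=rms, n_points=int(theta.size))


def predict_roi_correction(fit: EucentricFit, theta: float) -> tuple[float, float]:
    """Predict the targeting and focus correction for a fitted ROI.

    Returns ``(y_target, defocus_correction)``: the rotated in-plane
    position that the image shift must address and the height change to
    apply to the focus setting, both in micrometres.
    """
    return rotate_point_about_tilt_axis(fit.y0, fit.z0, theta)


def roi_positions_at_tilt(
    rois: Sequence[RoiTarget], theta: float
) -> np.ndarray:
    """Ground-truth ``(x, y', z')`` of each ROI at a tilt angle, shape (n, 3)."""
    out = np.empty((len(rois), 3), dtype=float)
    for i, roi in enumerate(rois):
        yp, zp = rotate_point_about_tilt_axis(roi.y, roi.z, theta)
        out[i] = (roi.x, yp, zp)
    return out
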