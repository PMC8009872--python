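"""Seeded virtual stage + specimen scene and the closed-loop acquisition
controller for beam-image-shift tilt-series collection.

The simulator is a declared model, not a claim about any instrument: the
stage draws fresh Gaussian in-plane jitter at every mechanical move, the
specimen sits at a fixed (unknown to the controller) height offset from the
plane of rotation, and each ROI carries its own topographic height offset.
Image shift is applied exactly. Tracking images are rendered at binned pixel
sizes so a full session runs in seconds; all thresholds remain in physical
nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from tiltkit.geometry import (
    EucentricFit,
    RoiTarget,
    UnderdeterminedFitError,
    fit_eucentric,
    predict_roi_correction,
    rotate_point_about_tilt_axis,
)
from tiltkit.scheme import TiltScheme
from tiltkit.tracking import TrackingState, iterative_track

__all__ = [
    "SceneConfig",
    "GridScene",
    "MagLevel",
    "NoiseModel",
    "StagePose",
    "SessionConfig",
    "VirtualStage",
    "AcquisitionLog",
    "make_grid_scene",
    "render_view",
    "run_bisect_session",
    "summarize_session",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic specimen scene."""

    lattice: tuple[int, int] = (5, 5)
    pitch_um: float = 2.5
    topography_sigma_um: float = 0.1
    z_max_um: float = 0.5
    n_fiducials: int = 300
    fiducial_field_um: float = 1.6
    fiducial_z_spread_um: float = 0.005


@dataclass(frozen=True)
class GridScene:
    """Deterministic synthetic scene: ROI lattice plus tracking-area content."""

    roi_xy: np.ndarray          # (n, 2) um, tracking area at the origin
    roi_z: np.ndarray           # (n,) um topographic height offsets
    fiducial_positions: np.ndarray  # (m, 3) um, content of the tracking area
    fiducial_weights: np.ndarray    # (m,) relative brightness
    config: SceneConfig
    background_texture_seed: int

    @property
    def rois(self) -> list[RoiTarget]:
        out = []
        for i, ((x, y), z) in enumerate(zip(self.roi_xy, self.roi_z)):
            out.append(
                RoiTarget(
                    id=f"roi_{i:02d}", x=float(x), y=float(y), z=float(z),
                    bis_offset=(float(x), float(y)),
                )
            )
        return out


def make_grid_scene(config: SceneConfig | None = None, seed: int = 0) -> GridScene:
    """Build a seeded scene with an ROI hole lattice centred on the origin."""
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    ny, nx = cfg.lattice
    gy, gx = np.mgrid[0:ny, 0:nx].astype(float)
    gy = (gy - (ny - 1) / 2.0) * cfg.pitch_um
    gx = (gx - (nx - 1) / 2.0) * cfg.pitch_um
    roi_xy = np.column_stack([gx.ravel(), gy.ravel()])
    roi_z = rng.normal(0.0, cfg.topography_sigma_um, size=len(roi_xy))
    roi_z = np.clip(roi_z, -cfg.z_max_um, cfg.z_max_um)
    half = cfg.fiducial_field_um / 2.0
    fid = np.column_stack([
        rng.uniform(-half, half, cfg.n_fiducials),
        rng.uniform(-half, half, cfg.n_fiducials),
        rng.normal(0.0, cfg.fiducial_z_spread_um, cfg.n_fiducials),
    ])
    weights = rng.uniform(0.5, 1.5, cfg.n_fiducials)
    return GridScene(
        roi_xy=roi_xy,
        roi_z=roi_z,
        fiducial_positions=fid,
        fiducial_weights=weights,
        config=cfg,
        background_texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass(frozen=True)
class MagLevel:
    """A rendering magnification level (binned for simulation speed)."""

    name: str
    pixel_size_a: float   # Angstrom / px
    shape: tuple[int, int] = (256, 256)
    blob_sigma_a: float = 120.0  # apparent bead radius after blur

    @property
    def field_um(self) -> tuple[float, float]:
        return (
            self.shape[0] * self.pixel_size_a * 1e-4,
            self.shape[1] * self.pixel_size_a * 1e-4,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Poisson counting noise at a mean dose plus Gaussian readout noise."""

    dose_per_px: float = 400.0
    contrast: float = 0.35
    readout_sigma: float = 1.0
    enabled: bool = True


@dataclass
class StagePose:
    """Ground-truth stage/optics state used for rendering."""

    tilt: float = 0.0            # degrees
    error_um: tuple[float, float] = (0.0, 0.0)   # (u, v) in-plane jitter
    image_shift_um: tuple[float, float] = (0.0, 0.0)
    specimen_z_um: float = 0.0   # height of the tracking plane vs rotation axis


def render_view(
    scene: GridScene,
    pose: StagePose,
    mag_level: MagLevel,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Project the tracking-area content at the pose's tilt and render it.

    The tilt axis runs along the image x (column) direction; positions
    perpendicular to it foreshorten by cos(tilt) and pick up the height
    term of the axis-rotation model. The pose's jitter and the (exact)
    image shift displace the content rigidly.
    """
    noise = noise_model or NoiseModel()
    theta = math.radians(pose.tilt)
    c, s = math.cos(theta), math.sin(theta)
    x = scene.fiducial_positions[:, 0]
    y = scene.fiducial_positions[:, 1]
    z = scene.fiducial_positions[:, 2] + pose.specimen_z_um
    u = x + pose.error_um[0] + pose.image_shift_um[0]
    v = y * c + z * s + pose.error_um[1] + pose.image_shift_um[1]

    h, w = mag_level.shape
    px_um = mag_level.pixel_size_a * 1e-4
    col = u / px_um + (w - 1) / 2.0
    row = v / px_um + (h - 1) / 2.0
    img = np.zeros((h, w))
    ok = (col > -1) & (col < w) & (row > -1) & (row < h)
    r0 = np.floor(row[ok]).astype(int)
    c0 = np.floor(col[ok]).astype(int)
    fr = row[ok] - r0
    fc = col[ok] - c0
    wt = scene.fiducial_weights[ok]
    for dr, dc, f in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        sel = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(img, (rr[sel], cc[sel]), wt[sel] * f[sel])
    sigma_px = mag_level.blob_sigma_a / mag_level.pixel_size_a
    img = ndimage.gaussian_filter(img, sigma_px)
    if img.max() > 0:
        img = img / img.max()
    if not noise.enabled:
        return img
    rng = np.random.default_rng(seed)
    expected = noise.dose_per_px * (1.0 + noise.contrast * img)
    out = rng.poisson(expected).astype(float)
    out += rng.normal(0.0, noise.readout_sigma, out.shape)
    return out


@dataclass
class VirtualStage:
    """Mechanical stage with imprecise moves and exact electron-optical shift."""

    in_plane_error_sigma_nm: float = 200.0
    specimen_z_um: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.rng_seed)
        self.pose = StagePose(specimen_z_um=self.specimen_z_um)

    def tilt_to(self, theta: float) -> None:
        """Mechanical tilt: reaches the angle exactly, jitters in plane."""
        sigma_um = self.in_plane_error_sigma_nm * 1e-3
        self.pose = StagePose(
            tilt=theta,
            error_um=tuple(self._rng.normal(0.0, sigma_um, 2)),
            image_shift_um=(0.0, 0.0),
            specimen_z_um=self.specimen_z_um,
        )

    def apply_image_shift(self, du_um: float, dv_um: float) -> None:
        s = self.pose.image_shift_um
        self.pose = replace(self.pose, image_shift_um=(s[0] + du_um, s[1] + dv_um))


@dataclass(frozen=True)
class SessionConfig:
    """Controller and simulator settings for one closed-loop session."""

    low_mag: MagLevel = MagLevel("low_mag", pixel_size_a=104.0, blob_sigma_a=250.0)
    high_mag: MagLevel = MagLevel("high_mag", pixel_size_a=27.4)
    low_threshold_nm: float = 100.0
    high_threshold_nm: float = 5.0
    max_iterations: int = 5
    jitter_sigma_nm: float = 200.0
    specimen_z_um: float = 0.25
    roi_measure_sigma_um: float = 0.005
    correct_eucentric: bool = True
    min_fit_points: int = 5
    peak_floor: float = 0.2
    focus_area_offset_um: float = 1.5  # along the tilt axis
    noise: NoiseModel = NoiseModel()

    def __post_init__(self) -> None:
        if self.low_threshold_nm <= self.high_threshold_nm:
            raise ValueError("low-mag threshold must exceed high-mag threshold")


@dataclass
class AcquisitionLog:
    """One record per (roi, tilt) in scheme order, plus per-tilt tracking."""

    records: pd.DataFrame
    tracking: pd.DataFrame
    config: SessionConfig
    seed: int


def _track_level(
    scene: GridScene,
    stage: VirtualStage,
    level: MagLevel,
    reference: np.ndarray,
    threshold_nm: float,
    theta: float,
    cfg: SessionConfig,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    c = math.cos(math.radians(theta))

    def acquire(correction_nm: tuple[float, float]) -> np.ndarray:
        # Corrections are measured in the stretched (zero-tilt) frame; the
        # perpendicular component compresses by cos(theta) on the detector.
        du = correction_nm[0] * 1e-3
        dv = correction_nm[1] * 1e-3 * c
        if du or dv:
            stage.apply_image_shift(du, dv)
        return render_view(
            scene, stage.pose, level, cfg.noise, seed=int(rng.integers(2**31))
        )

    state = TrackingState(
        reference_image=reference,
        level=level.name,
        pixel_size=level.pixel_size_a,
        threshold=threshold_nm,
        max_iterations=cfg.max_iterations,
    )
    _, iterations, converged = iterative_track(acquire, state, theta)
    return iterations, converged


def _specimen_center_um(pose: StagePose) -> tuple[float, float]:
    """Specimen-plane coordinate imaged at the field centre for a pose."""
    t = math.radians(pose.tilt)
    c = math.cos(t)
    u = -(pose.error_um[0] + pose.image_shift_um[0])
    v = -(pose.specimen_z_um * math.sin(t)
          + pose.error_um[1] + pose.image_shift_um[1]) / c
    return u, v


def _true_tracking_residual_nm(stage: VirtualStage, ref_pose: StagePose) -> float:
    """On-specimen displacement of the imaged centre vs the series reference.

    This is the quantity the iterative loop drives below its threshold: how
    far the specimen region currently under the beam centre has moved from
    the region centred in the series' first image.
    """
    u_now, v_now = _specimen_center_um(stage.pose)
    u_ref, v_ref = _specimen_center_um(ref_pose)
    return float(np.hypot(u_now - u_ref, v_now - v_ref)) * 1e3


def run_bisect_session(
    scene: GridScene,
    rois: Sequence[RoiTarget] | None,
    scheme: TiltScheme,
    config: SessionConfig | None = None,
    seed: int = 0,
) -> AcquisitionLog:
    """Simulate one multi-ROI tilt-series acquisition under closed-loop control.

    Per tilt: mechanical tilt with fresh jitter, two-level iterative tracking
    of the central area against the series' first images, then per-ROI
    correction. Each ROI keeps its own running eucentric-height fit (seeded
    with the planar model until ``min_fit_points`` targeting measurements
    have accumulated); with ``correct_eucentric`` disabled the planar model
    is used throughout. True targeting and defocus errors come from the
    simulator's ground truth. The autofocus area sits displaced along the
    tilt-axis direction, where its height is tilt-invariant.
    """
    cfg = config or SessionConfig()
    if rois is None:
        rois = scene.rois
    master = np.random.SeedSequence(seed)
    s_stage, s_render, s_meas = master.spawn(3)
    stage = VirtualStage(
        in_plane_error_sigma_nm=cfg.jitter_sigma_nm,
        specimen_z_um=cfg.specimen_z_um,
        rng_seed=int(s_stage.generate_state(1)[0]),
    )
    render_rng = np.random.default_rng(s_render)
    meas_rng = np.random.default_rng(s_meas)

    # Reference images at the first (zero) tilt define the targeting origin.
    stage.tilt_to(scheme.angles[0])
    ref_pose = replace(stage.pose)
    ref_low = render_view(scene, stage.pose, cfg.low_mag, cfg.noise,
                          seed=int(render_rng.integers(2**31)))
    ref_high = render_view(scene, stage.pose, cfg.high_mag, cfg.noise,
                           seed=int(render_rng.integers(2**31)))

    roi_obs: dict[str, list[tuple[float, float]]] = {r.id: [] for r in rois}
    rec_rows: list[dict] = []
    trk_rows: list[dict] = []

    for tilt_index, theta in enumerate(scheme.angles):
        stage.tilt_to(theta)
        if tilt_index == 0:
            # the reference pose *is* the first acquisition
            stage.pose = replace(ref_pose)
            it_lo = it_hi = 1
            conv_lo = conv_hi = True
        else:
            it_lo, conv_lo = _track_level(
                scene, stage, cfg.low_mag, ref_low, cfg.low_threshold_nm,
                theta, cfg, render_rng,
            )
            it_hi, conv_hi = _track_level(
                scene, stage, cfg.high_mag, ref_high, cfg.high_threshold_nm,
                theta, cfg, render_rng,
            )
        resid_nm = _true_tracking_residual_nm(stage, ref_pose)
        trk_rows.append({
            "tilt_index": tilt_index,
            "tilt_angle": theta,
            "iterations_low": it_lo,
            "iterations_high": it_hi,
            "converged": bool(conv_lo and conv_hi),
            "tracking_residual_nm": resid_nm,
        })

        t = math.radians(theta)
        for roi in rois:
            v_true, z_true = rotate_point_about_tilt_axis(roi.y, roi.z, theta)
            use_fit = False
            if cfg.correct_eucentric and len(roi_obs[roi.id]) >= cfg.min_fit_points:
                try:
                    fit = fit_eucentric(roi_obs[roi.id])
                    use_fit = True
                except UnderdeterminedFitError:
                    use_fit = False
            if use_fit:
                v_pred, z_pred = predict_roi_correction(fit, theta)
            else:
                v_pred = roi.y * math.cos(t)
                z_pred = -roi.y * math.sin(t)
            err_u = 0.0
            err_v = v_true - v_pred
            resid_um = resid_nm * 1e-3
            rec_rows.append({
                "roi": roi.id,
                "tilt_index": tilt_index,
                "tilt_angle": theta,
                "applied_shift_u_um": roi.x,
                "applied_shift_v_um": v_pred,
                "target_err_u_um": err_u,
                "target_err_v_um": err_v,
                "target_err_um": float(np.hypot(err_u, err_v)) + resid_um,
                "defocus_err_um": z_true - z_pred,
                "tracking_iterations": it_lo + it_hi,
                "converged": bool(conv_lo and conv_hi),
            })
            # Targeting measurement feeding the next tilts' fit; excluded if
            # the (modelled) correlation quality collapses.
            peak = float(meas_rng.uniform(0.3, 1.0) * math.cos(t))
            if peak >= cfg.peak_floor:
                v_obs = v_true + float(meas_rng.normal(0.0, cfg.roi_measure_sigma_um))
                roi_obs[roi.id].append((theta, v_obs))

    return AcquisitionLog(
        records=pd.DataFrame(rec_rows),
        tracking=pd.DataFrame(trk_rows),
        config=cfg,
        seed=seed,
    )


def summarize_session(log: AcquisitionLog | pd.DataFrame) -> pd.DataFrame:
    """Per-tilt median and IQR of |targeting error| and |defocus error|.

    The last row (``tilt_index = -1``) aggregates the whole session.
    """
    df = log.records if isinstance(log, AcquisitionLog) else log
    if df.empty:
        raise ValueError("empty acquisition log")

    def _stats(group: pd.DataFrame) -> pd.Series:
        te = group["target_err_um"].abs()
        de = group["defocus_err_um"].abs()
        return pd.Series({
            "n": len(group),
            "target_err_median_um": te.median(),
            "target_err_iqr_um": te.quantile(0.75) - te.quantile(0.25),
            "defocus_err_median_um": de.median(),
            "defocus_err_iqr_um": de.quantile(0.75) - de.quantile(0.25),
        })

    per_tilt = (
        df.groupby(["tilt_index", "tilt_angle"]).apply(_stats, include_groups=False)
        .reset_index()
    )
    overall = _stats(df)
    overall["tilt_index"] = -1
    overall["tilt_angle"] = float("nan")
    return pd.concat([per_tilt, overall.to_frame().T], ignore_index=True)
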