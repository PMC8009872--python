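"""Reconstruction from tilt-series particle projections: per-particle defocus
assignment, projection extraction, similarity scoring, score-driven exposure
weights, weighted direct-Fourier reconstruction, constrained rigid-body
refinement and Fourier shell correlation.

Conventions
-----------
* Euler angles are intrinsic ZYZ, degrees; the tilt transform composes on
  the left of the particle pose (``R_total = R_tilt @ R_particle``).
* Particle positions are physical micrometres from the tomogram centre;
  the tilt axis runs along +x, heights follow the axis-rotation model.
* Projection images are particle-centred boxes; FFTs use centred (fftshift)
  layout internally.
* Half-sets split by particle-id parity, never per projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from tiltkit.ctf import CtfParams, TiltGeometry, ctf_2d
from tiltkit.geometry import rotate_point_about_tilt_axis

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleRecord",
    "ExposureWeights",
    "FscCurve",
    "euler_to_matrix",
    "tilt_matrix",
    "assign_particle_defocus",
    "extract_particle_projections",
    "project_map",
    "score_projections",
    "derive_exposure_weights",
    "weighted_reconstruct",
    "constrained_refine",
    "compute_fsc",
]


class ReconError(ValueError):
    pass


# --------------------------------------------------------------------------
# rotations

def _rz(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(e1: float, e2: float, e3: float) -> np.ndarray:
    """Intrinsic ZYZ rotation matrix from Euler angles in degrees."""
    return _rz(e1) @ _ry(e2) @ _rz(e3)


def tilt_matrix(theta: float, axis_angle: float = 0.0) -> np.ndarray:
    """Rotation of the specimen by ``theta`` about the in-plane tilt axis.

    With ``axis_angle = 0`` the axis is +x and (y, z) transform by the
    axis-rotation model used throughout the package.
    """
    t = math.radians(theta)
    c, s = math.cos(t), math.sin(t)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    if axis_angle:
        return _rz(axis_angle) @ rx @ _rz(-axis_angle)
    return rx


# --------------------------------------------------------------------------
# domain types

@dataclass
class ParticleRecord:
    """Position + orientation of one sub-volume and its per-tilt links."""

    particle_id: int
    tilt_series_id: str
    position_um: tuple[float, float, float]   # (x, y, z) from tomogram centre
    eulers_deg: tuple[float, float, float]    # ZYZ intrinsic
    defocus_by_tilt: dict[int, tuple[float, float]] = field(default_factory=dict)
    center_by_tilt: dict[int, tuple[float, float]] = field(default_factory=dict)
    score_by_tilt: dict[int, float] = field(default_factory=dict)

    @property
    def rotation(self) -> np.ndarray:
        return euler_to_matrix(*self.eulers_deg)


@dataclass(frozen=True)
class ExposureWeights:
    """Per-tilt mean similarity scores converted to isotropic B weights.

    ``weight(f)`` is ``exp(-B_i f^2 / 4)`` with ``B_i = c (max_j s_j - s_i)``
    so the best tilt is never attenuated and no weight exceeds 1.
    """

    mean_scores: np.ndarray       # per tilt, acquisition order
    b_factors: np.ndarray         # A^2, >= 0, min is 0
    conversion: float             # c, A^2 per score unit

    def weight(self, tilt_index: int, freq):
        f = np.asarray(freq, dtype=float)
        return np.exp(-self.b_factors[tilt_index] * f * f / 4.0)

    def spectral_contribution(self, freqs: np.ndarray) -> np.ndarray:
        """Fractional contribution of each tilt per frequency (rows: tilts)."""
        w = np.stack([self.weight(i, freqs) for i in range(len(self.b_factors))])
        return w / np.maximum(w.sum(axis=0, keepdims=True), 1e-30)


@dataclass(frozen=True)
class FscCurve:
    """Per-shell correlation between two maps."""

    freq: np.ndarray        # 1/A at shell centres
    fsc: np.ndarray
    freq_masked: np.ndarray | None = None
    fsc_masked: np.ndarray | None = None

    def resolution_at(self, threshold: float = 0.143, masked: bool = False) -> float:
        """Resolution (A) where the curve first crosses the threshold,
        linearly interpolated between shells; inf if it never rises above,
        the finest shell frequency if it never falls below."""
        f = self.freq_masked if (masked and self.freq_masked is not None) else self.freq
        c = self.fsc_masked if (masked and self.fsc_masked is not None) else self.fsc
        for k in range(1, len(c)):
            if c[k] < threshold <= c[k - 1]:
                frac = (c[k - 1] - threshold) / (c[k - 1] - c[k])
                fx = f[k - 1] + frac * (f[k] - f[k - 1])
                return float(1.0 / fx) if fx > 0 else float("inf")
        if np.all(c < threshold):
            return float("inf")
        return float(1.0 / f[-1])


# --------------------------------------------------------------------------
# centred FFT helpers

def _cfft2(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def _icfft2(ft: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ft))).real


def _cfftn(vol: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))


def _icfftn(ft: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(ft))).real


def _freq_grid_2d(n: int, pixel_size: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    f = np.fft.fftshift(np.fft.fftfreq(n, d=pixel_size))
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return fx, fy, np.hypot(fx, fy)


# --------------------------------------------------------------------------
# defocus assignment and extraction

def assign_particle_defocus(
    particle: ParticleRecord,
    geoms: Sequence[TiltGeometry],
    per_tilt_ctf: Sequence[CtfParams],
) -> dict[int, tuple[float, float]]:
    """Per-tilt defocus pair for one particle from its tomogram position.

    The particle's height along the beam at tilt ``theta`` is
    ``-y sin(theta) + z cos(theta)`` (micrometres); converted to Angstrom it
    is added to both defocus components of that tilt's base CTF. The result
    is also stored on the record.
    """
    if len(geoms) != len(per_tilt_ctf):
        raise ReconError("need one CtfParams per tilt")
    _, y, z = particle.position_um
    out: dict[int, tuple[float, float]] = {}
    for i, (geom, ctf) in enumerate(zip(geoms, per_tilt_ctf)):
        if ctf is None:
            raise ReconError(f"missing CTF for tilt {i}")
        _, height = rotate_point_about_tilt_axis(y, z, geom.tilt_angle)
        off_a = height * 1e4
        out[i] = (ctf.defocus1 + off_a, ctf.defocus2 + off_a)
    particle.defocus_by_tilt = out
    return out


def project_position(
    position_um: tuple[float, float, float],
    geom: TiltGeometry,
    pixel_size: float,
    image_shape: tuple[int, int],
) -> tuple[float, float]:
    """Project a tomogram-frame position into tilt-image pixel coordinates."""
    x, y, z = position_um
    yp, _ = rotate_point_about_tilt_axis(y, z, geom.tilt_angle)
    a = math.radians(geom.tilt_axis_angle)
    u = x * math.cos(a) - yp * math.sin(a)
    v = x * math.sin(a) + yp * math.cos(a)
    a11, a12, a21, a22, dx, dy = geom.transform
    u, v = a11 * u + a12 * v, a21 * u + a22 * v
    px_um = pixel_size * 1e-4
    col = u / px_um + dx + (image_shape[1] - 1) / 2.0
    row = v / px_um + dy + (image_shape[0] - 1) / 2.0
    return col, row


def extract_particle_projections(
    tilt_series: np.ndarray,
    geoms: Sequence[TiltGeometry],
    particles: Sequence[ParticleRecord],
    box: int,
    pixel_size: float,
) -> tuple[np.ndarray, list[dict]]:
    """Cut particle-centred boxes from every tilt where the box fits.

    Returns ``(stack, metadata)``: metadata rows carry
    ``(particle_id, tilt_index, center_col, center_row, defocus)``. Tilts
    whose box would cross an image edge are skipped; particles visible in no
    tilt are dropped with a warning.
    """
    if tilt_series.ndim != 3 or len(geoms) != tilt_series.shape[0]:
        raise ReconError("tilt_series must be (n_tilts, h, w) matching geoms")
    half = box // 2
    h, w = tilt_series.shape[1:]
    boxes: list[np.ndarray] = []
    meta: list[dict] = []
    for p in particles:
        found = 0
        for i, geom in enumerate(geoms):
            col, row = project_position(p.position_um, geom, pixel_size, (h, w))
            c0, r0 = int(round(col)) - half, int(round(row)) - half
            if c0 < 0 or r0 < 0 or c0 + box > w or r0 + box > h:
                continue
            boxes.append(tilt_series[i, r0 : r0 + box, c0 : c0 + box].astype(float))
            meta.append({
                "particle_id": p.particle_id,
                "tilt_index": i,
                "center_col": col,
                "center_row": row,
                "defocus": p.defocus_by_tilt.get(i),
            })
            p.center_by_tilt[i] = (col, row)
            found += 1
        if found == 0:
            logger.warning("particle %d visible in no tilt; dropped", p.particle_id)
    if not boxes:
        raise ReconError("no projections could be extracted")
    return np.stack(boxes), meta


# --------------------------------------------------------------------------
# projection of a reference map (Fourier slice)

def _volume_ft_interp(vol: np.ndarray, pad: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centred FT of the (2x zero-padded) volume, split into re/im for interpolation."""
    n = vol.shape[0]
    m = pad * n
    lo = (m - n) // 2
    big = np.zeros((m, m, m))
    big[lo : lo + n, lo : lo + n, lo : lo + n] = vol
    ft = _cfftn(big)
    return ft.real.copy(), ft.imag.copy()


def _slice_ft(
    ft_re: np.ndarray,
    ft_im: np.ndarray,
    rot: np.ndarray,
    n: int,
) -> np.ndarray:
    """Sample the central slice perpendicular to the beam for rotation ``rot``.

    ``ft_re``/``ft_im`` may be oversampled (from a padded volume); frequencies
    are in cycles per original box of ``n`` pixels.
    """
    m3 = ft_re.shape[0]
    scale = m3 / n
    half = n // 2
    u = np.arange(n) - half
    uu, vv = np.meshgrid(u, u, indexing="xy")
    coords2d = np.stack([uu.ravel(), vv.ravel(), np.zeros(n * n)])
    g = rot.T @ coords2d  # lab-frame slice -> particle frame
    # array order (z, y, x)
    sample = np.stack([g[2], g[1], g[0]]) * scale + m3 // 2
    re = ndimage.map_coordinates(ft_re, sample, order=1, mode="constant", cval=0.0)
    im = ndimage.map_coordinates(ft_im, sample, order=1, mode="constant", cval=0.0)
    return (re + 1j * im).reshape(n, n)


def project_map(vol: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Real-space projection of ``vol`` along the beam after rotation ``rot``."""
    n = vol.shape[0]
    ft_re, ft_im = _volume_ft_interp(vol)
    return _icfft2(_slice_ft(ft_re, ft_im, rot, n))


# --------------------------------------------------------------------------
# scoring

def _band_mask(n: int, pixel_size: float, band: tuple[float, float]) -> np.ndarray:
    lo_a, hi_a = band  # A, lo_a is the coarser resolution bound
    if lo_a <= hi_a:
        raise ReconError("band must be (coarse_A, fine_A) with coarse > fine")
    _, _, fr = _freq_grid_2d(n, pixel_size)
    return (fr >= 1.0 / lo_a) & (fr <= 1.0 / hi_a)


def _band_abs_ncc(
    ft_a: np.ndarray, ft_b: np.ndarray, mask: np.ndarray
) -> float:
    a = ft_a[mask]
    b = ft_b[mask]
    denom = math.sqrt(float(np.sum(np.abs(a) ** 2)) * float(np.sum(np.abs(b) ** 2)))
    if denom == 0:
        return 0.0
    return abs(float(np.sum((a * np.conj(b)).real)) / denom)


def score_projections(
    stack: np.ndarray,
    reference_map: np.ndarray,
    rotations: Sequence[np.ndarray],
    ctfs: Sequence[np.ndarray] | None = None,
    band: tuple[float, float] = (20.0, 8.0),
    pixel_size: float = 2.0,
) -> np.ndarray:
    """|band-limited normalized cross-correlation| of each projection against
    the CTF-modulated reprojection of the reference at its orientation.

    ``ctfs`` are optional per-projection 2D CTF arrays in centred layout.
    The absolute value makes the score insensitive to contrast inversion.
    """
    if stack.ndim != 3 or len(rotations) != stack.shape[0]:
        raise ReconError("stack and rotations must match")
    n = stack.shape[1]
    mask = _band_mask(n, pixel_size, band)
    if not mask.any():
        raise ReconError("empty scoring band")
    ft_re, ft_im = _volume_ft_interp(reference_map)
    out = np.empty(stack.shape[0])
    for i, (img, rot) in enumerate(zip(stack, rotations)):
        ref_ft = _slice_ft(ft_re, ft_im, rot, n)
        if ctfs is not None:
            ref_ft = ref_ft * ctfs[i]
        out[i] = _band_abs_ncc(_cfft2(img), ref_ft, mask)
    return out


def derive_exposure_weights(
    scores_by_tilt: dict[int, Sequence[float]] | Sequence[Sequence[float]],
    conversion: float = 100.0,
) -> ExposureWeights:
    """Per-tilt isotropic B-factors from mean similarity scores.

    ``B_i = conversion * (max_j mean_j - mean_i)``; the best tilt gets
    ``B = 0`` so its weight is identically 1.
    """
    if isinstance(scores_by_tilt, dict):
        idx = sorted(scores_by_tilt)
        groups = [scores_by_tilt[i] for i in idx]
    else:
        groups = list(scores_by_tilt)
    if any(len(g) == 0 for g in groups):
        raise ReconError("every tilt needs at least one score")
    means = np.array([float(np.mean(g)) for g in groups])
    b = conversion * (means.max() - means)
    return ExposureWeights(mean_scores=means, b_factors=b, conversion=conversion)


# --------------------------------------------------------------------------
# reconstruction

def _upsample_filter(arr_n: np.ndarray, n: int, m: int) -> np.ndarray:
    """Resample a centred n-grid filter image onto the finer m-grid (flattened)."""
    pad = m / n
    idx = (np.arange(m) - m // 2) / pad + n // 2
    cy, cx = np.meshgrid(idx, idx, indexing="ij")
    return ndimage.map_coordinates(
        arr_n.astype(float), np.stack([cy.ravel(), cx.ravel()]),
        order=1, mode="nearest",
    )


def weighted_reconstruct(
    stack: np.ndarray,
    rotations: Sequence[np.ndarray],
    ctfs: Sequence[np.ndarray] | None = None,
    weights: Sequence[np.ndarray] | None = None,
    particle_ids: Sequence[int] | None = None,
    pixel_size: float = 2.0,
    wiener_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct Fourier insertion of projections into a 3D map.

    The numerator accumulates ``w * CTF * data`` and the denominator
    ``w * CTF^2`` plus a Wiener constant (``wiener_frac`` times the mean
    accumulated denominator). ``weights``/``ctfs`` are per-projection 2D
    arrays in centred layout (either may be omitted, meaning 1). Returns
    ``(full_map, half_map_even, half_map_odd)`` with halves split by
    particle-id parity (all particles in the full map).
    """
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ReconError("stack must be (P, N, N)")
    p_count, n, _ = stack.shape
    if p_count == 0:
        raise ReconError("empty projection stack")
    if particle_ids is None:
        particle_ids = np.zeros(p_count, dtype=int)
    # 2x oversampled Fourier grid: projections are zero-padded before the
    # FFT so trilinear insertion happens on a grid twice as fine, the
    # standard remedy for gridding interpolation loss.
    pad = 2
    m = pad * n
    half_m = m // 2
    lo = (m - n) // 2
    u = np.arange(m) - half_m
    uu, vv = np.meshgrid(u, u, indexing="xy")
    inside = (np.hypot(uu, vv) <= half_m - 1).ravel()
    uv0 = np.stack([uu.ravel(), vv.ravel(), np.zeros(m * m)])[:, inside]
    npts = uv0.shape[1]

    size = m**3
    num_re = [np.zeros(size) for _ in range(2)]
    num_im = [np.zeros(size) for _ in range(2)]
    den = [np.zeros(size) for _ in range(2)]

    flat_parts: list[list[np.ndarray]] = [[], []]
    val_parts: list[list[np.ndarray]] = [[], []]

    def _flush(hset: int) -> None:
        if not flat_parts[hset]:
            return
        flat = np.concatenate(flat_parts[hset])
        vals = np.concatenate(val_parts[hset], axis=1)
        num_re[hset] += np.bincount(flat, weights=vals[0], minlength=size)
        num_im[hset] += np.bincount(flat, weights=vals[1], minlength=size)
        den[hset] += np.bincount(flat, weights=vals[2], minlength=size)
        flat_parts[hset].clear()
        val_parts[hset].clear()

    padded = np.zeros((m, m))
    pending = [0, 0]
    for i in range(p_count):
        padded[:] = 0.0
        padded[lo : lo + n, lo : lo + n] = stack[i]
        ft = _cfft2(padded).ravel()[inside]
        if ctfs is not None:
            c = _upsample_filter(np.asarray(ctfs[i]), n, m)[inside]
        else:
            c = np.ones(npts)
        if weights is not None:
            w = _upsample_filter(np.asarray(weights[i]), n, m)[inside]
        else:
            w = np.ones(npts)
        g = rotations[i].T @ uv0 + half_m
        g0 = np.floor(g).astype(int)
        frac = g - g0
        data = w * c * ft
        dval = w * c * c
        hset = int(particle_ids[i]) % 2
        wz = np.stack([1 - frac[2], frac[2]])
        wy = np.stack([1 - frac[1], frac[1]])
        wx = np.stack([1 - frac[0], frac[0]])
        for dz in (0, 1):
            for dyy in (0, 1):
                for dxx in (0, 1):
                    wgt = wz[dz] * wy[dyy] * wx[dxx]
                    gx, gy, gz = g0[0] + dxx, g0[1] + dyy, g0[2] + dz
                    ok = (
                        (gx >= 0) & (gx < m)
                        & (gy >= 0) & (gy < m)
                        & (gz >= 0) & (gz < m)
                    )
                    flat = (gz[ok] * m + gy[ok]) * m + gx[ok]
                    flat_parts[hset].append(flat)
                    val_parts[hset].append(
                        np.stack([
                            wgt[ok] * data[ok].real,
                            wgt[ok] * data[ok].imag,
                            wgt[ok] * dval[ok],
                        ])
                    )
        pending[hset] += 1
        if pending[hset] >= 64:
            _flush(hset)
            pending[hset] = 0
    _flush(0)
    _flush(1)

    def _finish(nr: np.ndarray, ni: np.ndarray, den_g: np.ndarray) -> np.ndarray:
        wiener = wiener_frac * float(den_g[den_g > 0].mean()) if np.any(den_g > 0) else 1.0
        vol_ft = ((nr + 1j * ni) / (den_g + wiener)).reshape(m, m, m)
        big = _icfftn(vol_ft)
        return big[lo : lo + n, lo : lo + n, lo : lo + n] * pad

    full = _finish(num_re[0] + num_re[1], num_im[0] + num_im[1], den[0] + den[1])
    even = _finish(num_re[0], num_im[0], den[0])
    odd = _finish(num_re[1], num_im[1], den[1])
    return full, even, odd


# --------------------------------------------------------------------------
# constrained refinement

def _shift_phase(n: int, dx_px: float, dy_px: float) -> np.ndarray:
    f = np.fft.fftshift(np.fft.fftfreq(n))
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return np.exp(-2j * np.pi * (fx * dx_px + fy * dy_px))


def constrained_refine(
    stack: np.ndarray,
    reference_map: np.ndarray,
    particles: Sequence[ParticleRecord],
    proj_meta: Sequence[dict],
    geoms: Sequence[TiltGeometry],
    pixel_size: float = 2.0,
    band: tuple[float, float] = (20.0, 8.0),
    angle_budget_deg: float = 5.0,
    shift_budget_px: float = 5.0,
    refine_geometry: bool = False,
) -> tuple[list[ParticleRecord], float]:
    """Rigid-body refinement of each particle pose under tilt constraints.

    One pose (3 ZYZ Euler angles + an in-plane tomogram shift) is refined
    per particle by maximizing the summed band-limited |CC| over all its
    tilts; per-tilt orientations stay slaved to the common pose through the
    tilt geometry. Particles whose optimum leaves the search budget are
    reverted. With ``refine_geometry`` a second stage refines a global
    tilt-axis angle offset against all particles; the (possibly zero)
    refined offset is returned alongside the particles.
    """
    n = stack.shape[1]
    mask = _band_mask(n, pixel_size, band)
    ft_re, ft_im = _volume_ft_interp(reference_map)
    by_particle: dict[int, list[int]] = {}
    for row_idx, m in enumerate(proj_meta):
        by_particle.setdefault(m["particle_id"], []).append(row_idx)
    stack_fts = [_cfft2(img) for img in stack]

    def particle_score(
        p: ParticleRecord, rows: list[int], eulers, shift_um, axis_off: float
    ) -> float:
        rp = euler_to_matrix(*eulers)
        total = 0.0
        for r in rows:
            ti = proj_meta[r]["tilt_index"]
            geom = geoms[ti]
            rt = tilt_matrix(geom.tilt_angle, geom.tilt_axis_angle + axis_off)
            ref_ft = _slice_ft(ft_re, ft_im, rt @ rp, n)
            du_um = shift_um[0]
            dv_um = shift_um[1] * math.cos(math.radians(geom.tilt_angle))
            px_um = pixel_size * 1e-4
            ref_ft = ref_ft * _shift_phase(n, du_um / px_um, dv_um / px_um)
            total += _band_abs_ncc(stack_fts[r], ref_ft, mask)
        return total / max(len(rows), 1)

    refined: list[ParticleRecord] = []
    for p in particles:
        rows = by_particle.get(p.particle_id, [])
        if not rows:
            refined.append(p)
            continue
        e0 = np.asarray(p.eulers_deg, dtype=float)
        px_um = pixel_size * 1e-4

        def neg(v: np.ndarray) -> float:
            return -particle_score(
                p, rows, v[:3], (v[3] * px_um, v[4] * px_um), 0.0
            )

        x0 = np.concatenate([e0, [0.0, 0.0]])
        step = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        simplex = np.vstack([x0] + [x0 + np.eye(5)[k] * step[k] for k in range(5)])
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-7, "maxiter": 600,
                     "initial_simplex": simplex},
        )
        d_ang = np.max(np.abs(res.x[:3] - e0))
        d_shift = np.max(np.abs(res.x[3:]))
        if d_ang > angle_budget_deg or d_shift > shift_budget_px:
            logger.warning(
                "particle %d diverged (%.1f deg / %.1f px); reverted",
                p.particle_id, d_ang, d_shift,
            )
            refined.append(p)
            continue
        q = replace_particle_pose(p, res.x, pixel_size)
        refined.append(q)

    axis_offset = 0.0
    if refine_geometry:
        def neg_axis(a: float) -> float:
            return -sum(
                particle_score(
                    q, by_particle.get(q.particle_id, []),
                    q.eulers_deg, (0.0, 0.0), float(a),
                )
                for q in refined
            )

        res = optimize.minimize_scalar(
            neg_axis, bounds=(-3.0, 3.0), method="bounded",
            options={"xatol": 0.02},
        )
        axis_offset = float(res.x)
    return refined, axis_offset


def replace_particle_pose(
    p: ParticleRecord, x: np.ndarray, pixel_size: float
) -> ParticleRecord:
    """New record with refined Euler angles and tomogram-plane shift (px->um)."""
    px_um = pixel_size * 1e-4
    pos = (
        p.position_um[0] + float(x[3]) * px_um,
        p.position_um[1] + float(x[4]) * px_um,
        p.position_um[2],
    )
    return ParticleRecord(
        particle_id=p.particle_id,
        tilt_series_id=p.tilt_series_id,
        position_um=pos,
        eulers_deg=(float(x[0]), float(x[1]), float(x[2])),
        defocus_by_tilt=dict(p.defocus_by_tilt),
        center_by_tilt=dict(p.center_by_tilt),
        score_by_tilt=dict(p.score_by_tilt),
    )


def rotation_angle_between(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotation matrices."""
    tr = float(np.trace(r1.T @ r2))
    return math.degrees(math.acos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))


# --------------------------------------------------------------------------
# FSC

def _soft_mask(shape: tuple[int, ...], radius_frac: float = 0.4, soft_px: float = 3.0) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) - (s - 1) / 2.0 for s in shape], indexing="ij")
    r = np.sqrt(sum(g * g for g in grids))
    rad = radius_frac * min(shape)
    return 0.5 * (1.0 + np.cos(np.clip((r - rad) / soft_px, 0, 1) * np.pi)) * (r < rad + soft_px)


def compute_fsc(
    map_a: np.ndarray,
    map_b: np.ndarray,
    pixel_size: float = 2.0,
    mask: np.ndarray | None = None,
) -> FscCurve:
    """Fourier shell correlation between two equally shaped maps.

    If a mask is given the unmasked curve is still computed and the masked
    one reported alongside it.
    """
    if map_a.shape != map_b.shape:
        raise ReconError("FSC maps must have equal dimensions")
    if not (np.any(map_a) and np.any(map_b)):
        raise ReconError("FSC of an all-zero map is undefined")

    def _curve(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = a.shape[0]
        fa = _cfftn(a)
        fb = _cfftn(b)
        grids = np.meshgrid(*[np.arange(s) - s // 2 for s in a.shape], indexing="ij")
        r = np.sqrt(sum(g * g for g in grids)).astype(int)
        nshell = n // 2
        num = np.zeros(nshell)
        da = np.zeros(nshell)
        db = np.zeros(nshell)
        flat_r = r.ravel()
        sel = flat_r < nshell
        np.add.at(num, flat_r[sel], (fa.ravel()[sel] * np.conj(fb.ravel()[sel])).real)
        np.add.at(da, flat_r[sel], np.abs(fa.ravel()[sel]) ** 2)
        np.add.at(db, flat_r[sel], np.abs(fb.ravel()[sel]) ** 2)
        denom = np.sqrt(da * db)
        fsc = np.where(denom > 0, num / np.maximum(denom, 1e-30), 0.0)
        freq = np.arange(nshell) / (n * pixel_size)
        return freq, fsc

    freq, fsc = _curve(map_a, map_b)
    if mask is not None:
        freq_m, fsc_m = _curve(map_a * mask, map_b * mask)
        return FscCurve(freq=freq, fsc=fsc, freq_masked=freq_m, fsc_masked=fsc_m)
    return FscCurve(freq=freq, fsc=fsc)
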