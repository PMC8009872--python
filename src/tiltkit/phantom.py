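"""Synthetic phantom maps and particle tilt-series with known ground truth.

Each simulated particle is a random rigid rotation of a common blobby
phantom, projected through the tilt scheme with per-tilt astigmatic CTFs,
dose-dependent high-frequency damage (an isotropic B growing with the
accumulated exposure) and additive Gaussian noise. Everything is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from tiltkit.ctf import CtfParams, TiltGeometry, ctf_2d
from tiltkit.recon import (
    ParticleRecord,
    _cfft2,
    _freq_grid_2d,
    _icfft2,
    _slice_ft,
    _volume_ft_interp,
    euler_to_matrix,
    tilt_matrix,
)
from tiltkit.scheme import TiltScheme, accumulated_dose

__all__ = [
    "ParticleDataset",
    "make_phantom_map",
    "simulate_particle_dataset",
    "render_point_source_tilt_series",
]


def render_point_source_tilt_series(
    positions_um: Sequence[tuple[float, float, float]],
    geoms: Sequence["TiltGeometry"],
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 2.0,
    spot_sigma_px: float = 1.5,
) -> np.ndarray:
    """Render Gaussian point sources through the tilt geometry.

    Useful as an oracle for projection extraction: each frame contains one
    blob per particle at its projected position.
    """
    from tiltkit.recon import project_position

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    series = np.zeros((len(geoms), h, w))
    for i, geom in enumerate(geoms):
        for pos in positions_um:
            col, row = project_position(tuple(pos), geom, pixel_size, shape)
            series[i] += np.exp(
                -((yy - row) ** 2 + (xx - col) ** 2) / (2 * spot_sigma_px**2)
            )
    return series


def make_phantom_map(
    n: int = 32,
    pixel_size: float = 2.0,
    n_blobs: int = 10,
    texture: float = 0.6,
    seed: int = 0,
) -> np.ndarray:
    """A compact particle phantom: Gaussian blobs plus fine interior texture.

    The lightly smoothed noise texture keeps spectral content out to the
    Nyquist frequency so that resolution measures respond across the whole
    band, not only where smooth blobs carry signal.
    """
    rng = np.random.default_rng(seed)
    vol = np.zeros((n, n, n))
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    for _ in range(n_blobs):
        pos = rng.normal(0.0, n / 8.0, 3) + c
        sig = rng.uniform(1.0, 2.0)
        amp = rng.uniform(0.5, 1.5)
        vol += amp * np.exp(
            -((zz - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (xx - pos[2]) ** 2)
            / (2 * sig**2)
        )
    if texture > 0:
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        envelope = 1.0 / (1.0 + np.exp((r - n / 4.0) / 1.5))
        grains = ndimage.gaussian_filter(rng.normal(size=vol.shape), 0.45)
        vol += texture * grains * envelope
    return vol


@dataclass
class ParticleDataset:
    """Simulated projection stack plus all ground-truth bookkeeping."""

    stack: np.ndarray                    # (P*T_vis, box, box)
    proj_meta: list[dict]                # particle_id, tilt_index, ...
    rotations: list[np.ndarray]          # per projection, tilt @ particle
    ctf_images: list[np.ndarray]         # per projection, centred layout
    particles: list[ParticleRecord]
    geoms: list[TiltGeometry]
    ctf_params: list[CtfParams]
    scheme: TiltScheme
    phantom: np.ndarray
    pixel_size: float

    @property
    def tilt_of_projection(self) -> np.ndarray:
        return np.array([m["tilt_index"] for m in self.proj_meta])

    @property
    def particle_of_projection(self) -> np.ndarray:
        return np.array([m["particle_id"] for m in self.proj_meta])


def simulate_particle_dataset(
    scheme: TiltScheme,
    n_particles: int = 100,
    box: int = 32,
    pixel_size: float = 2.0,
    defocus_range: tuple[float, float] = (12000.0, 18000.0),
    astig_max: float = 1000.0,
    damage_rate: float = 3.0,      # A^2 per e-/A^2 of accumulated dose
    noise_sigma: float = 0.0,      # relative to projection RMS signal
    perturb_angles: float = 0.0,   # deg added to the stored (not true) pose
    perturb_shift_px: float = 0.0,
    with_ctf: bool = True,
    tilt_axis_angle: float = 0.0,
    seed: int = 0,
) -> ParticleDataset:
    """Project a phantom through a tilt scheme for many particles.

    ``noise_sigma`` scales white Gaussian noise relative to the RMS of the
    undamaged zero-tilt projection signal. ``perturb_*`` offsets are applied
    to the *recorded* particle poses only, for perturb-and-recover tests;
    the images are always generated at the true poses.
    """
    rng = np.random.default_rng(seed)
    phantom = make_phantom_map(box, pixel_size, seed=seed)
    ft_re, ft_im = _volume_ft_interp(phantom)
    fx, fy, fr = _freq_grid_2d(box, pixel_size)
    doses = accumulated_dose(scheme)

    geoms: list[TiltGeometry] = []
    ctf_params: list[CtfParams] = []
    for theta in scheme.angles:
        geoms.append(
            TiltGeometry(tilt_axis_angle=tilt_axis_angle, tilt_angle=float(theta))
        )
        z = rng.uniform(*defocus_range)
        astig = rng.uniform(0.0, astig_max)
        ctf_params.append(
            CtfParams(
                defocus1=z + astig / 2.0,
                defocus2=z - astig / 2.0,
                astig_angle=rng.uniform(-90.0, 90.0),
                pixel_size=pixel_size,
            )
        )

    # reference signal scale from the unmodified zero-tilt projection
    ref_proj = _icfft2(_slice_ft(ft_re, ft_im, np.eye(3), box))
    sig_rms = float(np.sqrt(np.mean(ref_proj**2)))

    stack: list[np.ndarray] = []
    meta: list[dict] = []
    rotations: list[np.ndarray] = []
    ctf_images: list[np.ndarray] = []
    particles: list[ParticleRecord] = []
    for pid in range(n_particles):
        true_eulers = (
            rng.uniform(-180, 180),
            rng.uniform(0, 180),
            rng.uniform(-180, 180),
        )
        stored_eulers = tuple(
            e + rng.uniform(-perturb_angles, perturb_angles) for e in true_eulers
        )
        shift_px = rng.uniform(-perturb_shift_px, perturb_shift_px, 2)
        rp = euler_to_matrix(*true_eulers)
        rec = ParticleRecord(
            particle_id=pid,
            tilt_series_id="sim",
            position_um=(0.0, 0.0, 0.0),
            eulers_deg=stored_eulers,
        )
        particles.append(rec)
        for ti, theta in enumerate(scheme.angles):
            rot = tilt_matrix(theta, tilt_axis_angle) @ rp
            ft = _slice_ft(ft_re, ft_im, rot, box)
            ctf_img = (
                ctf_2d(fx, fy, ctf_params[ti]) if with_ctf else np.ones_like(fx)
            )
            damage = np.exp(-damage_rate * doses[ti] * fr * fr / 4.0)
            ft_obs = ft * ctf_img * damage
            if perturb_shift_px:
                # true in-plane offset (tomogram frame) projected to this tilt;
                # the stored pose still claims the particle is centred
                du = shift_px[0]
                dv = shift_px[1] * math.cos(math.radians(theta))
                fxn = np.fft.fftshift(np.fft.fftfreq(box))
                gx, gy = np.meshgrid(fxn, fxn, indexing="xy")
                ft_obs = ft_obs * np.exp(-2j * np.pi * (gx * du + gy * dv))
            img = _icfft2(ft_obs)
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma * sig_rms, img.shape)
            stack.append(img)
            meta.append({
                "particle_id": pid,
                "tilt_index": ti,
                "center_col": box / 2.0,
                "center_row": box / 2.0,
                "defocus": (ctf_params[ti].defocus1, ctf_params[ti].defocus2),
                "true_eulers": true_eulers,
                "stored_shift_px": tuple(shift_px),
            })
            rotations.append(rot)
            ctf_images.append(ctf_img)
    return ParticleDataset(
        stack=np.stack(stack),
        proj_meta=meta,
        rotations=rotations,
        ctf_images=ctf_images,
        particles=particles,
        geoms=geoms,
        ctf_params=ctf_params,
        scheme=scheme,
        phantom=phantom,
        pixel_size=pixel_size,
    )
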