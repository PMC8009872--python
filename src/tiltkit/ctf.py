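"""Astigmatic CTF model, synthetic tilted micrographs, tilt-corrected power
spectra and per-tilt defocus fitting.

Sign convention: underfocus is positive, in Angstrom. ``defocus1`` is the
larger of the astigmatic pair and ``astig_angle`` the azimuth of that
maximum, normalized to [-90, 90) degrees.

The tilt geometry is supplied, never searched: the defocus of a point in a
tilted image is the field-centre defocus plus ``d * pixel_size * tan(tilt)``
where ``d`` is the point's signed in-image distance (pixels) from the line
through the centre parallel to the tilt axis. Overlapping tiles of the image
are frequency-rescaled from their local defocus onto the centre defocus
before averaging, which keeps the Thon rings of the averaged spectrum sharp
despite the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "CtfParams",
    "TiltGeometry",
    "electron_wavelength",
    "ctf_2d",
    "synth_tilted_micrograph",
    "tilted_power_spectrum",
    "fit_astigmatic_ctf",
]


class CtfError(ValueError):
    pass


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass(frozen=True)
class CtfParams:
    """Astigmatic defocus pair plus microscope constants.

    ``defocus1 >= defocus2`` (underfocus positive, Angstrom);
    ``astig_angle`` in degrees is the azimuth of ``defocus1``.
    """

    defocus1: float
    defocus2: float
    astig_angle: float = 0.0
    voltage: float = 300.0        # kV
    cs: float = 2.7               # mm
    amplitude_contrast: float = 0.07
    phase_shift: float = 0.0      # radians
    pixel_size: float = 1.37      # Angstrom / px

    def canonical(self) -> "CtfParams":
        """Order the defocus pair and wrap the angle into [-90, 90)."""
        z1, z2, ang = self.defocus1, self.defocus2, self.astig_angle
        if z1 < z2:
            z1, z2 = z2, z1
            ang += 90.0
        ang = (ang + 90.0) % 180.0 - 90.0
        return replace(self, defocus1=z1, defocus2=z2, astig_angle=ang)

    @property
    def defocus_mean(self) -> float:
        return 0.5 * (self.defocus1 + self.defocus2)


@dataclass(frozen=True)
class TiltGeometry:
    """Fixed per-image tilt geometry (known from tilt-series alignment)."""

    tilt_axis_angle: float = 0.0   # degrees, axis orientation from image x
    tilt_angle: float = 0.0        # degrees
    transform: tuple[float, float, float, float, float, float] = (1, 0, 0, 1, 0, 0)

    def __post_init__(self) -> None:
        if abs(self.tilt_angle) >= 90.0:
            raise CtfError("|tilt_angle| must be < 90 degrees")


def ctf_2d(fx, fy, params: CtfParams):
    """Evaluate the astigmatic CTF at spatial frequencies (1/Angstrom).

    Returns ``-sin(chi + asin(w))`` with the standard defocus + spherical
    aberration phase ``chi`` and the local defocus
    ``dz(phi) = ((z1+z2) + (z1-z2) cos 2(phi - phi_a)) / 2``.
    """
    p = params.canonical()
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    f2 = fx * fx + fy * fy
    phi = np.arctan2(fy, fx)
    phi_a = math.radians(p.astig_angle)
    dz = 0.5 * (
        (p.defocus1 + p.defocus2)
        + (p.defocus1 - p.defocus2) * np.cos(2.0 * (phi - phi_a))
    )
    lam = electron_wavelength(p.voltage)
    cs_a = p.cs * 1e7
    chi = (
        math.pi * lam * f2 * dz
        - 0.5 * math.pi * cs_a * lam**3 * f2 * f2
        + p.phase_shift
    )
    return -np.sin(chi + math.asin(p.amplitude_contrast))


def local_defocus_offset(
    geom: TiltGeometry, dx_px, dy_px, pixel_size: float
):
    """Defocus offset (Angstrom) at an image offset from the field centre.

    ``dx_px``/``dy_px`` are measured from the centre along image x (columns)
    and y (rows); points on the tilt-axis line through the centre have zero
    offset.
    """
    a = math.radians(geom.tilt_axis_angle)
    d = -np.asarray(dx_px) * math.sin(a) + np.asarray(dy_px) * math.cos(a)
    return d * pixel_size * math.tan(math.radians(geom.tilt_angle))


def _freq_grids(n: int, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftfreq(n, d=pixel_size)
    return np.meshgrid(f, f, indexing="xy")


def synth_tilted_micrograph(
    params: CtfParams,
    geom: TiltGeometry,
    dose: float = 3.0,
    seed: int = 0,
    size: int = 1024,
    tile: int = 128,
    contrast: float = 0.3,
) -> np.ndarray:
    """Render a white-noise specimen through a spatially varying CTF.

    The CTF is applied on overlapping Hann-stitched tiles whose defocus
    follows the tilt plane; Poisson counting noise is added at ``dose``
    electrons per square Angstrom. Deterministic for a given seed.
    """
    if size < 512:
        raise CtfError("micrograph size must be >= 512 px")
    rng = np.random.default_rng(seed)
    specimen = rng.normal(size=(size, size))
    out = np.zeros((size, size))
    norm = np.zeros((size, size))
    win = np.hanning(tile)[:, None] * np.hanning(tile)[None, :]
    fx, fy = _freq_grids(tile, params.pixel_size)
    step = tile // 2
    center = (size - 1) / 2.0
    for r0 in range(0, size - tile + 1, step):
        for c0 in range(0, size - tile + 1, step):
            dy = r0 + (tile - 1) / 2.0 - center
            dx = c0 + (tile - 1) / 2.0 - center
            off = float(local_defocus_offset(geom, dx, dy, params.pixel_size))
            local = replace(
                params,
                defocus1=params.defocus1 + off,
                defocus2=params.defocus2 + off,
            )
            block = specimen[r0 : r0 + tile, c0 : c0 + tile]
            filt = np.fft.ifft2(np.fft.fft2(block) * ctf_2d(fx, fy, local)).real
            out[r0 : r0 + tile, c0 : c0 + tile] += filt * win
            norm[r0 : r0 + tile, c0 : c0 + tile] += win
    out = out / np.maximum(norm, 1e-8)
    counts_mean = dose * params.pixel_size**2
    lam = counts_mean * np.clip(1.0 + contrast * out, 0.05, None)
    return rng.poisson(lam).astype(float)


def tilted_power_spectrum(
    image: np.ndarray,
    geom: TiltGeometry,
    tile_size: int = 128,
    center_defocus_hint: float = 15000.0,
    pixel_size: float = 1.37,
    correct_tilt: bool = True,
) -> np.ndarray:
    """Tile-averaged power spectrum corrected for the tilt defocus gradient.

    Each overlapping tile's spectrum is radially rescaled from the tile's
    predicted local defocus onto the field-centre defocus before averaging
    (zero-frequency at the array centre of the returned spectrum). With
    ``correct_tilt`` disabled this reduces to plain tiled averaging.
    """
    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    if tile_size > n:
        raise CtfError("tile_size exceeds image size")
    win = np.hanning(tile_size)[:, None] * np.hanning(tile_size)[None, :]
    step = tile_size // 2
    acc = np.zeros((tile_size, tile_size))
    count = 0
    center = (n - 1) / 2.0
    mid = tile_size / 2.0
    yy, xx = np.mgrid[0:tile_size, 0:tile_size].astype(float)
    for r0 in range(0, n - tile_size + 1, step):
        for c0 in range(0, n - tile_size + 1, step):
            block = img[r0 : r0 + tile_size, c0 : c0 + tile_size]
            block = block - block.mean()
            spec = np.abs(np.fft.fftshift(np.fft.fft2(block * win))) ** 2
            if correct_tilt and abs(geom.tilt_angle) > 1e-9:
                dy = r0 + (tile_size - 1) / 2.0 - center
                dx = c0 + (tile_size - 1) / 2.0 - center
                z_local = center_defocus_hint + float(
                    local_defocus_offset(geom, dx, dy, pixel_size)
                )
                if z_local <= 0:
                    continue
                scale = math.sqrt(center_defocus_hint / z_local)
                coords = np.array([
                    (yy - mid) * scale + mid,
                    (xx - mid) * scale + mid,
                ])
                spec = ndimage.map_coordinates(
                    spec, coords, order=1, mode="nearest"
                )
            acc += spec
            count += 1
    if count == 0:
        raise CtfError("no tiles fit in the image")
    return acc / count


def _radial_shells(n: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    mid = n / 2.0
    r = np.hypot(yy - mid, xx - mid)
    return r, r.astype(int)


def subtract_background(spectrum: np.ndarray, order: int = 4) -> np.ndarray:
    """Remove a smooth radial background (per-shell polynomial fit)."""
    n = spectrum.shape[0]
    r, ri = _radial_shells(n)
    nshell = n // 2
    shell_mean = np.zeros(nshell)
    for k in range(nshell):
        m = ri == k
        shell_mean[k] = spectrum[m].mean() if m.any() else 0.0
    x = np.arange(nshell)
    good = shell_mean > 0
    coef = np.polyfit(x[good], np.log(shell_mean[good] + 1e-30), order)
    bg_shell = np.exp(np.polyval(coef, x))
    bg = np.interp(r.ravel(), x, bg_shell, right=bg_shell[-1]).reshape(r.shape)
    return spectrum - bg


def _annulus_mask(n: int, pixel_size: float, f_lo: float, f_hi: float) -> np.ndarray:
    r, _ = _radial_shells(n)
    f = r / (n * pixel_size)
    return (f >= f_lo) & (f <= f_hi)


def _model_abs_ctf(n: int, params: CtfParams) -> np.ndarray:
    f = np.fft.fftshift(np.fft.fftfreq(n, d=params.pixel_size))
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return np.abs(ctf_2d(fx, fy, params))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(np.sum(a * a)) * float(np.sum(b * b)))
    return float(np.sum(a * b) / denom) if denom > 0 else 0.0


def fit_astigmatic_ctf(
    spectrum: np.ndarray,
    search: tuple[float, float, float],
    params0: CtfParams,
    f_range: tuple[float, float] | None = None,
    bg_order: int = 4,
) -> tuple[CtfParams, float, float]:
    """Fit an astigmatic CTF to a (tilt-corrected) power spectrum.

    ``search = (min_defocus, max_defocus, step)`` in Angstrom brackets the
    mean defocus for the initial 1D grid search; a simplex refinement of
    ``(z1, z2, astig_angle)`` follows, maximizing the normalized correlation
    between the model ``|CTF|`` and the background-subtracted spectrum over
    an annulus. Returns ``(params, fit_score, fit_resolution_A)`` where the
    fit resolution is the finest shell at which a sliding-window model
    correlation stays above 0.5.
    """
    zmin, zmax, step = search
    if not (zmax > zmin and step > 0):
        raise CtfError("degenerate defocus search range")
    n = spectrum.shape[0]
    px = params0.pixel_size
    nyq = 0.5 / px
    f_lo, f_hi = f_range if f_range else (1.0 / 30.0, min(1.0 / 5.0, 0.9 * nyq))
    mask = _annulus_mask(n, px, f_lo, f_hi)
    data = subtract_background(spectrum, order=bg_order)
    data_m = data[mask]

    def score_for(z1: float, z2: float, ang: float) -> float:
        p = replace(params0, defocus1=z1, defocus2=z2, astig_angle=ang)
        return _ncc(_model_abs_ctf(n, p)[mask], data_m)

    best_z = None
    best_s = -np.inf
    for z in np.arange(zmin, zmax + step / 2, step):
        s = score_for(z, z, 0.0)
        if s > best_s:
            best_s, best_z = s, z

    # Refine in (mean, astig*cos 2a, astig*sin 2a): unlike (z1, z2, angle)
    # this space has no degenerate direction at zero astigmatism.
    def unpack(v: np.ndarray) -> tuple[float, float, float]:
        zm, ac, as_ = v
        amp = math.hypot(ac, as_)
        ang = 0.5 * math.degrees(math.atan2(as_, ac))
        return zm + amp / 2.0, zm - amp / 2.0, ang

    def neg(v: np.ndarray) -> float:
        return -score_for(*unpack(v))

    x0 = np.array([best_z, 0.0, 0.0])
    simplex = np.array([
        x0,
        x0 + [step, 0, 0],
        x0 + [0, 1200.0, 0],
        x0 + [0, 0, 1200.0],
    ])
    res = optimize.minimize(
        neg,
        x0=x0,
        method="Nelder-Mead",
        options={
            "xatol": 5.0,
            "fatol": 1e-7,
            "maxiter": 600,
            "initial_simplex": simplex,
        },
    )
    z1, z2, ang = unpack(res.x)
    fitted = replace(
        params0, defocus1=float(z1), defocus2=float(z2), astig_angle=float(ang)
    ).canonical()
    fit_score = float(-res.fun)

    # sliding-window per-shell correlation for the fit resolution
    model = _model_abs_ctf(n, fitted)
    r, ri = _radial_shells(n)
    nshell = n // 2
    half_w = max(3, nshell // 40)
    shell_corr = np.full(nshell, np.nan)
    lo_shell = int(f_lo * n * px)
    for k in range(lo_shell, nshell):
        m = (ri >= k - half_w) & (ri <= k + half_w)
        if m.sum() > 16:
            shell_corr[k] = _ncc(model[m], data[m])
    fit_res = 1.0 / f_lo
    for k in range(lo_shell, nshell):
        if np.isnan(shell_corr[k]):
            continue
        f_k = k / (n * px)
        if shell_corr[k] >= 0.5:
            fit_res = 1.0 / f_k
        elif f_k > f_lo * 1.5:
            break
    return fitted, fit_score, float(fit_res)
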