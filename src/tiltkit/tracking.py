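"""Cross-correlation shift measurement on cosine-stretched images and the
iterative two-level tracking loop.

The reference for a tilt-series is always the *first* (zero-tilt) image at a
given magnification level; later tilts are cosine-stretched back to that
geometry before correlation, so tracking errors do not accumulate along the
series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

__all__ = [
    "TrackingState",
    "cosine_stretch",
    "measure_shift",
    "iterative_track",
]


class TrackingError(ValueError):
    pass


@dataclass
class TrackingState:
    """Per-level tracking configuration and accumulated corrections.

    ``pixel_size`` is in Angstrom per pixel at this magnification level and
    ``threshold`` in nanometres. The low-magnification level must use a
    larger (coarser) threshold than the high-magnification one.
    """

    reference_image: np.ndarray
    level: str  # "low_mag" | "high_mag"
    pixel_size: float
    threshold: float
    max_iterations: int = 5
    accumulated_shift: tuple[float, float] = (0.0, 0.0)
    axis_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.level not in ("low_mag", "high_mag"):
            raise TrackingError(f"unknown tracking level {self.level!r}")
        if self.threshold <= 0 or self.pixel_size <= 0:
            raise TrackingError("threshold and pixel_size must be positive")
        if self.max_iterations < 1:
            raise TrackingError("max_iterations must be >= 1")


def cosine_stretch(
    image: np.ndarray, theta: float, axis_angle: float = 0.0
) -> np.ndarray:
    """Resample ``image`` by 1/cos(theta) perpendicular to the tilt axis.

    ``axis_angle`` is the in-plane orientation of the tilt axis in degrees,
    measured from the image x (column) direction. Output has the same shape
    as the input; uncovered borders are filled with the image mean. Bilinear
    interpolation throughout.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise TrackingError("cosine_stretch expects a 2D image")
    if abs(theta) >= 90.0:
        raise TrackingError("cannot stretch at |theta| >= 90 degrees")
    c = math.cos(math.radians(theta))
    if abs(c - 1.0) < 1e-12:
        return img.copy()
    a = math.radians(axis_angle)
    # Rotate so the axis lies along x, compress y by cos(theta) (this is the
    # inverse of the output->input stretch), rotate back. Matrices act on
    # (row, col) = (y, x) coordinates.
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    scale = np.diag([c, 1.0])  # shrink along the perpendicular (row) direction
    m = rot @ scale @ rot.T
    center = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
    offset = center - m @ center
    return ndimage.affine_transform(
        img, m, offset=offset, order=1, mode="constant", cval=float(img.mean())
    )


def _bandpass_window(shape: tuple[int, int], lo: float, hi: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fy, fx)
    win = np.ones(shape)
    if lo > 0:
        win *= 1.0 - np.exp(-(r / lo) ** 2)
    if hi < 0.5:
        win *= np.exp(-((r / hi) ** 2))
    return win


def measure_shift(
    reference: np.ndarray,
    image: np.ndarray,
    *,
    apodize: bool = True,
    bandpass: tuple[float, float] | None = (0.01, 0.25),
) -> tuple[float, float, float]:
    """Measure the translation of ``image`` relative to ``reference``.

    Returns ``(dx, dy, peak_height)`` in pixels such that shifting the
    reference by ``(dx, dy)`` (x = columns, y = rows) best matches the
    image. Sub-pixel precision comes from parabolic interpolation around the
    integer correlation peak; ``peak_height`` is the normalized correlation
    coefficient there. The correlation is computed on mean-subtracted,
    optionally Hann-apodized and band-pass filtered copies (the defaults;
    disable both for exact recovery of pure circular shifts).
    """
    ref = np.asarray(reference, dtype=float)
    img = np.asarray(image, dtype=float)
    if ref.shape != img.shape or ref.ndim != 2:
        raise TrackingError("measure_shift expects two equal-shape 2D images")
    ref = ref - ref.mean()
    img = img - img.mean()
    if ref.std() == 0 or img.std() == 0:
        raise TrackingError("flat (zero-variance) image in measure_shift")
    if apodize:
        wy = np.hanning(ref.shape[0])[:, None]
        wx = np.hanning(ref.shape[1])[None, :]
        w = wy * wx
        ref = ref * w
        img = img * w
    fr = np.fft.fft2(ref)
    fi = np.fft.fft2(img)
    win = _bandpass_window(ref.shape, *bandpass) if bandpass is not None else 1.0
    cross = fi * np.conj(fr) * win
    cc = np.fft.ifft2(cross).real
    # Parseval: energy of the band-filtered images, so identical inputs peak at 1.
    n = ref.size
    e_ref = float(np.sum(np.abs(fr) ** 2 * win)) / n
    e_img = float(np.sum(np.abs(fi) ** 2 * win)) / n
    norm = math.sqrt(e_ref * e_img)
    if norm == 0:
        raise TrackingError("zero-energy image after filtering")
    cc = cc / norm

    peak = np.unravel_index(int(np.argmax(cc)), cc.shape)
    best = cc[peak]
    # Tie-break equal peaks toward the smallest-magnitude shift.
    ties = np.argwhere(cc >= best - 1e-12)
    if len(ties) > 1:
        ny, nx = cc.shape
        wrapped = ties.astype(float)
        wrapped[:, 0] = (wrapped[:, 0] + ny / 2) % ny - ny / 2
        wrapped[:, 1] = (wrapped[:, 1] + nx / 2) % nx - nx / 2
        peak = tuple(ties[int(np.argmin(np.hypot(wrapped[:, 0], wrapped[:, 1])))])

    def _parabolic(axis: int) -> float:
        step = np.array((1, 0)) if axis == 0 else np.array((0, 1))
        lo = cc[tuple(np.mod(np.asarray(peak) - step, cc.shape))]
        hi = cc[tuple(np.mod(np.asarray(peak) + step, cc.shape))]
        denom = cc[peak] - 0.5 * (lo + hi)
        if denom <= 0:
            return 0.0
        offset = 0.5 * (hi - lo) / (2.0 * denom)
        return float(np.clip(offset, -0.5, 0.5))

    dy = peak[0] + _parabolic(0)
    dx = peak[1] + _parabolic(1)
    ny, nx = cc.shape
    dy = (dy + ny / 2) % ny - ny / 2
    dx = (dx + nx / 2) % nx - nx / 2
    return float(dx), float(dy), float(np.clip(cc[peak], -1.0, 1.0))


def iterative_track(
    acquire: Callable[[tuple[float, float]], np.ndarray],
    state: TrackingState,
    theta: float,
) -> tuple[tuple[float, float], int, bool]:
    """Run the acquire/measure/correct loop for one tilt at one level.

    ``acquire`` takes the correction to apply, in nanometres ``(dx, dy)``
    expressed in reference-image coordinates, and returns a freshly
    "recorded" image (the first call receives ``(0, 0)``). Each image is
    cosine-stretched to the reference (zero-tilt) geometry, the residual
    displacement is measured against the series' fixed reference, and the
    loop repeats until the residual drops below ``state.threshold`` or
    ``state.max_iterations`` is exhausted.

    Returns ``(total_shift_nm, iterations, converged)``; non-convergence is
    reported through the flag, not an exception.
    """
    nm_per_px = state.pixel_size / 10.0
    total = np.zeros(2)
    correction = (0.0, 0.0)
    converged = False
    iterations = 0
    for iterations in range(1, state.max_iterations + 1):
        img = acquire(correction)
        if abs(theta) > 1e-9:
            img = cosine_stretch(img, theta, state.axis_angle)
        dx_px, dy_px, _ = measure_shift(state.reference_image, img)
        # measured shift of the image content; correct by moving it back
        resid = np.array([dx_px, dy_px]) * nm_per_px
        if float(np.hypot(*resid)) <= state.threshold:
            converged = True
            break
        correction = (-float(resid[0]), -float(resid[1]))
        total += resid
    state.accumulated_shift = (
        state.accumulated_shift[0] + float(total[0]),
        state.accumulated_shift[1] + float(total[1]),
    )
    return (float(total[0]), float(total[1])), iterations, converged
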