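"""Grouped dose-symmetric tilt schemes: generation, validation, dose bookkeeping.

A dose-symmetric scheme starts at zero tilt and alternates between the
positive and negative branches so that the low tilts — which carry the most
high-resolution signal — are exposed first. The *grouped* variant takes
several consecutive angles on a branch before switching sign, trading a
little dose efficiency for fewer (slow) large stage rotations.

Two published acquisition orders are shipped verbatim as fixture files
(``pm60``: +-60 deg range, ``pm36``: +-36 deg range, both 3 deg increment);
their irregular group structure is data, not generator output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TiltScheme",
    "SchemeReport",
    "generate_grouped_dose_symmetric",
    "validate_scheme",
    "accumulated_dose",
    "load_builtin_scheme",
    "builtin_scheme_names",
]

_ANGLE_TOL = 1e-6


class SchemeError(ValueError):
    """Inconsistent tilt-scheme parameters."""


@dataclass(frozen=True)
class TiltScheme:
    """An ordered tilt-angle sequence with dose bookkeeping.

    ``angles`` is in acquisition order; ``group_schedule`` lists the number
    of angles taken on a branch before each sign switch (the last value
    repeats if the schedule is exhausted).
    """

    angles: tuple[float, ...]
    increment: float
    max_tilt: float
    group_schedule: tuple[int, ...] = (1,)
    dose_per_tilt: float = 3.0

    def __post_init__(self) -> None:
        if len(self.angles) == 0:
            raise SchemeError("empty tilt scheme")
        if abs(self.angles[0]) > _ANGLE_TOL:
            raise SchemeError("first tilt angle must be 0")
        if self.dose_per_tilt <= 0:
            raise SchemeError("dose_per_tilt must be positive")
        expected = _full_range(self.max_tilt, self.increment)
        got = np.sort(np.asarray(self.angles))
        if got.size != expected.size or not np.allclose(got, expected, atol=_ANGLE_TOL):
            raise SchemeError(
                "angles do not cover every multiple of the increment in "
                f"[-{self.max_tilt:g}, +{self.max_tilt:g}] exactly once"
            )

    def __len__(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class SchemeReport:
    """Validation report for an externally supplied angle sequence."""

    count: int
    coverage_ok: bool
    duplicates: tuple[float, ...]
    inferred_increment: float | None
    starts_at_zero: bool


def _full_range(max_tilt: float, increment: float) -> np.ndarray:
    if increment <= 0:
        raise SchemeError("increment must be positive")
    n = max_tilt / increment
    if max_tilt < 0 or abs(n - round(n)) > 1e-9:
        raise SchemeError(
            f"max_tilt {max_tilt:g} is not a non-negative multiple of the "
            f"increment {increment:g}"
        )
    n = int(round(n))
    return np.arange(-n, n + 1) * float(increment)


def generate_grouped_dose_symmetric(
    max_tilt: float,
    increment: float,
    group_schedule: Sequence[int] = (1,),
) -> TiltScheme:
    """Generate a grouped dose-symmetric acquisition order.

    The sequence opens with 0, then takes ``group_schedule[0]`` angles from
    the positive branch. Every later branch visit takes twice the current
    schedule value — covering the return to the branch and the advance past
    it in one visit — alternating signs until both branches are exhausted
    (the schedule repeats its last value). With the default all-ones
    schedule this yields the classic order ``0, +i, -i, -2i, +2i, +3i, ...``.
    """
    schedule = tuple(int(g) for g in group_schedule)
    if not schedule or any(g < 1 for g in schedule):
        raise SchemeError("group_schedule entries must be >= 1")
    full = _full_range(max_tilt, increment)
    n = (full.size - 1) // 2
    pos = list(full[full > _ANGLE_TOL])          # ascending +i, +2i, ...
    neg = list(-full[full > _ANGLE_TOL])         # descending -i, -2i, ...
    order: list[float] = [0.0]

    def _take(branch: list[float], k: int) -> None:
        for _ in range(min(k, len(branch))):
            order.append(branch.pop(0))

    sched_at = lambda i: schedule[min(i, len(schedule) - 1)]
    _take(pos, sched_at(0))
    sign, visit = -1, 0
    while pos or neg:
        branch = neg if sign < 0 else pos
        _take(branch, 2 * sched_at(visit))
        sign = -sign
        visit += 1
    assert len(order) == 2 * n + 1
    return TiltScheme(
        angles=tuple(order),
        increment=float(increment),
        max_tilt=float(max_tilt),
        group_schedule=schedule,
    )


def validate_scheme(angles: Sequence[float]) -> SchemeReport:
    """Check an externally supplied angle list against the scheme invariants.

    Failures are carried in the report rather than raised, so that printed
    sequences from acquisition logs can be audited as-is.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise SchemeError("cannot validate an empty angle list")
    uniq, counts = np.unique(arr, return_counts=True)
    duplicates = tuple(float(a) for a in uniq[counts > 1])
    inferred = None
    coverage_ok = False
    if uniq.size >= 2:
        diffs = np.diff(uniq)
        inferred = float(np.min(diffs))
        expected = _full_range(float(np.max(np.abs(arr))), inferred)
        coverage_ok = (
            not duplicates
            and uniq.size == expected.size
            and bool(np.allclose(uniq, expected, atol=_ANGLE_TOL))
        )
    elif uniq.size == 1 and abs(uniq[0]) <= _ANGLE_TOL:
        coverage_ok = not duplicates
    return SchemeReport(
        count=int(arr.size),
        coverage_ok=coverage_ok,
        duplicates=duplicates,
        inferred_increment=inferred,
        starts_at_zero=bool(abs(arr[0]) <= _ANGLE_TOL),
    )


def accumulated_dose(scheme: TiltScheme) -> np.ndarray:
    """Cumulative electron dose (e-/A^2) after each tilt, in acquisition order."""
    return scheme.dose_per_tilt * np.arange(1, len(scheme) + 1, dtype=float)


def dose_by_angle(scheme: TiltScheme) -> dict[float, float]:
    """Cumulative dose re-indexed by tilt angle."""
    cum = accumulated_dose(scheme)
    return {float(a): float(d) for a, d in zip(scheme.angles, cum)}


def builtin_scheme_names() -> tuple[str, ...]:
    """Names accepted by :func:`load_builtin_scheme`."""
    return ("pm60", "pm36")


def load_builtin_scheme(name: str, dose_per_tilt: float | None = None) -> TiltScheme:
    """Load one of the shipped acquisition-order fixtures by name.

    ``pm60`` covers +-60 deg and ``pm36`` +-36 deg, both at 3 deg increment
    with the published irregular group structure. ``dose_per_tilt`` defaults
    to the dose each fixture was collected with (3 and 5 e-/A^2).
    """
    default_dose = {"pm60": 3.0, "pm36": 5.0}
    if name not in default_dose:
        raise SchemeError(
            f"unknown scheme {name!r}; available: {builtin_scheme_names()}"
        )
    ref = resources.files("tiltkit.schemes").joinpath(f"{name}.tlt")
    angles = read_tilt_angles(ref)
    return TiltScheme(
        angles=tuple(float(a) for a in angles),
        increment=3.0,
        max_tilt=float(np.max(np.abs(angles))),
        group_schedule=(1,),
        dose_per_tilt=dose_per_tilt if dose_per_tilt is not None else default_dose[name],
    )


def read_tilt_angles(path) -> np.ndarray:
    """Read a plain one-angle-per-line (.tlt) file into a float array."""
    text = Path(path).read_text() if not hasattr(path, "read_text") else path.read_text()
    vals = [float(line) for line in text.split() if line.strip()]
    if not vals:
        raise SchemeError(f"no angles found in {path}")
    return np.asarray(vals, dtype=float)
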