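"""Readers/writers for MRC2014 maps/stacks, IMOD-dialect tilt metadata
(.tlt/.xf), particle tables and run configuration.

Particle-table coordinates are physical micrometres from the tomogram
centre (0-based pixel indexing and half-open box intervals wherever pixels
appear); voxel conversion always requires an explicit pixel size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import mrcfile
import numpy as np
import pandas as pd
import yaml

from tiltkit.ctf import TiltGeometry

__all__ = [
    "RunConfig",
    "read_mrc",
    "write_mrc",
    "read_tlt",
    "write_tlt",
    "read_xf",
    "write_xf",
    "read_tilt_geometry",
    "read_particle_table",
    "write_particle_table",
]


class IoError(ValueError):
    pass


@dataclass
class RunConfig:
    """Serializable run configuration echoed verbatim into logs."""

    scheme: str = "pm36"
    low_threshold_nm: float = 100.0
    high_threshold_nm: float = 5.0
    defocus_search: tuple[float, float, float] = (10000.0, 20000.0, 500.0)
    weighting_conversion: float = 100.0
    seed: int = 0
    output_dir: str = "out"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["defocus_search"] = list(self.defocus_search)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "defocus_search" in data:
            data["defocus_search"] = tuple(data["defocus_search"])
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


# --------------------------------------------------------------------------
# MRC

def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 file; returns ``(data, pixel_size_A)``.

    Malformed or truncated files raise :class:`IoError` naming the byte
    offset where the header check failed; no partial array is returned.
    """
    path = Path(path)
    size = path.stat().st_size
    if size < 1024:
        raise IoError(
            f"{path}: file is {size} bytes, shorter than the 1024-byte "
            "MRC header (error at byte offset 0)"
        )
    try:
        with mrcfile.open(path, permissive=False) as f:
            data = np.asarray(f.data).copy()
            px = float(f.voxel_size.x)
    except Exception as exc:  # mrcfile raises plain ValueError on bad headers
        raise IoError(f"{path}: malformed MRC header (byte offset 0-1023): {exc}") from exc
    expected_min = 1024 + data.size * data.dtype.itemsize
    if size < expected_min:
        raise IoError(
            f"{path}: data section truncated at byte offset {size} "
            f"(expected >= {expected_min})"
        )
    return data, px


def write_mrc(path: str | Path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a float32 (mode 2) MRC2014 file with the given pixel size."""
    with mrcfile.new(str(path), overwrite=True) as f:
        f.set_data(np.asarray(data, dtype=np.float32))
        f.voxel_size = pixel_size


# --------------------------------------------------------------------------
# .tlt / .xf

def read_tlt(path: str | Path) -> np.ndarray:
    """One tilt angle (degrees) per line."""
    vals = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            vals.append(float(line))
        except ValueError as exc:
            raise IoError(f"{path}: line {i}: not a tilt angle: {line!r}") from exc
    if not vals:
        raise IoError(f"{path}: empty tilt-angle file")
    return np.asarray(vals)


def write_tlt(path: str | Path, angles: Sequence[float], sort_by_angle: bool = False) -> None:
    """Write angles one per line, acquisition order by default."""
    arr = np.asarray(list(angles), dtype=float)
    if sort_by_angle:
        arr = np.sort(arr)
    Path(path).write_text("".join(f"{a:9.2f}\n" for a in arr))


def read_xf(path: str | Path) -> np.ndarray:
    """Read in-plane transforms: six floats per line (a11 a12 a21 a22 dx dy)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise IoError(
                f"{path}: line {i}: expected 6 columns (a11 a12 a21 a22 dx dy), "
                f"got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise IoError(f"{path}: line {i}: non-numeric transform entry") from exc
    if not rows:
        raise IoError(f"{path}: empty transform file")
    return np.asarray(rows)


def write_xf(path: str | Path, transforms: np.ndarray) -> None:
    arr = np.asarray(transforms, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise IoError("transforms must be (n, 6)")
    Path(path).write_text(
        "".join(
            "  ".join(f"{v:12.7f}" for v in row) + "\n" for row in arr
        )
    )


def read_tilt_geometry(
    tlt_path: str | Path,
    xf_path: str | Path | None = None,
    tilt_axis_angle: float = 0.0,
) -> list[TiltGeometry]:
    """Combine a .tlt file and optional .xf file into per-tilt geometry."""
    angles = read_tlt(tlt_path)
    if xf_path is not None:
        xf = read_xf(xf_path)
        if len(xf) != len(angles):
            raise IoError(
                f"row-count mismatch: {tlt_path} has {len(angles)} angles but "
                f"{xf_path} has {len(xf)} transforms"
            )
    else:
        xf = np.tile([1.0, 0.0, 0.0, 1.0, 0.0, 0.0], (len(angles), 1))
    return [
        TiltGeometry(
            tilt_axis_angle=tilt_axis_angle,
            tilt_angle=float(a),
            transform=tuple(row),
        )
        for a, row in zip(angles, xf)
    ]


# --------------------------------------------------------------------------
# particle tables

_PARTICLE_COLUMNS = [
    "particle_id", "tilt_series_id", "x_um", "y_um", "z_um",
    "euler1_deg", "euler2_deg", "euler3_deg",
    "tilt_index", "defocus1_A", "defocus2_A", "astig_deg",
    "score", "weight_B_A2",
]

_TABLE_HEADER = (
    "# tiltkit particle table: coordinates in um from the tomogram centre,\n"
    "# 0-based pixel indexing, half-open box intervals; one row per\n"
    "# (particle, tilt) projection.\n"
)


def write_particle_table(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in _PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise IoError(f"particle table missing columns: {missing}")
    with open(path, "w") as f:
        f.write(_TABLE_HEADER)
        table[_PARTICLE_COLUMNS].to_csv(f, sep="\t", index=False)


def read_particle_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise IoError(f"{path}: particle table missing columns: {missing}")
    return df
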