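"""Containers and I/O for serial block-face EM volumes.

A stack is a 3D grid of grayscale intensities with anisotropic physical
voxel sizes: small lateral pixels (a few nm) and much thicker axial
sections (tens of nm), as produced by serial block-face scanning electron
microscopy where the block is imaged after each round of in-chamber
sectioning.

Coordinate convention
---------------------
Pixel ``(row r, col c)`` in slice ``k`` maps to physical coordinates

    x = c * dx_nm,   y = r * dy_nm,   z = k * dz_nm

with 0-based indices addressing pixel centres.  All physical quantities in
this package are expressed in nanometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelGeometry", "EMStack", "write_stack", "read_stack"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel sizes and grid shape of an EM stack.

    Parameters
    ----------
    shape
        ``(n_slices, n_rows, n_cols)`` voxel counts.
    dx_nm, dy_nm
        Lateral pixel sizes in nm (default 3.5 nm).
    dz_nm
        Section (slice) thickness in nm (default 50 nm).
    """

    shape: tuple[int, int, int]
    dx_nm: float = 3.5
    dy_nm: float = 3.5
    dz_nm: float = 50.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("shape must be (n_slices, n_rows, n_cols)")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        for name in ("dx_nm", "dy_nm", "dz_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_slices(self) -> int:
        return self.shape[0]

    @property
    def n_rows(self) -> int:
        return self.shape[1]

    @property
    def n_cols(self) -> int:
        return self.shape[2]

    @property
    def width_nm(self) -> float:
        """Physical extent along x (columns)."""
        return self.n_cols * self.dx_nm

    @property
    def height_nm(self) -> float:
        """Physical extent along y (rows)."""
        return self.n_rows * self.dy_nm

    @property
    def depth_nm(self) -> float:
        """Physical extent along z (slices)."""
        return self.n_slices * self.dz_nm

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "dx_nm": self.dx_nm,
            "dy_nm": self.dy_nm,
            "dz_nm": self.dz_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(
            shape=tuple(d["shape"]),
            dx_nm=float(d["dx_nm"]),
            dy_nm=float(d["dy_nm"]),
            dz_nm=float(d["dz_nm"]),
        )


_BIT_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class EMStack:
    """A grayscale EM stack plus its physical geometry.

    ``intensities`` is ``(n_slices, n_rows, n_cols)`` of unsigned integers
    within the declared bit depth.
    """

    intensities: np.ndarray
    geometry: VoxelGeometry
    bit_depth: int = 8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bit_depth not in _BIT_DTYPES:
            raise ValueError("bit_depth must be 8 or 16")
        want = _BIT_DTYPES[self.bit_depth]
        if self.intensities.dtype != want:
            raise ValueError(
                f"intensities dtype {self.intensities.dtype} does not match "
                f"bit depth {self.bit_depth}"
            )
        if tuple(self.intensities.shape) != self.geometry.shape:
            raise ValueError(
                f"intensity grid shape {self.intensities.shape} does not match "
                f"geometry shape {self.geometry.shape}"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_stack(stack: EMStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF with voxel metadata.

    Voxel sizes are written both to the TIFF tags (x/y resolution, ImageJ
    z-spacing) and to a JSON sidecar ``<stem>.meta.json`` next to the file.
    Returns the TIFF path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = stack.geometry
    # resolution in pixels per centimetre (1 cm = 1e7 nm)
    tifffile.imwrite(
        path,
        stack.intensities,
        photometric="minisblack",
        resolution=(1e7 / g.dx_nm, 1e7 / g.dy_nm),
        resolutionunit="CENTIMETER",
        metadata={"spacing": g.dz_nm / 1000.0, "unit": "um", "axes": "ZYX"},
    )
    sidecar = {
        "geometry": g.to_dict(),
        "bit_depth": stack.bit_depth,
        **stack.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> EMStack:
    """Read a stack written by :func:`write_stack` (TIFF + JSON sidecar)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(_sidecar_path(path).read_text())
    geometry = VoxelGeometry.from_dict(meta["geometry"])
    bit_depth = int(meta.get("bit_depth", 8))
    extra = {k: v for k, v in meta.items() if k not in ("geometry", "bit_depth")}
    return EMStack(
        intensities=data.astype(_BIT_DTYPES[bit_depth]),
        geometry=geometry,
        bit_depth=bit_depth,
        metadata=extra,
    )
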