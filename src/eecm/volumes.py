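"""Voxel volume containers and TIFF + JSON-sidecar input/output.

Two containers cover every stage of the pipeline: :class:`GrayscaleVolume`
for raw scalar stacks (e.g. micro-CT) and :class:`BinaryMicrostructure` for
segmented two-phase volumes (solid tissue vs. pore space).  Axes are ordered
``(z, y, x)`` as in a stack of transverse slices; the physical voxel size is
isotropic and carried in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

AXES = {"x": 2, "y": 1, "z": 0}
#: inverse of :data:`AXES`
AXIS_NAMES = {v: k for k, v in AXES.items()}


def axis_index(axis: int | str) -> int:
    """Normalize an axis identifier ('x'/'y'/'z' or 0/1/2, ZYX order) to an int."""
    if isinstance(axis, str):
        try:
            return AXES[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis {axis!r}; expected one of x, y, z") from None
    axis = int(axis)
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index must be 0, 1 or 2 (ZYX order), got {axis}")
    return axis


@dataclass
class GrayscaleVolume:
    """A 3D scalar voxel image with isotropic physical voxel size.

    Parameters
    ----------
    values
        3D integer (or float) array, axes ordered ``(z, y, x)``.
    voxel_size
        Edge length of a voxel in micrometres.
    """

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryMicrostructure:
    """A two-phase voxel volume: ``True`` = solid tissue, ``False`` = pore.

    Parameters
    ----------
    solid
        3D boolean array, axes ordered ``(z, y, x)``; True marks the solid
        phase (the tissue walls), False the pore space.
    voxel_size
        Edge length of a voxel in micrometres.
    threshold_used
        Grayscale threshold that produced this segmentation, if any
        (provenance only).
    """

    solid: np.ndarray
    voxel_size: float
    threshold_used: float | None = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.solid)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1, 255)).all():
                raise ValueError("binary volume must contain exactly two phase labels")
            arr = arr > 0
        self.solid = arr
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def pore(self) -> np.ndarray:
        return ~self.solid

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    def phase_mask(self, phase: str) -> np.ndarray:
        """Return the boolean mask of ``phase`` ('solid' or 'pore')."""
        if phase == "solid":
            return self.solid
        if phase == "pore":
            return self.pore
        raise ValueError(f"phase must be 'solid' or 'pore', got {phase!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: GrayscaleVolume | BinaryMicrostructure, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus a JSON sidecar.

    Binary volumes are encoded 0/255 (solid = 255); grayscale volumes are
    written in their own dtype (floats are cast to uint8 after clipping).
    The sidecar records voxel size, axes order and phase encoding.
    """
    path = Path(path)
    if isinstance(vol, BinaryMicrostructure):
        data = np.where(vol.solid, 255, 0).astype(np.uint8)
        meta = {
            "voxel_size_um": vol.voxel_size,
            "axes_order": "ZYX",
            "kind": "binary",
            "phase_encoding": {"solid": 255, "pore": 0},
            "threshold_used": vol.threshold_used,
        }
    else:
        data = vol.values
        if data.dtype.kind == "f":
            data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
        meta = {"voxel_size_um": vol.voxel_size, "axes_order": "ZYX", "kind": "grayscale"}
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path) -> GrayscaleVolume | BinaryMicrostructure:
    """Read a multi-page TIFF written by :func:`write_volume` (or a plain
    stack, assuming 1 um voxels and grayscale if no sidecar is present)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel = float(meta.get("voxel_size_um", 1.0))
        if meta.get("kind") == "binary":
            solid_label = meta.get("phase_encoding", {}).get("solid", 255)
            return BinaryMicrostructure(
                data == solid_label, voxel, threshold_used=meta.get("threshold_used")
            )
        return GrayscaleVolume(data, voxel)
    return GrayscaleVolume(data, 1.0)
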