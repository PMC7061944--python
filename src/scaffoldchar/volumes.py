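"""Volumetric containers and TIFF-stack input/output.

All volumes use (z, y, x) axis order with axis 0 as scaffold thickness
(depth 0 at the top face) and an isotropic voxel size in micrometres.
Voxel-size metadata travels with a volume in three places, resolved with
the precedence: explicit override > JSON sidecar (``<name>.meta.json``) >
TIFF resolution tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VolumeImage",
    "BinaryVolume",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar intensity grid with isotropic voxel size in µm."""

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={values.ndim}")
        if min(values.shape) < 2:
            raise ValueError(f"all dimensions must be >= 2, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) in µm."""
        return tuple(n * self.voxel_size for n in self.values.shape)


@dataclass(frozen=True)
class BinaryVolume:
    """A 3D pore/solid mask (True = pore phase) with isotropic voxel size in µm."""

    mask: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={mask.ndim}")
        if mask.dtype != bool:
            if not np.isin(mask, (0, 1)).all():
                raise ValueError("mask values must be boolean or 0/1")
            mask = mask.astype(bool)
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def porosity(self) -> float:
        return float(self.mask.mean())

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size for n in self.mask.shape)

    def require_two_phases(self) -> None:
        """Metrology operations need at least one voxel of each phase."""
        if not self.mask.any():
            raise ValueError("pore phase is empty")
        if self.mask.all():
            raise ValueError("solid phase is empty")


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".meta.json")


def write_volume(path: str | Path, volume: VolumeImage | BinaryVolume,
                 extra_meta: dict | None = None) -> Path:
    """Write a volume as a multi-page TIFF plus a ``<name>.meta.json`` sidecar.

    Voxel size is recorded both in the sidecar and in the TIFF X/Y
    resolution tags (pixels per centimetre).
    """
    path = Path(path)
    if isinstance(volume, BinaryVolume):
        data = volume.mask.astype(np.uint8)
    else:
        data = np.asarray(volume.values)
    ppcm = 1.0e4 / volume.voxel_size
    tifffile.imwrite(path, data, photometric="minisblack",
                     resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")
    meta = {"voxel_size_um": volume.voxel_size, "axis_order": "zyx",
            "shape": list(data.shape)}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _voxel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "YResolution" not in tags:
        return None
    xres = tags["XResolution"].value
    yres = tags["YResolution"].value
    xres = xres[0] / xres[1] if isinstance(xres, tuple) else float(xres)
    yres = yres[0] / yres[1] if isinstance(yres, tuple) else float(yres)
    if xres <= 0 or yres <= 0:
        return None
    unit = tags.get("ResolutionUnit")
    unit_value = getattr(unit, "value", None)
    unit_name = getattr(unit_value, "name", str(unit_value)).upper()
    if "CENTIMETER" in unit_name:
        per_um = 1.0e-4
    elif "INCH" in unit_name:
        per_um = 1.0 / 25400.0
    else:
        return None
    vx = 1.0 / (xres * per_um)
    vy = 1.0 / (yres * per_um)
    if abs(vx - vy) > 1e-6 * max(vx, vy):
        raise ValueError(
            f"anisotropic voxels unsupported (x: {vx:.4g} µm, y: {vy:.4g} µm)")
    return vx


def _resolve_voxel_size(path: Path, override: float | None,
                        tif: tifffile.TiffFile) -> float:
    if override is not None:
        if not override > 0:
            raise ValueError("voxel size override must be positive")
        return float(override)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "voxel_size_um" in meta:
            return float(meta["voxel_size_um"])
    from_tags = _voxel_size_from_tags(tif)
    if from_tags is not None:
        return from_tags
    raise ValueError(
        f"no voxel size available for {path}: pass an override or provide a "
        f"{sidecar.name} sidecar or TIFF resolution tags")


def read_volume(path: str | Path, voxel_size_override: float | None = None) -> VolumeImage:
    """Read a multi-page TIFF stack as a :class:`VolumeImage`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        voxel = _resolve_voxel_size(path, voxel_size_override, tif)
    if data.ndim == 2:
        data = data[None]
    return VolumeImage(values=data, voxel_size=voxel)


def read_mask(path: str | Path, voxel_size_override: float | None = None) -> BinaryVolume:
    """Read a multi-page TIFF stack as a binary pore/solid mask (nonzero = pore)."""
    vol = read_volume(path, voxel_size_override)
    return BinaryVolume(mask=np.asarray(vol.values) > 0, voxel_size=vol.voxel_size)


def write_mask(path: str | Path, mask: BinaryVolume,
               extra_meta: dict | None = None) -> Path:
    return write_volume(path, mask, extra_meta)
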