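"""Grayscale-to-binary segmentation of micro-CT volumes.

Mirrors the standard CT-analysis recipe for lyophilized scaffolds:
automatic Otsu thresholding of the full 3D intensity histogram followed
by a despeckling pass that removes spurious small components from both
phases.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .volumes import BinaryVolume, VolumeImage

__all__ = ["otsu_threshold", "despeckle", "segment"]

# 26-connectivity for the pore phase, 6-connectivity for the solid
# complement: the standard dual pair that avoids topological paradoxes.
_CONN_PORE = np.ones((3, 3, 3), dtype=bool)
_CONN_SOLID = ndi.generate_binary_structure(3, 1)


def otsu_threshold(image: VolumeImage, pore_is: str = "darker",
                   per_slice: bool = False) -> BinaryVolume:
    """Binarize a grayscale volume at the Otsu threshold.

    The threshold maximizes between-class variance of the intensity
    histogram (256 uniform bins over the value range), computed
    volumetrically by default (``per_slice=True`` thresholds each z-slice
    independently). Voxels on the ``pore_is`` side of the threshold become
    the pore phase.
    """
    if pore_is not in ("darker", "brighter"):
        raise ValueError(f"pore_is must be 'darker' or 'brighter', got {pore_is!r}")
    values = np.asarray(image.values)
    if np.ptp(values) == 0:
        raise ValueError("degenerate histogram: image has a single intensity value")

    def _binarize(arr: np.ndarray) -> np.ndarray:
        thr = threshold_otsu(arr, nbins=256)
        return arr <= thr if pore_is == "darker" else arr > thr

    if per_slice:
        mask = np.stack([
            _binarize(sl) if np.ptp(sl) > 0 else np.zeros_like(sl, dtype=bool)
            for sl in values
        ])
    else:
        mask = _binarize(values)
    return BinaryVolume(mask=mask, voxel_size=image.voxel_size)


def _keep_largest(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def _drop_small(mask: np.ndarray, structure: np.ndarray, min_size: int) -> np.ndarray:
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def despeckle(binary: BinaryVolume, policy: str = "keep_largest",
              min_size_voxels: int | None = None) -> BinaryVolume:
    """Remove spurious small components from a binary volume ("sweep").

    ``keep_largest`` retains only the largest 26-connected pore component,
    then the largest 6-connected solid component; orphaned voxels of each
    phase are reassigned to the other. ``min_size`` instead removes
    components smaller than ``min_size_voxels`` from both phases (pore
    first). Both policies are idempotent.
    """
    mask = binary.mask
    if mask.size == 0:
        raise ValueError("empty volume")
    if policy == "keep_largest":
        pore = _keep_largest(mask, _CONN_PORE)
        solid = _keep_largest(~pore, _CONN_SOLID)
        return BinaryVolume(mask=~solid, voxel_size=binary.voxel_size)
    if policy == "min_size":
        if min_size_voxels is None:
            raise ValueError("min_size policy requires min_size_voxels")
        pore = _drop_small(mask, _CONN_PORE, min_size_voxels)
        solid = _drop_small(~pore, _CONN_SOLID, min_size_voxels)
        return BinaryVolume(mask=~solid, voxel_size=binary.voxel_size)
    raise ValueError(f"unknown despeckle policy {policy!r}")


def segment(image: VolumeImage, pore_is: str = "darker",
            despeckle_policy: str | None = "keep_largest",
            min_size_voxels: int | None = None,
            per_slice: bool = False) -> BinaryVolume:
    """Threshold then despeckle: the full segmentation stage."""
    mask = otsu_threshold(image, pore_is=pore_is, per_slice=per_slice)
    if despeckle_policy is not None:
        mask = despeckle(mask, policy=despeckle_policy,
                         min_size_voxels=min_size_voxels)
    return mask
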