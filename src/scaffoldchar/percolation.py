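"""Percolation-diameter estimation from virtual-sphere accessibility.

The percolation diameter d_c of a porous structure is the diameter of the
largest spherical probe able to traverse an infinitely large sample. For a
finite slab it is estimated by sweeping the probe diameter d, measuring
the penetration length L(d) of the accessible region ("shrink wrap") from
an inlet face, and fitting the percolation-theory scaling law

    L = L0 * (d - d_c)^(-nu),    nu = 0.88 in three dimensions,

as ordinary least squares of d against L^(-1/nu); d_c is the intercept at
L^(-1/nu) = 0 and the slope equals L0^(1/nu). Saturated points (the probe
traverses the whole slab) and inaccessible points (L = 0) are outside the
diverging-but-finite regime the law describes and are excluded from the
fit. When no unsaturated regime exists (e.g. an open channel through a
thin slab) the breakthrough estimate — the largest d whose accessible
region still spans the slab — is used instead.

Digital probes live on a voxel grid: probe diameters are quantized up to
whole voxels (half-voxel radii), and the accessible region for diameter d
is the union of raw shrink-wrap regions over all grid diameters >= d.
In the continuum a smaller sphere reaches everywhere a larger one does,
but voxelized Euclidean balls of different radii are not morphological
multiples of each other, so the raw regions alone can miss a handful of
diagonal boundary voxels; the union restores the continuum monotonicity
exactly (region nesting and non-increasing L hold for every probe pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volumes import BinaryVolume

__all__ = ["PercolationCurve", "PercolationFit", "accessible_region",
           "penetration_length", "percolation_curve", "fit_percolation",
           "estimate_percolation_diameter", "NU_3D"]

NU_3D = 0.88  # universal 3D percolation correlation-length exponent

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_EPS = 1e-6  # float slack on integer squared distances

_AXES = {"z": 0, "y": 1, "x": 2}


def _parse_face(inlet_face: str) -> tuple[int, int]:
    """Return (axis index, 0 for the low face / -1 for the high face)."""
    if len(inlet_face) != 2 or inlet_face[0] not in _AXES or inlet_face[1] not in "-+":
        raise ValueError(f"inlet_face must be one of z-/z+/y-/y+/x-/x+, got {inlet_face!r}")
    return _AXES[inlet_face[0]], 0 if inlet_face[1] == "-" else -1


def _face_slicer(axis: int, end: int) -> tuple[slice, ...]:
    sl: list[slice | int] = [slice(None)] * 3
    sl[axis] = end
    return tuple(sl)


@dataclass(frozen=True)
class PercolationCurve:
    """(d, L) accessibility samples along one percolation axis."""

    d_um: np.ndarray
    L_um: np.ndarray
    saturated: np.ndarray
    axis: str
    sample_thickness_um: float
    voxel_size: float

    def __post_init__(self) -> None:
        d = np.asarray(self.d_um, dtype=float)
        L = np.asarray(self.L_um, dtype=float)
        sat = np.asarray(self.saturated, dtype=bool)
        if not (np.diff(d) > 0).all():
            raise ValueError("d grid must be strictly increasing")
        object.__setattr__(self, "d_um", d)
        object.__setattr__(self, "L_um", L)
        object.__setattr__(self, "saturated", sat)

    def is_monotone(self) -> bool:
        """Measured curves are non-increasing in d; noisy synthetic curves
        used as fit inputs need not be."""
        return bool((np.diff(self.L_um) <= 1e-9).all())

    def to_dict(self) -> dict:
        return {
            "d_um": self.d_um.tolist(),
            "L_um": self.L_um.tolist(),
            "saturated": self.saturated.tolist(),
            "axis": self.axis,
            "sample_thickness_um": self.sample_thickness_um,
            "voxel_size": self.voxel_size,
        }


@dataclass(frozen=True)
class PercolationFit:
    """Fitted (d_c, L0) under fixed nu, or a breakthrough estimate."""

    d_c: float
    L_0: float
    nu: float
    n_points_used: int
    residual_sd: float
    d_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    method: str = "scaling_fit"

    def to_dict(self) -> dict:
        def _num(x: float) -> float | None:
            return None if np.isnan(x) else float(x)

        return {
            "d_c_um": self.d_c,
            "L_0_um": _num(self.L_0),
            "nu": self.nu,
            "n_points_used": self.n_points_used,
            "residual_sd_um": _num(self.residual_sd),
            "d_grid_um": np.asarray(self.d_grid).tolist(),
            "method": self.method,
        }


def _quantize_radius_vx(d_um: float, voxel_size: float) -> float:
    """Probe radius in voxels, rounded up to the half-voxel grid."""
    return float(np.ceil(d_um / voxel_size - 1e-9)) / 2.0


def _sealed_edt(pore: np.ndarray, axis: int, end: int) -> np.ndarray:
    """EDT of the pore phase with every face except the inlet sealed by a
    solid layer: the probe enters only through the inlet (it may protrude
    out of it), and cannot bypass constrictions by slipping along clipped
    boundary pores."""
    pad = [[1, 1], [1, 1], [1, 1]]
    pad[axis][0 if end == 0 else 1] = 0
    padded = np.pad(pore, pad, constant_values=False)
    edt = ndi.distance_transform_edt(padded)
    crop = tuple(slice(p[0], s + p[0]) for p, s in zip(pad, pore.shape))
    return edt[crop]


def _raw_region(pore: np.ndarray, edt: np.ndarray, r_vx: float,
                axis: int, end: int) -> np.ndarray:
    """One raw shrink-wrap pass: erode (exact EDT dual of the digital ball
    ``{x : |x| <= r}``), keep 26-components touching the inlet face,
    dilate back by the same ball, intersect with the pore phase."""
    eroded = edt * edt > r_vx * r_vx + _EPS
    if not eroded.any():
        return np.zeros_like(pore)
    labels, _ = ndi.label(eroded, structure=_CONN26)
    inlet_labels = np.unique(labels[_face_slicer(axis, end)])
    inlet_labels = inlet_labels[inlet_labels > 0]
    kept = np.isin(labels, inlet_labels)
    if not kept.any():
        return np.zeros_like(pore)
    dist = ndi.distance_transform_edt(~kept)
    return pore & (dist * dist <= r_vx * r_vx + _EPS)


def _canonical_radii_down(r_min_vx: float, edt_max: float) -> np.ndarray:
    """Half-voxel radius grid from just under ``edt_max`` down to r_min."""
    top = np.floor((edt_max - 1e-9) * 2.0) / 2.0
    if top < r_min_vx:
        return np.array([r_min_vx])
    return np.arange(top, r_min_vx - 0.25, -0.5)


def accessible_region(mask: BinaryVolume, d_um: float,
                      inlet_face: str = "z-") -> BinaryVolume:
    """Pore voxels reachable by a sphere of diameter ``d_um`` from a face.

    The probe diameter is quantized up to a whole number of voxels and
    the returned region is the union of raw shrink-wrap regions over all
    grid diameters >= d (see the module docstring), which makes region
    nesting exact for any pair of probe diameters.
    """
    axis, end = _parse_face(inlet_face)
    if d_um < mask.voxel_size:
        raise ValueError(
            f"probe diameter {d_um} µm is below the voxel size {mask.voxel_size} µm")
    pore = mask.mask
    r = _quantize_radius_vx(d_um, mask.voxel_size)

    edt = _sealed_edt(pore, axis, end)
    region = np.zeros_like(pore)
    for r_k in _canonical_radii_down(r, float(edt.max())):
        region |= _raw_region(pore, edt, r_k, axis, end)
    return BinaryVolume(mask=region, voxel_size=mask.voxel_size)


def penetration_length(region: BinaryVolume, axis: str = "z",
                       inlet_face: str = "z-") -> float:
    """Reach of the accessible region into the sample, in µm.

    L = (1 + deepest accessible slice index from the inlet face) * voxel
    size; 0 for an empty region.
    """
    ax, end = _parse_face(inlet_face)
    if _AXES[axis] != ax:
        raise ValueError("inlet_face must lie on the percolation axis")
    if not region.mask.any():
        return 0.0
    occupied = np.any(region.mask, axis=tuple(i for i in range(3) if i != ax))
    idx = np.nonzero(occupied)[0]
    depth = idx.max() if end == 0 else (region.mask.shape[ax] - 1 - idx.min())
    return float((depth + 1) * region.voxel_size)


def _depth_um(region: np.ndarray, ax: int, end: int, voxel_size: float) -> float:
    if not region.any():
        return 0.0
    occupied = np.any(region, axis=tuple(i for i in range(3) if i != ax))
    idx = np.nonzero(occupied)[0]
    depth = idx.max() if end == 0 else (region.shape[ax] - 1 - idx.min())
    return float((depth + 1) * voxel_size)


def _sweep_L(mask: BinaryVolume, r_min_vx: float, axis: str,
             inlet_face: str) -> dict[float, float]:
    """L at every canonical probe radius >= r_min, in one descending
    sweep with a running union (each raw region is computed once)."""
    ax, end = _parse_face(inlet_face)
    pore = mask.mask
    edt = _sealed_edt(pore, ax, end)
    region = np.zeros_like(pore)
    out: dict[float, float] = {}
    for r_k in _canonical_radii_down(r_min_vx, float(edt.max())):
        region |= _raw_region(pore, edt, r_k, ax, end)
        out[float(r_k)] = _depth_um(region, ax, end, mask.voxel_size)
    return out


def percolation_curve(mask: BinaryVolume, d_min_um: float | None = None,
                      d_max_um: float | None = None, step_um: float | None = None,
                      axis: str = "z", inlet_face: str | None = None,
                      refine: bool = True) -> PercolationCurve:
    """Sweep the probe diameter and measure L(d).

    Defaults: d from 2 voxels to the maximal inscribed-sphere diameter of
    the pore phase, in steps of 1 voxel. The sweep stops after the first
    empty (L = 0) diameter. With ``refine`` a single bisection pass adds
    one sample inside the saturation knee and one at the accessibility
    limit, halving the grid error of both estimates.
    """
    mask.require_two_phases()
    vox = mask.voxel_size
    inlet_face = inlet_face if inlet_face is not None else axis + "-"
    ax, _ = _parse_face(inlet_face)
    if _AXES[axis] != ax:
        raise ValueError("inlet_face must lie on the percolation axis")

    if d_min_um is None:
        d_min_um = 2.0 * vox
    if d_min_um < vox:
        raise ValueError("d_min must be at least one voxel")
    if step_um is None:
        step_um = vox
    if not step_um > 0:
        raise ValueError("step must be positive")
    if d_max_um is None:
        edt = ndi.distance_transform_edt(mask.mask)
        d_max_um = 2.0 * float(edt.max()) * vox + step_um
    grid = np.arange(d_min_um, d_max_um + 0.5 * step_um, step_um)
    if grid.size == 0:
        raise ValueError("empty probe-diameter grid")

    L_at = _sweep_L(mask, _quantize_radius_vx(grid[0], vox), axis, inlet_face)

    def measure(d: float) -> float:
        return L_at.get(_quantize_radius_vx(d, vox), 0.0)

    thickness = mask.mask.shape[ax] * vox
    d_list: list[float] = []
    L_list: list[float] = []
    for d in grid:
        d_list.append(float(d))
        L_list.append(measure(d))
        if L_list[-1] == 0.0:
            break

    if refine:
        inserts = []
        L_arr = np.asarray(L_list)
        sat = L_arr >= thickness - 1e-9
        knee = np.nonzero(sat[:-1] & ~sat[1:])[0]
        if knee.size:
            i = knee[0]
            inserts.append(0.5 * (d_list[i] + d_list[i + 1]))
        lost = np.nonzero((L_arr[:-1] > 0) & (L_arr[1:] == 0))[0]
        if lost.size:
            i = lost[0]
            inserts.append(0.5 * (d_list[i] + d_list[i + 1]))
        for d in inserts:
            if d not in d_list:
                d_list.append(d)
                L_list.append(measure(d))
        order = np.argsort(d_list)
        d_list = [d_list[i] for i in order]
        L_list = [L_list[i] for i in order]

    d_arr = np.asarray(d_list)
    L_arr = np.asarray(L_list)
    return PercolationCurve(d_um=d_arr, L_um=L_arr,
                           saturated=L_arr >= thickness - 1e-9, axis=axis,
                           sample_thickness_um=thickness, voxel_size=vox)


def fit_percolation(curve: PercolationCurve, nu: float = NU_3D) -> PercolationFit:
    """Fit L = L0 (d - d_c)^(-nu) by OLS of d on L^(-1/nu)."""
    qualify = (curve.L_um > 0) & ~curve.saturated
    d = curve.d_um[qualify]
    L = curve.L_um[qualify]
    if d.size < 3:
        raise ValueError(
            "insufficient unsaturated regime: need >= 3 points with 0 < L < "
            "sample thickness (use a thicker sample or a finer d grid)")
    if np.ptp(L) == 0:
        raise ValueError("degenerate regression: all penetration lengths equal")
    x = L ** (-1.0 / nu)
    slope, intercept = np.polyfit(x, d, 1)
    if slope <= 0:
        raise ValueError("no diverging regime: fitted slope is non-positive")
    resid = d - (intercept + slope * x)
    residual_sd = float(np.sqrt(resid @ resid / max(d.size - 2, 1)))
    return PercolationFit(d_c=float(intercept), L_0=float(slope ** nu), nu=nu,
                          n_points_used=int(d.size), residual_sd=residual_sd,
                          d_grid=d, method="scaling_fit")


def estimate_percolation_diameter(curve: PercolationCurve,
                                  nu: float = NU_3D) -> PercolationFit:
    """Best available d_c estimate for a curve.

    The scaling fit is used when the unsaturated regime has >= 3 points
    and actually shows the divergence the law describes (largest
    unsaturated L at least twice the smallest); for step-like curves —
    open channels, window-limited lattices — where L drops from saturation
    to a plateau, the breakthrough diameter (largest d whose region still
    spans the slab) is exact and is used instead.
    """
    unsat = (curve.L_um > 0) & ~curve.saturated
    L = curve.L_um[unsat]
    diverging = L.size >= 3 and L.max() >= 2.0 * L.min()
    sat_d = curve.d_um[curve.saturated]
    if diverging:
        try:
            return fit_percolation(curve, nu)
        except ValueError:
            if sat_d.size == 0:
                raise
    if sat_d.size == 0:
        if L.size >= 3:
            return fit_percolation(curve, nu)
        raise ValueError("no spanning diameters: probe never traverses the slab")
    return PercolationFit(d_c=float(sat_d.max()), L_0=float("nan"), nu=nu,
                          n_points_used=int(sat_d.size), residual_sd=float("nan"),
                          d_grid=sat_d, method="breakthrough")
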