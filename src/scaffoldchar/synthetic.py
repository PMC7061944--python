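"""Synthetic volumes with known ground truth.

Four generator families:

* ``generate_lyophilized_volume`` — a random proxy for freeze-dried
  (lyophilized) scaffold geometry: ice-crystal domains are modelled as a
  nearest-nucleation-site tessellation (Voronoi-like) of Poisson-sampled
  sites, with thin solid walls on the cell boundaries and windows opened
  in the wall faces away from the triple junctions, mimicking solid
  material pushed to ice-crystal boundaries during freezing. No thermal
  or phase-field physics is simulated.
* ``generate_channel_fixture`` / ``generate_sphere_lattice`` — analytic
  fixtures whose mean pore size and percolation diameter are exact by
  construction; they are the oracles for the metrology modules. The
  sphere lattice decouples the two quantities: pore bodies of one
  diameter connected through circular windows of a smaller one.
* ``render_grayscale`` — turns a mask into a noisy grayscale volume for
  the segmentation stage.
* ``generate_nuclei_stack`` — nuclear-stain fluorescence stacks with
  Gaussian-blob nuclei at controlled density and depth profile.

Every generator is a pure function of its arguments including the seed;
random streams are created per call, never global.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .segmentation import despeckle
from .volumes import BinaryVolume, VolumeImage

__all__ = [
    "ScaffoldGroundTruth",
    "NucleiGroundTruth",
    "generate_lyophilized_volume",
    "generate_channel_fixture",
    "generate_sphere_lattice",
    "render_grayscale",
    "generate_nuclei_stack",
]

# Calibration of the tessellation generator, fitted once on a pilot sweep
# of nucleation densities (two seeds per point, 96³-128³ grids, walls 1.5
# voxels, rim fraction 0.15): measured voxel-weighted mean local thickness
# per site spacing s = (volume per site)^(1/3), both in voxels. The ratio
# drifts from ~0.74 at small cells (walls eat proportionally more) to >1
# at very open foams (inscribed spheres bulge through windows), so the
# target-to-spacing map is inverted from this table rather than a single
# proportionality constant.
_CAL_SPACING_VX = np.array([10.0, 12.0, 15.0, 18.0, 22.0, 26.0, 30.0,
                            36.0, 42.0, 48.0, 54.0])
_CAL_MEAN_VX = np.array([7.43, 9.19, 11.94, 14.56, 19.35, 21.91, 27.12,
                         33.68, 41.14, 56.66, 59.03])
# Wall rim kept where (d3 - d2) <= _RIM_FRAC * spacing: controls how much
# of each wall face is opened into an interconnection window.
_RIM_FRAC = 0.15
_WALL_THICKNESS_VX = 1.5


def _spacing_for_target(target_vx: float) -> float:
    """Invert the pilot calibration (linear extrapolation at the ends)."""
    if target_vx <= _CAL_MEAN_VX[0]:
        return target_vx * _CAL_SPACING_VX[0] / _CAL_MEAN_VX[0]
    if target_vx >= _CAL_MEAN_VX[-1]:
        return target_vx * _CAL_SPACING_VX[-1] / _CAL_MEAN_VX[-1]
    return float(np.interp(target_vx, _CAL_MEAN_VX, _CAL_SPACING_VX))

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass(frozen=True)
class ScaffoldGroundTruth:
    """What a generated scaffold volume is known to be."""

    generator_name: str
    parameters: dict
    true_mean_pore_size_um: float | None
    true_percolation_diameter_um: float | None
    voxel_size: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if min(self.shape) < 8:
            raise ValueError("all shape entries must be >= 8")
        d = self.true_percolation_diameter_um
        if d is not None:
            if d < self.voxel_size:
                raise ValueError("percolation diameter below voxel size")
            if d >= min(self.shape) * self.voxel_size:
                raise ValueError("percolation diameter exceeds the volume extent")


@dataclass(frozen=True)
class NucleiGroundTruth:
    """True nucleus positions for a synthetic fluorescence stack."""

    coordinates_um: np.ndarray  # (n, 3) as (z, y, x)
    count: int
    field_area_um2: float
    field_depth_um: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates_um, dtype=float).reshape(-1, 3)
        if self.count != coords.shape[0]:
            raise ValueError("count does not match number of coordinates")
        side = np.sqrt(self.field_area_um2)
        if coords.size and (
            (coords < -1e-9).any()
            or (coords[:, 0] > self.field_depth_um + 1e-9).any()
            or (coords[:, 1:] > side + 1e-9).any()
        ):
            raise ValueError("coordinates outside the stated field")
        object.__setattr__(self, "coordinates_um", coords)


def generate_lyophilized_volume(
    shape: tuple[int, int, int],
    voxel_size_um: float,
    target_mean_pore_um: float,
    seed: int,
    wall_thickness_vx: float = _WALL_THICKNESS_VX,
    rim_frac: float = _RIM_FRAC,
) -> tuple[BinaryVolume, ScaffoldGroundTruth]:
    """Random proxy for lyophilized scaffold geometry.

    Nucleation sites are sampled uniformly (Poisson process, fixed count)
    at a density calibrated so that the measured voxel-weighted mean pore
    size lands within 20% of ``target_mean_pore_um``; cells of the
    nearest-site tessellation are the pores, walls of fixed thickness
    (default 1.5 voxels) form where the two nearest sites are nearly
    equidistant, and the wall faces are opened away from the triple
    junctions so the pore phase stays interconnected, as in a freeze-dried
    foam. The pore phase is reduced to its largest 26-connected component;
    porosity falls in the lyophilized band 0.85-0.97 for pore sizes of
    roughly 7 voxels and up (thinner cells leave proportionally more wall).
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 8:
        raise ValueError("all shape entries must be >= 8")
    if target_mean_pore_um < 4.0 * voxel_size_um:
        raise ValueError(
            f"target pore size {target_mean_pore_um} µm is not resolvable at "
            f"voxel size {voxel_size_um} µm (need >= 4 voxels)")
    spacing_vx = _spacing_for_target(target_mean_pore_um / voxel_size_um)
    extent_vx = np.asarray(shape, dtype=float)
    if (extent_vx < 3.0 * spacing_vx).any():
        raise ValueError(
            "volume too small for this pore size: needs at least 3 "
            "tessellation cells per axis for the calibration to hold")

    n_sites = max(8, int(round(np.prod(extent_vx) / spacing_vx**3)))
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0.0, extent_vx, size=(n_sites, 3))

    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                    axis=-1).reshape(-1, 3)
    dists, _ = cKDTree(sites).query(grid, k=3)
    d1, d2, d3 = (dists[:, i].reshape(shape) for i in range(3))

    wall = (d2 - d1) <= wall_thickness_vx
    rim = (d3 - d2) <= rim_frac * spacing_vx
    solid = wall & rim

    # Reduce to one pore component and one solid component (isolated wall
    # shards go back to pore), so the mask is a despeckle fixed point and
    # noise-free segmentation reproduces it bitwise.
    vol = despeckle(BinaryVolume(mask=~solid, voxel_size=voxel_size_um),
                    policy="keep_largest")
    gt = ScaffoldGroundTruth(
        generator_name="lyophilized_tessellation",
        parameters={
            "seed": seed,
            "target_mean_pore_um": target_mean_pore_um,
            "n_sites": n_sites,
            "spacing_vx": spacing_vx,
            "wall_thickness_vx": wall_thickness_vx,
            "rim_frac": rim_frac,
        },
        true_mean_pore_size_um=target_mean_pore_um,
        true_percolation_diameter_um=None,
        voxel_size=voxel_size_um,
        shape=shape,
    )
    return vol, gt


def generate_channel_fixture(
    shape: tuple[int, int, int],
    voxel_size_um: float,
    channel_diameter_um: float,
    axis: str = "z",
) -> tuple[BinaryVolume, ScaffoldGroundTruth]:
    """A single straight circular channel spanning the volume.

    The largest sphere that can traverse is exactly the channel diameter,
    and every pore voxel's inscribed-sphere diameter equals it, so both
    ground truths are the channel diameter.
    """
    shape = tuple(int(n) for n in shape)
    if axis not in _AXES:
        raise ValueError(f"axis must be one of z/y/x, got {axis!r}")
    if channel_diameter_um < 3.0 * voxel_size_um:
        raise ValueError("channel not resolvable: diameter below 3 voxels")
    ax = _AXES[axis]
    trans = [i for i in range(3) if i != ax]
    for i in trans:
        if channel_diameter_um >= shape[i] * voxel_size_um:
            raise ValueError("channel wider than the transverse volume extent")

    r_vx = channel_diameter_um / (2.0 * voxel_size_um)
    coords = [np.arange(shape[i]) - shape[i] // 2 for i in trans]
    u, v = np.meshgrid(*coords, indexing="ij")
    disk = (u * u + v * v) <= r_vx * r_vx
    mask = np.zeros(shape, dtype=bool)
    mover = np.moveaxis(mask, ax, 0)
    mover[:] = disk[None]

    gt = ScaffoldGroundTruth(
        generator_name="channel_fixture",
        parameters={"channel_diameter_um": channel_diameter_um, "axis": axis},
        true_mean_pore_size_um=channel_diameter_um,
        true_percolation_diameter_um=channel_diameter_um,
        voxel_size=voxel_size_um,
        shape=shape,
    )
    return BinaryVolume(mask=mask, voxel_size=voxel_size_um), gt


def generate_sphere_lattice(
    shape: tuple[int, int, int],
    voxel_size_um: float,
    pore_diameter_um: float,
    window_diameter_um: float,
    seed: int | None = None,
) -> tuple[BinaryVolume, ScaffoldGroundTruth]:
    """Spherical pores on a cubic lattice, joined by circular windows.

    The lattice spacing is derived from the requested window: two
    neighbouring spheres of radius R at distance a overlap in a circle of
    radius sqrt(R^2 - (a/2)^2), so a = 2*sqrt(R^2 - (w/2)^2). The mean
    pore size is the sphere diameter while the percolation diameter is
    the window diameter — the fixture that shows the two are measured
    independently. ``seed`` is accepted for API symmetry; the lattice is
    deterministic.
    """
    del seed
    shape = tuple(int(n) for n in shape)
    vox = voxel_size_um
    if window_diameter_um >= pore_diameter_um:
        raise ValueError("window must be smaller than the pore diameter")
    if pore_diameter_um < 4.0 * vox:
        raise ValueError("pore not resolvable: diameter below 4 voxels")
    if window_diameter_um < 2.0 * vox:
        raise ValueError("window not resolvable: diameter below 2 voxels")
    R = pore_diameter_um / (2.0 * vox)
    rw = window_diameter_um / (2.0 * vox)
    a = 2.0 * np.sqrt(R * R - rw * rw)
    if not a > 0:
        raise ValueError("inconsistent geometry: spheres fully overlap")
    if a >= 2.0 * R:
        raise ValueError("inconsistent geometry: neighbouring spheres do not overlap")
    if min(shape) < 2 * a:
        raise ValueError("volume too small to hold two pore layers per axis")

    # Distance to the nearest lattice point factorizes per axis for a
    # simple cubic lattice anchored at the origin (spheres are truncated
    # by the faces, so probes can enter from any face).
    def axis_dist(n: int) -> np.ndarray:
        x = np.arange(n, dtype=float)
        return np.abs((x + a / 2.0) % a - a / 2.0)

    dz, dy, dx = (axis_dist(n) for n in shape)
    dist2 = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
             + dx[None, None, :] ** 2)
    mask = dist2 <= R * R

    gt = ScaffoldGroundTruth(
        generator_name="sphere_lattice",
        parameters={
            "pore_diameter_um": pore_diameter_um,
            "window_diameter_um": window_diameter_um,
            "lattice_spacing_vx": a,
        },
        true_mean_pore_size_um=pore_diameter_um,
        true_percolation_diameter_um=window_diameter_um,
        voxel_size=vox,
        shape=shape,
    )
    return BinaryVolume(mask=mask, voxel_size=vox), gt


def render_grayscale(mask: BinaryVolume, pore_intensity: float = 60.0,
                     solid_intensity: float = 190.0, noise_sd: float = 0.0,
                     seed: int = 0) -> VolumeImage:
    """Render a mask as a grayscale volume with Gaussian intensity noise.

    Each voxel is drawn from a Gaussian centred on its phase intensity.
    Micro-CT of collagen renders pores darker than walls, hence the
    default pore < solid; callers may invert.
    """
    if pore_intensity == solid_intensity:
        raise ValueError("pore and solid intensities must differ")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    values = np.where(mask.mask, float(pore_intensity), float(solid_intensity))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return VolumeImage(values=values, voxel_size=mask.voxel_size)


def _sample_depths(rng: np.random.Generator, n: int, depth_um: float,
                   depth_profile) -> np.ndarray:
    if isinstance(depth_profile, str):
        if depth_profile == "uniform":
            return rng.uniform(0.0, depth_um, n)
        if depth_profile == "surface":
            # Exponential fall-off with length scale depth/3, truncated.
            scale = depth_um / 3.0
            u = rng.uniform(0.0, 1.0, n)
            return -scale * np.log1p(-u * (1.0 - np.exp(-depth_um / scale)))
        raise ValueError(f"unknown depth profile {depth_profile!r}")
    density = np.asarray(depth_profile, dtype=float)
    if density.ndim != 1 or density.size < 1 or (density < 0).any() or density.sum() == 0:
        raise ValueError("user-supplied depth profile must be a non-negative 1D density")
    edges = np.linspace(0.0, depth_um, density.size + 1)
    bins = rng.choice(density.size, size=n, p=density / density.sum())
    return rng.uniform(edges[bins], edges[bins + 1])


def generate_nuclei_stack(
    field_area_um2: float,
    depth_um: float,
    voxel_size_um: float,
    n_nuclei: int,
    depth_profile="uniform",
    seed: int = 0,
    nucleus_radius_um: float = 6.0,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    min_separation_um: float | None = None,
    margin_um: float | None = None,
) -> tuple[VolumeImage, NucleiGroundTruth]:
    """Synthetic nuclear-stain z-stack over a square field.

    Nuclei are isotropic Gaussian blobs (sigma = one nucleus radius,
    peak ``amplitude``) at positions drawn from ``depth_profile`` in z
    and uniformly in the plane; blob-SNR is amplitude / noise_sd. Lateral
    positions keep ``margin_um`` (default one nucleus radius) away from
    the field edges so blobs are not clipped; ``min_separation_um``
    enforces a minimum pairwise distance by dart throwing.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be non-negative")
    if nucleus_radius_um < voxel_size_um:
        raise ValueError(
            f"nuclei unresolvable: radius {nucleus_radius_um} µm below voxel "
            f"size {voxel_size_um} µm")
    side_um = float(np.sqrt(field_area_um2))
    if margin_um is None:
        margin_um = nucleus_radius_um
    if side_um <= 2 * margin_um:
        raise ValueError("field too small for the requested margin")

    rng = np.random.default_rng(seed)
    coords = np.empty((0, 3))
    if n_nuclei > 0:
        z = _sample_depths(rng, n_nuclei, depth_um, depth_profile)
        if min_separation_um is None:
            yx = rng.uniform(margin_um, side_um - margin_um, (n_nuclei, 2))
            coords = np.column_stack([z, yx])
        else:
            placed: list[np.ndarray] = []
            tries = 0
            while len(placed) < n_nuclei:
                cand = np.array([
                    z[len(placed)],
                    rng.uniform(margin_um, side_um - margin_um),
                    rng.uniform(margin_um, side_um - margin_um),
                ])
                if all(np.linalg.norm(cand - p) >= min_separation_um for p in placed):
                    placed.append(cand)
                tries += 1
                if tries > 2000 * n_nuclei:
                    raise ValueError("cannot satisfy min_separation_um in this field")
            coords = np.vstack(placed)

    shape = (max(2, int(np.ceil(depth_um / voxel_size_um))),
             max(2, int(np.ceil(side_um / voxel_size_um))),
             max(2, int(np.ceil(side_um / voxel_size_um))))
    img = np.zeros(shape, dtype=float)
    sigma_vx = nucleus_radius_um / voxel_size_um
    half = int(np.ceil(4.0 * sigma_vx))
    offsets = np.arange(-half, half + 1)
    for c_um in coords:
        c_vx = c_um / voxel_size_um
        base = np.round(c_vx).astype(int)
        windows, gauss_1d = [], []
        for ax in range(3):
            idx = base[ax] + offsets
            valid = (idx >= 0) & (idx < shape[ax])
            idx = idx[valid]
            windows.append(idx)
            gauss_1d.append(np.exp(-((idx - c_vx[ax]) ** 2) / (2.0 * sigma_vx**2)))
        blob = amplitude * (gauss_1d[0][:, None, None]
                            * gauss_1d[1][None, :, None]
                            * gauss_1d[2][None, None, :])
        img[np.ix_(windows[0], windows[1], windows[2])] += blob
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)

    stack = VolumeImage(values=img, voxel_size=voxel_size_um)
    gt = NucleiGroundTruth(coordinates_um=coords, count=int(n_nuclei),
                           field_area_um2=float(field_area_um2),
                           field_depth_um=float(depth_um))
    return stack, gt
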