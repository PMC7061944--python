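import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.signal import fftconvolve

from scaffoldchar import (BinaryVolume, PercolationCurve, accessible_region,
                          estimate_percolation_diameter, fit_percolation,
                          penetration_length, percolation_curve)
from conftest import VOX, random_blob_mask


def digital_ball(r_vx: float) -> np.ndarray:
    n = int(np.floor(r_vx))
    ax = np.arange(-n, n + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz * zz + yy * yy + xx * xx) <= r_vx * r_vx + 1e-9


def _brute_force_raw(mask: np.ndarray, r_vx: float) -> np.ndarray:
    """Explicit digital-ball erosion (FFT convolution counting uncovered
    background voxels), 26-connected flood from the z- inlet face, explicit
    dilation by the same ball, intersected with pores. All faces except
    the inlet are sealed by padding enough solid to block the ball."""
    w = int(np.floor(r_vx)) + 1
    padded = np.pad(mask, [[0, w], [w, w], [w, w]], constant_values=False)
    ball = digital_ball(r_vx)
    bg_hits = fftconvolve((~padded).astype(float), ball.astype(float), mode="same")
    eroded = padded & (bg_hits < 0.5)
    crop = (slice(0, mask.shape[0]), slice(w, w + mask.shape[1]),
            slice(w, w + mask.shape[2]))
    if not eroded.any():
        return np.zeros_like(mask)
    labels, _ = ndi.label(eroded, structure=np.ones((3, 3, 3), bool))
    inlet = np.unique(labels[0])
    kept = np.isin(labels, inlet[inlet > 0])
    if not kept.any():
        return np.zeros_like(mask)
    cover = fftconvolve(kept.astype(float), ball.astype(float), mode="same")
    return mask & (cover > 0.5)[crop]


def brute_force_accessible(mask: np.ndarray, d_um: float, voxel: float) -> np.ndarray:
    """Independent accessibility oracle: raw explicit-ball shrink-wrap
    passes unioned over the canonical half-voxel radius grid at and above
    the (quantized) probe radius — same definition, none of the EDT code."""
    r = np.ceil(d_um / voxel - 1e-9) / 2.0
    r_bound = max(mask.shape) / 2.0  # no inscribed ball can be larger
    r_top = np.floor(r_bound * 2.0) / 2.0
    out = np.zeros_like(mask)
    for rr in np.arange(max(r_top, r), r - 0.25, -0.5):
        out |= _brute_force_raw(mask, rr)
    return out


def test_channel_accessibility_thresholds(channel_45):
    vol, gt = channel_45
    thick = vol.shape[0] * VOX
    for d in (30.0, 39.0, 45.0):
        region = accessible_region(vol, d, "z-")
        assert region.mask.any()
        assert penetration_length(region, "z", "z-") == pytest.approx(thick)
    assert not accessible_region(vol, 48.0, "z-").mask.any()


def test_single_voxel_probe_reaches_inlet_connected_pores():
    vol = random_blob_mask(seed=21)
    region = accessible_region(vol, VOX, "z-")
    labels, _ = ndi.label(vol.mask, structure=np.ones((3, 3, 3), bool))
    inlet = np.unique(labels[0])
    expected = np.isin(labels, inlet[inlet > 0])
    assert np.array_equal(region.mask, expected)


@pytest.mark.parametrize("seed", [1, 5, 9])
def test_region_nesting_and_L_monotone(seed):
    vol = random_blob_mask(seed=seed)
    diam = [VOX, 2 * VOX, 4 * VOX, 6 * VOX]
    regions = [accessible_region(vol, d, "z-") for d in diam]
    lengths = [penetration_length(r, "z", "z-") for r in regions]
    for small, big in zip(regions[:-1], regions[1:]):
        assert not (big.mask & ~small.mask).any()  # region(d2) ⊆ region(d1)
    assert all(a >= b for a, b in zip(lengths[:-1], lengths[1:]))


def test_accessible_region_matches_brute_force(channel_45):
    vol = random_blob_mask(seed=13, shape=(36, 36, 36))
    for d in (VOX, 2.5 * VOX, 4 * VOX):
        got = accessible_region(vol, d, "z-").mask
        want = brute_force_accessible(vol.mask, d, VOX)
        assert np.array_equal(got, want)
    chan, _ = channel_45
    got = accessible_region(chan, 45.0, "z-").mask
    assert np.array_equal(got, brute_force_accessible(chan.mask, 45.0, VOX))


def test_penetration_length_arithmetic():
    empty = BinaryVolume(mask=np.zeros((60, 8, 8), bool), voxel_size=3.0)
    assert penetration_length(empty, "z", "z-") == 0.0
    region = np.zeros((60, 8, 8), bool)
    region[:50, 4, 4] = True  # deepest slice index 49
    vol = BinaryVolume(mask=region, voxel_size=3.0)
    assert penetration_length(vol, "z", "z-") == pytest.approx(150.0)
    full = BinaryVolume(mask=np.ones((60, 8, 8), bool), voxel_size=3.0)
    assert penetration_length(full, "z", "z-") == pytest.approx(180.0)


def test_channel_curve_saturated_then_empty(channel_45):
    vol, _ = channel_45
    curve = percolation_curve(vol, d_min_um=30.0, d_max_um=60.0, step_um=3.0,
                              refine=False)
    sat = dict(zip(curve.d_um, curve.saturated))
    for d in np.arange(30.0, 45.1, 3.0):
        assert sat[d]
    assert curve.L_um[-1] == 0.0
    assert (np.diff(curve.L_um) <= 1e-9).all()


def test_lattice_breakthrough_at_window(lattice_60_27):
    """Last spanning probe diameter = the 27 µm window, within 1 voxel."""
    vol, gt = lattice_60_27
    curve = percolation_curve(vol, axis="z")
    est = estimate_percolation_diameter(curve)
    assert est.d_c == pytest.approx(gt.true_percolation_diameter_um, abs=VOX)


def test_axis_independence_on_lattice(lattice_60_27):
    vol, _ = lattice_60_27
    estimates = []
    for axis in ("z", "y", "x"):
        curve = percolation_curve(vol, axis=axis)
        estimates.append(estimate_percolation_diameter(curve).d_c)
    assert max(estimates) - min(estimates) <= VOX


def synthetic_curve(d_c, L_0, d_values, nu=0.88, noise=None, rng=None):
    L = L_0 * (np.asarray(d_values, float) - d_c) ** (-nu)
    if noise is not None:
        L = L * rng.lognormal(0.0, noise, size=L.shape)
    return PercolationCurve(d_um=np.asarray(d_values, float), L_um=L,
                            saturated=np.zeros(len(L), bool), axis="z",
                            sample_thickness_um=np.inf, voxel_size=1.0)


def test_fit_exact_on_noiseless_curve():
    curve = synthetic_curve(100.0, 50.0, np.arange(110.0, 201.0, 10.0))
    fit = fit_percolation(curve)
    assert fit.d_c == pytest.approx(100.0, abs=1e-8)
    assert fit.L_0 == pytest.approx(50.0, rel=1e-8)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-8)
    assert fit.n_points_used == 10


def test_fit_under_multiplicative_noise():
    """Median d_c error stays within 5% under 5% noise on L."""
    errors = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        curve = synthetic_curve(100.0, 50.0, np.arange(110.0, 201.0, 10.0),
                                noise=0.05, rng=rng)
        errors.append(abs(fit_percolation(curve).d_c - 100.0))
    assert np.median(errors) <= 5.0


def test_fit_error_modes():
    with pytest.raises(ValueError, match="insufficient unsaturated"):
        fit_percolation(synthetic_curve(100.0, 50.0, [110.0, 120.0]))
    flat = PercolationCurve(d_um=np.array([10.0, 20.0, 30.0]),
                            L_um=np.array([50.0, 50.0, 50.0]),
                            saturated=np.zeros(3, bool), axis="z",
                            sample_thickness_um=np.inf, voxel_size=1.0)
    with pytest.raises(ValueError, match="degenerate"):
        fit_percolation(flat)


def test_probe_below_voxel_errors():
    vol = random_blob_mask(seed=2)
    with pytest.raises(ValueError, match="voxel"):
        accessible_region(vol, 0.5 * VOX, "z-")


def test_curve_invariants_enforced():
    with pytest.raises(ValueError, match="increasing"):
        PercolationCurve(d_um=np.array([3.0, 2.0, 4.0]),
                         L_um=np.array([5.0, 4.0, 3.0]),
                         saturated=np.zeros(3, bool), axis="z",
                         sample_thickness_um=10.0, voxel_size=1.0)
    wobbly = PercolationCurve(d_um=np.array([2.0, 3.0, 4.0]),
                              L_um=np.array([3.0, 5.0, 3.0]),
                              saturated=np.zeros(3, bool), axis="z",
                              sample_thickness_um=10.0, voxel_size=1.0)
    assert not wobbly.is_monotone()


def test_measured_curves_are_monotone(lattice_60_27):
    vol, _ = lattice_60_27
    assert percolation_curve(vol, axis="z").is_monotone()
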