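import numpy as np
import pytest

from scaffoldchar import (generate_channel_fixture, generate_lyophilized_volume,
                          generate_nuclei_stack, generate_sphere_lattice,
                          local_thickness, otsu_threshold,
                          pore_size_distribution, render_grayscale)
from conftest import VOX


class TestChannelFixture:
    def test_ground_truth_and_geometry(self, channel_45):
        vol, gt = channel_45
        assert gt.true_percolation_diameter_um == 45.0
        assert gt.true_mean_pore_size_um == 45.0
        tm = local_thickness(vol)
        vals = tm.diameters[vol.mask]
        assert np.all(np.abs(vals - 45.0) <= VOX)

    def test_errors(self):
        with pytest.raises(ValueError, match="wider"):
            generate_channel_fixture((32, 16, 16), VOX, 60.0)
        with pytest.raises(ValueError, match="resolvable"):
            generate_channel_fixture((32, 32, 32), VOX, 2.0 * VOX)

    def test_axis_choice(self):
        vol, _ = generate_channel_fixture((20, 24, 28), VOX, 30.0, axis="x")
        # channel spans the x axis: every x-slice has the same disk
        assert np.array_equal(vol.mask[..., 0], vol.mask[..., -1])
        assert vol.mask[..., 0].any()


class TestSphereLattice:
    def test_mean_pore_size(self, lattice_60_27):
        vol, gt = lattice_60_27
        tm = local_thickness(vol)
        res = pore_size_distribution(tm, bin_width_um=VOX)
        assert res.mean == pytest.approx(gt.true_mean_pore_size_um, abs=2 * VOX)

    def test_errors(self):
        with pytest.raises(ValueError, match="window"):
            generate_sphere_lattice((64, 64, 64), VOX, 60.0, 60.0)
        with pytest.raises(ValueError, match="window"):
            generate_sphere_lattice((64, 64, 64), VOX, 60.0, 75.0)


class TestLyophilized:
    def test_deterministic(self):
        a, _ = generate_lyophilized_volume((32, 32, 32), VOX, 24.0, seed=7)
        b, _ = generate_lyophilized_volume((32, 32, 32), VOX, 24.0, seed=7)
        assert np.array_equal(a.mask, b.mask)
        c, _ = generate_lyophilized_volume((32, 32, 32), VOX, 24.0, seed=8)
        assert not np.array_equal(a.mask, c.mask)

    def test_unresolvable_target_errors(self):
        with pytest.raises(ValueError, match="resolvable"):
            generate_lyophilized_volume((64, 64, 64), 3.0, 5.0, seed=1)

    @pytest.mark.parametrize("target_um,n", [(66.0, 96), (101.0, 112),
                                             (143.0, 144)])
    def test_porosity_band_and_connectivity(self, target_um, n):
        """Porosity in the lyophilized band; pore phase 26-connected."""
        from scipy import ndimage as ndi
        vol, gt = generate_lyophilized_volume((n, n, n), 2.97, target_um,
                                              seed=11)
        assert 0.85 <= vol.porosity <= 0.97
        _, n = ndi.label(vol.mask, np.ones((3, 3, 3), bool))
        assert n == 1

    def test_calibrated_mean(self):
        """Measured mean pore size within 20% of the 100 µm target."""
        vol, _ = generate_lyophilized_volume((128, 128, 128), 3.0, 100.0, seed=3)
        res = pore_size_distribution(local_thickness(vol), bin_width_um=3.0)
        assert abs(res.mean - 100.0) <= 20.0

    def test_too_small_volume_errors(self):
        with pytest.raises(ValueError, match="too small"):
            generate_lyophilized_volume((48, 48, 48), 3.0, 100.0, seed=1)


class TestRenderGrayscale:
    def test_noise_free_two_valued_and_recovered(self):
        vol, _ = generate_lyophilized_volume((24, 24, 24), 3.0, 16.0, seed=1)
        img = render_grayscale(vol, pore_intensity=60.0, solid_intensity=190.0,
                               noise_sd=0.0)
        assert set(np.unique(img.values)) == {60.0, 190.0}
        seg = otsu_threshold(img, pore_is="darker")
        assert np.array_equal(seg.mask, vol.mask)

    def test_deterministic_and_errors(self):
        vol, _ = generate_lyophilized_volume((24, 24, 24), 3.0, 16.0, seed=1)
        a = render_grayscale(vol, noise_sd=5.0, seed=9)
        b = render_grayscale(vol, noise_sd=5.0, seed=9)
        assert np.array_equal(a.values, b.values)
        with pytest.raises(ValueError, match="differ"):
            render_grayscale(vol, pore_intensity=100.0, solid_intensity=100.0)
        with pytest.raises(ValueError):
            render_grayscale(vol, noise_sd=-1.0)


class TestNucleiStack:
    def test_empty_field(self):
        stack, gt = generate_nuclei_stack(150.0**2, 60.0, 2.0, n_nuclei=0, seed=1)
        assert gt.count == 0
        assert not stack.values.any()

    def test_counts_and_bounds(self):
        _, gt = generate_nuclei_stack(200.0**2, 80.0, 2.0, n_nuclei=50, seed=3)
        assert gt.count == 50 == len(gt.coordinates_um)
        assert (gt.coordinates_um[:, 0] >= 0).all()
        assert (gt.coordinates_um[:, 0] <= 80.0).all()
        assert (gt.coordinates_um[:, 1:] <= 200.0).all()

    def test_surface_profile_dominates_uniform(self):
        """Surface-weighted depths are stochastically shallower."""
        surf, unif = [], []
        for seed in range(20):
            _, g1 = generate_nuclei_stack(150.0**2, 100.0, 2.5, 40,
                                          depth_profile="surface", seed=seed)
            _, g2 = generate_nuclei_stack(150.0**2, 100.0, 2.5, 40,
                                          depth_profile="uniform", seed=seed)
            surf.append(g1.coordinates_um[:, 0])
            unif.append(g2.coordinates_um[:, 0])
        surf, unif = np.sort(np.concatenate(surf)), np.sort(np.concatenate(unif))
        grid = np.linspace(1.0, 99.0, 50)
        cdf_s = np.searchsorted(surf, grid) / len(surf)
        cdf_u = np.searchsorted(unif, grid) / len(unif)
        assert np.all(cdf_s >= cdf_u - 0.02)
        assert cdf_s.mean() > cdf_u.mean() + 0.1

    def test_custom_depth_density(self):
        density = np.array([0.0, 0.0, 1.0, 1.0])  # deep half only
        _, gt = generate_nuclei_stack(150.0**2, 100.0, 2.5, 30,
                                      depth_profile=density, seed=2)
        assert (gt.coordinates_um[:, 0] >= 50.0).all()

    def test_unresolvable_radius_errors(self):
        with pytest.raises(ValueError, match="unresolvable"):
            generate_nuclei_stack(150.0**2, 60.0, 2.0, 5, nucleus_radius_um=1.0)
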