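import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_laplace

from conftest import make_spec
from gapct.phantom import (
    GapSpec,
    PhantomSpec,
    add_edge_fringes,
    generate_phantom,
    true_sector_occupancy,
)


def brute_force_gap_count(spec, gap):
    """Independent per-voxel membership oracle for one planted gap."""
    nz, ny, nx = spec.shape
    cy, cx = spec.center
    r_i = spec.interface_radius_um
    n = 0
    for y in range(ny):
        for x in range(nx):
            r = math.hypot(y - cy, x - cx) * spec.voxel_um
            theta = math.degrees(math.atan2(y - cy, x - cx)) % 360.0
            in_band = r_i - gap.thickness_um / 2 <= r < r_i + gap.thickness_um / 2
            in_arc = (theta - gap.angle_start) % 360.0 < gap.angle_extent
            if in_band and in_arc:
                n += 1
    return n * (gap.z_end - gap.z_start)


class TestGeneratePhantom:
    def test_no_gaps_yields_empty_truth(self):
        _, truth = generate_phantom(make_spec(gaps=[]))
        assert not truth.gap_mask.any()
        assert np.all(truth.sector_occupancy == 0)

    def test_gap_covers_stated_fraction_of_interface(self):
        spec = make_spec(gaps=[GapSpec(0.0, 120.0, 0, 8, 5.0)])
        _, truth = generate_phantom(spec)
        # interface circumference coverage = extent/360 = 1/3
        assert truth.sector_occupancy.mean() == pytest.approx(1 / 3, abs=1e-12)
        # and voxel-wise: gapped fraction of the interface band ~ 1/3
        band_px = truth.bonded_mask_2d.sum()
        gap_px = truth.gap_mask[0].sum()
        assert gap_px / band_px == pytest.approx(1 / 3, abs=0.01)

    def test_gap_voxel_count_matches_membership_oracle_and_analytic_volume(self):
        gap = GapSpec(30.0, 120.0, 0, 4, 5.0)
        spec = make_spec(shape=(4, 96, 96), gaps=[gap])
        _, truth = generate_phantom(spec)
        oracle = brute_force_gap_count(spec, gap)
        assert int(truth.gap_mask.sum()) == oracle
        r_i = spec.interface_radius_um
        t = gap.thickness_um
        analytic_um3 = (
            math.pi
            * ((r_i + t / 2) ** 2 - (r_i - t / 2) ** 2)
            * (gap.angle_extent / 360.0)
            * (gap.z_end - gap.z_start)
            * spec.voxel_um
        )
        got_um3 = truth.gap_mask.sum() * spec.voxel_um**3
        assert got_um3 == pytest.approx(analytic_um3, rel=0.05)

    def test_voxelized_volume_converges_to_analytic_with_resolution(self):
        radii = (10.0, 15.0, 20.0, 25.0, 35.0)
        gap = GapSpec(10.0, 90.0, 0, 2, 6.0)
        errs = []
        for npx, vx in [(64, 1.3), (128, 0.65)]:
            spec = make_spec(shape=(2, npx, npx), voxel_um=vx, radii=radii, gaps=[gap])
            _, truth = generate_phantom(spec)
            analytic = math.pi * (2 * 25.0 * 6.0) * (90 / 360) * 2 * vx
            got = truth.gap_mask.sum() * vx**3
            errs.append(abs(got - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_same_spec_and_seed_is_bit_identical(self):
        spec_kw = dict(noise=True, fringe=0.5, gaps=[GapSpec(0.0, 90.0, 0, 8, 5.0)], seed=7)
        v1, _ = generate_phantom(make_spec(**spec_kw))
        v2, _ = generate_phantom(make_spec(**spec_kw))
        np.testing.assert_array_equal(v1.voxels, v2.voxels)

    def test_noise_free_histogram_one_grey_per_material(self, clean_spec):
        vol, _ = generate_phantom(clean_spec)
        values = np.unique(vol.voxels)
        # air/gap share a grey; post, cement, composite, adhesive, dentin distinct
        assert set(np.round(values, 6)) == {0.05, 0.35, 0.55, 0.7, 0.8, 0.9}

    def test_overlapping_gaps_rejected(self):
        gaps = [GapSpec(0.0, 90.0, 0, 8, 5.0), GapSpec(45.0, 90.0, 4, 8, 5.0)]
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(make_spec(gaps=gaps))

    def test_same_angle_different_z_is_allowed(self):
        gaps = [GapSpec(0.0, 90.0, 0, 4, 5.0), GapSpec(45.0, 90.0, 4, 8, 5.0)]
        _, truth = generate_phantom(make_spec(gaps=gaps))
        assert truth.gap_mask.any()

    def test_subvoxel_gap_thickness_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            generate_phantom(make_spec(gaps=[GapSpec(0.0, 90.0, 0, 8, 0.3)]))

    def test_geometry_must_fit_field_of_view(self):
        with pytest.raises(ValueError, match="fit"):
            PhantomSpec(shape=(4, 32, 32), voxel_um=0.65, gaps=[])  # default radii too big


class TestEdgeFringes:
    def test_zero_strength_is_identity(self, rng):
        vol = rng.random((4, 16, 16))
        np.testing.assert_array_equal(add_edge_fringes(vol, 0.0), vol)

    def test_constant_volume_unchanged(self):
        vol = np.full((4, 16, 16), 0.4)
        out = add_edge_fringes(vol, 2.0)
        np.testing.assert_allclose(out, vol, atol=1e-6)

    def test_step_edge_amplitude_matches_direct_convolution_oracle(self):
        # slab phantom: step edge along x
        vol = np.zeros((8, 16, 32))
        vol[:, :, 16:] = 0.6
        strength, sigma = 0.7, 1.0
        out = add_edge_fringes(vol, strength, sigma)
        # oracle: direct convolution with the discrete LoG kernel (impulse
        # response), minus the kernel's DC response so constants map to zero
        imp = np.zeros((1, 1, 33))
        imp[0, 0, 16] = 1.0
        kernel = gaussian_laplace(imp.astype(np.float32), sigma)[0, 0].astype(float)
        line = vol[0, 0]
        padded = np.pad(line, 16, mode="reflect")
        log_line = np.convolve(padded, kernel[::-1], mode="same")[16:-16]
        expected = line - strength * (log_line - kernel.sum() * line)
        np.testing.assert_allclose(out[4, 8], expected, atol=1e-5)


class TestSectorOccupancy:
    def test_no_gaps_all_zero(self):
        occ = true_sector_occupancy(make_spec(gaps=[]), 18)
        assert occ.shape == (18,)
        assert np.all(occ == 0)

    def test_gap_exactly_filling_sector_zero(self):
        spec = make_spec(gaps=[GapSpec(0.0, 20.0, 0, 8, 5.0)])
        occ = true_sector_occupancy(spec, 18)
        expected = np.zeros(18)
        expected[0] = 1.0
        np.testing.assert_allclose(occ, expected)

    def test_gap_straddling_two_sectors(self):
        # 30-50 deg: half of sector 1 (20-40) and half of sector 2 (40-60)
        spec = make_spec(gaps=[GapSpec(30.0, 20.0, 0, 8, 5.0)])
        occ = true_sector_occupancy(spec, 18)
        expected = np.zeros(18)
        expected[1] = expected[2] = 0.5
        np.testing.assert_allclose(occ, expected)

    def test_wraparound_gap(self):
        spec = make_spec(gaps=[GapSpec(350.0, 20.0, 0, 8, 5.0)])
        occ = true_sector_occupancy(spec, 18)
        assert occ[17] == pytest.approx(0.5)
        assert occ[0] == pytest.approx(0.5)
        assert occ.sum() == pytest.approx(1.0)

    def test_invalid_sector_count_rejected(self):
        with pytest.raises(ValueError):
            true_sector_occupancy(make_spec(), 0)
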