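import numpy as np
import pytest
from scipy.stats import norm

from conftest import make_spec
from gapct.gapseg import (
    GreyRange,
    label_components,
    overlay_qc,
    select_labels,
    suggest_range,
    threshold_range,
)
from gapct.phantom import GapSpec, generate_phantom


def flood_fill_labels(mask, connectivity):
    """Independent stack-based flood-fill labelling oracle."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in np.argwhere(mask):
        start = tuple(start)
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)):
                    if mask[p] and not labels[p]:
                        labels[p] = nxt
                        stack.append(p)
    return labels, nxt


def assert_same_partition(a, b):
    """Label arrays are equal up to a bijection of label ids."""
    assert (a > 0).sum() == (b > 0).sum()
    pairs = set(zip(a[a > 0].ravel(), b[a > 0].ravel()))
    assert len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


class TestThresholdRange:
    def test_full_domain_selects_everything(self, rng):
        vol = rng.random((4, 8, 8))
        assert threshold_range(vol, GreyRange(0.0, 1.0)).all()

    def test_noise_free_phantom_recovers_truth_exactly(self, clean_spec):
        vol, truth = generate_phantom(clean_spec)
        mask = threshold_range(vol, GreyRange(0.049, 0.051))
        # gap grey is shared with surrounding air; restrict to the band
        band = np.broadcast_to(truth.bonded_mask_2d, vol.shape)
        np.testing.assert_array_equal(mask & band, truth.gap_mask)

    def test_three_sigma_range_recall_matches_gaussian_tail(self):
        # P(|noise| <= 3 sigma) = 2*Phi(3) - 1 ~ 0.9973, so recall >= 0.99
        sigma = 0.02
        spec = make_spec(noise=True, gaps=[GapSpec(0.0, 180.0, 0, 8, 5.0)], seed=3)
        vol, truth = generate_phantom(spec)
        mask = threshold_range(vol, GreyRange(0.05 - 3 * sigma, 0.05 + 3 * sigma))
        recall = (mask & truth.gap_mask).sum() / truth.gap_mask.sum()
        assert recall >= 0.99
        assert recall >= 2 * norm.cdf(3) - 1 - 0.01

    def test_out_of_domain_range_warns_and_gives_empty_mask(self, rng):
        vol = rng.random((2, 4, 4))
        with pytest.warns(UserWarning, match="outside"):
            mask = threshold_range(vol, GreyRange(5.0, 6.0))
        assert not mask.any()

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            GreyRange(0.5, 0.1)


class TestSuggestRange:
    def test_two_material_valley_strictly_between_modes(self):
        vol = np.full((4, 32, 32), 0.1)
        vol[:, 16:, :] = 0.6
        r = suggest_range(vol)
        assert 0.1 < r.hi < 0.6
        assert r.lo == 0.1

    def test_gaussian_mixture_valley_near_analytic_minimum(self, rng):
        # equal-weight N(0.2, 0.05) + N(0.8, 0.05): density minimum at 0.5
        samples = np.concatenate(
            [rng.normal(0.2, 0.05, 40000), rng.normal(0.8, 0.05, 40000)]
        ).reshape(20, 40, 100)
        r = suggest_range(samples)
        assert abs(r.hi - 0.5) <= 0.05

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant|manual"):
            suggest_range(np.full((2, 4, 4), 0.3))


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        lm = label_components(mask, 26)
        assert lm.n_labels == 2
        assert list(lm.counts[1:]) == [27, 27]

    def test_corner_touch_connectivity_semantics(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        assert label_components(mask, 26).n_labels == 1
        assert label_components(mask, 6).n_labels == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        mask = rng.random((16, 16, 16)) < 0.2
        lm = label_components(mask, connectivity)
        oracle, n = flood_fill_labels(mask, connectivity)
        assert lm.n_labels == n
        assert_same_partition(lm.labels, oracle)
        # raster-scan numbering: first voxels of labels appear in id order
        firsts = [np.flatnonzero(lm.labels.ravel() == k)[0] for k in range(1, n + 1)]
        assert firsts == sorted(firsts)

    def test_counts_sum_to_mask_size(self, rng):
        mask = rng.random((12, 12, 12)) < 0.3
        lm = label_components(mask)
        assert lm.counts[1:].sum() == mask.sum()

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_components(np.arange(8).reshape(2, 2, 2))


class TestSelectLabels:
    def test_keep_all_is_identity(self, rng):
        mask = rng.random((8, 8, 8)) < 0.2
        lm = label_components(mask)
        out = select_labels(lm, keep=list(range(1, lm.n_labels + 1)))
        np.testing.assert_array_equal(out, mask)

    def test_seed_retains_only_its_component(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:3, 1:3, 1:3] = True
        mask[5:7, 5:7, 5:7] = True
        lm = label_components(mask)
        out = select_labels(lm, seeds=[(1, 1, 1)])
        assert out[1, 1, 1] and not out[5, 5, 5]
        assert out.sum() == 8

    def test_centroid_annulus_keeps_interface_gap_drops_pore(self):
        # phantom with a 60 deg interface gap (centroid radius ~19.1 µm, inside
        # the 17.5-22.5 µm band) plus a spurious dark pore in the composite at
        # ~14 µm and the surrounding air (centroid radius ~0): only the gap stays
        spec = make_spec(gaps=[GapSpec(0.0, 60.0, 0, 8, 5.0)])
        vol, truth = generate_phantom(spec)
        arr = vol.voxels.copy()
        arr[3:5, 69:71, 47:49] = 0.05  # pore ~21.5 px = 14 µm from the (48, 48) axis
        mask = threshold_range(arr, GreyRange(0.0, 0.2))
        lm = label_components(mask, 26)
        # oracle: per-label centroid radii verify the expected classification
        from scipy import ndimage

        cents = ndimage.center_of_mass(mask, lm.labels, range(1, lm.n_labels + 1))
        radii = sorted(
            np.hypot(c[1] - 48.0, c[2] - 48.0) * spec.voxel_um for c in cents
        )
        lo, hi = truth.band_bounds_um
        assert sum(lo <= r <= hi for r in radii) == 1
        out = select_labels(
            lm,
            annulus_um=truth.band_bounds_um,
            center=spec.center,
            voxel_um=spec.voxel_um,
            predicate="centroid",
        )
        np.testing.assert_array_equal(out, truth.gap_mask)

    def test_overlap_predicate_keeps_extended_arc(self):
        # a 300 deg arc's centroid sits near the axis; the overlap predicate
        # must still keep it while dropping the surrounding air
        spec = make_spec(gaps=[GapSpec(0.0, 300.0, 0, 8, 5.0)])
        vol, truth = generate_phantom(spec)
        mask = threshold_range(vol, GreyRange(0.0, 0.2))
        lm = label_components(mask, 26)
        out = select_labels(
            lm,
            annulus_um=truth.band_bounds_um,
            center=spec.center,
            voxel_um=spec.voxel_um,
            predicate="overlap",
        )
        np.testing.assert_array_equal(out, truth.gap_mask)

    def test_unknown_label_id_rejected(self):
        lm = label_components(np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError, match="unknown"):
            select_labels(lm, keep=[5])

    def test_seed_on_background_rejected(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        lm = label_components(mask)
        with pytest.raises(ValueError, match="background"):
            select_labels(lm, seeds=[(2, 2, 2)])


class TestOverlayQC:
    def test_empty_mask_gives_pure_greyscale(self, rng):
        vol = rng.random((2, 8, 8))
        rgb = overlay_qc(vol, np.zeros(vol.shape, bool))
        assert rgb.shape == (2, 8, 8, 3)
        assert (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all()

    def test_tinted_pixels_are_exactly_the_mask(self, rng):
        vol = rng.random((2, 8, 8))
        mask = rng.random(vol.shape) < 0.3
        rgb = overlay_qc(vol, mask)
        tinted = rgb[..., 0].astype(int) > rgb[..., 1].astype(int)
        np.testing.assert_array_equal(tinted, mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            overlay_qc(np.zeros((2, 4, 4)), np.zeros((2, 4, 5), bool))
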