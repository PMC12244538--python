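"""Feature bank: LDP/LFP texture, shape and color descriptors, registry."""

import itertools

import numpy as np
import pytest

from mitodet.features import (
    KIRSCH_MASKS, FeatureRegistry, RegistryMismatchError, color_features,
    default_feature_registry, extract_feature_vector, ldp_histogram,
    lfp_histogram, shape_descriptors,
)
from mitodet.tile import HistologyTile

SHAPE_NAMES = [
    f"{p}_{s}"
    for p in ("area", "perimeter", "eccentricity", "circularity", "solidity")
    for s in ("mean", "sd", "min", "max", "median", "iqr", "skew", "sum")
]


def brute_force_ldp(img: np.ndarray, k: int = 3) -> np.ndarray:
    """Independent per-patch oracle: evaluate all 8 masks by hand."""
    combos = {c: i for i, c in enumerate(itertools.combinations(range(8), k))}
    h, w = img.shape
    hist = np.zeros(len(combos))
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            patch = img[r - 1:r + 2, c - 1:c + 2]
            resp = [float((patch * m).sum()) for m in KIRSCH_MASKS]
            order = sorted(range(8), key=lambda i: (-abs(resp[i]), i))
            hist[combos[tuple(sorted(order[:k]))]] += 1
    return hist / hist.sum()


class TestLDP:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            img = rng.integers(0, 256, size=(9, 9)).astype(float)
            assert np.array_equal(ldp_histogram(img), brute_force_ldp(img))

    def test_vertical_edge_patch_code(self):
        patch = np.zeros((3, 3))
        patch[:, 2] = 100.0
        assert np.array_equal(ldp_histogram(patch), brute_force_ldp(patch))

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, size=(31, 17))
        assert ldp_histogram(img).sum() == pytest.approx(1.0)

    def test_constant_image_single_bin_via_tie_break(self):
        hist = ldp_histogram(np.full((12, 12), 9.0))
        # all responses tie at 0 -> lowest mask indices {0,1,2} -> bin 0
        assert hist[0] == 1.0

    def test_k_controls_bin_count(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        assert ldp_histogram(img, k=2).size == 28
        assert ldp_histogram(img, k=4).size == 70

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            ldp_histogram(np.zeros((2, 5)))


class TestLFP:
    def test_constant_image_all_zero_rates(self):
        assert np.all(lfp_histogram(np.full((64, 64), 0.37)) == 0.0)

    def test_rates_within_unit_interval(self):
        rng = np.random.default_rng(2)
        v = lfp_histogram(rng.uniform(size=(48, 48)))
        assert v.size == 30
        assert np.all((v >= 0) & (v <= 1))

    def test_sinusoid_energizes_matching_band(self):
        # a horizontal sinusoid at a band's center frequency must make some
        # slot of that band the maximal slot
        freqs = np.geomspace(0.08, 0.4, 5)
        x = np.arange(64)
        for band in (1, 3):
            img = 0.5 + 0.4 * np.sin(2 * np.pi * freqs[band] * x)
            img = np.tile(img, (64, 1))
            v = lfp_histogram(img)
            best_band, best_orient = divmod(int(np.argmax(v)), 6)
            assert best_band == band
            assert best_orient == 0  # constant along rows -> theta = 0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="8x8"):
            lfp_histogram(np.zeros((4, 4)))


class TestShape:
    def test_matches_pixel_counting_oracle_on_random_masks(self):
        from skimage import measure

        rng = np.random.default_rng(7)
        for _ in range(50):
            mask = (rng.uniform(size=(24, 24)) < 0.3).astype(np.uint8)
            sd = shape_descriptors(mask)
            labeled = measure.label(mask, connectivity=2)
            assert sd[SHAPE_NAMES.index("area_sum")] == mask.sum()
            assert sd[len(SHAPE_NAMES)] == labeled.max()
            assert sd[len(SHAPE_NAMES) + 1] == pytest.approx(mask.mean())

    def test_disk_limits(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 400).astype(np.uint8)
        sd = shape_descriptors(disk)
        circ = sd[SHAPE_NAMES.index("circularity_mean")]
        sol = sd[SHAPE_NAMES.index("solidity_mean")]
        ecc = sd[SHAPE_NAMES.index("eccentricity_mean")]
        assert 0.85 <= circ <= 1.05
        assert sol >= 0.95  # rasterized convex hull slightly exceeds the disk
        assert ecc <= 0.2

    def test_square_solidity_exactly_one(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[5:30, 8:33] = 1
        sd = shape_descriptors(mask)
        assert sd[SHAPE_NAMES.index("solidity_mean")] == 1.0

    def test_ellipse_eccentricity_matches_analytic(self):
        yy, xx = np.mgrid[0:120, 0:120]
        ell = (((yy - 60) / 40.0) ** 2 + ((xx - 60) / 20.0) ** 2 <= 1)
        sd = shape_descriptors(ell.astype(np.uint8))
        expected = np.sqrt(1 - (20.0 / 40.0) ** 2)  # 0.866
        assert abs(sd[SHAPE_NAMES.index("eccentricity_mean")] - expected) < 0.05

    def test_empty_mask_gives_zero_vector(self):
        assert np.all(shape_descriptors(np.zeros((16, 16), np.uint8)) == 0)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            shape_descriptors(np.full((8, 8), 3))


class TestColor:
    def test_gray_image_has_zero_saturation_and_hue_in_bin_zero(self):
        tile = HistologyTile(np.full((16, 16, 3), 77, np.uint8), id="g")
        v = color_features(tile)
        assert v[8] == 0.0 and v[9] == 0.0  # saturation mean/sd
        assert v[12] == 1.0  # all hue mass in bin 0 (undefined-hue rule)

    def test_constant_image_degenerate_statistics(self):
        tile = HistologyTile(np.full((16, 16, 3), 200, np.uint8), id="c")
        v = color_features(tile)
        sd_slots = v[[1, 3, 5, 7, 9, 11]]
        assert np.all(sd_slots < 1e-12)
        assert v[20] == 0.0  # entropy of a single intensity

    def test_half_red_half_blue_hue_histogram(self):
        img = np.zeros((20, 20, 3), np.uint8)
        img[:10, :, 0] = 255
        img[10:, :, 2] = 255
        v = color_features(HistologyTile(img, id="rb"))
        hist = v[12:20]
        assert hist[0] == pytest.approx(0.5)   # red at hue 0
        assert hist[5] == pytest.approx(0.5)   # blue at hue 240/360 -> bin 5
        assert hist.sum() == pytest.approx(1.0)


class TestRegistryAndExtraction:
    def test_default_registry_layout(self):
        reg = default_feature_registry()
        assert len(reg) == 150
        counts = reg.category_counts()
        assert counts == {"texture": 86, "shape": 42, "color": 22}
        # shares inside the reported bands
        assert 0.50 <= counts["texture"] / 150 <= 0.60
        assert 0.25 <= counts["shape"] / 150 <= 0.30
        assert 0.10 <= counts["color"] / 150 <= 0.15

    def test_duplicate_slot_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureRegistry(slots=[("a", "texture"), ("a", "color")])

    def test_extraction_is_150_long_finite_and_deterministic(self, small_tile):
        reg = default_feature_registry()
        fv1 = extract_feature_vector(small_tile, reg)
        fv2 = extract_feature_vector(small_tile, reg)
        assert fv1.values.shape == (150,)
        assert np.all(np.isfinite(fv1.values))
        assert np.array_equal(fv1.values, fv2.values)

    def test_histogram_slots_normalized(self, small_tile):
        fv = extract_feature_vector(small_tile)
        assert fv.values[:56].sum() == pytest.approx(1.0)     # LDP
        assert fv.values[140:148].sum() == pytest.approx(1.0)  # hue histogram

    def test_mismatched_registry_rejected(self, small_tile):
        bad = FeatureRegistry(slots=[("x", "texture"), ("y", "color")])
        with pytest.raises(RegistryMismatchError):
            extract_feature_vector(small_tile, bad)

    def test_maskless_tile_uses_otsu_foreground(self, small_tile):
        bare = HistologyTile(small_tile.pixels.copy(), id="nomask")
        fv = extract_feature_vector(bare)
        # foreground fraction slot must be positive: nuclei were found
        assert fv.values[96 + len(SHAPE_NAMES) - 56 + 1] >= 0  # sanity
        assert np.all(np.isfinite(fv.values))

    def test_feature_table_round_trip(self, small_tile, tmp_path):
        from mitodet.features import read_feature_table, write_feature_table

        reg = default_feature_registry()
        fv = extract_feature_vector(small_tile, reg, label=1)
        path = tmp_path / "features.csv"
        write_feature_table(path, [fv, fv])
        ids, X, y, names = read_feature_table(path)
        assert X.shape == (2, 150)
        assert list(y) == [1, 1]
        assert names == reg.names
        np.testing.assert_allclose(X[0], fv.values, rtol=1e-12)
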