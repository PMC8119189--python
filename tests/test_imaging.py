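"""Image/mask I/O, connected-component labeling and size filtering."""

import numpy as np
import pytest
import tifffile
import imageio.v3 as iio

from podoseg.imaging import (MaskPair, MultiChannelImage, SegSample,
                             equivalent_diameter_um, filter_small_objects,
                             label_objects, read_image, read_mask,
                             split_touching_objects, write_mask)


def brute_force_components(mask, connectivity):
    """Flood-fill labeling oracle."""
    mask = mask > 0
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    k = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        k += 1
        stack = [start]
        labels[start] = k
        while stack:
            y, x = stack.pop()
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if 0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1] \
                        and mask[ny, nx] and not labels[ny, nx]:
                    labels[ny, nx] = k
                    stack.append((ny, nx))
    return k


class TestImageIO:
    def test_8bit_png_rescaled_to_unit_interval(self, tmp_path):
        arr = np.zeros((64, 64, 3), dtype=np.uint8)
        arr[10, 10] = 255
        path = tmp_path / "img.png"
        iio.imwrite(path, arr)
        img = read_image(path, pixel_size_um=0.5)
        assert img.pixels.max() == pytest.approx(1.0)
        assert img.pixels.min() == 0.0
        assert img.pixel_size_um == 0.5

    def test_16bit_tiff_max_value_maps_to_one(self, tmp_path):
        arr = np.zeros((32, 32, 3), dtype=np.uint16)
        arr[0, 0, 2] = 65535
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, arr)
        img = read_image(path)
        assert img.pixels[0, 0, 2] == pytest.approx(1.0)

    def test_channel_map_permutes_roles(self, tmp_path):
        arr = np.zeros((32, 32, 3), dtype=np.uint8)
        arr[:, :, 2] = 200
        path = tmp_path / "img.png"
        iio.imwrite(path, arr)
        img = read_image(path, channel_map={"dna": 2, "wt1": 1, "dach1": 0})
        assert img.channel("dna").max() == pytest.approx(200 / 255)
        assert img.channel("dach1").max() == 0.0

    def test_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "absent.png")
        arr = np.zeros((32, 32), dtype=np.uint8)
        path = tmp_path / "gray.png"
        iio.imwrite(path, arr)
        with pytest.raises(ValueError, match="channels"):
            read_image(path)
        with pytest.raises(ValueError, match="roles"):
            iio.imwrite(tmp_path / "c.png", np.zeros((32, 32, 3), np.uint8))
            read_image(tmp_path / "c.png", channel_map={"dna": 0, "bad": 1,
                                                        "dach1": 2})


class TestMaskIO:
    def test_roundtrip_identity(self, tmp_path, rng):
        mask = (rng.random((64, 64)) > 0.5).astype(np.uint8)
        path = tmp_path / "m.png"
        write_mask(mask, path)
        assert np.array_equal(read_mask(path), mask)

    def test_nonzero_becomes_one(self, tmp_path):
        arr = np.array([[0, 128], [255, 0]], dtype=np.uint8)
        path = tmp_path / "m.png"
        iio.imwrite(path, arr)
        assert np.array_equal(read_mask(path), [[0, 1], [1, 0]])

    def test_multichannel_mask_rejected(self, tmp_path):
        path = tmp_path / "m.png"
        iio.imwrite(path, np.zeros((16, 16, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="single-channel"):
            read_mask(path)


class TestDomainTypes:
    def test_image_invariants(self):
        with pytest.raises(ValueError):
            MultiChannelImage(np.full((64, 64, 3), 1.5))
        with pytest.raises(ValueError):
            MultiChannelImage(np.zeros((16, 16, 3)))
        with pytest.raises(ValueError):
            MultiChannelImage(np.zeros((64, 64, 3)), pixel_size_um=-1)

    def test_mask_pair_invariants(self):
        with pytest.raises(ValueError):
            MaskPair(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            MaskPair(np.full((4, 4), 2), np.zeros((4, 4)))

    def test_sample_requires_ids(self):
        img = MultiChannelImage(np.zeros((64, 64, 3)))
        masks = MaskPair(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.raises(ValueError):
            SegSample(img, masks, "", "g1")


class TestLabeling:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20))
        mask[2:5, 2:5] = 1
        mask[10:13, 10:13] = 1
        objs = label_objects(mask, pixel_size_um=2.0)
        assert objs.n_objects == 2
        assert np.allclose(sorted(objs.areas_um2), [36.0, 36.0])

    def test_diagonal_touch_connectivity(self):
        mask = np.zeros((10, 10))
        mask[2:4, 2:4] = 1
        mask[4:6, 4:6] = 1          # touches only at the corner
        assert label_objects(mask, connectivity=8).n_objects == 1
        assert label_objects(mask, connectivity=4).n_objects == 2

    def test_empty_mask(self):
        objs = label_objects(np.zeros((8, 8)))
        assert objs.n_objects == 0
        assert objs.areas_um2.shape == (0,)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_on_random_masks(self, connectivity, rng):
        for _ in range(200):
            mask = rng.random((32, 32)) > 0.7
            got = label_objects(mask, connectivity=connectivity).n_objects
            assert got == brute_force_components(mask, connectivity)

    def test_centroids_in_pixel_coordinates(self):
        mask = np.zeros((10, 10))
        mask[4:7, 2:5] = 1
        objs = label_objects(mask)
        assert np.allclose(objs.centroids_px[0], (5.0, 3.0))


class TestSizeFilter:
    def _objects(self, diameters_um, pixel_size=1.0):
        """Disjoint disks with the given equivalent diameters."""
        mask = np.zeros((200, 200))
        x = 20
        for d in diameters_um:
            r = d / 2.0 / pixel_size
            yy, xx = np.mgrid[:200, :200]
            mask[(yy - 30) ** 2 + (xx - x) ** 2 <= r * r] = 1
            x += 60
        return label_objects(mask, pixel_size)

    def test_zero_threshold_keeps_everything(self):
        objs = self._objects([4, 8])
        out = filter_small_objects(objs, 0.0)
        assert np.array_equal(out, objs.mask())

    def test_single_small_circle_removed(self):
        objs = self._objects([2.0])
        assert filter_small_objects(objs, 3.0).sum() == 0

    def test_mixed_diameters_survivor_count(self):
        objs = self._objects([2, 5, 10])
        out = filter_small_objects(objs, 3.0)
        assert label_objects(out).n_objects == 2

    def test_area_units_switch(self):
        objs = self._objects([10.0])
        area = objs.areas_um2[0]
        assert filter_small_objects(objs, area + 1, "um2_area").sum() == 0
        assert filter_small_objects(objs, area - 1, "um2_area").sum() > 0

    def test_idempotent_and_monotone(self, rng):
        mask = rng.random((64, 64)) > 0.8
        objs = label_objects(mask)
        for thr in (1.0, 2.0, 4.0):
            once = filter_small_objects(objs, thr)
            twice = filter_small_objects(label_objects(once), thr)
            assert np.array_equal(once, twice)
        small = filter_small_objects(objs, 1.0)
        large = filter_small_objects(objs, 4.0)
        assert np.all(small >= large)          # larger threshold -> subset

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_small_objects(self._objects([5]), -1.0)


def test_watershed_splits_touching_disks():
    mask = np.zeros((40, 60))
    yy, xx = np.mgrid[:40, :60]
    mask[(yy - 20) ** 2 + (xx - 22) ** 2 <= 64] = 1
    mask[(yy - 20) ** 2 + (xx - 37) ** 2 <= 64] = 1   # overlapping pair
    assert label_objects(mask).n_objects == 1
    assert split_touching_objects(mask, min_distance_um=5).n_objects == 2


def test_equivalent_diameter():
    assert equivalent_diameter_um(np.pi * 25) == pytest.approx(10.0)
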