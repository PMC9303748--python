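import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from myoculture import filter_segments, isodata_threshold, segment_nuclei, watershed_nuclei
from myoculture.errors import ParameterError


def intermeans_oracle(values: np.ndarray) -> int:
    """Independent direct iteration of the intermeans recurrence on raw
    pixel values (no histogram cumsums)."""
    values = values.astype(float).ravel()
    t = int(values.mean())
    for _ in range(500):
        lo = values[values <= t]
        hi = values[values > t]
        if len(lo) == 0 or len(hi) == 0:
            break
        t_new = int((lo.mean() + hi.mean()) / 2)
        if t_new == t:
            break
        t = t_new
    return t


class TestIsodataThreshold:
    def test_two_spike_histogram(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[:10] = 200
        out = isodata_threshold(img)
        assert out.threshold_value == intermeans_oracle(img) == 100
        assert np.array_equal(out.mask, img == 200)

    def test_constant_image_gives_empty_mask(self):
        img = np.full((16, 16), 7, dtype=np.uint8)
        out = isodata_threshold(img)
        assert out.threshold_value == 7
        assert not out.mask.any()

    def test_mask_definition(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = isodata_threshold(img)
        assert np.array_equal(out.mask, img > out.threshold_value)

    def test_background_padding_invariance(self):
        rng = np.random.default_rng(0)
        img = np.full((40, 40), 10, dtype=np.uint8)
        rr, cc = draw_disk((20, 20), 8)
        img[rr, cc] = 180
        padded = np.pad(img, 15, constant_values=10)
        t_img = isodata_threshold(img).threshold_value
        t_pad = isodata_threshold(padded).threshold_value
        assert t_pad == intermeans_oracle(padded)
        inner = isodata_threshold(padded).mask[15:-15, 15:-15]
        assert np.array_equal(inner, isodata_threshold(img).mask)

    def test_matches_oracle_on_random_bimodal_images(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            img = np.where(
                rng.random((50, 50)) < 0.3,
                rng.integers(150, 220, (50, 50)),
                rng.integers(0, 40, (50, 50)),
            ).astype(np.uint8)
            assert isodata_threshold(img).threshold_value == intermeans_oracle(img)

    def test_min_contrast_suppresses_noise_only_images(self):
        rng = np.random.default_rng(3)
        img = np.clip(rng.normal(30, 3, (64, 64)), 0, 255).astype(np.uint8)
        assert not isodata_threshold(img, min_contrast=16).mask.any()

    def test_empty_image_rejected(self):
        with pytest.raises(ParameterError):
            isodata_threshold(np.empty((0, 0), dtype=np.uint8))


def count_distance_maxima(mask: np.ndarray, min_sep: int) -> int:
    """Brute-force count of distance-transform local maxima at least
    ``min_sep`` apart (greedy suppression by decreasing height)."""
    dist = ndi.gaussian_filter(ndi.distance_transform_edt(mask), 1.0)
    cand = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            window = dist[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
            if dist[r, c] == window.max():
                cand.append((dist[r, c], r, c))
    cand.sort(reverse=True)
    kept = []
    for h, r, c in cand:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep**2 for _, kr, kc in kept):
            kept.append((h, r, c))
    return len(kept)


class TestWatershed:
    def test_single_disk_one_label(self):
        mask = np.zeros((30, 30), dtype=bool)
        rr, cc = draw_disk((15, 15), 5)
        mask[rr, cc] = True
        labels = watershed_nuclei(mask)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, mask)

    def test_two_overlapping_disks_split(self):
        mask = np.zeros((40, 40), dtype=bool)
        for center in ((20, 16), (20, 24)):
            rr, cc = draw_disk(center, 5)
            mask[rr, cc] = True
        labels = watershed_nuclei(mask)
        assert labels.max() == count_distance_maxima(mask, 5) == 2

    def test_empty_mask(self):
        labels = watershed_nuclei(np.zeros((10, 10), dtype=bool))
        assert labels.max() == 0

    def test_labels_cover_exactly_foreground(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((80, 80), dtype=bool)
        for _ in range(12):
            rr, cc = draw_disk(rng.integers(8, 72, 2), rng.integers(3, 6), shape=mask.shape)
            mask[rr, cc] = True
        labels = watershed_nuclei(mask)
        assert np.array_equal(labels > 0, mask)

    def test_separated_blobs_match_component_count(self):
        # equivalence oracle: well-separated convex blobs
        mask = np.zeros((100, 100), dtype=bool)
        centers = [(15, 15), (15, 80), (50, 50), (85, 20), (80, 80)]
        for center in centers:
            rr, cc = draw_disk(center, 5)
            mask[rr, cc] = True
        _, n_cc = ndi.label(mask, structure=np.ones((3, 3)))
        assert watershed_nuclei(mask).max() == n_cc == len(centers)


class TestFilterSegments:
    def _label_image_with_areas(self, areas, start_row=5):
        img = np.zeros((300, 60), dtype=np.int32)
        row = start_row
        for i, area in enumerate(areas, start=1):
            # horizontal bars of exact area (width 5)
            length, rem = divmod(area, 5)
            img[row : row + 5, 5 : 5 + length] = i
            if rem:
                img[row, 5 + length : 5 + length + rem] = i
            row += 10
        return img

    def test_inclusive_size_window(self):
        img = self._label_image_with_areas([10, 15, 230, 231])
        kept = filter_segments(img)
        assert sorted(s.area_px for s in kept) == [15, 230]

    def test_border_segment_dropped(self):
        img = np.zeros((50, 50), dtype=np.int32)
        img[0:10, 10:20] = 1  # 100 px touching row 0
        assert filter_segments(img) == []
        kept = filter_segments(img, exclude_border=False)
        assert len(kept) == 1 and kept[0].touches_border

    def test_empty_label_image(self):
        assert filter_segments(np.zeros((20, 20), dtype=np.int32)) == []

    def test_bad_bounds(self):
        with pytest.raises(ParameterError):
            filter_segments(np.zeros((5, 5), dtype=np.int32), min_area=20, max_area=10)

    def test_retained_disjoint_subsets_of_mask(self, clean_field):
        stack, _ = clean_field
        mask = isodata_threshold(stack["dapi"]).mask
        segments, _ = segment_nuclei(stack["dapi"])
        seen = np.zeros(mask.shape, dtype=bool)
        for seg in segments:
            assert not seen[seg.coords[:, 0], seg.coords[:, 1]].any()
            seen[seg.coords[:, 0], seg.coords[:, 1]] = True
            assert mask[seg.coords[:, 0], seg.coords[:, 1]].all()

    def test_counting_deterministic(self, clean_field):
        stack, _ = clean_field
        a, _ = segment_nuclei(stack["dapi"])
        b, _ = segment_nuclei(stack["dapi"])
        assert [s.label for s in a] == [s.label for s in b]
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))
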