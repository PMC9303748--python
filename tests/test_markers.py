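import dataclasses

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from myoculture import (
    SceneParams,
    assign_markers,
    detect_marker_segments,
    detect_myotubes,
    generate_field,
    quantify_field,
)
from myoculture.errors import ConfigError, DataError
from myoculture.segmentation import NucleusSegment


def _segment_from_disk(label, center, radius, shape=(100, 100)):
    rr, cc = draw_disk(center, radius, shape=shape)
    coords = np.stack([rr, cc], axis=1)
    return NucleusSegment(
        label=label,
        coords=coords,
        area_px=len(rr),
        centroid=(float(rr.mean()), float(cc.mean())),
        touches_border=False,
    )


def _channel_with_blobs(blobs, shape=(100, 100), bg=0, fg=200):
    img = np.full(shape, bg, dtype=np.uint8)
    for center, radius in blobs:
        rr, cc = draw_disk(center, radius, shape=shape)
        img[rr, cc] = fg
    return img


def _bar_channel(area, shape=(100, 100)):
    img = np.zeros(shape, dtype=np.uint8)
    length, rem = divmod(area, 5)
    img[20:25, 10 : 10 + length] = 200
    if rem:
        img[20, 10 + length : 10 + length + rem] = 200
    return img


class TestDetectMarkerSegments:
    def test_blank_channel(self):
        labels = detect_marker_segments(np.zeros((50, 50), dtype=np.uint8))
        assert labels.max() == 0

    def test_single_blob(self):
        labels = detect_marker_segments(_bar_channel(100))
        assert labels.max() == 1

    @pytest.mark.parametrize("area", [14, 231])
    def test_out_of_window_blobs_dropped(self, area):
        labels = detect_marker_segments(_bar_channel(area))
        assert (labels > 0).sum() == 0

    def test_border_segments_retained(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        img[0:5, 10:20] = 200  # 50 px touching row 0
        labels = detect_marker_segments(img)
        assert labels.max() == 1


class TestAssignMarkers:
    def test_contained_segment_marks_nucleus(self):
        nucleus = _segment_from_disk(1, (50, 50), 8)
        green = detect_marker_segments(_channel_with_blobs([((50, 50), 4)]))
        phen = assign_markers([nucleus], green, None)
        assert phen[0].green_positive and not phen[0].red_positive

    def test_no_segments_all_negative(self):
        nucleus = _segment_from_disk(1, (50, 50), 8)
        phen = assign_markers([nucleus], None, None)
        assert not phen[0].green_positive and not phen[0].double_positive

    def test_double_positive_requires_both(self):
        nucleus = _segment_from_disk(1, (50, 50), 8)
        seg = detect_marker_segments(_channel_with_blobs([((52, 52), 4)]))
        phen = assign_markers([nucleus], seg, seg)
        assert phen[0].green_positive and phen[0].red_positive and phen[0].double_positive

    def test_intersection_vs_containment(self):
        nucleus = _segment_from_disk(1, (50, 50), 6)
        # marker blob straddling the nucleus boundary
        straddling = detect_marker_segments(_channel_with_blobs([((50, 57), 4)]))
        inter = assign_markers([nucleus], straddling, None, rule="intersection")
        contain = assign_markers([nucleus], straddling, None, rule="containment")
        assert inter[0].green_positive
        assert not contain[0].green_positive

    def test_duplicate_labels_rejected(self):
        a = _segment_from_disk(1, (30, 30), 5)
        b = _segment_from_disk(1, (70, 70), 5)
        with pytest.raises(DataError):
            assign_markers([a, b], None, None)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ConfigError):
            assign_markers([], None, None, rule="overlap50")


class TestDetectMyotubes:
    def _myhc_bar(self, shape=(100, 100)):
        img = np.zeros(shape, dtype=np.uint8)
        img[40:55, 10:90] = 180  # 1200 px elongated component
        return img

    def test_component_with_three_centroids(self):
        nuclei = [_segment_from_disk(i, (47, 20 + 25 * i), 5) for i in range(3)]
        tubes = detect_myotubes(self._myhc_bar(), nuclei)
        assert len(tubes) == 1
        assert len(tubes[0].member_nuclei) == 3

    def test_single_centroid_is_not_a_myotube(self):
        nuclei = [_segment_from_disk(1, (47, 50), 5)]
        assert detect_myotubes(self._myhc_bar(), nuclei) == []

    def test_blank_channel(self):
        nuclei = [_segment_from_disk(1, (47, 50), 5)]
        assert detect_myotubes(np.zeros((100, 100), dtype=np.uint8), nuclei) == []

    def test_small_components_suppressed(self):
        img = _channel_with_blobs([((50, 50), 7)])  # ~150 px < min area
        nuclei = [_segment_from_disk(i, (50, 45 + 10 * i), 4) for i in range(2)]
        assert detect_myotubes(img, nuclei, min_myotube_area=300) == []


class TestQuantifyField:
    def test_matches_ground_truth_on_clean_field(self, clean_field):
        stack, truth = clean_field
        q = quantify_field(stack, mode="pax7-myod")
        assert q.n_nuclei == truth.n_nuclei
        assert q.n_green == truth.n_green
        assert q.n_red == truth.n_red
        assert q.n_double == truth.n_double

    def test_empty_field_all_zero(self):
        stack, _ = generate_field(SceneParams(n_nuclei=0, seed=2))
        q = quantify_field(stack, mode="pax7-myod")
        assert (q.n_nuclei, q.n_green, q.n_red, q.n_double) == (0, 0, 0, 0)

    def test_channel_order_invariance(self, clean_field):
        stack, _ = clean_field
        q1 = quantify_field(stack, mode="pax7-myod")
        swapped = dataclasses.replace(
            stack,
            channels={
                "dapi": stack["dapi"],
                "red": stack["red"],
                "green": stack["green"],
            },
        )
        q2 = quantify_field(swapped, mode="pax7-myod")
        assert (q1.n_green, q1.n_red, q1.n_double) == (q2.n_green, q2.n_red, q2.n_double)

    def test_missing_channel_is_config_error(self, clean_field):
        stack, _ = clean_field
        with pytest.raises(ConfigError):
            quantify_field(stack, mode="myhc")  # no myhc channel rendered
        with pytest.raises(ConfigError):
            quantify_field(stack, mode="no-such-mode")

    def test_double_bounded_by_marginals_across_noisy_fields(self):
        for seed in range(4):
            params = SceneParams(
                n_nuclei=90, p_green=0.6, p_red=0.5, p_double=0.3, seed=seed
            )
            stack, _ = generate_field(params)
            q = quantify_field(stack, mode="pax7-myod")
            assert q.n_double <= min(q.n_green, q.n_red)
            assert q.n_nuclei >= 0

    def test_permutation_invariance_of_counts(self, clean_field):
        from myoculture.markers import detect_marker_segments as dms
        from myoculture.segmentation import segment_nuclei

        stack, _ = clean_field
        nuclei, _ = segment_nuclei(stack["dapi"])
        green = dms(stack["green"])
        red = dms(stack["red"])
        phen_fwd = assign_markers(nuclei, green, red)
        phen_rev = assign_markers(list(reversed(nuclei)), green, red)
        count = lambda ps: (
            sum(p.green_positive for p in ps),
            sum(p.red_positive for p in ps),
            sum(p.double_positive for p in ps),
        )
        assert count(phen_fwd) == count(phen_rev)

    def test_fusion_mode_counts_match_truth(self):
        params = SceneParams(n_nuclei=80, n_myotubes=8, noise_sd=0.0, blur_sigma_px=0.0, seed=6)
        stack, truth = generate_field(params)
        q = quantify_field(stack, mode="myhc")
        assert q.n_myotubes == len(truth.myotubes)
        assert q.n_nuclei_in_myotubes == truth.n_in_myotubes
        assert q.n_nuclei_in_myotubes <= q.n_nuclei

    def test_count_correlation_over_density_sweep(self):
        from myoculture.experiments import density_sweep_correlation

        r, _, _ = density_sweep_correlation(seed=77)
        assert r >= 0.9
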