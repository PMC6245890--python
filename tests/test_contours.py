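"""Temporal MIP, polar delineation, overrides and AHA segment maps."""

import numpy as np
import pytest

from fermiperf.contours import (ContourSet, SliceContour, TERRITORIES,
                                build_segment_map, delineate,
                                delineate_series, override_contours,
                                segment_labels_from_radii, temporal_mip)
from fermiperf.data import DynamicSeries
from fermiperf.exceptions import (ConfigError, ContourValidationError,
                                  DelineationError)


class TestTemporalMip:
    def test_definition_on_small_example(self):
        frames = np.array([[[1, 3], [2, 4]],
                           [[5, 0], [3, 9]],
                           [[2, 1], [1, 0]]], dtype=float)
        np.testing.assert_array_equal(temporal_mip(frames),
                                      [[5, 3], [3, 9]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        frames = rng.random((6, 8, 8))
        once = temporal_mip(frames)
        np.testing.assert_array_equal(temporal_mip(once), once)

    def test_monotone_series_gives_last_frame(self):
        t = np.arange(10, dtype=float)
        data = np.tile(t[None, :, None, None], (1, 1, 4, 4)) * \
            np.arange(1, 17, dtype=float).reshape(1, 1, 4, 4)
        series = DynamicSeries(data, t)
        np.testing.assert_array_equal(temporal_mip(series)[0], data[0, -1])


class TestDelineate:
    def test_subpixel_accuracy_on_phantom(self, clean_phantom):
        stress, *_, truth = clean_phantom
        cfg = truth.config
        mips = temporal_mip(stress)
        angles = np.arange(360.0)
        for sl in range(3):
            sc = delineate(mips[sl])
            endo, epi = sc.radius_profiles(angles)
            assert np.abs(endo - cfg.endo_radius).mean() < 1.0
            assert np.abs(epi - cfg.epi_radius).mean() < 1.0
            assert np.allclose(sc.center, truth.center, atol=1.0)

    def test_blank_image_raises(self):
        with pytest.raises(DelineationError):
            delineate(np.zeros((40, 40)))

    def test_translation_equivariance(self, clean_phantom):
        stress, *_, truth = clean_phantom
        mip = temporal_mip(stress)[0]
        base = delineate(mip)
        moved = delineate(np.roll(mip, (7, 7), axis=(0, 1)))
        assert np.allclose(np.asarray(moved.center),
                           np.asarray(base.center) + 7, atol=1.0)
        assert np.allclose(moved.endo.mean(axis=0),
                           base.endo.mean(axis=0) + 7, atol=1.0)


class TestOverride:
    def _circle(self, center, radius, n=90):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.stack([center[0] - radius * np.sin(th),
                         center[1] + radius * np.cos(th)], axis=1)

    def test_no_manual_returns_auto(self, clean_phantom):
        stress, *_ = clean_phantom
        auto = delineate_series(stress)
        assert override_contours(auto, None) is auto

    def test_partial_override_tracks_provenance(self, clean_phantom):
        stress, *_, truth = clean_phantom
        auto = delineate_series(stress)
        manual = SliceContour(self._circle(truth.center, 7.0),
                              self._circle(truth.center, 13.0), truth.center)
        merged = override_contours(auto, {1: manual})
        assert merged.provenance == {0: "auto", 1: "manual", 2: "auto"}
        assert merged[1] is manual and merged[0] is auto[0]

    def test_non_nested_manual_rejected(self, clean_phantom):
        stress, *_, truth = clean_phantom
        auto = delineate_series(stress)
        bad = SliceContour(self._circle(truth.center, 13.0),
                           self._circle(truth.center, 7.0), truth.center)
        with pytest.raises(ContourValidationError):
            override_contours(auto, {0: bad})


class TestSegmentMap:
    def test_sector_pixel_counts_balanced(self, clean_phantom):
        stress, *_ = clean_phantom
        cs = delineate_series(stress)
        segmap = build_segment_map(cs, shape=stress.spatial_shape)
        for first, count in ((1, 6), (7, 6)):
            sizes = [int((segmap.labels == first + i).sum())
                     for i in range(count)]
            assert max(sizes) - min(sizes) <= 0.1 * np.mean(sizes)

    def test_between_contours_no_gaps_no_overlap(self, clean_phantom):
        stress, *_ = clean_phantom
        cs = delineate_series(stress)
        segmap = build_segment_map(cs, shape=stress.spatial_shape)
        from fermiperf.contours import myocardium_mask
        myo = myocardium_mask(cs, stress.spatial_shape)
        np.testing.assert_array_equal(segmap.labels > 0, myo)

    def test_territory_lookup_partitions_segments(self, clean_phantom):
        stress, *_ = clean_phantom
        cs = delineate_series(stress)
        segmap = build_segment_map(cs, shape=stress.spatial_shape)
        seen = sorted(s for segs in TERRITORIES.values() for s in segs)
        assert seen == list(range(1, 17))
        assert set(segmap.territory_of) == set(range(1, 17))

    def test_reference_angle_rotation_permutes_basal_labels(self):
        shape = (40, 40)
        center = (19.5, 19.5)
        base = segment_labels_from_radii(shape, center, 6.0, 12.0, "basal",
                                         reference_angle=90.0)
        rotated = segment_labels_from_radii(shape, center, 6.0, 12.0, "basal",
                                            reference_angle=150.0)
        ring = base > 0
        # rotating the reference by one sector maps label L -> L-1 (mod 6)
        expected = (base[ring] - 1 - 1) % 6 + 1
        assert (rotated[ring] == expected).mean() > 0.98

    def test_missing_role_rejected(self, clean_phantom):
        stress, *_ = clean_phantom
        cs = delineate_series(stress)
        with pytest.raises(ConfigError):
            build_segment_map(cs, slice_roles=("basal", "mid"),
                              shape=stress.spatial_shape)
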