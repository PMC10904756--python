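"""Tissue volumes, geodesic distances, profiles, signal summaries."""

import numpy as np
import pytest

import trunkphenix as tp
from trunkphenix.phantom import LabelVolume
from conftest import oracle_geodesic

SPACING = (0.68, 0.68, 0.60)


def _label_volume(data, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(data=np.asarray(data, dtype=np.uint8), spacing=spacing)


class TestQuantifyTissues:
    def test_white_rot_volume_arithmetic(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data.ravel()[:1000] = tp.CLASS_CODES["white_rot"]
        summary = tp.quantify_tissues(_label_volume(data, SPACING))
        assert summary.table.loc["white_rot", "volume_cm3"] == pytest.approx(0.27744)

    def test_all_intact_region_has_unit_fraction(self):
        data = np.full((4, 4, 4), tp.CLASS_CODES["intact"], dtype=np.uint8)
        summary = tp.quantify_tissues(_label_volume(data))
        assert summary.table.loc["intact", "tissue_fraction"] == 1.0
        assert summary.table.loc["degraded", "tissue_fraction"] == 0.0

    def test_counts_match_loop_oracle(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 5, size=(9, 9, 9)).astype(np.uint8)
        summary = tp.quantify_tissues(_label_volume(data))
        for name, code in tp.CLASS_CODES.items():
            expected = sum(1 for v in data.ravel() if v == code)
            assert summary.count(name) == expected

    def test_no_tissue_region_flagged_undefined(self):
        data = np.full((3, 3, 3), tp.CLASS_CODES["bark"], dtype=np.uint8)
        summary = tp.quantify_tissues(_label_volume(data))
        assert not summary.defined

    def test_region_restriction_never_increases_counts(self, small_record):
        full = tp.quantify_tissues(small_record.labels)
        mask = np.zeros(small_record.labels.shape, bool)
        mask[:, :, :20] = True
        sub = tp.quantify_tissues(small_record.labels, region_mask=mask)
        for name in tp.CLASS_NAMES:
            assert sub.count(name) <= full.count(name)


class TestGeodesicMap:
    def test_straight_tube_distance_is_axial(self):
        mask = np.zeros((5, 5, 30), bool)
        mask[1:4, 1:4, :] = True
        dmap = tp.geodesic_map(mask, (2, 2, 0), (1.0, 1.0, 1.0))
        assert dmap.distance_mm[2, 2, 25] == pytest.approx(25.0)

    def test_l_shaped_tube_matches_dijkstra(self):
        mask = np.zeros((24, 5, 24), bool)
        mask[0:20, 1:4, 0:3] = True      # arm along x
        mask[17:20, 1:4, 0:20] = True    # arm along z
        ref = (0, 2, 1)
        dmap = tp.geodesic_map(mask, ref, (1.0, 1.0, 1.0))
        oracle = oracle_geodesic(mask, ref, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(dmap.distance_mm[mask], oracle[mask], atol=1e-9)
        far = dmap.distance_mm[18, 2, 19]
        assert far > 30  # both arms traversed

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_random_masks_match_dijkstra(self, connectivity):
        rng = np.random.default_rng(31)
        for trial in range(3):
            mask = rng.random((14, 14, 14)) < 0.6
            mask[7, 7, 7] = True
            dmap = tp.geodesic_map(mask, (7, 7, 7), SPACING, connectivity=connectivity)
            oracle = oracle_geodesic(mask, (7, 7, 7), SPACING, connectivity=connectivity)
            np.testing.assert_allclose(dmap.distance_mm[mask], oracle[mask], atol=1e-9)

    def test_out_of_mask_voxel_unreachable(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, :] = True
        dmap = tp.geodesic_map(mask, (0, 0, 0), (1.0, 1.0, 1.0))
        assert not dmap.reachable[3, 3, 3]
        assert np.isinf(dmap.distance_mm[3, 3, 3])

    def test_reference_outside_mask_rejected(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            tp.geodesic_map(mask, (3, 3, 3), (1.0, 1.0, 1.0))

    def test_reference_distance_zero_and_triangle_inequality(self):
        rng = np.random.default_rng(8)
        mask = rng.random((10, 10, 10)) < 0.7
        mask[5, 5, 5] = True
        dmap = tp.geodesic_map(mask, (5, 5, 5), (1.0, 1.0, 1.0))
        assert dmap.distance_mm[5, 5, 5] == 0.0
        d = dmap.distance_mm
        # stepping to any 26-neighbor changes distance by at most the step length
        for (dx, dy, dz) in [(1, 0, 0), (0, 1, 1), (1, 1, 1)]:
            step = np.linalg.norm([dx, dy, dz])
            a = d[1:9, 1:9, 1:9]
            b = d[1 + dx:9 + dx, 1 + dy:9 + dy, 1 + dz:9 + dz]
            ok = np.isfinite(a) & np.isfinite(b)
            assert (np.abs(a[ok] - b[ok]) <= step + 1e-9).all()


@pytest.fixture(scope="module")
def record_map(small_record):
    depth = small_record.spec.resolved_reference_depth()
    dmap = tp.geodesic_map(small_record.labels.wood_mask(),
                           small_record.reference_point,
                           small_record.labels.spacing,
                           reference_depth_mm=depth)
    return small_record, dmap


class TestDistanceProfile:
    def test_uniform_trunk_profile_is_all_intact(self, noiseless_record):
        import dataclasses
        from conftest import SMALL_SPEC
        spec = dataclasses.replace(SMALL_SPEC, lesion_fraction_degraded=0.0,
                                   lesion_fraction_white_rot=0.0)
        record = tp.generate_specimen(spec, seed=2, specimen_id="uniform")
        dmap = tp.geodesic_map(record.labels.wood_mask(), record.reference_point,
                               record.labels.spacing,
                               reference_depth_mm=spec.resolved_reference_depth())
        profile = tp.distance_profile(record.labels, dmap, bin_width_cm=0.5,
                                      position_range_cm=(-2, 0.5))
        fractions = profile.fractions().dropna()
        assert (fractions["intact"] == 1.0).all()

    def test_profile_counts_conserve_in_range_totals(self, record_map):
        record, dmap = record_map
        profile = tp.distance_profile(record.labels, dmap, bin_width_cm=0.5,
                                      position_range_cm=(-2, 1))
        pos = dmap.signed_position_cm()
        in_range = dmap.reachable & (pos >= -2) & (pos < 1) & record.labels.wood_mask()
        assert profile.counts.to_numpy().sum() == in_range.sum()

    def test_lesion_absent_far_below_head(self, record_map):
        record, dmap = record_map
        profile = tp.distance_profile(record.labels, dmap, bin_width_cm=0.25,
                                      position_range_cm=(-1.8, 0.5))
        fractions = profile.fractions()
        # white rot is carved around the lesion center near the head; the
        # lowest bins of the trunk stay lesion-free
        low_bins = fractions.iloc[:2].dropna()
        assert (low_bins["white_rot"] == 0.0).all()

    def test_nonpositive_bin_width_rejected(self, record_map):
        record, dmap = record_map
        with pytest.raises(ValueError):
            tp.distance_profile(record.labels, dmap, bin_width_cm=0.0)


class TestRegionFractions:
    def test_whole_mask_band_reproduces_global_summary(self, small_record):
        depth = small_record.spec.resolved_reference_depth()
        dmap = tp.geodesic_map(small_record.labels.wood_mask(),
                               small_record.reference_point,
                               small_record.labels.spacing, reference_depth_mm=depth)
        band = tp.region_fractions(small_record.labels, dmap, -1e6, 1e6)
        wood_only = tp.quantify_tissues(small_record.labels,
                                        region_mask=small_record.labels.wood_mask())
        for name in tp.TISSUE_CLASSES:
            assert band.count(name) == wood_only.count(name)

    def test_inverted_band_rejected(self, small_record):
        dmap = tp.geodesic_map(small_record.labels.wood_mask(),
                               small_record.reference_point, small_record.labels.spacing)
        with pytest.raises(ValueError):
            tp.region_fractions(small_record.labels, dmap, 2.0, -2.0)


class TestSummarizeSignals:
    def test_noiseless_declines_match_configured_model(self, noiseless_record):
        summary = tp.summarize_signals(noiseless_record.volume, noiseless_record.labels)
        assert summary.change_pct("intact->degraded", "T2w") == pytest.approx(-86.3)
        assert summary.change_pct("intact->degraded", "Xray") == pytest.approx(-19.3)
        assert summary.change_pct("degraded->white_rot", "Xray") == pytest.approx(-56.0)

    def test_single_class_volume_has_undefined_changes(self):
        data = np.full((4, 4, 4), tp.CLASS_CODES["intact"], dtype=np.uint8)
        volume = tp.MultimodalVolume(channels={m: np.ones((4, 4, 4)) for m in tp.MODALITIES},
                                     spacing=(1, 1, 1))
        summary = tp.summarize_signals(volume, _label_volume(data))
        assert summary.relative_change.isna().all().all()

    def test_moments_match_two_pass_oracle(self, small_record):
        summary = tp.summarize_signals(small_record.volume, small_record.labels)
        labels = small_record.labels.data
        for name, code in tp.CLASS_CODES.items():
            sel = labels == code
            if not sel.any():
                continue
            values = small_record.volume.get("PDw")[sel]
            mean = values.sum() / values.size
            var = ((values - mean) ** 2).sum() / values.size
            assert summary.moments.loc[(name, "PDw"), "mean"] == pytest.approx(mean)
            assert summary.moments.loc[(name, "PDw"), "sd"] == pytest.approx(np.sqrt(var))
            assert summary.moments.loc[(name, "PDw"), "n"] == sel.sum()
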