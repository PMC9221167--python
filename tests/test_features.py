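"""Intensity statistics, percentage normalization, viability rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radialcell.features import (
    DegenerateCellError,
    CellFeatures,
    ViabilityCount,
    cell_intensity,
    classify_viability,
    compute_cv,
    extract_cell_features,
    frame_background,
    region_features,
)
from radialcell.frames import ConfigurationError, ImageFrame, LabelMap
from radialcell.radial import RadialMap, partition_regions, radial_ratio
from radialcell.synthetic import (
    SceneParams,
    expected_profile_weights,
    generate_scene,
    render_drug_channel,
    truth_cell_objects,
)



def drug_frame(arr):
    return ImageFrame(np.asarray(arr, dtype=float), channel="drug")


class TestCellIntensity:
    def test_uniform_intensity_cancels_areas(self, disk_cell):
        img = np.zeros(disk_cell.cell_mask.shape)
        img[disk_cell.cell_mask] = 4.5
        Ic, In, I_bar = cell_intensity(drug_frame(img), disk_cell)
        assert I_bar == pytest.approx(4.5)

    def test_direct_substitution(self):
        # Sc=100, Sn=20; Ic=500, In=100 -> I_bar = 400/80 = 5
        cell = np.zeros((20, 20), dtype=bool)
        cell[:10, :10] = True
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[:4, :5] = True
        from radialcell.segmentation import CellObject

        obj = CellObject(1, cell, [nuc])
        img = np.zeros((20, 20))
        img[cell] = 5.0  # 100 px * 5 = 500 total; nucleus 20 px * 5 = 100
        Ic, In, I_bar = cell_intensity(drug_frame(img), obj)
        assert (Ic, In) == (500.0, 100.0)
        assert I_bar == pytest.approx(5.0)

    def test_zero_channel(self, disk_cell):
        img = np.zeros(disk_cell.cell_mask.shape)
        assert cell_intensity(drug_frame(img), disk_cell) == (0.0, 0.0, 0.0)

    def test_degenerate_cell_rejected(self):
        from radialcell.segmentation import CellObject, SegmentationError

        cell = np.zeros((8, 8), dtype=bool)
        cell[2:4, 2:4] = True
        with pytest.raises((DegenerateCellError, SegmentationError)):
            obj = CellObject(1, cell, [cell.copy()])
            cell_intensity(drug_frame(np.zeros((8, 8))), obj)


class TestRegionFeatures:
    def _rmap_with_sums(self, sums):
        """5 bands of 10 px each; band k filled at sums[k]/10 per pixel."""
        region = np.zeros((10, 10), dtype=np.int32)
        img = np.zeros((10, 10))
        for k, s in enumerate(sums, start=1):
            region[k - 1, :] = k
            img[k - 1, :] = s / 10.0
        cyto = region > 0
        ratio = np.full((10, 10), np.nan)
        ratio[cyto] = (region[cyto] - 0.5) / 5
        rmap = RadialMap(cell_id=1, ratio=ratio, cytoplasm_mask=cyto,
                         region=region, n_bands=5)
        return rmap, img

    def test_percentage_arithmetic(self):
        rmap, img = self._rmap_with_sums([10, 20, 30, 40, 0])
        out = region_features(drug_frame(img), rmap)
        assert [rf.Perc_Ri for rf in out] == pytest.approx([10, 20, 30, 40, 0])
        assert math.fsum(rf.Perc_Ri for rf in out) == pytest.approx(100, abs=1e-9)

    def test_uniform_field_percentages_track_area(self, disk_cell):
        rmap = partition_regions(radial_ratio(disk_cell), n_bands=5)
        img = np.zeros(disk_cell.cell_mask.shape)
        img[disk_cell.cell_mask] = 2.0
        out = region_features(drug_frame(img), rmap)
        total_area = sum(rf.S_Ri for rf in out)
        for rf in out:
            assert rf.Ibar_Ri == pytest.approx(2.0)
            assert rf.Perc_Ri == pytest.approx(100 * rf.S_Ri / total_area)

    def test_zero_signal_flagged_as_zero_percentages(self, disk_cell):
        rmap = partition_regions(radial_ratio(disk_cell), n_bands=5)
        out = region_features(drug_frame(np.zeros(disk_cell.cell_mask.shape)), rmap)
        assert all(rf.Perc_Ri == 0 for rf in out)

    def test_empty_band_mean_is_missing_not_zero(self):
        rmap, img = self._rmap_with_sums([10, 20, 30, 40, 0])
        rmap.region[rmap.region == 5] = 4  # empty band 5 entirely
        rmap.cytoplasm_mask = rmap.region > 0
        out = region_features(drug_frame(img), rmap)
        assert out[4].S_Ri == 0 and out[4].Ibar_Ri is None

    def test_decomposition_reconstructs_cytoplasmic_total(self, small_scene):
        _, _, drug, truth = small_scene
        for obj in truth_cell_objects(truth):
            rmap = partition_regions(radial_ratio(obj), n_bands=5)
            feats = extract_cell_features(drug, obj, rmap=rmap)
            assert math.fsum(rf.I_Ri for rf in feats.region_features) == pytest.approx(
                feats.Ic - feats.In, rel=1e-12, abs=1e-9
            )

    def test_scale_equivariance(self, small_scene):
        _, _, drug, truth = small_scene
        obj = truth_cell_objects(truth)[0]
        rmap = partition_regions(radial_ratio(obj), n_bands=5)
        f1 = extract_cell_features(drug, obj, rmap=rmap)
        f2 = extract_cell_features(drug.with_pixels(drug.pixels * 3.0), obj, rmap=rmap)
        assert f2.I_bar == pytest.approx(3 * f1.I_bar)
        assert f2.Ic == pytest.approx(3 * f1.Ic)
        for a, b in zip(f1.region_features, f2.region_features):
            assert b.Perc_Ri == pytest.approx(a.Perc_Ri, rel=1e-12)
            assert b.Ibar_Ri == pytest.approx(3 * a.Ibar_Ri)

    def test_band_masses_match_generator_expectation(self):
        """Noise-free band percentages equal the analytic profile masses
        within 2 points absolute, per band."""
        params = SceneParams(
            image_height_px=256, image_width_px=256, n_cells=6, seed=13,
            profile="peripheral", dead_prob=0.0,
        )
        _, _, truth = generate_scene(params, noise=False)
        drug = render_drug_channel(truth, params)
        for obj in truth_cell_objects(truth):
            rmap = partition_regions(radial_ratio(obj), n_bands=5)
            feats = extract_cell_features(drug, obj, rmap=rmap)
            rec = truth.record(obj.cell_id)
            w = expected_profile_weights(
                truth, obj.cell_id, rec["profile"], rec["sector_angle"]
            )
            total = w[rmap.region > 0].sum()
            for rf in feats.region_features:
                analytic = 100 * w[rmap.region == rf.region_index].sum() / total
                assert abs(rf.Perc_Ri - analytic) < 2.0


    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        sums=st.lists(
            st.floats(0.0, 1e6, allow_nan=False), min_size=5, max_size=5
        ).filter(lambda s: sum(s) > 1e-6)
    )
    def test_percentages_always_sum_to_100(self, sums):
        rmap, img = self._rmap_with_sums(sums)
        out = region_features(drug_frame(img), rmap)
        assert math.fsum(rf.Perc_Ri for rf in out) == pytest.approx(100, abs=1e-9)
        assert all(rf.Perc_Ri >= 0 for rf in out)


class TestViability:
    def _features(self, Ic, In, Sc, Sn):
        return CellFeatures(cell_id=1, Ic=Ic, In=In, Sc=Sc, Sn=Sn,
                            I_bar=(Ic - In) / (Sc - Sn))

    def test_empty_nucleus_is_viable(self):
        assert classify_viability(self._features(100, 0, 50, 10))

    def test_uniform_fill_is_dead(self):
        # nuclear mean == cytoplasmic mean -> rule fires at theta 0.75
        assert not classify_viability(self._features(500, 100, 50, 10))

    def test_floor_suppresses_background_level_calls(self):
        f = self._features(Ic=1.0, In=0.2, Sc=50, Sn=10)  # both means tiny
        assert classify_viability(f, background_floor=0.5)

    def test_no_nucleus_unavailable(self):
        with pytest.raises(ConfigurationError):
            classify_viability(self._features(10, 0, 50, 0))

    def test_filter_accuracy_against_truth(self):
        """>= 95% agreement with generator dead flags on 100 noisy cells."""
        correct = total = 0
        seed = 0
        while total < 100:
            params = SceneParams(
                image_height_px=320, image_width_px=320, n_cells=20,
                seed=400 + seed, dead_prob=0.3,
            )
            _, drug, truth = generate_scene(params)
            floor = 3 * frame_background(drug, truth.cell_labels)
            for obj in truth_cell_objects(truth):
                f = extract_cell_features(drug, obj, background_floor=floor)
                if f.viable is None:
                    continue
                correct += f.viable == (not truth.record(obj.cell_id)["dead"])
                total += 1
            seed += 1
        assert correct / total >= 0.95


class TestViabilityCount:
    @pytest.mark.parametrize("viable,total,expected", [
        (85, 100, 85.0),
        (0, 50, 0.0),
        (788, 1000, 78.8),
    ])
    def test_percentage(self, viable, total, expected):
        assert compute_cv(ViabilityCount(viable, total)) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        with pytest.raises(ConfigurationError):
            compute_cv(ViabilityCount(0, 0))


def test_frame_background_is_outside_median():
    img = np.full((20, 20), 3.0)
    lab = np.zeros((20, 20), dtype=np.int32)
    lab[5:15, 5:15] = 1
    img[lab == 1] = 100.0
    assert frame_background(drug_frame(img), LabelMap(lab)) == 3.0
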