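import numpy as np
import pandas as pd
import pytest

from densefuse.core_io import LabelScheme, LabelVolume, SchemeEntry
from densefuse.reporting import (
    asymmetry_ratios,
    build_report,
    group_labels,
    keep_labels,
    read_report,
    scale_class_table,
    structure_volumes,
    thickness_summary,
    write_report,
)


def _lab(arr, affine=None):
    return LabelVolume(np.asarray(arr, dtype=np.int32), affine if affine is not None else np.eye(4))


class TestGrouping:
    def test_tissue_grouping_conserves_counts(self, small_phantom):
        _, lab, scheme, _ = small_phantom
        grouped = group_labels(lab, scheme, "tissue")
        cwm_ids = scheme.ids_of_tissue("cWM")
        cwm_class = 3  # TISSUE_CLASSES order: CSF, cGM, cWM, ...
        assert (grouped.labels == cwm_class).sum() == np.isin(lab.labels, cwm_ids).sum()
        assert (grouped.labels > 0).sum() == (lab.labels > 0).sum()

    def test_full_phantom_yields_eight_tissues(self, small_phantom):
        _, lab, scheme, _ = small_phantom
        grouped = group_labels(lab, scheme, "tissue")
        assert len(np.unique(grouped.labels[grouped.labels > 0])) == 8

    def test_lobe_grouping_of_cortical_structures(self, small_phantom):
        _, lab, scheme, _ = small_phantom
        lobed = [e.label_id for e in scheme.entries if e.lobe_class]
        lobes = group_labels(keep_labels(lab, lobed), scheme, "lobe")
        names = scale_class_table(scheme, "lobe")
        assert set(np.unique(lobes.labels[lobes.labels > 0])) <= set(names)
        assert (lobes.labels > 0).sum() == np.isin(lab.labels, lobed).sum()

    def test_structure_without_lobe_class_rejected(self, small_phantom):
        _, lab, scheme, _ = small_phantom
        with pytest.raises(ValueError, match="no lobe class"):
            group_labels(lab, scheme, "lobe")  # brainstem etc. have no lobe

    def test_idempotent_at_same_scale(self, small_phantom):
        _, lab, scheme, _ = small_phantom
        g = group_labels(lab, scheme, "tissue")
        tissue_scheme = LabelScheme(
            entries=[
                SchemeEntry(i + 1, t, "none", t)
                for i, t in enumerate(
                    ["CSF", "cGM", "cWM", "sGM", "ceGM", "ceWM", "BS", "WML"]
                )
            ]
        )
        gg = group_labels(g, tissue_scheme, "tissue")
        np.testing.assert_array_equal(gg.labels, g.labels)


class TestVolumes:
    def test_thousand_voxels_at_unit_resolution(self):
        lab = np.zeros((20, 20, 20), dtype=np.int32)
        lab[:10, :10, :10] = 7
        vols = structure_volumes(_lab(lab))
        row = vols[vols.label_id == 7].iloc[0]
        assert row.volume_mm3_template == 1000.0

    def test_native_determinant_scales_volume(self):
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[:5] = 1
        vols = structure_volumes(_lab(lab), native_affine_det=2.0)
        row = vols.iloc[0]
        assert row.volume_mm3_native == 2.0 * row.volume_mm3_template

    def test_voxel_volume_from_affine(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        lab = np.zeros((4, 4, 4), dtype=np.int32)
        lab[0, 0, 0] = 3
        vols = structure_volumes(_lab(lab, affine))
        assert vols.iloc[0].volume_mm3_template == pytest.approx(8.0)

    def test_structures_partition_icc(self, loo_segmentation):
        result, *_ = loo_segmentation
        vols = structure_volumes(result.structures)
        icc_vol = float((result.structures.labels > 0).sum())
        assert vols.volume_mm3_template.sum() == icc_vol


class TestAsymmetry:
    def _scheme(self):
        return LabelScheme(
            entries=[
                SchemeEntry(1, "x_left", "left", "sGM"),
                SchemeEntry(2, "x_right", "right", "sGM"),
            ],
            flip_pairs={(1, 2)},
        )

    def _volumes(self, left, right):
        return pd.DataFrame(
            {
                "label_id": [1, 2],
                "voxels": [int(left), int(right)],
                "volume_mm3_template": [left, right],
                "volume_mm3_native": [left, right],
            }
        )

    def test_equal_volumes_zero(self):
        out = asymmetry_ratios(self._volumes(50.0, 50.0), self._scheme())
        assert out.iloc[0].asymmetry_pct == 0.0

    def test_one_versus_three(self):
        out = asymmetry_ratios(self._volumes(1.0, 3.0), self._scheme())
        assert out.iloc[0].asymmetry_pct == pytest.approx(100.0)

    def test_antisymmetric_under_hemisphere_swap(self):
        fwd = asymmetry_ratios(self._volumes(10.0, 30.0), self._scheme())
        rev = asymmetry_ratios(self._volumes(30.0, 10.0), self._scheme())
        assert fwd.iloc[0].asymmetry_pct == -rev.iloc[0].asymmetry_pct

    def test_missing_member_reported_missing(self):
        vols = pd.DataFrame(
            {
                "label_id": [1],
                "voxels": [10],
                "volume_mm3_template": [10.0],
                "volume_mm3_native": [10.0],
            }
        )
        out = asymmetry_ratios(vols, self._scheme())
        assert np.isnan(out.iloc[0].asymmetry_pct)

    def test_symmetric_noiseless_phantom_nearly_symmetric(self):
        from densefuse.synthdata import PhantomSpec, make_phantom

        img, lab, scheme = make_phantom(
            PhantomSpec(shape=(48, 48, 48), noise_sigma=0.0, lesion_count=0, seed=1)
        )
        vols = structure_volumes(lab)
        out = asymmetry_ratios(vols, scheme)
        assert np.nanmax(np.abs(out.asymmetry_pct.values)) < 5.0


class TestThickness:
    def test_constant_map(self):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[:4] = 1
        lab[4:] = 2
        t = np.full((8, 8, 8), 2.5)
        out = thickness_summary(t, _lab(lab), [1, 2])
        assert np.allclose(out.thickness_mean_mm, 2.5)
        assert np.allclose(out.thickness_sd_mm, 0.0)

    def test_region_without_positive_thickness_omitted(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[:3] = 1
        lab[3:] = 2
        t = np.zeros((6, 6, 6))
        t[:3] = 1.5
        out = thickness_summary(t, _lab(lab), [1, 2])
        assert out.label_id.tolist() == [1]

    def test_matches_masked_average(self):
        rng = np.random.default_rng(6)
        lab = rng.integers(0, 3, (10, 10, 10)).astype(np.int32)
        t = rng.uniform(0, 4, (10, 10, 10))
        out = thickness_summary(t, _lab(lab), [1, 2])
        for row in out.itertuples():
            sel = (lab == row.label_id) & (t > 0)
            assert row.thickness_mean_mm == pytest.approx(t[sel].mean())
            assert row.thickness_sd_mm == pytest.approx(t[sel].std())


class TestReport:
    def test_round_trip_and_determinism(self, tmp_path, loo_segmentation):
        result, *_ , scheme = loo_segmentation
        p1, p2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        write_report(result.report, p1)
        write_report(result.report, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_report(p1)
        assert len(back.table) == len(result.report.table)
        assert back.table.region.tolist() == result.report.table.region.tolist()

    def test_row_order_icc_tissue_lobe_structure(self, loo_segmentation):
        result, *_ = loo_segmentation
        scales = result.report.table.scale.tolist()
        order = {"ICC": 0, "tissue": 1, "lobe": 2, "structure": 3}
        assert scales == sorted(scales, key=order.get)
        assert scales[0] == "ICC"

    def test_tissue_rows_partition_icc_volume(self, loo_segmentation):
        result, *_ = loo_segmentation
        table = result.report.table
        icc = table[table.scale == "ICC"].volume_mm3_template.iloc[0]
        tissues = table[table.scale == "tissue"].volume_mm3_template.sum()
        assert tissues == icc

    def test_thickness_columns_filled_when_map_supplied(self, loo_segmentation):
        result, subject, *_ , scheme = loo_segmentation
        cgm_ids = scheme.ids_of_tissue("cGM")
        tmap = np.where(np.isin(result.structures.labels, cgm_ids), 2.5, 0.0)
        rep = build_report(result.structures, scheme, thickness_map=tmap)
        cortical = rep.table[
            (rep.table.scale == "structure")
            & rep.table.region.str.startswith("cortical_gm")
        ]
        assert cortical.thickness_mean_mm.notna().all()
        assert np.allclose(cortical.thickness_mean_mm, 2.5)
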