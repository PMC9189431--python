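import numpy as np
import pandas as pd
import pytest

from embryoseg.io_config import CalibratedVolume, MultiChannelVolume
from embryoseg.measure import (
    CellRecord,
    classify_inner_outer,
    measure_cells,
    records_to_frame,
    summarise_groups,
)
from embryoseg.segment import LabelVolume

SPACING = (1.0, 0.2, 0.2)


def mcv(arrays, **roles):
    channels = [CalibratedVolume(np.asarray(a, dtype=float), SPACING) for a in arrays]
    return MultiChannelVolume(channels, **roles)


def two_cell_labels():
    nuc = np.zeros((8, 40, 40), dtype=np.int32)
    cel = np.zeros((8, 40, 40), dtype=np.int32)
    nuc[2:5, 5:12, 5:12] = 1
    cel[1:6, 2:16, 2:16] = 1
    nuc[2:5, 25:32, 25:32] = 2
    cel[1:6, 22:36, 22:36] = 2
    return LabelVolume(nuc, SPACING), LabelVolume(cel, SPACING, kind="cell")


class TestMeasureCells:
    def test_constant_channel_means_and_ratio(self):
        nuclei, cells = two_cell_labels()
        channels = mcv([np.full((8, 40, 40), 7.5)], nucleus_index=0)
        records = measure_cells(nuclei, cells, channels)
        for r in records:
            assert r.nuc_mean[0] == pytest.approx(7.5)
            assert r.cyto_mean[0] == pytest.approx(7.5)
            assert r.nc_ratio[0] == pytest.approx(1.0)

    def test_digital_ellipsoid_volume(self):
        """Half-axes (5, 3.75, 3.75) μm: volume within 5% of 4/3*pi*a*b*c."""
        shape = (24, 100, 100)
        zz, yy, xx = np.indices(shape, dtype=float)
        r2 = (
            ((zz - 12) * SPACING[0] / 5.0) ** 2
            + ((yy - 50) * SPACING[1] / 3.75) ** 2
            + ((xx - 50) * SPACING[2] / 3.75) ** 2
        )
        nuc = (r2 <= 1.0).astype(np.int32)
        nuclei = LabelVolume(nuc, SPACING)
        channels = mcv([np.ones(shape)], nucleus_index=0)
        (rec,) = measure_cells(nuclei, None, channels)
        analytic = 4 / 3 * np.pi * 5.0 * 3.75 * 3.75  # ~294.5 μm³
        assert rec.nucleus_volume_um3 == pytest.approx(analytic, rel=0.05)

    def test_normalised_expression_is_two(self, rng):
        nuclei, cells = two_cell_labels()
        dapi = rng.random((8, 40, 40)) + 0.5
        expr = 2.0 * dapi
        channels = mcv(
            [dapi, expr], nucleus_index=0, expression_indices=[1], normalisation_index=0
        )
        records = measure_cells(nuclei, cells, channels, normalisation_channel=0)
        for r in records:
            assert r.normalised_nuc_mean[1] == pytest.approx(2.0, rel=1e-9)

    def test_empty_cytoplasm_warns_and_is_missing(self, caplog):
        nuc = np.zeros((4, 10, 10), dtype=np.int32)
        nuc[1:3, 2:6, 2:6] = 1
        nuclei = LabelVolume(nuc, SPACING)
        cells = LabelVolume(nuc.copy(), SPACING, kind="cell")  # cell == nucleus
        channels = mcv([np.ones((4, 10, 10))], nucleus_index=0)
        (rec,) = measure_cells(nuclei, cells, channels)
        assert np.isnan(rec.nc_ratio[0])
        assert any("empty cytoplasm" in r.message for r in caplog.records)

    def test_intensity_scaling_leaves_ratios_unchanged(self, rng):
        nuclei, cells = two_cell_labels()
        base = rng.random((8, 40, 40)) + 0.2
        r1 = measure_cells(nuclei, cells, mcv([base], nucleus_index=0))
        r2 = measure_cells(nuclei, cells, mcv([base * 37.0], nucleus_index=0))
        for a, b in zip(r1, r2):
            assert a.nc_ratio[0] == pytest.approx(b.nc_ratio[0], rel=1e-9)
            assert a.volume_ratio == pytest.approx(b.volume_ratio)


def make_records(centroids):
    return [
        CellRecord(
            cell_id=i + 1,
            nucleus_volume_um3=1.0,
            cell_volume_um3=2.0,
            volume_ratio=2.0,
            nucleus_centroid_um=np.asarray(c, dtype=float),
            cell_centroid_um=None,
        )
        for i, c in enumerate(centroids)
    ]


class TestInnerOuter:
    def test_cube_corners_and_centre(self):
        """8 nuclei at cube corners + 1 at the centre, D_T = 0.5: the centre
        is inner, all corners outer."""
        corners = [(z, y, x) for z in (0, 10) for y in (0, 10) for x in (0, 10)]
        records = make_records(corners + [(5, 5, 5)])
        records, centroid = classify_inner_outer(records, 0.5)
        np.testing.assert_allclose(centroid, [5, 5, 5], atol=1e-9)
        assert [r.inner_outer for r in records[:8]] == ["outer"] * 8
        assert records[8].inner_outer == "inner"
        assert records[8].distance_to_centroid_um == pytest.approx(0.0)

    def test_cell_at_centroid_is_inner_and_extreme_is_outer(self):
        records = make_records([(0, 0, 0), (0, 0, 4), (0, 0, 8)])
        records, _ = classify_inner_outer(records, 0.5)
        assert records[1].inner_outer == "inner"  # sits exactly at the centroid
        assert records[0].inner_outer == "outer"  # attains D_m
        assert records[2].inner_outer == "outer"

    def test_single_cell_inner_by_convention(self, caplog):
        records = make_records([(1, 2, 3)])
        records, _ = classify_inner_outer(records, 0.5)
        assert records[0].inner_outer == "inner"
        assert any("single-cell" in r.message for r in caplog.records)

    def test_translation_invariance(self, rng):
        pts = rng.random((12, 3)) * 30
        a, _ = classify_inner_outer(make_records(pts), 0.5)
        b, _ = classify_inner_outer(make_records(pts + [5.0, -3.0, 11.0]), 0.5)
        assert [r.inner_outer for r in a] == [r.inner_outer for r in b]

    def test_small_dt_perturbation_moves_only_boundary_cells(self, rng):
        """±10% on D_T only reclassifies cells whose D_i sits near the
        threshold radius."""
        pts = rng.random((40, 3)) * 30
        base, _ = classify_inner_outer(make_records(pts), 0.5)
        for dt in (0.45, 0.55):
            alt, _ = classify_inner_outer(make_records(pts), dt)
            for r0, r1 in zip(base, alt):
                if r0.inner_outer != r1.inner_outer:
                    d_m = max(r.distance_to_centroid_um for r in base)
                    assert 0.44 * d_m <= r0.distance_to_centroid_um <= 0.56 * d_m

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_inner_outer([], 0.5)
        with pytest.raises(ValueError):
            classify_inner_outer(make_records([(0, 0, 0)]), 1.5)


class TestRecordsFrame:
    def test_roundtrip_columns(self):
        records = make_records([(0, 0, 0), (1, 1, 1)])
        classify_inner_outer(records, 0.5)
        df = records_to_frame(records)
        assert list(df["cell_id"]) == [1, 2]
        assert {"centroid_z_um", "inner_outer", "distance_to_centroid_um"} <= set(df.columns)

    def test_empty_frame_has_header(self):
        df = records_to_frame([])
        assert df.empty and "cell_id" in df.columns


class TestSummariseGroups:
    def test_identical_groups_p_is_one(self):
        df = pd.DataFrame({"v": [1, 2, 3, 1, 2, 3], "g": list("aaabbb")})
        _, comp = summarise_groups(df, "v", "g")
        assert comp.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_groups_exact_p(self):
        """{1,2,3} vs {10,20,30}: U = 0, exact two-sided p = 0.1
        (2 of the 20 equally likely rank assignments are as extreme)."""
        df = pd.DataFrame({"v": [1, 2, 3, 10, 20, 30], "g": list("aaabbb")})
        _, comp = summarise_groups(df, "v", "g")
        assert comp.loc[0, "u"] == 0.0
        assert comp.loc[0, "p"] == pytest.approx(0.1)

    def test_summary_median_iqr_against_direct_formula(self, rng):
        vals = rng.normal(size=200)
        df = pd.DataFrame({"v": vals, "g": ["a"] * 200})
        summary, _ = summarise_groups(df, "v", "g")
        assert summary.loc[0, "median"] == pytest.approx(np.median(vals))
        assert summary.loc[0, "q25"] == pytest.approx(np.percentile(vals, 25))
        assert summary.loc[0, "q75"] == pytest.approx(np.percentile(vals, 75))

    def test_small_group_skipped_with_note(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 9.0], "g": ["a", "a", "a", "b"]})
        _, comp = summarise_groups(df, "v", "g")
        assert "skipped" in comp.loc[0, "note"]
        assert np.isnan(comp.loc[0, "p"])
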