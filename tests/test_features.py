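"""Crown feature extraction: normalization, 3D and intensity features,
multispectral indices, brute-force oracles, and invariance properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon, box

from crownid import (PointCloud, RasterGrid, clip_and_normalize,
                     compute_3d_features, compute_intensity_features,
                     compute_msl_indices, normalize_feature)
from crownid.features import (CrownPointSet, CrownUnusableError,
                              assemble_feature_table, feature_names_3d,
                              feature_names_intensity)
from crownid.pointcloud import VEGETATION


def make_cps(z, intensity=None, return_number=None, channel=None, x=None, y=None):
    z = np.asarray(z, float)
    n = len(z)
    rng = np.random.default_rng(0)
    return CrownPointSet(
        crown_id=0,
        x=np.asarray(x, float) if x is not None else rng.uniform(0, 5, n),
        y=np.asarray(y, float) if y is not None else rng.uniform(0, 5, n),
        z=z,
        intensity=np.asarray(intensity, float) if intensity is not None
        else np.full(n, 50.0),
        return_number=np.asarray(return_number, int) if return_number is not None
        else np.ones(n, int),
        channel=np.asarray(channel, int) if channel is not None
        else np.full(n, 1550),
    )


def flat_dtm(value=100.0):
    return RasterGrid(0, 0, 1.0, np.full((40, 40), value))


def simple_cloud(x, y, z, **kw):
    n = len(x)
    return PointCloud(
        x=np.asarray(x, float), y=np.asarray(y, float), z=np.asarray(z, float),
        intensity=kw.get("intensity", np.full(n, 50.0)),
        return_number=kw.get("return_number", np.ones(n, int)),
        number_of_returns=kw.get("number_of_returns", np.ones(n, int)),
        channel=kw.get("channel", np.full(n, 1550)),
        classification=np.full(n, VEGETATION),
    )


class TestClipAndNormalize:
    def test_single_dtm_value_normalization(self):
        cloud = simple_cloud([5.0], [5.0], [120.0])
        cps = clip_and_normalize(cloud, box(0, 0, 10, 10), flat_dtm(100.0))
        assert cps.z[0] == pytest.approx(20.0)

    def test_two_metre_cutoff(self):
        cloud = simple_cloud([5, 5, 5], [5, 5, 5], [101.9, 102.0, 110.0])
        cps = clip_and_normalize(cloud, box(0, 0, 10, 10), flat_dtm(100.0))
        assert len(cps) == 1  # 1.9 m and exactly-2 m returns discarded
        assert cps.z[0] == pytest.approx(10.0)

    def test_points_outside_polygon_excluded(self):
        cloud = simple_cloud([5, 25], [5, 25], [110, 110])
        cps = clip_and_normalize(cloud, box(0, 0, 10, 10), flat_dtm(100.0))
        assert len(cps) == 1

    def test_slope_preserves_relative_heights(self):
        # single-value normalization keeps within-crown dz exactly, even on
        # sloped terrain where per-point normalization would warp the crown
        slope_dtm = RasterGrid(0, 0, 1.0,
                               np.tile(np.arange(40) * 0.5, (40, 1)))
        x = np.array([2.0, 8.0])
        y = np.array([5.0, 5.0])
        z = np.array([120.0, 125.0])
        cloud = simple_cloud(x, y, z)
        cps = clip_and_normalize(cloud, box(0, 0, 10, 10), slope_dtm)
        assert np.diff(cps.z)[0] == pytest.approx(np.diff(z)[0])

    def test_nodata_centroid_flags_crown(self):
        dtm = flat_dtm()
        dtm.values[:] = np.nan
        with pytest.raises(CrownUnusableError):
            clip_and_normalize(simple_cloud([5], [5], [110]),
                               box(0, 0, 10, 10), dtm)


class TestNormalizeFeature:
    def test_identity_and_ratio(self):
        assert normalize_feature(25.0, 25.0) == pytest.approx(1.0)
        assert normalize_feature(12.5, 25.0) == pytest.approx(0.5)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            normalize_feature(1.0, 0.0)

    @settings(deadline=None, max_examples=40)
    @given(F=st.floats(0.1, 50), H=st.floats(1, 40), c=st.floats(0.1, 10))
    def test_scale_invariance(self, F, H, c):
        assert normalize_feature(F * c, H * c) == pytest.approx(
            normalize_feature(F, H))


class Test3DFeatures:
    def test_uniform_heights_degenerate(self):
        f = compute_3d_features(make_cps([10.0] * 8))
        assert f["3D_DI_all_cv"] == pytest.approx(0.0)
        assert f["3D_RB_95_100"] == pytest.approx(1.0)
        assert f["3D_RB_60_80"] == pytest.approx(0.0)

    def test_two_point_slope(self):
        cps = make_cps([10.0, 4.0], x=[0.0, 3.0], y=[0.0, 0.0])
        f = compute_3d_features(cps)
        assert f["3D_SLOPE_all_mn"] == pytest.approx(2.0)

    def test_unit_cube_hull(self):
        # 8 cube corners with H = 1: hull volume 1, so CH = 1 / H^3 = 1
        x = np.array([0, 1, 0, 1, 0, 1, 0, 1], float)
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1], float)
        z = np.array([1e-9, 1e-9, 1e-9, 1e-9, 1, 1, 1, 1], float)
        f = compute_3d_features(make_cps(z, x=x, y=y))
        assert f["3D_CH"] == pytest.approx(1.0, rel=1e-6)

    def test_hull_matches_delaunay_oracle(self):
        # independent oracle: hull volume as the sum of Delaunay simplices
        from scipy.spatial import Delaunay
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(6, 20)
            x, y = rng.uniform(0, 6, (2, n))
            z = rng.uniform(2.5, 20, n)
            cps = make_cps(z, x=x, y=y)
            f = compute_3d_features(cps)
            tri = Delaunay(np.column_stack([x, y, z]))
            vol = 0.0
            for simplex in tri.simplices:
                mat = tri.points[simplex[1:]] - tri.points[simplex[0]]
                vol += abs(np.linalg.det(mat)) / 6
            assert f["3D_CH"] == pytest.approx(vol / z.max() ** 3, rel=1e-9)

    def test_rm_missing_without_second_returns(self):
        f = compute_3d_features(make_cps([5, 8, 10], return_number=[1, 1, 1]))
        assert np.isnan(f["3D_RM_zmn_2nd_1st"])
        assert np.isnan(f["3D_RM_n_2nd_all"])
        assert np.isfinite(f["3D_RM_n_1st_all"])

    def test_uniform_xyz_scaling_invariance(self):
        rng = np.random.default_rng(5)
        n = 40
        x, y = rng.uniform(0, 6, (2, n))
        z = rng.uniform(2.5, 20, n)
        rn = rng.choice([1, 1, 1, 2], n)
        a = compute_3d_features(make_cps(z, return_number=rn, x=x, y=y))
        c = 3.7
        b = compute_3d_features(make_cps(z * c, return_number=rn, x=x * c, y=y * c))
        for name in feature_names_3d():
            if np.isnan(a[name]):
                assert np.isnan(b[name])
            else:
                assert b[name] == pytest.approx(a[name], rel=1e-9), name

    def test_missingness_monotone_under_point_removal(self):
        rng = np.random.default_rng(7)
        n = 30
        cps = make_cps(rng.uniform(2.5, 20, n),
                       return_number=rng.choice([1, 2], n, p=[0.8, 0.2]))
        full = compute_3d_features(cps)
        sub = compute_3d_features(cps.subset(np.arange(n) < 10))
        for name in feature_names_3d():
            if np.isnan(full[name]):
                assert np.isnan(sub[name]), name

    def test_feature_count_is_34(self):
        assert len(feature_names_3d()) == 34


class TestPercentileOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_linear_interpolation_definition(self, seed):
        # brute-force oracle on <= 20 points for the documented definition
        rng = np.random.default_rng(seed)
        values = np.sort(rng.uniform(0, 100, rng.integers(2, 20)))
        for p in (5, 25, 50, 75, 95):
            rank = p / 100 * (len(values) - 1)
            lo = int(np.floor(rank))
            hi = int(np.ceil(rank))
            expected = values[lo] + (rank - lo) * (values[hi] - values[lo])
            assert np.percentile(values, p) == pytest.approx(expected)


class TestIntensityFeatures:
    def test_constant_intensity_degenerate(self):
        cps = make_cps([3, 5, 8, 10], intensity=[50.0] * 4)
        f = compute_intensity_features(cps, 1550)
        assert f["I_DI_1st_sd"] == pytest.approx(0.0)
        assert f["I_DI_1st_cv"] == pytest.approx(0.0)
        for p in (5, 50, 95):
            assert f[f"I_PE_p{p}"] == pytest.approx(50.0)
        assert f["I_RM_mn_1st_all"] == pytest.approx(1.0)

    def test_mean_and_median(self):
        f = compute_intensity_features(make_cps([3, 5, 8],
                                                intensity=[10, 20, 30]), 1550)
        assert f["I_MI_all"] == pytest.approx(20.0)

    def test_second_to_first_ratio(self):
        cps = make_cps([4, 5, 8, 9], intensity=[10, 10, 5, 5],
                       return_number=[1, 1, 2, 2])
        f = compute_intensity_features(cps, 1550)
        assert f["I_RM_mn_2nd_1st"] == pytest.approx(0.5)

    def test_intensity_scale_invariance(self):
        rng = np.random.default_rng(11)
        n = 30
        inten = rng.uniform(5, 80, n)
        rn = rng.choice([1, 2], n, p=[0.7, 0.3])
        z = rng.uniform(2.5, 15, n)
        a = compute_intensity_features(make_cps(z, intensity=inten,
                                                return_number=rn), 1550)
        b = compute_intensity_features(make_cps(z, intensity=inten * 4.2,
                                                return_number=rn), 1550)
        for name in ("I_DI_1st_cv", "I_RM_mn_2nd_1st", "I_RM_p50_1st_all"):
            assert b[name] == pytest.approx(a[name], rel=1e-9)

    def test_feature_count_is_16(self):
        assert len(feature_names_intensity()) == 16


class TestMslIndices:
    def _three_channel(self, means, n=30, seed=0):
        rng = np.random.default_rng(seed)
        parts = []
        for wl, mean in means.items():
            z = rng.uniform(2.5, 15, n)
            parts.append(make_cps(z, intensity=np.full(n, float(mean)),
                                  channel=np.full(n, wl)))
        return CrownPointSet(
            0,
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.z for p in parts]),
            np.concatenate([p.intensity for p in parts]),
            np.concatenate([p.return_number for p in parts]),
            np.concatenate([p.channel for p in parts]),
        )

    def test_equal_channels_give_zero(self):
        f = compute_msl_indices(self._three_channel({532: 30, 1064: 30, 1550: 30}))
        assert f["I_G_IR1_mn"] == pytest.approx(0.0)
        assert f["I_NDIR_p50"] == pytest.approx(0.0)

    def test_ir_minus_green_sign_convention(self):
        f = compute_msl_indices(self._three_channel({532: 10, 1064: 30, 1550: 10}))
        assert f["I_G_IR1_mn"] == pytest.approx(0.5)

    def test_swapping_channels_negates_index(self):
        a = compute_msl_indices(self._three_channel({532: 10, 1064: 40, 1550: 20}))
        b = compute_msl_indices(self._three_channel({532: 40, 1064: 10, 1550: 20}))
        assert b["I_G_IR1_mn"] == pytest.approx(-a["I_G_IR1_mn"])

    def test_indices_bounded(self):
        rng = np.random.default_rng(2)
        f = compute_msl_indices(self._three_channel(
            {532: rng.uniform(1, 80), 1064: rng.uniform(1, 80),
             1550: rng.uniform(1, 80)}))
        for name, value in f.items():
            if not name.startswith("I_SR"):
                assert -1.0 <= value <= 1.0


@pytest.fixture(scope="module")
def small_tables():
    rng = np.random.default_rng(4)
    n = 120
    x = rng.uniform(0, 10, n)
    y = rng.uniform(0, 10, n)
    z = rng.uniform(103, 115, n)
    rn = rng.choice([1, 2], n, p=[0.8, 0.2])
    chans = rng.choice([532, 1064, 1550], n)
    msl = simple_cloud(x, y, z, return_number=rn,
                       number_of_returns=np.where(rn == 2, 2, 1),
                       channel=chans,
                       intensity=rng.uniform(10, 60, n))
    als = simple_cloud(x, y, z, return_number=rn,
                       number_of_returns=np.where(rn == 2, 2, 1),
                       intensity=rng.uniform(10, 60, n))
    polys = {1: box(0, 0, 10, 10), 2: box(20, 20, 25, 25)}
    return assemble_feature_table(
        polys, {"16": (msl, (532, 1064, 1550)), "12": (als, (1550,))},
        flat_dtm(100.0))


class TestAssembleTable:
    def test_msl_schema(self, small_tables):
        df = small_tables.tables["16"]
        assert df.shape[1] == 34 + 3 * 16 + 18
        assert "I_DI_1st_sd_c532_16" in df.columns
        assert "I_G_IR1_mn_16" in df.columns
        assert np.isfinite(df.loc[1, "3D_CH_16"])

    def test_monospectral_schema(self, small_tables):
        df = small_tables.tables["12"]
        assert df.shape[1] == 50
        assert "I_DI_1st_sd_12" in df.columns

    def test_empty_crown_flagged_not_dropped(self, small_tables):
        # crown 2 contains no points: all-NaN row, flagged
        df = small_tables.tables["12"]
        assert 2 in df.index
        assert df.loc[2].isna().all()
        assert bool(small_tables.flags("12").loc[2])

    def test_pooled_column_count(self, small_tables):
        pooled = small_tables.pooled()
        assert pooled.shape[1] == 50 + (34 + 3 * 16 + 18)

    def test_no_second_returns_leaves_rm_missing(self):
        cloud = simple_cloud([5, 6, 7], [5, 6, 7], [110, 112, 114])
        table = assemble_feature_table({1: box(0, 0, 10, 10)},
                                       {"12": (cloud, (1550,))}, flat_dtm(100.0))
        row = table.tables["12"].loc[1]
        assert np.isnan(row["3D_RM_zmn_2nd_1st_12"])
        assert bool(table.flags("12").loc[1])
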