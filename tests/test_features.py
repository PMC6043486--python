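import math

import numpy as np
import pytest

from conftest import dvoi_from_grid
from oracles import (
    glcm_features_oracle,
    glcm_oracle,
    glrlm_features_oracle,
    glrlm_oracle,
    glszm_features_oracle,
    glszm_oracle,
    ngtdm_features_oracle,
    ngtdm_oracle,
    random_level_grid,
)
from radnorm.discretize import discretize
from radnorm.features import (
    FEATURE_NAMES,
    GL_NORM_FACTORS,
    GL_PANEL,
    VOXEL_NORM_RULES,
    VOXEL_PANEL,
    apply_gl_normalization,
    apply_voxel_normalization,
    extract_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    intensity_features,
    ngtdm_features,
)
from radnorm.resample import expand_grid
from radnorm.texture import build_glcm, build_glrlm, build_glszm, build_ngtdm
from radnorm.volume import ImageVolume, VOIMask, extract_voi


def _full_voi(values, spacing=(1, 1, 1)):
    values = np.asarray(values, dtype=float)
    vol = ImageVolume(values, spacing)
    mask = VOIMask(np.ones(values.shape, bool), spacing)
    return extract_voi(vol, mask)


class TestPanels:
    def test_panel_sizes_and_families(self):
        assert len(FEATURE_NAMES) == 24
        assert len(VOXEL_PANEL) == 10
        assert len(GL_PANEL) == 17
        by_family = {}
        for name in GL_PANEL:
            by_family.setdefault(name.split("-")[0], []).append(name)
        assert len(by_family["GLCM"]) == 9
        assert len(by_family["GLRLM"]) == 3
        assert len(by_family["GLSZM"]) == 1
        assert len(by_family["NGTDM"]) == 4

    def test_each_normalized_feature_has_exactly_one_rule(self):
        assert set(VOXEL_NORM_RULES.values()) <= {"multiply_N", "divide_N", "divide_logN"}
        assert set(GL_NORM_FACTORS.values()) <= {"1", "d", "d2", "log2d"}


class TestIntensityFeatures:
    def test_constant_voi(self):
        voi = _full_voi(np.full((4, 4, 4), 3.0))
        f = intensity_features(voi)
        assert f["Intensity-Energy"] == pytest.approx(64 * 9.0)
        assert f["Intensity-Entropy"] == 0.0
        assert f["Intensity-TGV"] == 0.0
        assert f["Intensity-Contrast"] == 0.0

    def test_two_valued_voi_entropy_one_bit(self):
        vals = np.zeros((4, 4, 2))
        vals[..., 1] = 5.0
        f = intensity_features(_full_voi(vals))
        assert f["Intensity-Entropy"] == pytest.approx(1.0)
        assert f["Intensity-Contrast"] == pytest.approx(5.0)

    def test_random_voi_matches_direct_summation(self, rng):
        vals = rng.normal(size=(5, 4, 3))
        f = intensity_features(_full_voi(vals))
        assert f["Intensity-Energy"] == pytest.approx(float((vals ** 2).sum()), rel=1e-12)
        # histogram-formula entropy oracle
        hist, _ = np.histogram(vals, bins=64, range=(vals.min(), vals.max()))
        p = hist[hist > 0] / vals.size
        assert f["Intensity-Entropy"] == pytest.approx(-np.sum(p * np.log2(p)), rel=1e-12)
        # TGV: explicit double loop over 6-neighbor ordered pairs
        tgv = 0.0
        for x in range(5):
            for y in range(4):
                for z in range(3):
                    for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                                       (0, 0, 1), (0, 0, -1)):
                        xx, yy, zz = x + dx, y + dy, z + dz
                        if 0 <= xx < 5 and 0 <= yy < 4 and 0 <= zz < 3:
                            tgv += abs(vals[x, y, z] - vals[xx, yy, zz])
        assert f["Intensity-TGV"] == pytest.approx(tgv, rel=1e-12)


class TestMatrixFeatureFormulas:
    @pytest.mark.parametrize("seed", range(5))
    def test_glcm_features_match_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_level_grid(rng, d=4, mask_p=0.8)
        got = glcm_features(build_glcm(dvoi_from_grid(grid, d=4)))
        exp = glcm_features_oracle(glcm_oracle(grid))
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10, abs=1e-12), k

    def test_glcm_constant_image(self):
        m = build_glcm(dvoi_from_grid(np.full((3, 3, 3), 2), d=4))
        f = glcm_features(m)
        assert f["GLCM-Entropy"] == 0.0
        assert f["GLCM-Contrast"] == 0.0
        assert f["GLCM-Dissimilarity"] == 0.0
        assert f["GLCM-Mean"] == pytest.approx(2.0)
        assert f["GLCM-Inverse Variance"] == 0.0

    def test_glcm_alternating_pattern(self):
        grid = np.array([1, 2, 1, 2, 1, 2]).reshape(6, 1, 1)
        m = build_glcm(dvoi_from_grid(grid, d=2), directions=[(1, 0, 0)])
        f = glcm_features(m)
        assert f["GLCM-Contrast"] == pytest.approx(1.0)
        assert f["GLCM-Dissimilarity"] == pytest.approx(1.0)
        assert f["GLCM-Entropy"] == pytest.approx(1.0)

    def test_glrlm_single_run(self):
        grid = np.full((1, 1, 5), 3, np.int32)
        m = build_glrlm(dvoi_from_grid(grid, d=4), directions=[(0, 0, 1)])
        f = glrlm_features(m)
        assert f["GLRLM-GLNU"] == pytest.approx(1.0)
        assert f["GLRLM-RLNU"] == pytest.approx(1.0)
        assert f["GLRLM-HGRE"] == pytest.approx(9.0)
        assert f["GLRLM-SRHGE"] == pytest.approx(9.0 / 25.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_glrlm_features_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_level_grid(rng, d=4, mask_p=0.8)
        got = glrlm_features(build_glrlm(dvoi_from_grid(grid, d=4)))
        exp = glrlm_features_oracle(glrlm_oracle(grid))
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10), k

    def test_glszm_two_zone_hand_value(self):
        grid = np.zeros((5, 1, 1), np.int32)
        grid[0:2, 0, 0] = 1
        grid[3:5, 0, 0] = 3
        f = glszm_features(build_glszm(dvoi_from_grid(grid, d=4)))
        assert f["GLSZM-HIE"] == pytest.approx((1 + 9) / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_glszm_features_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_level_grid(rng, d=4, mask_p=0.8)
        got = glszm_features(build_glszm(dvoi_from_grid(grid, d=4)))
        exp = glszm_features_oracle(glszm_oracle(grid))
        assert got["GLSZM-HIE"] == pytest.approx(exp["GLSZM-HIE"], rel=1e-10)

    def test_ngtdm_constant_voi(self):
        m = build_ngtdm(dvoi_from_grid(np.full((3, 3, 3), 2), d=4))
        f = ngtdm_features(m, eps=1e-6)
        assert f["NGTDM-Coarseness"] == pytest.approx(1e6)
        assert f["NGTDM-Contrast"] == 0.0
        assert f["NGTDM-Complexity"] == 0.0

    def test_ngtdm_three_voxel_line_hand_evaluation(self):
        grid = np.array([1, 2, 1]).reshape(1, 1, 3).astype(np.int32)
        m = build_ngtdm(dvoi_from_grid(grid, d=2))
        f = ngtdm_features(m, eps=1e-6)
        exp = ngtdm_features_oracle(*ngtdm_oracle(grid, 2), eps=1e-6)
        for k in exp:
            assert f[k] == pytest.approx(exp[k], rel=1e-10), k

    @pytest.mark.parametrize("seed", range(5))
    def test_ngtdm_features_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_level_grid(rng, d=4, mask_p=0.8)
        got = ngtdm_features(build_ngtdm(dvoi_from_grid(grid, d=4)))
        exp = ngtdm_features_oracle(*ngtdm_oracle(grid, 4))
        for k in exp:
            assert got[k] == pytest.approx(exp[k], rel=1e-10), k


class TestVoxelNormalization:
    def _record(self, values, n):
        from radnorm.features import FeatureRecord

        return FeatureRecord(
            subject="s", variant="non_normalized", pixel_size=1.0,
            slice_thickness=1.0, n_gray_levels=64, n_voxels=n, values=values,
        )

    def test_divide_n_cancels_linear_growth(self):
        for n in (10, 100, 1000):
            rec = self._record({"Intensity-Energy": float(n)}, n)
            out = apply_voxel_normalization(rec)
            assert out.values["Intensity-Energy"] == pytest.approx(1.0)

    def test_multiply_rule_arithmetic(self):
        rec = self._record({"NGTDM-Coarseness": 0.5}, 100)
        out = apply_voxel_normalization(rec)
        assert out.values["NGTDM-Coarseness"] == pytest.approx(50.0)
        assert out.variant == "voxel_normalized"

    def test_log_rule_uses_natural_log(self):
        rec = self._record({"Intensity-Entropy": 6.0}, 100)
        out = apply_voxel_normalization(rec)
        assert out.values["Intensity-Entropy"] == pytest.approx(6.0 / math.log(100))

    def test_pass_through_is_bit_identical(self, rng):
        values = {"GLCM-Contrast": rng.normal(), "GLCM-Sum Average": rng.normal()}
        rec = self._record(dict(values), 50)
        out = apply_voxel_normalization(rec)
        assert out.values == values

    def test_n_of_one_rejected_for_log_rule(self):
        rec = self._record({"Intensity-Entropy": 1.0}, 1)
        with pytest.raises(ValueError, match="log N"):
            apply_voxel_normalization(rec)

    def test_constant_field_energy_flat_across_grid(self, rng):
        # on a constant-intensity VOI, normalized Energy equals c^2 at every
        # grid point while the non-normalized value tracks N
        spacing = (1.17, 1.17, 3.0)
        c = 7.0
        vol = ImageVolume(np.full((20, 20, 10), c), spacing)
        flags = np.zeros((20, 20, 10), bool)
        flags[4:16, 4:16, 2:8] = True
        mask = VOIMask(flags, spacing)
        raw_energy, norm_energy, ns = [], [], []
        for ds in expand_grid(vol, mask):
            rec = extract_features(ds.volume, ds.mask, d=8)
            out = apply_voxel_normalization(rec)
            raw_energy.append(rec.values["Intensity-Energy"])
            norm_energy.append(out.values["Intensity-Energy"])
            ns.append(rec.n_voxels)
        assert np.allclose(norm_energy, c ** 2, rtol=1e-9)
        assert np.std(raw_energy) > 0
        np.testing.assert_allclose(raw_energy, [n * c ** 2 for n in ns], rtol=1e-9)


class TestGLNormalization:
    def _record_at_d(self, values, d):
        from radnorm.features import FeatureRecord

        return FeatureRecord(
            subject="s", variant="non_normalized", pixel_size=1.0,
            slice_thickness=1.0, n_gray_levels=d, n_voxels=100, values=values,
        )

    def test_factor_one_unchanged(self):
        rec = self._record_at_d({"GLRLM-GLNU": 123.4}, 64)
        out = apply_gl_normalization(rec)
        assert out.values["GLRLM-GLNU"] == 123.4
        assert out.variant == "gl_normalized"

    def test_entropy_factor_log2d(self):
        # maximal-entropy limit: a uniform d x d GLCM has entropy 2 log2 d,
        # so entropy / log2 d is d-independent
        for d in (8, 64, 256):
            ent = 2 * math.log2(d)
            rec = self._record_at_d({"GLCM-Entropy": ent}, d)
            out = apply_gl_normalization(rec)
            assert out.values["GLCM-Entropy"] == pytest.approx(2.0)

    def test_contrast_scaling_cancellation_on_smooth_field(self, rng):
        # GLCM contrast on a fixed continuous field scales ~ d^2, so the
        # d^2-normalized values converge as d grows
        vals = rng.normal(size=(12, 12, 6))
        from scipy import ndimage

        vals = ndimage.gaussian_filter(vals, 2.0)
        vol = ImageVolume(vals, (1, 1, 1))
        mask = VOIMask(np.ones(vals.shape, bool), (1, 1, 1))
        voi = extract_voi(vol, mask)
        normed = []
        for d in (64, 128, 256):
            dv = discretize(voi, d)
            con = glcm_features(build_glcm(dv))["GLCM-Contrast"]
            normed.append(con / d ** 2)
        assert abs(normed[2] / normed[1] - 1) < 0.05
        assert abs(normed[1] / normed[0] - 1) < 0.10

    def test_d_below_two_rejected(self):
        rec = self._record_at_d({"GLCM-Entropy": 1.0}, 1)
        with pytest.raises(ValueError):
            apply_gl_normalization(rec)


class TestExtractFeatures:
    def test_full_record(self, rng):
        vals = rng.normal(size=(8, 8, 6))
        vol = ImageVolume(vals, (1.0, 1.0, 2.0))
        flags = np.zeros((8, 8, 6), bool)
        flags[1:7, 1:7, 1:5] = True
        rec = extract_features(vol, VOIMask(flags, (1.0, 1.0, 2.0)), d=16, subject="t")
        assert set(rec.values) == set(FEATURE_NAMES)
        assert rec.n_voxels == 6 * 6 * 4
        assert rec.pixel_size == 1.0 and rec.slice_thickness == 2.0
        assert all(np.isfinite(v) for v in rec.values.values())

    def test_constant_voi_flagged_degenerate(self):
        vol = ImageVolume(np.full((4, 4, 4), 2.0), (1, 1, 1))
        mask = VOIMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        rec = extract_features(vol, mask, d=8)
        assert "degenerate_constant_voi" in rec.flags
        assert rec.values["GLCM-Entropy"] == 0.0
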