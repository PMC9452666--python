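"""GLCM construction, the eight statistics, and windowed texture images."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import canopyagb as ca
from canopyagb.glcm import (
    GLCMConfig,
    compute_glcm,
    field_glcm_features,
    glcm_features,
    plot_glcm_features,
    texture_image,
    texture_image_reference,
)
from canopyagb.raster import Raster, ROIBox


def _brute_force_glcm(gray, offset, levels, symmetric):
    """Independent oracle: enumerate every pixel pair explicitly."""
    H, W = gray.shape
    dr, dc = offset
    p = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                p[gray[r, c], gray[r2, c2]] += 1
                if symmetric:
                    p[gray[r2, c2], gray[r, c]] += 1
    return p / p.sum()


class TestComputeGlcm:
    def test_two_row_block_example(self):
        g = compute_glcm(np.array([[0, 0], [1, 1]]), (0, 1), 2, symmetric=True)
        assert g.p[0, 0] == 0.5
        assert g.p[1, 1] == 0.5
        assert g.p[0, 1] == g.p[1, 0] == 0.0

    def test_constant_grid(self):
        g = compute_glcm(np.full((4, 4), 3), (0, 1), 5)
        assert g.p[3, 3] == 1.0
        assert g.p.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_bruteforce_on_random_grids(self, symmetric):
        rng = np.random.default_rng(7)
        for _ in range(50):
            gray = rng.integers(0, 4, size=(8, 8))
            offset = [(0, 1), (-1, 1), (-1, 0), (-1, -1)][rng.integers(0, 4)]
            ours = compute_glcm(gray, offset, 4, symmetric).p
            oracle = _brute_force_glcm(gray, offset, 4, symmetric)
            assert np.array_equal(ours, oracle)

    def test_normalisation_and_symmetry_contract(self):
        gray = np.random.default_rng(8).integers(0, 6, size=(9, 9))
        g = compute_glcm(gray, (-1, 1), 6, symmetric=True)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(g.p, g.p.T)

    def test_matches_skimage_graycomatrix(self):
        skimage_feature = pytest.importorskip("skimage.feature")
        gray = np.random.default_rng(9).integers(0, 5, size=(12, 12)).astype(np.uint8)
        # empirically verified angle convention of graycomatrix
        for angle_deg, offset in [(0, (0, 1)), (45, (1, 1)), (90, (-1, 0)), (135, (1, -1))]:
            ours = compute_glcm(gray, offset, 5, symmetric=True).p
            theirs = skimage_feature.graycomatrix(
                gray, [1], [np.deg2rad(angle_deg)], levels=5, symmetric=True, normed=True
            )[:, :, 0, 0]
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_grid_smaller_than_offset_is_error(self):
        with pytest.raises(ValueError, match="pair"):
            compute_glcm(np.array([[0]]), (0, 1), 2)


class TestGlcmFeatures:
    def test_diagonal_half_half_example(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(p)
        assert f == pytest.approx(
            {
                "Mea": 0.5,
                "Var": 0.25,
                "Hom": 1.0,
                "Con": 0.0,
                "Dis": 0.0,
                "Ent": 1.0,
                "Sec": 0.5,
                "Cor": 1.0,
            }
        )

    def test_constant_image_degenerate_conventions(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = glcm_features(p)
        assert f["Con"] == 0 and f["Dis"] == 0 and f["Ent"] == 0
        assert f["Hom"] == 1.0 and f["Sec"] == 1.0 and f["Cor"] == 1.0

    def test_checkerboard_example(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(p)
        assert f["Con"] == pytest.approx(1.0)
        assert f["Dis"] == pytest.approx(1.0)
        assert f["Hom"] == pytest.approx(0.5)
        assert f["Cor"] == pytest.approx(-1.0)

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            gray = rng.integers(0, 4, size=(8, 8))
            p = compute_glcm(gray, (0, 1), 4).p
            f = glcm_features(p)
            idx = np.arange(4)
            ii, jj = np.meshgrid(idx, idx, indexing="ij")
            mea = (ii * p).sum()
            assert f["Mea"] == pytest.approx(mea, abs=1e-10)
            assert f["Var"] == pytest.approx(((ii - mea) ** 2 * p).sum(), abs=1e-10)
            assert f["Con"] == pytest.approx(((ii - jj) ** 2 * p).sum(), abs=1e-10)
            assert f["Dis"] == pytest.approx((np.abs(ii - jj) * p).sum(), abs=1e-10)
            assert f["Hom"] == pytest.approx((p / (1 + (ii - jj) ** 2)).sum(), abs=1e-10)
            nz = p > 0
            assert f["Ent"] == pytest.approx(-(p[nz] * np.log2(p[nz])).sum(), abs=1e-10)
            assert f["Sec"] == pytest.approx((p**2).sum(), abs=1e-10)

    def test_direction_closure_for_symmetric_glcm(self):
        gray = np.random.default_rng(11).integers(0, 4, size=(10, 10))
        for d in [(0, 1), (-1, 1), (-1, 0), (-1, -1)]:
            f_pos = glcm_features(compute_glcm(gray, d, 4, True))
            f_neg = glcm_features(compute_glcm(gray, (-d[0], -d[1]), 4, True))
            assert f_pos == pytest.approx(f_neg, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_statistic_ranges(self, seed):
        gray = np.random.default_rng(seed).integers(0, 8, size=(6, 6))
        f = glcm_features(compute_glcm(gray, (0, 1), 8))
        assert 0.0 <= f["Hom"] <= 1.0
        assert 0.0 < f["Sec"] <= 1.0
        assert f["Con"] >= 0 and f["Dis"] >= 0 and f["Ent"] >= 0
        assert -1.0 - 1e-12 <= f["Cor"] <= 1.0 + 1e-12


class TestTextureImage:
    CFG = GLCMConfig(levels=4)

    def test_constant_input(self):
        grids = texture_image(np.zeros((8, 8), dtype=int), self.CFG, 45, 5)
        assert np.all(grids["Con"] == 0)
        assert np.all(grids["Hom"] == 1.0)

    @pytest.mark.parametrize("direction,window", [(0, 3), (45, 5), (90, 5), (135, 7)])
    def test_matches_per_pixel_oracle(self, direction, window):
        gray = np.random.default_rng(12).integers(0, 4, size=(11, 13))
        fast = texture_image(gray, self.CFG, direction, window)
        ref = texture_image_reference(gray, self.CFG, direction, window)
        for name in fast:
            assert np.allclose(fast[name], ref[name], atol=1e-10), name

    def test_output_shapes(self):
        gray = np.random.default_rng(13).integers(0, 4, size=(9, 14))
        grids = texture_image(gray, self.CFG, 45, 5)
        assert len(grids) == 8
        assert all(g.shape == (9, 14) for g in grids.values())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            texture_image(np.zeros((8, 8), dtype=int), self.CFG, 45, 4)


class TestPlotFeatures:
    def _uniform_rgb(self, h=60, w=60):
        vals = np.full((h, w, 3), 120, dtype=np.uint8)
        r = Raster(vals, 1.0, (0.005, (h - 0.5) / 100))
        roi = ROIBox("p1", 0.0, 0.0, w / 100, h / 100)
        return r, roi

    def test_single_gds_level_yields_24_features(self):
        rng = np.random.default_rng(14)
        vals = rng.integers(0, 256, size=(60, 60, 3)).astype(np.uint8)
        r = Raster(vals, 1.0, (0.005, 0.595))
        roi = ROIBox("p1", 0.0, 0.0, 0.6, 0.6)
        feats = plot_glcm_features(r, roi, GLCMConfig(), gds_levels=[1])
        assert len(feats) == 24
        assert "R-GDS1-Con" in feats and "B-GDS1-Cor" in feats

    def test_uniform_roi_has_zero_contrast_at_every_level(self):
        r, roi = self._uniform_rgb()
        feats = plot_glcm_features(r, roi, GLCMConfig(), gds_levels=[1, 5, 10])
        for key, value in feats.items():
            if key.endswith("-Con"):
                assert value == 0.0

    def test_roi_smaller_than_window_names_the_level(self):
        r, roi = self._uniform_rgb(h=30, w=30)
        with pytest.raises(ValueError, match="GDS10"):
            plot_glcm_features(r, roi, GLCMConfig(), gds_levels=[1, 10])

    def test_correlation_sign_structure_with_agb(self, tiny_scene):
        """At GDS1, pooled over periods, dissimilarity-family textures track AGB
        positively and correlation-family textures negatively (fixed seed)."""
        feats = {}
        for period, ps in tiny_scene.periods.items():
            per = field_glcm_features(ps.rgb, tiny_scene.rois, GLCMConfig(), [1])
            for pid, f in per.items():
                feats[(pid, period)] = f
        truth = tiny_scene.truth.set_index(["plot_id", "period"])
        agb = np.array([truth.loc[k, "agb_kg_hm2"] for k in feats])
        dis_r = [
            np.corrcoef([feats[k][f"{ch}-GDS1-Dis"] for k in feats], agb)[0, 1]
            for ch in "RGB"
        ]
        cor_r = [
            np.corrcoef([feats[k][f"{ch}-GDS1-Cor"] for k in feats], agb)[0, 1]
            for ch in "RGB"
        ]
        assert max(dis_r) > 0.3
        assert min(cor_r) < -0.3
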