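"""Texture module: discretization, GLCM/NGTDM/GLRLM/GLSZM, primary features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorad import ImageVolume, VOIMask
from tumorad.synthetic import PhantomParams, generate_phantom
from tumorad.texture import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    DegenerateVOIError,
    TextureParams,
    build_glcm,
    build_glrlm,
    build_glszm,
    discretize,
    extract_all,
    glcm_features,
    glrlm_features,
    glszm_features,
    max_diameter,
    ngtdm_features,
    primary_features,
)

from reference import ref_glszm, ref_discretize


def _voi(values, mask=None, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[..., None]
    if mask is None:
        mask = np.ones_like(arr, dtype=bool)
    return ImageVolume(arr, spacing), VOIMask(np.asarray(mask, bool), spacing)


class TestDiscretize:
    def test_identity_binning(self):
        img, m = _voi(np.arange(32, dtype=float).reshape(4, 8))
        d = discretize(img, m, n_bins=32)
        assert sorted(np.unique(d.levels[d.mask])) == list(range(1, 33))
        # one level per intensity
        assert np.array_equal(
            d.levels[d.mask], np.arange(32) + 1
        )

    def test_constant_region_maps_to_level_one(self):
        img, m = _voi(np.full((3, 3), 7.0))
        d = discretize(img, m, n_bins=16)
        assert np.all(d.levels[d.mask] == 1)

    def test_two_value_edge_case(self):
        img, m = _voi(np.array([[0.0, 10.0, 0.0, 10.0]]))
        d = discretize(img, m, n_bins=2)
        assert sorted(np.unique(d.levels[d.mask])) == [1, 2]

    def test_out_of_mask_sentinel_zero(self):
        mask = np.zeros((2, 3, 1), dtype=bool)
        mask[0, :, 0] = True
        img, m = _voi(np.arange(6, dtype=float).reshape(2, 3), mask=mask)
        d = discretize(img, m, n_bins=4)
        assert np.all(d.levels[~d.mask] == 0)
        assert np.all((d.levels[d.mask] >= 1) & (d.levels[d.mask] <= 4))

    @given(shift=st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance_of_levels(self, shift):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 30, size=(5, 4, 3)).astype(float)
        img1, m = _voi(vals)
        img2, _ = _voi(vals + shift)
        d1 = discretize(img1, m, 8)
        d2 = discretize(img2, m, 8)
        assert np.array_equal(d1.levels, d2.levels)


class TestGLCM:
    def test_constant_patch_single_cell(self):
        img, m = _voi(np.full((2, 2), 5.0))
        d = discretize(img, m, 4)
        g = build_glcm(d)
        assert g[0, 0] == pytest.approx(1.0)
        assert g.sum() == pytest.approx(1.0)

    def test_alternating_strip(self):
        # levels [1,2,1,2], distance 1, single direction: 3 pairs, all (1,2)
        img, m = _voi(np.array([[0.0, 10.0, 0.0, 10.0]]))
        d = discretize(img, m, 2)
        g = build_glcm(d, distance=1, directions=((0, 1, 0),))
        assert g[0, 0] == 0 and g[1, 1] == 0
        assert g[0, 1] == pytest.approx(0.5)
        assert g[1, 0] == pytest.approx(0.5)

    def test_symmetry_on_random_input(self):
        rng = np.random.default_rng(5)
        img, m = _voi(rng.integers(0, 9, size=(6, 5, 4)).astype(float))
        g = build_glcm(discretize(img, m, 6))
        assert np.allclose(g, g.T)

    def test_single_voxel_degenerate(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        img, m = _voi(np.ones((3, 3, 3)), mask=mask)
        with pytest.raises(DegenerateVOIError, match="degenerate"):
            build_glcm(discretize(img, m, 2))


class TestGLCMFeatures:
    def test_constant_image_limit(self):
        g = np.zeros((4, 4))
        g[0, 0] = 1.0
        f = glcm_features(g)
        assert f["Contrast"] == 0.0
        assert f["Homogeneity"] == pytest.approx(1.0)
        assert np.isnan(f["Correlation"])  # zero-variance marginal

    def test_two_offdiagonal_cells(self):
        g = np.zeros((2, 2))
        g[0, 1] = g[1, 0] = 0.5
        f = glcm_features(g)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Homogeneity"] == pytest.approx(0.5)
        assert f["Correlation"] == pytest.approx(-1.0)  # perfectly anti-correlated

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((3, 3)))


class TestNGTDM:
    def test_constant_voi(self):
        img, m = _voi(np.full((3, 3, 2), 4.0))
        f = ngtdm_features(discretize(img, m, 8))
        assert f["Busyness"] == 0.0
        assert f["Complexity"] == 0.0
        assert f["Coarseness"] == pytest.approx(1e6)  # epsilon-guard ceiling

    def test_level_swap_coarseness_invariance(self):
        # symmetric two-level layout: swapping the levels preserves Coarseness
        a = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float)
        img1, m = _voi(a)
        img2, _ = _voi(3 - a)
        f1 = ngtdm_features(discretize(img1, m, 2))
        f2 = ngtdm_features(discretize(img2, m, 2))
        assert f1["Coarseness"] == pytest.approx(f2["Coarseness"], rel=1e-12)
        assert f1["Complexity"] == pytest.approx(f2["Complexity"], rel=1e-12)

    def test_busyness_monotone_in_noise(self):
        """With equal-width binning over the in-mask range, added noise is
        range-normalized away and Busyness falls strictly and monotonically
        as the noise level rises (means over 10 seeded phantoms)."""
        means = []
        for sd in (1.0, 2.0, 4.0, 8.0):
            vals = []
            for seed in range(10):
                p = PhantomParams(
                    grid_shape=(36, 36, 24), voxel_spacing=(0.25, 0.25, 0.5),
                    tumor_diameters=(4, 4, 5), noise_sd=sd, seed=seed,
                )
                img, mask = generate_phantom(p)
                vals.append(ngtdm_features(discretize(img, mask, 32))["Busyness"])
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestGLRLM:
    def test_strip_hand_enumeration(self):
        img, m = _voi(np.array([[0.0, 0.0, 10.0]]))
        d = discretize(img, m, 2)
        g = build_glrlm(d, directions=((0, 1, 0),))
        # one run (level 1, length 2), one run (level 2, length 1)
        assert g[0, 1] == 1 and g[1, 0] == 1
        assert g.sum() == 2

    def test_constant_strip_single_run(self):
        n = 4
        img, m = _voi(np.full((1, n), 3.0))
        d = discretize(img, m, 2)
        g = build_glrlm(d, directions=((0, 1, 0),))
        assert g[0, n - 1] == 1 and g.sum() == 1
        f = glrlm_features(g, n_voxels=n, n_directions=1)
        assert f["Short-Run Emphasis"] == pytest.approx(1 / n**2)
        assert f["Long-Run Emphasis"] == pytest.approx(n**2)
        assert f["Run Percentage"] == pytest.approx(1 / n)

    def test_single_run_of_length_one(self):
        g = np.zeros((2, 1))
        g[0, 0] = 1
        f = glrlm_features(g, n_voxels=1, n_directions=1)
        assert f["Short-Run Emphasis"] == 1.0
        assert f["Long-Run Emphasis"] == 1.0
        assert f["Run Percentage"] == 1.0

    def test_run_mass_conservation_per_direction(self):
        rng = np.random.default_rng(11)
        img, m = _voi(rng.integers(0, 6, size=(7, 6, 3)).astype(float),
                      mask=rng.random((7, 6, 3)) < 0.7)
        d = discretize(img, m, 4)
        for direction in DIRECTIONS_13:
            g = build_glrlm(d, directions=(direction,))
            lengths = np.arange(1, g.shape[1] + 1)
            assert (g * lengths).sum() == d.n_voxels
        merged = build_glrlm(d)
        lengths = np.arange(1, merged.shape[1] + 1)
        assert (merged * lengths).sum() == 13 * d.n_voxels

    def test_sre_lre_weight_bounds(self):
        rng = np.random.default_rng(13)
        img, m = _voi(rng.integers(0, 8, size=(5, 5, 4)).astype(float))
        g = build_glrlm(discretize(img, m, 8))
        f = glrlm_features(g, n_voxels=100)
        assert f["Short-Run Emphasis"] <= 1.0 <= f["Long-Run Emphasis"]


class TestGLSZM:
    def test_constant_connected_voi(self):
        n = 3 * 3 * 2
        img, m = _voi(np.full((3, 3, 2), 2.0))
        d = discretize(img, m, 4)
        g = build_glszm(d)
        assert g.sum() == 1 and g[0, n - 1] == 1
        f = glszm_features(g, n_voxels=n)
        assert f["Zone Percentage"] == pytest.approx(1 / n)

    def test_checkerboard_matches_flood_fill_oracle(self):
        # 26-connectivity links equal-parity diagonals: the two-level 4x4x4
        # checkerboard forms exactly 2 zones of size 32, not 64 singletons
        x, y, z = np.indices((4, 4, 4))
        cb = ((x + y + z) % 2 + 1).astype(float)
        mask = np.ones((4, 4, 4), dtype=bool)
        img, m = _voi(cb)
        got = build_glszm(discretize(img, m, 2))
        exp = ref_glszm(ref_discretize(cb, mask, 2), mask, 2)
        assert np.array_equal(got, exp)
        assert got.sum() == 2 and got[0, 31] == 1 and got[1, 31] == 1

    def test_zone_mass_conservation(self):
        rng = np.random.default_rng(17)
        mask = rng.random((6, 6, 4)) < 0.6
        mask[0, 0, 0] = True
        img, m = _voi(rng.integers(0, 5, size=(6, 6, 4)).astype(float), mask=mask)
        d = discretize(img, m, 5)
        g = build_glszm(d)
        sizes = np.arange(1, g.shape[1] + 1)
        assert (g * sizes).sum() == d.n_voxels

    def test_single_zone_of_size_one(self):
        g = np.zeros((1, 1))
        g[0, 0] = 1
        f = glszm_features(g, n_voxels=1)
        for name in ("Short-Zone Emphasis", "Long-Zone Emphasis",
                     "Low Gray-Level Zone Emphasis", "High Gray-Level Zone Emphasis",
                     "Zone Percentage"):
            assert f[name] == pytest.approx(1.0)


class TestPrimaryFeatures:
    def test_constant_voi(self):
        img, m = _voi(np.full((3, 3, 2), 9.0))
        d = discretize(img, m, 8)
        f = primary_features(img, m, d)
        assert f["Entropy"] == 0.0
        assert f["Deviation"] == 0.0
        assert f["Intensity Variance"] == 0.0
        assert np.isnan(f["Kurtosis"])

    def test_two_equiprobable_levels_one_bit(self):
        img, m = _voi(np.array([[0.0, 10.0, 0.0, 10.0]]))
        d = discretize(img, m, 2)
        f = primary_features(img, m, d)
        assert f["Entropy"] == pytest.approx(1.0)

    def test_max_diameter_345_triangle(self):
        mask = np.zeros((5, 6, 2), dtype=bool)
        mask[0, 0, 0] = True
        mask[3, 4, 0] = True
        m = VOIMask(mask, (1.0, 1.0, 1.0))
        assert max_diameter(m) == pytest.approx(5.0)

    def test_max_diameter_uses_physical_spacing(self):
        mask = np.zeros((4, 1, 1), dtype=bool)
        mask[0, 0, 0] = mask[3, 0, 0] = True
        assert max_diameter(VOIMask(mask, (0.5, 1.0, 1.0))) == pytest.approx(1.5)


class TestExtractAll:
    def test_panel_has_exactly_39_named_features(self):
        p = PhantomParams(grid_shape=(36, 36, 16), voxel_spacing=(0.25, 0.25, 0.5),
                          tumor_diameters=(3.0, 4.0, 5.0), seed=2)
        img, m = generate_phantom(p)
        vec = extract_all(img, m)
        assert len(vec) == 39
        assert list(vec.index) == list(FEATURE_NAMES)

    def test_deterministic(self):
        p = PhantomParams(grid_shape=(36, 36, 16), voxel_spacing=(0.25, 0.25, 0.5),
                          tumor_diameters=(3.0, 4.0, 5.0), seed=4)
        img, m = generate_phantom(p)
        v1 = extract_all(img, m)
        v2 = extract_all(img, m)
        assert np.array_equal(v1.to_numpy(), v2.to_numpy())

    def test_misaligned_grids_rejected(self):
        img = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        m = VOIMask(np.ones((4, 4, 3), bool), (1, 1, 1))
        with pytest.raises(Exception, match="shape"):
            extract_all(img, m)

    def test_intensity_shift_invariance(self):
        """Adding a constant shifts Mean/Max/Min/Sum and nothing else."""
        rng = np.random.default_rng(23)
        vals = rng.normal(50, 10, size=(7, 6, 5))
        mask = rng.random((7, 6, 5)) < 0.7
        img1, m = _voi(vals, mask=mask)
        img2, _ = _voi(vals + 123.4, mask=mask)
        v1 = extract_all(img1, m, TextureParams(n_bins=8))
        v2 = extract_all(img2, m, TextureParams(n_bins=8))
        shifted = {"Mean", "Max", "Min", "Sum"}
        for name in FEATURE_NAMES:
            if name in shifted:
                assert v2[name] == pytest.approx(v1[name] + 123.4 * (1 if name != "Sum" else mask.sum()), rel=1e-9)
            else:
                assert v2[name] == pytest.approx(v1[name], rel=1e-9, abs=1e-12), name

    def test_entropy_nondecreasing_in_noise(self):
        """Rank association of Entropy with noise level is non-negative."""
        from scipy.stats import spearmanr

        sds = np.linspace(0.5, 16, 10)
        ents = []
        for i, sd in enumerate(sds):
            p = PhantomParams(
                grid_shape=(36, 36, 24), voxel_spacing=(0.25, 0.25, 0.5),
                tumor_diameters=(4, 4, 5), noise_sd=float(sd), seed=100 + i,
            )
            img, m = generate_phantom(p)
            ents.append(extract_all(img, m)["Entropy"])
        rho = spearmanr(sds, ents).statistic
        assert rho >= 0

    def test_average_direction_mode_runs(self):
        p = PhantomParams(grid_shape=(24, 24, 14), voxel_spacing=(0.25, 0.25, 0.5),
                          tumor_diameters=(2.0, 3.0, 4.0), seed=6)
        img, m = generate_phantom(p)
        vec = extract_all(img, m, TextureParams(direction_mode="average"))
        assert len(vec) == 39
        assert np.isfinite(vec.drop(["Correlation"]).to_numpy()).all()
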