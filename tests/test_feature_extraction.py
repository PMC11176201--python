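"""Feature extraction: quantization edges, GLCM against a brute-force pair
oracle and skimage, Haralick worked values and reference agreement,
windowed texture degeneracies and rotation consistency, morphometry
against analytic phantoms, intensity closed forms, table assembly."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wallrad.core import CaseRecord, FeatureDescriptor, VolumeImage, WallMask, WallRadError
from wallrad.feature_extraction import (
    ANGLE_OFFSETS_2D,
    TextureConfig,
    assemble_feature_table,
    clinical_features,
    extract_case_features,
    glcm,
    haralick,
    intensity_features,
    morphological_features,
    quantize,
    robust_range,
    windowed_texture,
)

from conftest import TINY_TEXTURE


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_glcm(levels, mask, offset, b, symmetric):
    """Enumerate every voxel pair explicitly."""
    counts = np.zeros((b, b))
    it = np.ndindex(*levels.shape)
    for pos in it:
        q = tuple(p + o for p, o in zip(pos, offset))
        if any(not (0 <= qi < n) for qi, n in zip(q, levels.shape)):
            continue
        if not (mask[pos] and mask[q]):
            continue
        counts[levels[pos], levels[q]] += 1
        if symmetric:
            counts[levels[q], levels[pos]] += 1
    return counts


def reference_haralick(p, feature):
    """Direct double-loop implementation of the textbook formulas."""
    b = p.shape[0]
    mu_x = sum(i * p[i, j] for i in range(b) for j in range(b))
    mu_y = sum(j * p[i, j] for i in range(b) for j in range(b))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * p[i, j] for i in range(b) for j in range(b)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * p[i, j] for i in range(b) for j in range(b)))
    total = 0.0
    for i in range(b):
        for j in range(b):
            v = p[i, j]
            if feature == "contrast":
                total += v * (i - j) ** 2
            elif feature == "dissimilarity":
                total += v * abs(i - j)
            elif feature == "homogeneity":
                total += v / (1 + (i - j) ** 2)
            elif feature == "energy":
                total += v * v
            elif feature == "entropy":
                total += -v * math.log2(v) if v > 0 else 0.0
            elif feature == "correlation":
                if sd_x > 1e-12 and sd_y > 1e-12:
                    total += (i - mu_x) * (j - mu_y) * v / (sd_x * sd_y)
            elif feature == "variance":
                total += v * (i - mu_x) ** 2
            elif feature == "sum-average":
                total += v * (i + j)
            elif feature == "cluster-shade":
                total += v * (i + j - mu_x - mu_y) ** 3
            elif feature == "cluster-prominence":
                total += v * (i + j - mu_x - mu_y) ** 4
    return total


# ---------------------------------------------------------------------------


class TestQuantize:
    def test_exact_levels(self):
        np.testing.assert_array_equal(
            quantize(np.array([0.0, 1.0, 2.0, 3.0]), 4, (0, 3)), [0, 1, 2, 3]
        )

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(quantize(np.full(5, 9.9), 8, (9.9, 9.9)), np.zeros(5))

    def test_equal_width_edges(self):
        # range [0, 99] in 8 bins: edges at multiples of 99/8 = 12.375
        vals = np.arange(100, dtype=float)
        levels = quantize(vals, 8, (0, 99))
        expected = np.minimum(np.floor(vals / 12.375), 7).astype(int)
        np.testing.assert_array_equal(levels, expected)

    def test_clipping_outside_range(self):
        levels = quantize(np.array([-5.0, 200.0]), 4, (0, 10))
        np.testing.assert_array_equal(levels, [0, 3])

    def test_rejects_single_bin(self):
        with pytest.raises(WallRadError):
            quantize(np.arange(4.0), 1)


class TestQuantizeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        vals=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
        bins=st.integers(2, 64),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_levels_bounded_and_monotone(self, vals, bins):
        x = np.array(vals)
        levels = quantize(x, bins, (float(x.min()), float(x.max())))
        assert levels.min() >= 0 and levels.max() <= bins - 1
        order = np.argsort(x, kind="mergesort")
        assert (np.diff(levels[order]) >= 0).all()


class TestGLCM:
    def test_worked_three_by_three(self):
        img = np.array([[0, 0, 1], [0, 0, 1], [0, 2, 2]])
        P = glcm(img, None, 0.0, 1, n_levels=3, symmetric=True, normalize=True)
        expected = np.array([[4, 2, 1], [2, 0, 0], [1, 0, 2]]) / 12.0
        np.testing.assert_allclose(P, expected)

    def test_constant_image_single_diagonal_entry(self):
        P = glcm(np.zeros((4, 4), int), None, 0.0, 1, n_levels=3, normalize=True)
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    def test_symmetric_equals_transpose(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, (6, 6))
        P = glcm(a, None, 45.0, 2, n_levels=4, symmetric=True, normalize=False)
        np.testing.assert_array_equal(P, P.T)

    def test_no_valid_pairs_returns_zero_matrix(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = True  # single voxel: no pair at any offset
        P = glcm(np.zeros((4, 4), int), m, 0.0, 1, n_levels=2)
        assert P.sum() == 0

    @pytest.mark.parametrize("symmetric", [False, True])
    def test_brute_force_oracle_2d_and_3d(self, symmetric):
        rng = np.random.default_rng(42)
        offsets_2d = list(ANGLE_OFFSETS_2D.values())
        offsets_3d = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (-1, 1, 1)]
        for trial in range(30):
            if trial % 2 == 0:
                shape, offsets = (rng.integers(2, 9), rng.integers(2, 9)), offsets_2d
            else:
                shape, offsets = (
                    rng.integers(2, 9), rng.integers(2, 9), rng.integers(1, 4),
                ), offsets_3d
            b = int(rng.integers(2, 6))
            levels = rng.integers(0, b, shape)
            mask = rng.random(shape) < 0.8
            d = int(rng.integers(1, 3))
            for direction in offsets:
                offset = tuple(d * c for c in direction)
                mine = glcm(
                    levels, mask, direction, d, n_levels=b,
                    symmetric=symmetric, normalize=False,
                )
                oracle = brute_force_glcm(levels, mask, offset, b, symmetric)
                np.testing.assert_array_equal(mine, oracle)

    def test_skimage_cross_check(self):
        # independent library as oracle on unmasked arrays; wallrad's 45/135
        # labels map to skimage's 135/45 (skimage offsets use +sin(theta)
        # with the row axis pointing down)
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(1)
        pairs = [(0.0, 0.0), (90.0, np.pi / 2), (45.0, 3 * np.pi / 4), (135.0, np.pi / 4)]
        for _ in range(10):
            a = rng.integers(0, 5, (7, 6))
            for ang, skang in pairs:
                mine = glcm(a, None, ang, 1, n_levels=5, symmetric=True, normalize=False)
                sk = graycomatrix(a, [1], [skang], levels=5, symmetric=True)[:, :, 0, 0]
                np.testing.assert_array_equal(mine, sk)


class TestHaralick:
    def test_constant_image_values(self):
        P = glcm(np.zeros((5, 5), int), None, 0.0, 1, n_levels=4, normalize=True)
        assert haralick(P, "contrast") == 0.0
        assert haralick(P, "energy") == 1.0
        assert haralick(P, "entropy") == 0.0

    def test_worked_example_values(self):
        img = np.array([[0, 0, 1], [0, 0, 1], [0, 2, 2]])
        P = glcm(img, None, 0.0, 1, n_levels=3, normalize=True)
        assert haralick(P, "contrast") == pytest.approx(1.0)
        assert haralick(P, "energy") == pytest.approx(30.0 / 144.0)

    def test_checkerboard_maximal_contrast(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        P = glcm(board, None, 0.0, 1, n_levels=2, normalize=True)
        assert haralick(P, "contrast") == pytest.approx(1.0)
        assert haralick(P, "energy") == pytest.approx(reference_haralick(P, "energy"))

    def test_empty_matrix_gives_nan(self):
        assert math.isnan(haralick(np.zeros((3, 3)), "contrast"))

    @pytest.mark.parametrize("feature", [
        "contrast", "dissimilarity", "homogeneity", "energy", "entropy",
        "correlation", "variance", "sum-average", "cluster-shade",
        "cluster-prominence",
    ])
    def test_reference_agreement_on_random_matrices(self, feature):
        rng = np.random.default_rng(7)
        for _ in range(20):
            b = int(rng.integers(2, 9))
            raw = rng.random((b, b))
            raw[rng.random((b, b)) < 0.3] = 0.0
            if raw.sum() == 0:
                continue
            p = raw / raw.sum()
            assert haralick(p, feature) == pytest.approx(
                reference_haralick(p, feature), abs=1e-6
            )

    def test_skimage_graycoprops_agreement(self):
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(8)
        a = rng.integers(0, 8, (20, 20))
        P = glcm(a, None, 0.0, 1, n_levels=8, symmetric=True, normalize=True)
        gm = graycomatrix(a, [1], [0.0], levels=8, symmetric=True, normed=True)
        for mine_name, sk_name in [
            ("contrast", "contrast"), ("dissimilarity", "dissimilarity"),
            ("homogeneity", "homogeneity"), ("correlation", "correlation"),
            ("energy", "ASM"),
        ]:
            assert haralick(P, mine_name) == pytest.approx(
                float(graycoprops(gm, sk_name)[0, 0]), abs=1e-6
            )


def shell_case(n=28, R=9.0, r=5.5, fill=400.0, seed=None):
    g = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    d2 = sum((gi - c) ** 2 for gi in g)
    shell = ((d2 <= R**2) & (d2 > r**2)).astype(np.uint8)
    if seed is None:
        data = np.full((n, n, n), fill)
    else:
        data = np.random.default_rng(seed).uniform(0, 4095, (n, n, n))
    return (
        VolumeImage(data=data, spacing=(1, 1, 1)),
        WallMask(data=shell, spacing=(1, 1, 1)),
    )


class TestWindowedTexture:
    def test_homogeneous_wall_degenerate_values(self):
        image, mask = shell_case()
        cfg = TextureConfig(
            angles_deg=(0.0, 90.0), distances=(1,), bins=(8,), windows=(5,),
        )
        desc, vals = windowed_texture(image, mask, cfg)
        by_name = dict(zip((d.name for d in desc), vals))
        for d in desc:
            if d.haralick == "contrast":
                assert by_name[d.name] == 0.0
            if d.haralick == "energy":
                assert by_name[d.name] == 1.0

    def test_mask_thinner_than_window_all_sentinel(self):
        image, mask = shell_case(seed=1)
        cfg = TextureConfig(
            angles_deg=(0.0,), distances=(1,), bins=(8,), windows=(15,),
            min_in_mask_fraction=1.0,
        )
        _, vals = windowed_texture(image, mask, cfg)
        assert np.isnan(vals).all()

    def test_rotation_consistency_in_plane(self):
        """Mean over the four in-plane angles is invariant to 90-degree
        rotation of image and mask together."""
        image, mask = shell_case(seed=2)
        cfg = TextureConfig(distances=(1, 2), bins=(8,), windows=(5,))
        rng_range = robust_range(image.data[mask.data.astype(bool)])
        desc, vals = windowed_texture(image, mask, cfg, value_range=rng_range)
        rot_image = VolumeImage(data=np.rot90(image.data, axes=(0, 1)).copy(), spacing=(1, 1, 1))
        rot_mask = WallMask(data=np.rot90(mask.data, axes=(0, 1)).copy(), spacing=(1, 1, 1))
        desc_r, vals_r = windowed_texture(rot_image, rot_mask, cfg, value_range=rng_range)
        names = [d.name for d in desc]
        v = dict(zip(names, vals))
        vr = dict(zip([d.name for d in desc_r], vals_r))
        for d in (1, 2):
            for w in (5,):
                for f in cfg.features:
                    cols = [f"{f}_a{a:g}_d{d}_b8_w{w}" for a in (0, 45, 90, 135)]
                    mean_orig = np.mean([v[c] for c in cols])
                    mean_rot = np.mean([vr[c] for c in cols])
                    assert mean_orig == pytest.approx(mean_rot, abs=1e-9)

    def test_morphology_texture_separation(self):
        """Changing wall texture with a fixed mask leaves morphological
        columns bit-identical."""
        image_a, mask = shell_case(seed=3)
        image_b, _ = shell_case(seed=4)
        assert morphological_features(mask) == morphological_features(mask)
        record = CaseRecord(case_id="x", image_ref=None, mask_ref=None,
                            age=65, bmi=27.0, prostate_size=45.0, ipss=3)
        da, va = extract_case_features(image_a, mask, record, TINY_TEXTURE)
        db, vb = extract_case_features(image_b, mask, record, TINY_TEXTURE)
        morph_idx = [i for i, d in enumerate(da) if d.category == "morphological"]
        np.testing.assert_array_equal(va[morph_idx], vb[morph_idx])
        tex_idx = [i for i, d in enumerate(da) if d.category == "texture"]
        assert not np.array_equal(va[tex_idx], vb[tex_idx])


class TestMorphology:
    def test_hollow_sphere_analytic_volume_and_thickness(self):
        n, R, r = 50, 20.0, 16.0
        g = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        d2 = sum((gi - c) ** 2 for gi in g)
        shell = ((d2 <= R**2) & (d2 > r**2)).astype(np.uint8)
        feats = morphological_features(WallMask(data=shell, spacing=(1, 1, 1)))
        analytic = 4.0 / 3.0 * math.pi * (R**3 - r**3)
        assert feats["morph_wall_volume_mm3"] == pytest.approx(analytic, rel=0.05)
        assert feats["morph_thickness_mean_mm"] == pytest.approx(4.0, abs=1.0)
        assert 0.8 < feats["morph_sphericity"] <= 1.05

    def test_spacing_scaling_units(self):
        _, mask = shell_case()
        f1 = morphological_features(mask, spacing=(1, 1, 1))
        f2 = morphological_features(mask, spacing=(2, 2, 2))
        assert f2["morph_wall_volume_mm3"] == pytest.approx(8 * f1["morph_wall_volume_mm3"])
        assert f2["morph_thickness_mean_mm"] == pytest.approx(
            2 * f1["morph_thickness_mean_mm"], rel=1e-9
        )

    def test_non_shell_rejected(self):
        solid = np.zeros((10, 10, 10), np.uint8)
        solid[3:7, 3:7, 3:7] = 1
        with pytest.raises(WallRadError, match="hollow shell"):
            morphological_features(WallMask(data=solid, spacing=(1, 1, 1)))


class TestIntensity:
    def test_constant_wall(self):
        image, mask = shell_case(fill=123.0)
        f = intensity_features(image, mask)
        assert f["int_mean"] == f["int_median"] == 123.0
        assert f["int_sd"] == 0.0
        assert f["int_hist_entropy"] == 0.0

    def test_two_value_wall_closed_form(self):
        image, mask = shell_case()
        data = image.data.copy()
        idx = np.argwhere(mask.data)
        half = len(idx) // 2
        data[tuple(idx[:half].T)] = 0.0
        data[tuple(idx[half:].T)] = 4095.0
        f = intensity_features(image.with_data(data), mask)
        if len(idx) % 2 == 0:
            assert f["int_mean"] == pytest.approx(2047.5)
            assert f["int_hist_entropy"] == pytest.approx(1.0)  # one bit

    def test_percentiles_ordered(self):
        image, mask = shell_case(seed=5)
        f = intensity_features(image, mask)
        assert f["int_p5"] <= f["int_p25"] <= f["int_median"] <= f["int_p75"] <= f["int_p95"]


class TestClinicalAndAssembly:
    def test_clinical_passthrough_order(self):
        rec = CaseRecord(case_id="x", image_ref=None, mask_ref=None,
                         age=65, bmi=27.1, prostate_size=45, ipss=3)
        assert list(clinical_features(rec).items()) == [
            ("clin_age", 65.0), ("clin_prostate_size", 45.0), ("clin_bmi", 27.1),
        ]

    def _descriptors(self, k):
        return [FeatureDescriptor(name=f"int_f{j}", category="intensity") for j in range(k)]

    def test_sentinel_imputed_with_column_median(self):
        rows = np.array([[1.0, 5.0], [np.nan, 7.0], [3.0, 9.0]])
        table = assemble_feature_table(["a", "b", "c"], self._descriptors(2), rows)
        assert table.values[1, 0] == 2.0  # median of {1, 3}
        assert np.isfinite(table.values).all()

    def test_majority_sentinel_column_dropped(self):
        rows = np.array([[np.nan, 5.0], [np.nan, 7.0], [3.0, 9.0]])
        table = assemble_feature_table(["a", "b", "c"], self._descriptors(2), rows)
        assert table.n_features == 1
        assert table.feature_names == ("int_f1",)

    def test_row_independence(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(4, 3))
        full = assemble_feature_table(list("abcd"), self._descriptors(3), rows.copy())
        reduced = assemble_feature_table(list("abd"), self._descriptors(3),
                                         rows[[0, 1, 3]].copy())
        np.testing.assert_array_equal(full.values[[0, 1, 3]], reduced.values)

    def test_column_count_is_config_product(self):
        cfg = TextureConfig(distances=(1, 2), bins=(8,), windows=(5,),
                            features=("contrast", "energy"))
        assert cfg.n_columns() == 4 * 2 * 1 * 1 * 2
        image, mask = shell_case(seed=6)
        desc, vals = windowed_texture(image, mask, cfg)
        assert len(desc) == cfg.n_columns() == len(vals)
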