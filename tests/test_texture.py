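import numpy as np
import pytest
from scipy.stats import kruskal

from octprofiler.errors import TextureError
from octprofiler.phantom import PhantomConfig, make_phantom
from octprofiler.roi import RoiPatch
from octprofiler.texture import (
    FEATURES,
    GlcmConfig,
    box_features,
    glcm,
    glcm_features,
    quantize_levels,
    sectioned_features,
)
from oracles import glcm_brute_force, glcm_features_brute_force

# values mapping onto levels {0,1,2,3} under 4-level quantization of [0,256)
L = {0: 0, 1: 64, 2: 128, 3: 192}


def _img(level_rows):
    return np.array([[L[v] for v in row] for row in level_rows], dtype=np.uint8)


class TestGlcm:
    def test_constant_box_single_entry(self):
        P = glcm(np.full((8, 8), 100, dtype=np.uint8), d=2, angle=0, levels=16)
        assert P.sum() == pytest.approx(1.0)
        assert np.count_nonzero(P) == 1
        assert P.max() == pytest.approx(1.0)

    def test_hand_enumerated_pairs_4x4(self):
        img = _img([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        P = glcm(img, d=1, angle=0, levels=4)
        # 12 horizontal pairs, enumerated by hand
        expected = np.zeros((4, 4))
        expected[0, 0] = 2 / 12  # rows 0,1: (0,0)
        expected[0, 1] = 2 / 12  # rows 0,1: (0,1)
        expected[1, 1] = 2 / 12  # rows 0,1: (1,1)
        expected[0, 2] = 1 / 12  # row 2: (0,2)
        expected[2, 2] = 3 / 12  # row 2: (2,2) x2, row 3: (2,2)
        expected[2, 3] = 1 / 12  # row 3: (2,3)
        expected[3, 3] = 1 / 12  # row 3: (3,3)
        assert np.allclose(P, expected)

    def test_opposite_angles_transpose(self, rng):
        box = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        for a, b in [(0, 180), (90, 270)]:
            Pa = glcm(box, d=3, angle=a, levels=16)
            Pb = glcm(box, d=3, angle=b, levels=16)
            assert np.allclose(Pa, Pb.T)

    def test_box_too_small_for_offset_rejected(self):
        with pytest.raises(TextureError):
            glcm(np.zeros((4, 4), dtype=np.uint8), d=5, angle=0, levels=8)

    @pytest.mark.parametrize("angle", [0, 90, 180, 270])
    def test_matches_brute_force_enumeration(self, rng, angle):
        for _ in range(25):
            box = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
            d = int(rng.integers(1, 4))
            P = glcm(box, d=d, angle=angle, levels=8)
            assert np.allclose(P, glcm_brute_force(box, d, angle, 8), atol=1e-12)


class TestGlcmFeatures:
    def test_constant_box_features(self):
        P = glcm(np.full((8, 8), 100, dtype=np.uint8), d=2, angle=0, levels=16)
        f = glcm_features(P)
        assert f.contrast == 0.0
        assert f.dissimilarity == 0.0
        assert f.homogeneity == pytest.approx(1.0)
        assert f.energy == pytest.approx(1.0)
        assert f.correlation == 1.0 and not f.correlation_defined

    def test_diagonal_two_level_matrix(self):
        f = glcm_features(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert f.contrast == 0.0
        assert f.dissimilarity == 0.0
        assert f.energy == pytest.approx(np.sqrt(0.5))
        assert f.correlation == pytest.approx(1.0)

    def test_antidiagonal_two_level_matrix(self):
        f = glcm_features(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert f.contrast == pytest.approx(1.0)
        assert f.dissimilarity == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(TextureError):
            glcm_features(np.array([[1.0, 1.0], [0.0, 1.0]]))

    def test_matches_brute_force_features(self, rng):
        for _ in range(50):
            box = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
            P = glcm(box, d=2, angle=0, levels=8)
            mine = glcm_features(P).as_dict()
            ref = glcm_features_brute_force(P)
            for name in FEATURES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_transpose_invariance_of_all_features(self, rng):
        box = rng.integers(0, 256, size=(15, 15)).astype(np.uint8)
        P = glcm(box, d=2, angle=0, levels=16)
        f, ft = glcm_features(P).as_dict(), glcm_features(P.T).as_dict()
        for name in FEATURES:
            assert f[name] == pytest.approx(ft[name], abs=1e-12)

    def test_linear_features_match_symmetric_glcm(self, rng):
        # contrast/dissimilarity/homogeneity are linear in P with
        # transpose-symmetric kernels, so averaging the {0, 180} pair
        # equals evaluating the symmetrized matrix
        box = rng.integers(0, 256, size=(15, 15)).astype(np.uint8)
        P0 = glcm(box, d=2, angle=0, levels=16)
        P180 = glcm(box, d=2, angle=180, levels=16)
        f_avg = {
            n: 0.5 * (glcm_features(P0).as_dict()[n] + glcm_features(P180).as_dict()[n])
            for n in FEATURES
        }
        f_sym = glcm_features((P0 + P180) / 2).as_dict()
        for name in ("contrast", "dissimilarity", "homogeneity"):
            assert f_avg[name] == pytest.approx(f_sym[name], abs=1e-12)

    def test_agrees_with_skimage_angle_average(self, rng):
        # independent cross-check: averaging over all four axis
        # directions is convention-free, so compare angle-averaged
        # features against scikit-image's implementation
        from skimage.feature import graycomatrix, graycoprops

        name_map = {
            "contrast": "contrast",
            "dissimilarity": "dissimilarity",
            "homogeneity": "homogeneity",
            "energy": "energy",
            "correlation": "correlation",
        }
        for _ in range(10):
            box = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
            q = quantize_levels(box, 16).astype(np.uint8)
            mine = box_features(box, GlcmConfig(distance_d=2, levels=16, box_px=20))
            sk = graycomatrix(
                q, [2], [0, np.pi / 2, np.pi, 3 * np.pi / 2], levels=16, normed=True
            )
            for ours, theirs in name_map.items():
                sk_avg = graycoprops(sk, theirs).mean()
                assert mine[ours] == pytest.approx(sk_avg, rel=1e-10), ours

    def test_energy_decreases_with_gray_level_entropy(self, rng):
        energies = []
        for n_levels in [1, 2, 4, 16]:
            vals = (rng.integers(0, n_levels, size=(20, 20)) * (256 // max(n_levels, 1))).astype(
                np.uint8
            )
            P = glcm(vals, d=1, angle=0, levels=64)
            energies.append(glcm_features(P).energy)
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_requantization_never_increases_contrast(self, rng):
        for _ in range(10):
            box = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            contrasts = [
                glcm_features(glcm(box, d=2, angle=0, levels=lv)).contrast
                for lv in [64, 32, 16, 8]
            ]
            assert all(a >= b - 1e-12 for a, b in zip(contrasts, contrasts[1:]))


def _flat_patch(pixels, label="lesion"):
    return RoiPatch(pixels=pixels, origin_col=0, label=label, flattened=True)


class TestSectionedFeatures:
    def test_tiling_counts(self, rng):
        patch = _flat_patch(rng.integers(0, 256, size=(75, 100)).astype(np.uint8))
        summary = sectioned_features(patch, GlcmConfig())
        assert sorted(summary.per_box["section"].unique()) == [0, 1, 2]
        assert (summary.per_box.groupby("section").size() == 4).all()
        assert (summary.summary["n_boxes"] == 4).all()

    def test_unflattened_patch_rejected(self, rng):
        patch = RoiPatch(
            pixels=rng.integers(0, 256, size=(75, 100)).astype(np.uint8),
            origin_col=0,
            label="lesion",
        )
        with pytest.raises(TextureError):
            sectioned_features(patch)

    def test_narrow_patch_names_failing_section(self, rng):
        patch = _flat_patch(rng.integers(0, 256, size=(75, 20)).astype(np.uint8))
        with pytest.raises(TextureError, match="section 0"):
            sectioned_features(patch, GlcmConfig())

    def test_shallow_patch_rejected(self, rng):
        patch = _flat_patch(rng.integers(0, 256, size=(60, 100)).astype(np.uint8))
        with pytest.raises(TextureError):
            sectioned_features(patch, GlcmConfig())

    def test_homogeneous_noise_has_no_depth_trend(self):
        # i.i.d. texture: section medians differ only by sampling noise
        rng = np.random.default_rng(99)
        medians = {0: [], 1: [], 2: []}
        for _ in range(20):
            patch = _flat_patch(rng.integers(0, 256, size=(75, 100)).astype(np.uint8))
            summary = sectioned_features(patch, GlcmConfig())
            for s in range(3):
                medians[s].append(summary.section_median(s, "contrast"))
        stat, p = kruskal(medians[0], medians[1], medians[2])
        assert p > 0.01

    def test_rough_lesion_texture_raises_contrast(self):
        # lesion speckle rougher than healthy: lesion contrast median
        # exceeds the healthy one in the most superficial section
        cfg = PhantomConfig(
            seed=21,
            healthy_mu_t=0.8,
            lesion_mu_t=0.8,  # same attenuation: difference is texture only
            speckle_shape=50.0,
            lesion_speckle_shape=3.0,
        )
        bscan, _, annotation, truth = make_phantom(cfg)
        from octprofiler.delimitation import LesionBounds
        from octprofiler.roi import flatten, healthy_adjacent_roi, lesion_center_roi, truncate_depth

        bounds = LesionBounds(*truth.lesion_cols, "bscan")
        lesion = truncate_depth(flatten(lesion_center_roi(bscan, bounds), annotation), 75)
        healthy = truncate_depth(
            flatten(healthy_adjacent_roi(bscan, bounds)[0], annotation), 75
        )
        tex_l = sectioned_features(lesion, GlcmConfig())
        tex_h = sectioned_features(healthy, GlcmConfig())
        assert tex_l.section_median(0, "contrast") > tex_h.section_median(0, "contrast")


class TestGlcmConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"distance_d": 0},
            {"distance_d": 25, "box_px": 25},
            {"levels": 1},
            {"levels": 500},
            {"angles": (45,)},
            {"sections": ((10, 5),)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(TextureError):
            GlcmConfig(**kwargs)
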