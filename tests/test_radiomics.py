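import numpy as np
import pytest

from aneuhemo.fields import LabeledImageVolume
from aneuhemo.radiomics import (
    discretize,
    extract_feature_vector,
    first_order,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    FEATURE_NAMES,
)
from aneuhemo.radiomics.ngtdm import COARSENESS_SENTINEL
from conftest import random_roi_image


def image_from(voxels, mask=None, spacing=(1.0, 1.0, 1.0)):
    voxels = np.asarray(voxels, dtype=float)
    if mask is None:
        mask = np.ones(voxels.shape, dtype=bool)
    return LabeledImageVolume(voxels, spacing, {"roi": np.asarray(mask, bool)})


class TestDiscretize:
    def test_constant_roi_single_level(self):
        img = image_from(np.full((3, 3, 3), 7.0))
        d = discretize(img, "roi", n_bins=32)
        assert d.ng == 1
        assert (d.level_values() == 1).all()

    def test_midpoint_split(self):
        img = image_from(np.array([0.0, 1.0, 2.0, 3.0]).reshape(4, 1, 1))
        d = discretize(img, "roi", n_bins=2)
        np.testing.assert_array_equal(d.level_values(), [1, 1, 2, 2])

    def test_fixed_bin_width(self):
        img = image_from(np.array([0.0, 0.9, 1.0, 2.5]).reshape(4, 1, 1))
        d = discretize(img, "roi", policy="fixed_bin_width", bin_width=1.0)
        np.testing.assert_array_equal(d.level_values(), [1, 1, 2, 3])

    def test_uniform_histogram(self, rng):
        vox = rng.random((12, 12, 12))
        img = image_from(vox)
        d = discretize(img, "roi", n_bins=32)
        counts = np.bincount(d.level_values(), minlength=33)[1:]
        expected = vox.size / 32
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 80  # df=31, very loose sanity bound

    def test_bad_params(self):
        img = image_from(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            discretize(img, "roi", n_bins=0)
        with pytest.raises(ValueError):
            discretize(img, "roi", policy="fixed_bin_width", bin_width=0.0)


class TestFirstOrder:
    def test_constant_block(self):
        f = first_order(np.full(8, 5.0), voxel_volume=2.0)
        assert f["Mean"] == 5.0
        assert f["Minimum"] == 5.0
        assert f["RMS"] == 5.0
        assert f["Energy"] == 200.0
        assert f["Total Energy"] == 400.0

    def test_signed_values(self):
        f = first_order(np.array([-1.0, 1.0]), voxel_volume=1.0)
        assert f["Mean"] == 0.0
        assert f["RMS"] == 1.0
        assert f["Energy"] == 2.0

    def test_random_matches_bruteforce(self, rng):
        x = rng.standard_normal(100)
        f = first_order(x, voxel_volume=1.7)
        assert f["Mean"] == pytest.approx(sum(x) / len(x))
        assert f["Energy"] == pytest.approx(sum(v * v for v in x))
        assert f["Total Energy"] == pytest.approx(1.7 * sum(v * v for v in x))

    def test_intensity_shift(self):
        f = first_order(np.array([1.0, 2.0]), voxel_volume=1.0, shift=10.0)
        assert f["Energy"] == pytest.approx(11.0**2 + 12.0**2)
        assert f["Mean"] == 1.5  # shift applies only inside the squares


class TestDegenerateRois:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        img = image_from(np.full((3, 3, 3), 4.0), mask)
        d = discretize(img, "roi")
        g = glcm_features(d)
        assert g["degenerate"]
        assert g["Contrast"] == 0.0
        gd = gldm_features(d)
        assert gd["GLDM.DN"] == 1.0
        assert gd["GLDM.DNN"] == 1.0
        assert gd["GLDM.HGLE"] == 1.0

    def test_constant_roi_sentinels(self):
        img = image_from(np.full((4, 4, 4), 3.0))
        d = discretize(img, "roi")
        n = ngtdm_features(d)
        assert n["NGTDM.Coarseness"] == COARSENESS_SENTINEL
        assert n["NGTDM.Complexity"] == 0.0
        assert n["NGTDM.Strength"] == 0.0
        s = glszm_features(d)
        assert s["GLSZM.GLN"] == 1.0
        assert s["GLSZM.SZN"] == 1.0
        assert s["GLSZM.GLV"] == 0.0
        g = glcm_features(d)
        for k in ("Contrast", "CS", "CP", "GLCM.DA", "GLCM.DV"):
            assert g[k] == 0.0


class TestHandComputedExamples:
    def test_glrlm_single_row(self):
        # 1-D row [1, 1, 2]: runs {(1, len 2), (2, len 1)} along that axis
        img = image_from(np.array([1.0, 1.0, 2.0]).reshape(3, 1, 1))
        d = discretize(img, "roi", n_bins=2)
        from aneuhemo.radiomics.glrlm import glrlm_matrices

        mats = glrlm_matrices(d)
        # direction (1, 0, 0) is the first of the 13 offsets with runs
        along = [m for m in mats if m.sum() == 2]
        assert len(along) == 1
        m = along[0]
        assert m[0, 1] == 1  # level 1, length 2
        assert m[1, 0] == 1  # level 2, length 1
        nr = 2
        assert (m.sum(axis=1) ** 2).sum() / nr == 1.0  # GLN
        assert (m.sum(axis=0) ** 2).sum() / nr == 1.0  # RLN
        # HGLRE = (1^2 + 2^2) / 2
        i = np.arange(1, 3)[:, None]
        assert (m * i**2).sum() / nr == 2.5

    def test_glrlm_constant_row(self):
        L = 5
        img = image_from(np.full((L, 1, 1), 2.0))
        d = discretize(img, "roi")
        from aneuhemo.radiomics.glrlm import glrlm_matrices

        along = [m for m in glrlm_matrices(d) if m[0, L - 1] == 1]
        assert len(along) == 1  # single maximal run of length L on one axis
        m = along[0]
        nr = m.sum()
        j = np.arange(1, m.shape[1] + 1)[None, :]
        assert (m.sum(axis=0) ** 2).sum() / nr == 1.0  # RLN
        assert (m * j**2).sum() / nr == L**2  # LRHGLE at level 1

    def test_glszm_two_singleton_zones(self):
        vox = np.zeros((1, 1, 3))
        vox[0, 0, 0] = 1.0
        vox[0, 0, 2] = 3.0
        mask = np.array([[[True, False, True]]])
        img = image_from(vox, mask)
        # levels 1 and 3 out of Ng=3 via bin width 1 from min=1
        d = discretize(img, "roi", policy="fixed_bin_width", bin_width=1.0)
        s = glszm_features(d)
        # two zones at levels 1 and 3: GLV = mean((i - 2)^2) = 1.0
        assert s["GLSZM.GLV"] == pytest.approx(1.0)
        assert s["GLSZM.SZN"] == pytest.approx(2.0)  # both zones size 1
        assert s["GLSZM.GLN"] == pytest.approx(1.0)

    def test_gldm_constant_cube(self):
        img = image_from(np.full((3, 3, 3), 2.0))
        d = discretize(img, "roi")
        from aneuhemo.radiomics.gldm import gldm_matrix

        mat = gldm_matrix(d, alpha=0)
        # center voxel has 26 neighbors -> dependence 27
        assert mat[0, 26] == 1
        # corner voxels have 7 neighbors -> dependence 8
        assert mat[0, 7] == 8
        assert mat.sum() == 27

    def test_checkerboard_glcm_axis_contrast(self):
        # strict 2-level 3-D checkerboard: along any axis offset every pair
        # differs by exactly one level
        idx = np.indices((4, 4, 4)).sum(axis=0) % 2
        img = image_from(idx.astype(float) + 1.0)
        d = discretize(img, "roi", n_bins=2)
        from aneuhemo.radiomics.glcm import glcm_matrices
        from aneuhemo.radiomics._offsets import UNIQUE_OFFSETS

        mats = glcm_matrices(d)
        for off, mat in zip(UNIQUE_OFFSETS, mats):
            p = mat / mat.sum()
            if sum(abs(o) for o in off) % 2 == 1:  # odd parity shift
                assert p[0, 0] == 0 and p[1, 1] == 0
                contrast = ((0 - 1) ** 2) * (p[0, 1] + p[1, 0])
                assert contrast == pytest.approx(1.0)
            else:  # even parity: identical levels
                assert p[0, 1] == 0 and p[1, 0] == 0


class TestExtraction:
    def test_two_rois_same_names(self, rng):
        vox = rng.random((6, 6, 4))
        masks = {
            "wall_free_of_IST": np.zeros((6, 6, 4), bool),
            "wall_next_to_IST": np.zeros((6, 6, 4), bool),
        }
        masks["wall_free_of_IST"][:3] = True
        masks["wall_next_to_IST"][3:] = True
        img = LabeledImageVolume(vox, (1, 1, 1), masks)
        out = extract_feature_vector(img)
        assert set(out["wall_free_of_IST"]) == set(FEATURE_NAMES)
        assert set(out["wall_next_to_IST"]) == set(FEATURE_NAMES)
        assert out["_metadata"]["policy"] == "fixed_bin_count"

    def test_identical_rois_identical_vectors(self, rng):
        vox = rng.random((5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.6
        mask[2, 2, 2] = True
        img = LabeledImageVolume(
            vox, (1, 1, 1), {"wall_free_of_IST": mask, "wall_next_to_IST": mask.copy()}
        )
        out = extract_feature_vector(img)
        assert out["wall_free_of_IST"] == out["wall_next_to_IST"]

    def test_missing_roi_errors(self, rng):
        img = random_roi_image(rng)
        with pytest.raises(KeyError):
            extract_feature_vector(img, roi_names=("wall_free_of_IST",))

    def test_total_energy_voxel_volume_relation(self, rng):
        img = random_roi_image(rng, spacing=(0.5, 0.7, 1.1))
        out = extract_feature_vector(img, roi_names=("roi",))
        f = out["roi"]
        assert f["Total Energy"] == pytest.approx(
            f["Energy"] * 0.5 * 0.7 * 1.1, rel=1e-15
        )

    def test_axis_permutation_invariance(self, rng):
        vox = rng.random((5, 6, 4))
        mask = rng.random((5, 6, 4)) < 0.7
        mask[0, 0, 0] = True
        img = LabeledImageVolume(vox, (1, 1, 1), {"roi": mask})
        out = extract_feature_vector(img, roi_names=("roi",))["roi"]
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            img_p = LabeledImageVolume(
                np.transpose(vox, perm), (1, 1, 1), {"roi": np.transpose(mask, perm)}
            )
            out_p = extract_feature_vector(img_p, roi_names=("roi",))["roi"]
            for name in FEATURE_NAMES:
                assert out_p[name] == pytest.approx(out[name], rel=1e-12), name

    def test_storage_order_invariance(self, rng):
        vox = rng.random((5, 5, 3))
        mask = np.ones((5, 5, 3), bool)
        img_c = LabeledImageVolume(vox.copy(order="C"), (1, 1, 1), {"roi": mask})
        img_f = LabeledImageVolume(np.asfortranarray(vox), (1, 1, 1), {"roi": mask})
        a = extract_feature_vector(img_c, roi_names=("roi",))["roi"]
        b = extract_feature_vector(img_f, roi_names=("roi",))["roi"]
        assert a == b

    def test_grf_contrast_monotone_in_heterogeneity(self):
        from aneuhemo.synthetic import make_texture_image

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            contrasts = []
            for corr in (3.0, 1.0):
                img, _ = make_texture_image(
                    (12, 12, 12),
                    pattern={
                        "kind": "gaussian_random_field",
                        "correlation_length": corr,
                        "variance": 1.0,
                    },
                    seed=seed,
                )
                d = discretize(img, "roi", n_bins=16)
                contrasts.append(glcm_features(d)["Contrast"])
            if contrasts[1] >= contrasts[0]:
                hits += 1
        assert hits >= 0.95 * n_seeds
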