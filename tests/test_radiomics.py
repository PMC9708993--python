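"""Radiomics: cardinalities, first-order hand oracles, texture-matrix checks."""

import numpy as np
import pytest

from ggnforge.radiomics import (
    FAMILY_COUNTS,
    FEATURE_NAMES,
    RadiomicsConfig,
    extract_features,
)
from ggnforge.types import CTSlice


@pytest.fixture(scope="module")
def lesion_features(lesion_slice):
    sl, mask = lesion_slice
    return extract_features(sl, mask)


class TestCardinality:
    def test_exactly_93_features_with_stated_family_counts(self, lesion_features):
        assert len(lesion_features) == 93
        counts = {}
        for family, _ in lesion_features:
            counts[family] = counts.get(family, 0) + 1
        assert counts == FAMILY_COUNTS == {
            "firstorder": 18, "GLCM": 24, "GLDM": 14,
            "GLRLM": 16, "GLSZM": 16, "NGTDM": 5,
        }

    def test_names_match_declared_lists(self, lesion_features):
        for family, names in FEATURE_NAMES.items():
            assert set(lesion_features.family(family)) == set(names)

    def test_all_values_finite(self, lesion_features):
        assert all(np.isfinite(v) for v in lesion_features.values())


class TestFirstOrder:
    def test_constant_region_conventions(self):
        img = np.full((8, 8), 0.5)
        mask = np.ones((8, 8), dtype=bool)
        fv = extract_features(img, mask, RadiomicsConfig(bin_width=0.1))
        fo = fv.family("firstorder")
        assert fo["Mean"] == pytest.approx(0.5)
        assert fo["Variance"] == 0.0
        assert fo["Skewness"] == 0.0
        assert fo["Kurtosis"] == 0.0
        assert fo["Uniformity"] == pytest.approx(1.0)
        assert fo["Entropy"] == pytest.approx(0.0, abs=1e-9)

    def test_toy_grid_energy_and_entropy_hand_oracle(self):
        # 4x4 grid, bin width 1 -> each value is its own grey level
        grid = np.array([
            [1.0, 1.0, 2.0, 2.0],
            [1.0, 1.0, 2.0, 2.0],
            [3.0, 3.0, 4.0, 4.0],
            [3.0, 3.0, 4.0, 4.0],
        ])
        mask = np.ones((4, 4), dtype=bool)
        fv = extract_features(grid, mask, RadiomicsConfig(bin_width=1.0))
        fo = fv.family("firstorder")
        # independent elementwise computation
        energy = float(np.sum(grid ** 2))
        p = np.array([4, 4, 4, 4]) / 16
        entropy = float(-np.sum(p * np.log2(p)))
        assert fo["Energy"] == pytest.approx(energy, rel=1e-12)
        assert fo["Entropy"] == pytest.approx(entropy, rel=1e-9)
        assert fo["Median"] == pytest.approx(np.median(grid))
        assert fo["InterquartileRange"] == pytest.approx(
            np.percentile(grid, 75) - np.percentile(grid, 25))

    def test_statistics_match_numpy_on_random_region(self, lesion_slice):
        sl, mask = lesion_slice
        fv = extract_features(sl, mask)
        x = sl.pixels[mask]
        fo = fv.family("firstorder")
        assert fo["Mean"] == pytest.approx(x.mean())
        assert fo["Variance"] == pytest.approx(x.var())
        assert fo["Minimum"] == x.min() and fo["Maximum"] == x.max()
        assert fo["Range"] == pytest.approx(x.max() - x.min())
        assert fo["RootMeanSquared"] == pytest.approx(np.sqrt((x ** 2).mean()))


class TestGLCM:
    def test_contrast_and_energy_match_brute_force(self):
        grid = np.array([
            [1.0, 2.0, 2.0],
            [2.0, 1.0, 1.0],
            [1.0, 1.0, 2.0],
        ])
        mask = np.ones((3, 3), dtype=bool)
        fv = extract_features(grid, mask, RadiomicsConfig(bin_width=1.0))
        gl = grid.astype(int)

        # brute-force oracle: accumulate symmetric pair counts per direction
        feats = {"Contrast": [], "JointEnergy": [], "MaximumProbability": []}
        for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1)):
            P = np.zeros((2, 2))
            for r in range(3):
                for c in range(3):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 3 and 0 <= cc < 3:
                        P[gl[r, c] - 1, gl[rr, cc] - 1] += 1
                        P[gl[rr, cc] - 1, gl[r, c] - 1] += 1
            P /= P.sum()
            i, j = np.meshgrid([1, 2], [1, 2], indexing="ij")
            feats["Contrast"].append(np.sum(P * (i - j) ** 2))
            feats["JointEnergy"].append(np.sum(P ** 2))
            feats["MaximumProbability"].append(P.max())
        glcm = fv.family("GLCM")
        for name, vals in feats.items():
            assert glcm[name] == pytest.approx(np.mean(vals), rel=1e-10)

    def test_uniform_region_degenerate_values(self):
        fv = extract_features(np.full((6, 6), 10.0), np.ones((6, 6), bool),
                              RadiomicsConfig(bin_width=1.0))
        glcm = fv.family("GLCM")
        assert glcm["Contrast"] == 0.0
        assert glcm["JointEnergy"] == pytest.approx(1.0)
        assert glcm["Correlation"] == pytest.approx(1.0)  # no-variance limit


class TestRunAndZoneFamilies:
    def test_single_level_run_matrix_known_values(self):
        # 1x4 strip of one grey level: one run of length 4 per horizontal
        # direction; four runs of length 1 vertically / diagonally
        grid = np.full((1, 4), 7.0)
        mask = np.ones((1, 4), dtype=bool)
        fv = extract_features(grid, mask, RadiomicsConfig(bin_width=1.0))
        glrlm = fv.family("GLRLM")
        # horizontal: RP = 1/4; the other three directions: RP = 1
        assert glrlm["RunPercentage"] == pytest.approx((0.25 + 3 * 1.0) / 4)
        glszm = fv.family("GLSZM")
        assert glszm["ZonePercentage"] == pytest.approx(1 / 4)  # one 4-zone
        assert glszm["LargeAreaEmphasis"] == pytest.approx(16.0)

    def test_striped_grid_dependence_counts(self):
        # horizontal stripes: within a row only left/right neighbours share
        # the level -> interior pixels have 2 dependent neighbours (j = 3),
        # first/last column have 1 (j = 2); count them directly
        grid = (np.indices((6, 6))[0] % 2).astype(float)
        mask = np.ones((6, 6), dtype=bool)
        fv = extract_features(grid, mask, RadiomicsConfig(bin_width=1.0))
        gldm = fv.family("GLDM")
        n_interior, n_edge = 6 * 4, 6 * 2
        lde = (n_interior * 3 ** 2 + n_edge * 2 ** 2) / 36
        sde = (n_interior / 3 ** 2 + n_edge / 2 ** 2) / 36
        assert gldm["LargeDependenceEmphasis"] == pytest.approx(lde)
        assert gldm["SmallDependenceEmphasis"] == pytest.approx(sde)

    def test_mask_isolation(self, lesion_slice):
        # changing pixels outside the mask must not change any feature
        sl, mask = lesion_slice
        fv1 = extract_features(sl, mask)
        tampered = sl.copy()
        tampered.pixels[~mask] += 500.0
        fv2 = extract_features(tampered, mask)
        for key in fv1:
            assert fv1[key] == pytest.approx(fv2[key], rel=1e-12), key


class TestErrors:
    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((4, 4)), np.zeros((4, 4), bool))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((4, 4)), np.zeros((5, 5), bool))

    def test_ctslice_input_uses_spacing_for_total_energy(self):
        px = np.full((4, 4), 3.0)
        mask = np.ones((4, 4), bool)
        sl = CTSlice(px, spacing=2.0)
        fv = extract_features(sl, mask, RadiomicsConfig(bin_width=1.0))
        fo = fv.family("firstorder")
        assert fo["TotalEnergy"] == pytest.approx(4.0 * fo["Energy"])
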