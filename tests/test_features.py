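"""The 72-feature descriptor: GLCM statistics, entropy, geometry, Hu, intensity.

The GLCM oracle below rebuilds co-occurrence matrices by explicit pair
enumeration and evaluates every statistic with scalar loops,
independently of the vectorized implementation.
"""

import os

import numpy as np
import pandas as pd
import pytest

from nodugrade import features
from nodugrade.features import (FEATURE_NAMES, feature_vector, geometric_features,
                                glcm_statistics, hu_moments, image_entropy,
                                intensity_features, quantize)

from conftest import disc_mask

GOLDEN = os.path.join(os.path.dirname(__file__), "data", "feature_registry_golden.csv")


# --- independent GLCM oracle --------------------------------------------------

def glcm_oracle(G, n_levels, distance):
    """Pair-enumeration GLCM (symmetric, 4 offsets) + scalar statistics."""
    q = quantize(G, n_levels).astype(int)
    h, w = q.shape
    counts = np.zeros((n_levels, n_levels))
    offsets = [(0, distance), (-distance, distance), (-distance, 0), (-distance, -distance)]
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[q[r, c], q[r2, c2]] += 1
                    counts[q[r2, c2], q[r, c]] += 1
    P = counts / counts.sum()

    L = n_levels
    mu_x = sum((i + 1) * P[i, j] for i in range(L) for j in range(L))
    var_x = sum((i + 1 - mu_x) ** 2 * P[i, j] for i in range(L) for j in range(L))
    p_sum = np.zeros(2 * L + 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(p):
        return -sum(v * np.log2(v) for v in np.ravel(p) if v > 0)

    sa = sum(k * p_sum[k] for k in range(2 * L + 1))
    dm = sum(k * p_diff[k] for k in range(L))
    stats = {
        "autocorrelation": sum((i + 1) * (j + 1) * P[i, j] for i in range(L) for j in range(L)),
        "contrast": sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        "correlation": (sum((i + 1 - mu_x) * (j + 1 - mu_x) * P[i, j]
                            for i in range(L) for j in range(L)) / var_x) if var_x > 0 else 0.0,
        "cluster_prominence": sum((i + j + 2 - 2 * mu_x) ** 4 * P[i, j]
                                  for i in range(L) for j in range(L)),
        "cluster_shade": sum((i + j + 2 - 2 * mu_x) ** 3 * P[i, j]
                             for i in range(L) for j in range(L)),
        "dissimilarity": sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L)),
        "energy": float((P ** 2).sum()),
        "entropy": ent(P),
        "homogeneity": sum(P[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L)),
        "maximum_probability": float(P.max()),
        "sum_of_squares": var_x,
        "sum_average": sa,
        "sum_variance": sum((k - sa) ** 2 * p_sum[k] for k in range(2 * L + 1)),
        "sum_entropy": ent(p_sum),
        "difference_variance": sum((k - dm) ** 2 * p_diff[k] for k in range(L)),
        "difference_entropy": ent(p_diff),
    }
    return [stats[name] for name in features.GLCM_STAT_NAMES]


class TestGLCM:
    def test_constant_image_limits(self):
        vals = glcm_statistics(np.full((16, 16), 0.7)).reshape(3, 16)
        names = features.GLCM_STAT_NAMES
        for d in range(3):
            row = dict(zip(names, vals[d]))
            assert row["contrast"] == 0.0
            assert row["energy"] == 1.0
            assert row["maximum_probability"] == 1.0
            assert row["correlation"] == 0.0  # variance-zero guard

    def test_checkerboard_frozen_values(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        vals = glcm_statistics(board.astype(float), n_levels=2, distances=(1,))
        row = dict(zip(features.GLCM_STAT_NAMES, vals))
        # of the 210 symmetric d=1 pair slots, 112 (horizontal/vertical)
        # differ by one level and 98 (diagonal) are equal
        assert row["contrast"] == pytest.approx(8 / 15)
        assert row["homogeneity"] == pytest.approx(11 / 15)
        assert row["dissimilarity"] == pytest.approx(8 / 15)

    def test_random_patches_match_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            G = rng.random((16, 16))
            for di, d in enumerate(features.DISTANCES):
                got = glcm_statistics(G)[di * 16:(di + 1) * 16]
                expected = glcm_oracle(G, features.N_LEVELS, d)
                np.testing.assert_allclose(got, expected, atol=1e-10, rtol=1e-10)

    def test_matrix_normalized(self):
        rng = np.random.default_rng(1)
        q = quantize(rng.random((20, 20)), 32)
        for d in (1, 2, 3):
            assert features.glcm_matrix(q, d).sum() == pytest.approx(1.0)


class TestImageEntropy:
    def test_constant_zero(self):
        assert image_entropy(np.full((8, 8), 3.0)) == 0.0

    def test_two_equal_levels_one_bit(self):
        G = np.zeros((8, 8))
        G[:, 4:] = 1.0
        assert image_entropy(G) == pytest.approx(1.0)

    def test_matches_hand_histogram(self):
        rng = np.random.default_rng(2)
        G = rng.random((16, 16))
        q = quantize(G, 32)
        counts = np.bincount(q.ravel(), minlength=32)
        p = counts / counts.sum()
        expected = -sum(v * np.log2(v) for v in p if v > 0)
        assert image_entropy(G) == pytest.approx(expected)


class TestGeometric:
    def test_centered_square_identities(self):
        B = np.zeros((64, 64), dtype=np.uint8)
        B[27:37, 27:37] = 1
        names = features.GEOMETRIC_NAMES
        row = dict(zip(names, geometric_features(B)))
        assert row["centroid_offset"] <= 0.5
        assert row["filled_area"] == 100
        assert row["extent"] == 1.0
        assert row["solidity"] == 1.0
        assert row["euler_number"] == 1

    def test_interior_hole_euler_zero(self):
        B = np.zeros((64, 64), dtype=np.uint8)
        B[27:37, 27:37] = 1
        B[31, 31] = 0
        row = dict(zip(features.GEOMETRIC_NAMES, geometric_features(B)))
        assert row["euler_number"] == 0

    def test_disc_eccentricity_and_diameter(self):
        B = disc_mask((64, 64), (32, 32), 15).astype(np.uint8)
        row = dict(zip(features.GEOMETRIC_NAMES, geometric_features(B)))
        assert row["eccentricity"] < 0.15
        assert row["equiv_diameter"] == pytest.approx(30, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            geometric_features(np.zeros((8, 8), dtype=np.uint8))

    def test_invariant_to_gray_level(self, fixture_patch):
        # geometric block depends on B only, never on G
        import dataclasses
        p2 = dataclasses.replace(fixture_patch, G=fixture_patch.G * 0.3 + 0.1)
        np.testing.assert_array_equal(
            geometric_features(fixture_patch.B), geometric_features(p2.B))


def hu_oracle(B):
    """Raw double-sum moments pushed through the Hu combinations."""
    B = np.asarray(B, float)
    h, w = B.shape
    m = {(p, q): sum(B[r, c] * (r ** p) * (c ** q) for r in range(h) for c in range(w))
         for p in range(4) for q in range(4)}
    xc, yc = m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]
    mu = {(p, q): sum(B[r, c] * (r - xc) ** p * (c - yc) ** q
                      for r in range(h) for c in range(w))
          for p in range(4) for q in range(4)}
    eta = {k: mu[k] / m[0, 0] ** (1 + sum(k) / 2) for k in mu if sum(k) >= 2}
    n = eta
    h1 = n[2, 0] + n[0, 2]
    h2 = (n[2, 0] - n[0, 2]) ** 2 + 4 * n[1, 1] ** 2
    h3 = (n[3, 0] - 3 * n[1, 2]) ** 2 + (3 * n[2, 1] - n[0, 3]) ** 2
    h4 = (n[3, 0] + n[1, 2]) ** 2 + (n[2, 1] + n[0, 3]) ** 2
    h5 = ((n[3, 0] - 3 * n[1, 2]) * (n[3, 0] + n[1, 2])
          * ((n[3, 0] + n[1, 2]) ** 2 - 3 * (n[2, 1] + n[0, 3]) ** 2)
          + (3 * n[2, 1] - n[0, 3]) * (n[2, 1] + n[0, 3])
          * (3 * (n[3, 0] + n[1, 2]) ** 2 - (n[2, 1] + n[0, 3]) ** 2))
    h6 = ((n[2, 0] - n[0, 2]) * ((n[3, 0] + n[1, 2]) ** 2 - (n[2, 1] + n[0, 3]) ** 2)
          + 4 * n[1, 1] * (n[3, 0] + n[1, 2]) * (n[2, 1] + n[0, 3]))
    h7 = ((3 * n[2, 1] - n[0, 3]) * (n[3, 0] + n[1, 2])
          * ((n[3, 0] + n[1, 2]) ** 2 - 3 * (n[2, 1] + n[0, 3]) ** 2)
          - (n[3, 0] - 3 * n[1, 2]) * (n[2, 1] + n[0, 3])
          * (3 * (n[3, 0] + n[1, 2]) ** 2 - (n[2, 1] + n[0, 3]) ** 2))
    return np.array([h1, h2, h3, h4, h5, h6, h7])


class TestHuMoments:
    def test_translation_invariance_exact(self):
        B = np.zeros((64, 64))
        B[20:30, 25:33] = 1
        B[22, 20:25] = 1
        B2 = np.roll(np.roll(B, 7, axis=0), -4, axis=1)
        np.testing.assert_array_equal(hu_moments(B), hu_moments(B2))

    def test_rotation_invariance(self):
        B = np.zeros((64, 64))
        B[20:30, 25:40] = 1
        B[15:20, 30:33] = 1
        np.testing.assert_allclose(hu_moments(B), hu_moments(np.rot90(B)), rtol=1e-6)

    def test_small_mask_matches_raw_moment_oracle(self):
        B = np.array([
            [0, 1, 1, 0, 0],
            [0, 1, 1, 1, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 0, 0],
            [0, 0, 0, 0, 0],
        ])
        raw = hu_oracle(B)
        expected = np.where(raw != 0, np.sign(raw) * np.log10(np.abs(raw)), 0.0)
        np.testing.assert_allclose(hu_moments(B), expected, rtol=1e-9)


class TestIntensity:
    def test_constant_interior(self):
        G = np.full((8, 8), 0.4)
        B = np.ones((8, 8), dtype=np.uint8)
        np.testing.assert_allclose(intensity_features(G, B), [0.4, 0.0, 0.0])

    def test_three_point_symmetric(self):
        G = np.array([[1.0, 2.0, 3.0]])
        B = np.ones((1, 3), dtype=np.uint8)
        np.testing.assert_allclose(intensity_features(G, B), [2.0, 2 / 3, 0.0])

    def test_matches_moment_formulas(self):
        rng = np.random.default_rng(3)
        G = rng.random((10, 10))
        B = (rng.random((10, 10)) > 0.4).astype(np.uint8)
        vals = G[B.astype(bool)]
        mean = vals.sum() / vals.size
        var = ((vals - mean) ** 2).sum() / vals.size
        skew = (((vals - mean) ** 3).sum() / vals.size) / var ** 1.5
        np.testing.assert_allclose(intensity_features(G, B), [mean, var, skew])


class TestFeatureVector:
    def test_length_and_finiteness(self, fixture_patch):
        fv = feature_vector(fixture_patch)
        assert len(fv.values) == 72
        assert len(set(fv.names)) == 72
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, fixture_patch):
        fv1 = feature_vector(fixture_patch)
        fv2 = feature_vector(fixture_patch)
        np.testing.assert_array_equal(fv1.values, fv2.values)

    def test_translated_twin_blocks(self, fixture_patch):
        import dataclasses
        G2 = np.roll(np.roll(fixture_patch.G, 4, 0), 3, 1)
        B2 = np.roll(np.roll(fixture_patch.B, 4, 0), 3, 1)
        p2 = dataclasses.replace(fixture_patch, G=G2, B=B2)
        fv1, fv2 = feature_vector(fixture_patch), feature_vector(p2)
        names = list(fv1.names)
        hu = slice(names.index("hu_1"), names.index("hu_7") + 1)
        np.testing.assert_allclose(fv1.values[hu], fv2.values[hu], atol=1e-9)
        off = names.index("geom_centroid_offset")
        assert fv1.values[off] != pytest.approx(fv2.values[off], abs=1e-3)

    def test_golden_registry(self, fixture_patch):
        golden = pd.read_csv(GOLDEN)
        fv = feature_vector(fixture_patch)
        assert list(golden["name"]) == list(fv.names)
        np.testing.assert_allclose(fv.values, golden["value"].to_numpy(), rtol=1e-7)
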