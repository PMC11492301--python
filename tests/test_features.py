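"""GLCM texture features and adjacent-aperture Dice."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mlcqa.errors import ValidationError
from mlcqa.features import (
    OFFSETS,
    dice_field,
    dice_pair,
    dice_pair_analytic,
    glcm,
    quantize,
    spatial_features,
    texture_features,
)
from mlcqa.plan_fluence import ApertureMask, beam_grid, rasterize_aperture
from mlcqa.synthetic import SimulationConfig, synth_plan

from conftest import make_rectangle_beam


def oracle_glcm_features(labels, offset, k, symmetric=True):
    """Independent brute-force oracle: literal double loops over a
    co-occurrence count table, then the feature definitions."""
    nr, nc = labels.shape
    dr, dc = offset
    counts = [[0.0] * k for _ in range(k)]
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc:
                counts[labels[r, c]][labels[r2, c2]] += 1.0
                if symmetric:
                    counts[labels[r2, c2]][labels[r, c]] += 1.0
    total = sum(sum(row) for row in counts)
    p = [[v / total for v in row] for row in counts]
    mean = labels.mean()
    var = labels.var()
    contrast = energy = entropy = homog = corr_paper = 0.0
    for i in range(k):
        for j in range(k):
            pij = p[i][j]
            contrast += pij * (i - j) ** 2
            energy += pij * pij
            if pij > 0:
                entropy -= pij * math.log2(pij)
            homog += pij / (1 + (i - j) ** 2)
            if var > 0:
                corr_paper += (i - mean) * (j - mean) * pij**2 / var
    pi = [sum(p[i]) for i in range(k)]
    pj = [sum(p[i][j] for i in range(k)) for j in range(k)]
    mi = sum(i * pi[i] for i in range(k))
    mj = sum(j * pj[j] for j in range(k))
    si = math.sqrt(sum(pi[i] * (i - mi) ** 2 for i in range(k)))
    sj = math.sqrt(sum(pj[j] * (j - mj) ** 2 for j in range(k)))
    corr_std = 0.0
    if si > 0 and sj > 0:
        corr_std = sum(
            (i - mi) * (j - mj) * p[i][j] for i in range(k) for j in range(k)
        ) / (si * sj)
    return {
        "contrast": contrast,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homog,
        "correlation_paper": corr_paper,
        "correlation_standard": corr_std,
    }


class TestQuantize:
    def test_constant_image_maps_to_zero(self):
        np.testing.assert_array_equal(quantize(np.full((4, 4), 7.0), 16), 0)

    def test_hand_binning_two_levels(self):
        labels = quantize(np.array([[0.0, 1.0], [2.0, 3.0]]), 2)
        np.testing.assert_array_equal(labels, [[0, 0], [1, 1]])

    @given(
        arrays(float, (6, 6), elements=st.integers(0, 50).map(float)),
        st.sampled_from([0.5, 2.0, 4.0]),
        st.sampled_from([-8.0, 0.0, 16.0]),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, img, a, b):
        """Bin edges rescale with the image, so labels are unchanged under
        x -> a*x + b (a > 0); values kept on a grid to avoid ulp-level
        boundary flips."""
        np.testing.assert_array_equal(quantize(img, 8), quantize(a * img + b, 8))


class TestGlcm:
    def test_worked_pair_enumeration(self):
        """[[0,0,1],[0,1,1]] at offset (0,1), symmetric: four pair types,
        probability 0.25 each."""
        g = glcm(np.array([[0, 0, 1], [0, 1, 1]]), (0, 1), symmetric=True, n_levels=2)
        np.testing.assert_allclose(g.matrix, 0.25)

    def test_constant_image_concentrates_mass(self):
        g = glcm(np.zeros((4, 4), dtype=int), (0, 1), n_levels=2)
        assert g.matrix[0, 0] == 1.0
        assert g.matrix.sum() == 1.0

    def test_transpose_swaps_offsets(self, rng):
        labels = rng.integers(0, 4, size=(8, 10))
        a = glcm(labels.T, (1, 0), n_levels=4)
        b = glcm(labels, (0, 1), n_levels=4)
        np.testing.assert_allclose(a.matrix, b.matrix)

    def test_probabilities_and_symmetry(self, rng):
        labels = rng.integers(0, 5, size=(9, 9))
        g = glcm(labels, (-1, 1), symmetric=True, n_levels=5)
        assert g.matrix.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g.matrix, g.matrix.T)

    def test_image_smaller_than_offset_rejected(self):
        with pytest.raises(ValidationError):
            glcm(np.zeros((1, 3), dtype=int), (1, 0), n_levels=2)

    def test_matches_skimage_counts(self, rng):
        """Independent library cross-check of the co-occurrence counting and
        the standard correlation feature."""
        skimage_feature = pytest.importorskip("skimage.feature")
        labels = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        ours = glcm(labels, OFFSETS[0], symmetric=True, n_levels=8)
        theirs = skimage_feature.graycomatrix(
            labels, [1], [0], levels=8, symmetric=True, normed=True
        )
        np.testing.assert_allclose(ours.matrix, theirs[:, :, 0, 0], atol=1e-12)
        ref_corr = skimage_feature.graycoprops(theirs, "correlation")[0, 0]
        got = texture_features([ours]).correlation_standard
        assert got == pytest.approx(ref_corr, abs=1e-10)


class TestTextureFeatures:
    def test_worked_quarter_probability_glcm(self):
        """p = 0.25 everywhere on 2 levels: contrast 0.5, energy 0.25,
        entropy 2 bits, homogeneity 0.75."""
        g = glcm(np.array([[0, 0, 1], [0, 1, 1]]), (0, 1), symmetric=True, n_levels=2)
        f = texture_features([g])
        assert f.contrast == pytest.approx(0.5)
        assert f.energy == pytest.approx(0.25)
        assert f.entropy == pytest.approx(2.0)
        assert f.homogeneity == pytest.approx(0.75)

    def test_constant_image_limits(self):
        f = spatial_features(np.full((8, 8), 3.0), n_levels=16)
        assert f.contrast == 0.0
        assert f.energy == 1.0
        assert f.entropy == 0.0
        assert f.homogeneity == 1.0

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(10):
            labels = rng.integers(0, 6, size=(12, 12))
            for off in OFFSETS.values():
                got = texture_features([glcm(labels, off, n_levels=6)])
                want = oracle_glcm_features(labels, off, 6)
                for key, val in want.items():
                    assert getattr(got, key) == pytest.approx(val, abs=1e-12), (key, off)

    def test_noise_raises_entropy_and_lowers_energy(self, rng):
        flat = spatial_features(np.full((32, 32), 5.0), n_levels=8)
        noisy = spatial_features(rng.random((32, 32)), n_levels=8)
        assert noisy.entropy > flat.entropy
        assert noisy.energy < flat.energy


def square_mask(rows, cols, shape=(8, 8), pitch=1.0):
    g = np.zeros(shape, dtype=bool)
    g[rows, cols] = True
    return ApertureMask(g, pitch, (0.0, 0.0))


class TestDice:
    def test_identical_masks(self):
        a = square_mask(slice(1, 4), slice(1, 4))
        assert dice_pair(a, a) == 1.0

    def test_disjoint_masks(self):
        a = square_mask(slice(0, 2), slice(0, 2))
        b = square_mask(slice(5, 7), slice(5, 7))
        assert dice_pair(a, b) == 0.0

    def test_worked_half_overlap(self):
        """|a| = |b| = 4, overlap 2: Dice = 2*2/(4+4) = 0.5."""
        a = square_mask(slice(0, 1), slice(0, 4))
        b = square_mask(slice(0, 1), slice(2, 6))
        assert dice_pair(a, b) == pytest.approx(0.5)

    def test_empty_pair_defined_as_one(self):
        a = square_mask(slice(0, 0), slice(0, 0))
        assert dice_pair(a, a) == 1.0

    def test_grid_mismatch_rejected(self):
        a = square_mask(slice(0, 2), slice(0, 2), shape=(8, 8))
        b = square_mask(slice(0, 2), slice(0, 2), shape=(9, 8))
        with pytest.raises(ValidationError):
            dice_pair(a, b)

    @given(
        arrays(bool, (6, 6), elements=st.booleans()),
        arrays(bool, (6, 6), elements=st.booleans()),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_symmetry_and_jaccard_relation(self, ga, gb):
        a = ApertureMask(ga, 1.0, (0.0, 0.0))
        b = ApertureMask(gb, 1.0, (0.0, 0.0))
        d = dice_pair(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice_pair(b, a)
        union = (ga | gb).sum()
        if union:
            iou = (ga & gb).sum() / union
            assert d == pytest.approx(2 * iou / (1 + iou))


class TestDiceField:
    def test_static_beam_scores_one(self, geometry):
        beam = make_rectangle_beam(geometry, weights=(0.0, 0.5, 1.0))
        assert dice_field(beam, geometry, 0.5).dice == 1.0

    def test_field_value_is_mean_of_pairs(self, geometry):
        """3 CPs with pairwise Dice {1.0, 0.5}: field Dice 0.75."""
        b1 = make_rectangle_beam(geometry, half_width=10.0, n_open_pairs=1, weights=(0, 0.5, 1))
        cps = b1.control_points
        # cp0 == cp1 (dice 1); cp2 shifted by half the width (dice 0.5)
        cps[2].bank_b += 10.0
        cps[2].bank_a += 10.0
        t = dice_field(b1, geometry, 0.5)
        assert t.per_pair_dice[0] == pytest.approx(1.0)
        assert t.per_pair_dice[1] == pytest.approx(0.5, abs=0.02)
        assert t.dice == pytest.approx(np.mean(t.per_pair_dice))

    def test_order_sensitivity(self, geometry):
        beam = make_rectangle_beam(geometry, half_width=10.0, n_open_pairs=4, weights=(0, 0.5, 1))
        for cp in beam.control_points[1:]:
            cp.bank_a += 12.0
            cp.bank_b += 12.0
        beam.control_points[2].bank_a += 12.0
        beam.control_points[2].bank_b += 12.0
        d_ordered = dice_field(beam, geometry, 0.5).dice
        beam.control_points[1], beam.control_points[2] = (
            beam.control_points[2],
            beam.control_points[1],
        )
        for k, cp in enumerate(beam.control_points):
            cp.cumulative_meterset_weight = k / 2.0
        d_shuffled = dice_field(beam, geometry, 0.5).dice
        assert d_ordered != pytest.approx(d_shuffled)

    def test_matches_analytic_leaf_interval_oracle(self, geometry):
        beam = synth_plan(SimulationConfig(seed=21), 0, geometry)[0]
        origin, shape = beam_grid(beam, geometry, 0.25)
        cps = beam.control_points[:4]
        for cp1, cp2 in zip(cps, cps[1:]):
            m1 = rasterize_aperture(cp1, geometry, 0.25, origin, shape)
            m2 = rasterize_aperture(cp2, geometry, 0.25, origin, shape)
            assert dice_pair(m1, m2) == pytest.approx(
                dice_pair_analytic(cp1, cp2, geometry), abs=0.02
            )
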