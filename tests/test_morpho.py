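"""Geometric morphometrics: GPA, partial warps, shape regression, ratios."""

import numpy as np
import pytest

from conftest import similarity_transform
from swimkit import (
    LandmarkConfig,
    gen_landmarks,
    gpa_align,
    morpho_ratios,
    shape_regression,
    tps_partial_warps,
)
from swimkit.errors import InsufficientDataError, InvalidParameterError
from swimkit.morpho import bending_energy_matrix, opa_distance
from swimkit.synth import FISH_TEMPLATE_17


def _cfg(coords, name="s"):
    return LandmarkConfig(specimen_id=name, coords=coords)


def two_shape_oracle(c1, c2):
    """Closed-form partial Procrustes distance via complex arithmetic.

    For centered unit-size configurations written as complex vectors, the
    optimal rotation aligns the phase of <z1, z2>, giving
    d = sqrt(2 - 2 |<z1, z2>|).
    """
    def pre(c):
        z = c[:, 0] + 1j * c[:, 1]
        z = z - z.mean()
        return z / np.sqrt((np.abs(z) ** 2).sum())

    z1, z2 = pre(np.asarray(c1, float)), pre(np.asarray(c2, float))
    return float(np.sqrt(max(2.0 - 2.0 * abs(np.vdot(z2, z1)), 0.0)))


class TestGpa:
    def test_identical_shapes_have_zero_distance(self, triangle):
        assert opa_distance(triangle, triangle.copy()) < 1e-12

    def test_similarity_transformed_copy_has_zero_distance(self, triangle):
        moved = similarity_transform(triangle)
        assert opa_distance(triangle, moved) < 1e-8

    def test_matches_closed_form_two_shape_oracle(self, rng):
        for _ in range(20):
            c1 = rng.normal(size=(3, 2))
            c2 = rng.normal(size=(3, 2))
            assert opa_distance(c1, c2) == pytest.approx(two_shape_oracle(c1, c2), abs=1e-10)

    def test_gpa_invariant_to_input_similarity_transforms(self, rng):
        sample = gen_landmarks(8, 17, deformation_magnitude=0.05, noise_sd=0.01, seed=2)
        plain = gpa_align(sample.configs)
        moved = [
            _cfg(similarity_transform(c.coords, angle=float(rng.uniform(0, 6)),
                                      scale=float(rng.uniform(0.5, 3)),
                                      shift=tuple(rng.normal(size=2) * 10)), c.specimen_id)
            for c in sample.configs
        ]
        aligned2 = gpa_align(moved)
        assert opa_distance(plain.consensus, aligned2.consensus) < 1e-6

    def test_gpa_invariant_to_input_ordering(self):
        sample = gen_landmarks(8, 17, deformation_magnitude=0.05, noise_sd=0.01, seed=2)
        fwd = gpa_align(sample.configs)
        rev = gpa_align(sample.configs[::-1])
        assert opa_distance(fwd.consensus, rev.consensus) < 1e-8

    def test_mismatched_landmark_counts_rejected(self, rng):
        square = rng.normal(size=(4, 2))
        pentagon = rng.normal(size=(5, 2))
        with pytest.raises(InvalidParameterError):
            gpa_align([_cfg(square, "a"), _cfg(pentagon, "b")])

    def test_single_config_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            gpa_align([_cfg(rng.normal(size=(5, 2)))])


class TestPartialWarps:
    def test_score_dimensions_for_17_landmarks(self):
        sample = gen_landmarks(6, 17, deformation_magnitude=0.05, noise_sd=0.01, seed=1)
        scores = tps_partial_warps(gpa_align(sample.configs))
        assert scores.partial_warp_scores.shape == (6, 28)  # 2(k-3), k=17
        assert scores.uniform_component.shape == (6, 2)

    def test_specimen_equal_to_consensus_scores_zero(self):
        sample = gen_landmarks(4, 17, deformation_magnitude=0, noise_sd=0, seed=1)
        scores = tps_partial_warps(gpa_align(sample.configs))
        assert np.abs(scores.matrix).max() < 1e-10

    def test_affine_shear_loads_only_on_uniform_component(self):
        base = FISH_TEMPLATE_17
        shear = np.array([[1.0, 0.12], [0.0, 1.0]])
        configs = [_cfg(base, "ref"), _cfg(base @ shear.T, "sheared")]
        scores = tps_partial_warps(gpa_align(configs))
        assert np.abs(scores.partial_warp_scores).max() < 1e-8
        assert np.abs(scores.uniform_component).max() > 1e-4

    def test_pythagorean_decomposition_of_tangent_residual(self):
        sample = gen_landmarks(10, 17, deformation_magnitude=0.08, noise_sd=0.02, seed=5)
        aligned = gpa_align(sample.configs)
        scores = tps_partial_warps(aligned)
        consensus = aligned.consensus
        s = np.concatenate([consensus[:, 0], consensus[:, 1]])
        q = np.concatenate([-consensus[:, 1], consensus[:, 0]])
        q = q - (q @ s) * s
        q /= np.linalg.norm(q)
        for i in range(aligned.n):
            resid = aligned.aligned[i] - consensus
            v = np.concatenate([resid[:, 0], resid[:, 1]])
            v = v - (v @ s) * s - (v @ q) * q
            assert (scores.matrix[i] ** 2).sum() == pytest.approx(v @ v, abs=1e-8)

    def test_bending_energy_null_space_is_affine(self):
        be = bending_energy_matrix(FISH_TEMPLATE_17 / np.linalg.norm(FISH_TEMPLATE_17))
        for vec in [np.ones(17), FISH_TEMPLATE_17[:, 0], FISH_TEMPLATE_17[:, 1]]:
            assert np.abs(be @ vec).max() < 1e-8


class TestShapeRegression:
    def test_strong_deformation_is_detected(self):
        sample = gen_landmarks(25, 17, deformation_magnitude=0.15, noise_sd=0.005, seed=3)
        scores = tps_partial_warps(gpa_align(sample.configs))
        res = shape_regression(scores, sample.covariate, n_perm=999, seed=0)
        assert res.p <= 0.01

    def test_statistic_invariant_to_specimen_order(self):
        sample = gen_landmarks(12, 17, deformation_magnitude=0.1, noise_sd=0.01, seed=7)
        scores = tps_partial_warps(gpa_align(sample.configs))
        res = shape_regression(scores, sample.covariate, n_perm=99, seed=1)
        perm = np.random.default_rng(0).permutation(12)
        from swimkit.morpho import ShapeScores

        shuffled = ShapeScores(
            partial_warp_scores=scores.partial_warp_scores[perm],
            uniform_component=scores.uniform_component[perm],
            ids=[scores.ids[i] for i in perm],
        )
        res2 = shape_regression(shuffled, sample.covariate[perm], n_perm=99, seed=1)
        assert res2.F == pytest.approx(res.F, rel=1e-9)

    def test_p_reproducible_under_fixed_seed(self):
        sample = gen_landmarks(15, 17, deformation_magnitude=0.05, noise_sd=0.02, seed=9)
        scores = tps_partial_warps(gpa_align(sample.configs))
        p1 = shape_regression(scores, sample.covariate, n_perm=199, seed=5).p
        p2 = shape_regression(scores, sample.covariate, n_perm=199, seed=5).p
        assert p1 == p2

    def test_constant_covariate_rejected(self):
        sample = gen_landmarks(8, 17, deformation_magnitude=0.05, noise_sd=0.01, seed=2)
        scores = tps_partial_warps(gpa_align(sample.configs))
        with pytest.raises(InvalidParameterError):
            shape_regression(scores, np.ones(8), n_perm=99)


class TestMorphoRatios:
    def test_printed_formulas(self):
        r = morpho_ratios(body_length=8.0, body_depth=1.6, caudal_fin_height=2.0,
                          caudal_fin_area=1.0, caudal_peduncle_depth=0.6)
        assert r.FR == pytest.approx(5.0)
        assert r.AR == pytest.approx(4.0)
        assert r.CPH == pytest.approx(100 * 0.6 / 8.0)

    def test_peduncle_depth_factor_in_plausible_range(self):
        r = morpho_ratios(8.0, 1.5, 2.0, 1.0, 0.6)
        assert r.CPD_BD == pytest.approx(0.40)
        assert 38.3 <= 100 * r.CPD_BD <= 43.9

    def test_non_positive_measurement_rejected(self):
        with pytest.raises(InvalidParameterError):
            morpho_ratios(8.0, 0.0, 2.0, 1.0, 0.6)
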