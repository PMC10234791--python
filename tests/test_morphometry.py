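import numpy as np
import pytest

from facecue import (
    GeneratorConfig,
    LandmarkConfiguration,
    align_pair,
    dimorphism_axis,
    dimorphism_pipeline,
    gpa,
    score_faces,
)
from facecue.simulate import gen_faces
from oracles import grid_search_distance


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestAlignPair:
    def test_identity_gives_zero_distance(self, rng):
        A = rng.standard_normal((10, 2))
        _, d = align_pair(A, A)
        assert d < 1e-12

    def test_similarity_transform_invariance(self, rng):
        A = rng.standard_normal((10, 2))
        B = 3.7 * A @ _rot(np.deg2rad(37)).T + [5, -2]
        _, d = align_pair(A, B)
        assert d < 1e-9

    def test_matches_rotation_grid_search_oracle(self):
        A = [(0, 0), (1, 0), (0, 1)]
        B = [(0, 0), (0, 2), (-2, 0)]
        _, d = align_pair(A, B)
        assert d == pytest.approx(grid_search_distance(A, B), abs=1e-4)

    def test_no_reflection_allowed(self, rng):
        A = rng.standard_normal((8, 2))
        B = A * [1, -1]  # mirrored landmarking
        R, d = align_pair(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert d > 0.1  # a reflection would give 0

    def test_errors(self, rng):
        A = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="point counts differ"):
            align_pair(A, A[:4])
        with pytest.raises(ValueError, match="zero centroid size"):
            align_pair(np.zeros((5, 2)), A)


class TestGPA:
    def test_identical_copies_collapse_to_consensus(self, rng):
        A = rng.standard_normal((12, 2))
        out = gpa([A.copy() for _ in range(5)])
        for shape in out.shapes:
            np.testing.assert_allclose(shape, out.consensus, atol=1e-10)

    def test_aligned_shapes_are_centered_unit_size(self, rng):
        configs = [rng.standard_normal((9, 2)) * s for s in (1, 3, 10)]
        out = gpa(configs)
        for shape in out.shapes:
            np.testing.assert_allclose(shape.mean(axis=0), 0, atol=1e-9)
            assert np.sqrt((shape**2).sum()) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            out.consensus, out.shapes.mean(axis=0), atol=1e-9
        )

    def test_similarity_transformed_copies_align_exactly(self, rng):
        A = rng.standard_normal((15, 2))
        configs = [
            s * A @ _rot(th).T + mu
            for s, th, mu in [(1, 0, [0, 0]), (2.5, 1.1, [4, 4]), (0.3, -2, [-9, 1])]
        ]
        out = gpa(configs)
        for shape in out.shapes[1:]:
            np.testing.assert_allclose(shape, out.shapes[0], atol=1e-8)

    def test_two_shape_gpa_matches_pairwise_alignment(self, rng):
        A, B = rng.standard_normal((2, 11, 2))
        out = gpa([A, B])
        _, pair_d = align_pair(A, B)
        gpa_d = np.sqrt(((out.shapes[0] - out.shapes[1]) ** 2).sum())
        # same residual distance up to the common rotation convention
        assert gpa_d == pytest.approx(pair_d, abs=1e-6)

    def test_heterogeneous_point_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="points"):
            gpa([rng.standard_normal((5, 2)), rng.standard_normal((6, 2))])


class TestDimorphismAxis:
    def test_axis_is_difference_of_sex_means(self, rng):
        S1, S2 = rng.standard_normal((2, 8))
        ax = dimorphism_axis([S1, S1, S1], [S2, S2])
        np.testing.assert_allclose(ax.axis, S2 - S1)

    def test_swapping_sex_labels_negates_axis(self, rng):
        F = rng.standard_normal((4, 8))
        M = rng.standard_normal((5, 8))
        np.testing.assert_allclose(
            dimorphism_axis(F, M).axis, -dimorphism_axis(M, F).axis
        )

    def test_degenerate_axis_rejected(self, rng):
        S = rng.standard_normal(8)
        with pytest.raises(ValueError, match="degenerate"):
            dimorphism_axis([S], [S])

    def test_recovers_generating_axis_from_references(self):
        cfg = GeneratorConfig(seed=42, n_participants=5)
        rng = np.random.default_rng(42)
        ref_f, ref_m, _, _ = gen_faces(cfg, rng)
        aligned = gpa(ref_f + ref_m)
        flat = aligned.flat()
        ax = dimorphism_axis(flat[: len(ref_f)], flat[len(ref_f):])
        # project the reference shapes: sexes must separate along the axis
        scores = (flat - ax.female_mean) @ ax.axis / ax.norm_sq
        assert scores[len(ref_f):].mean() > scores[: len(ref_f)].mean()
        # female refs centre near 0, male refs near 1 on the axis scale
        assert scores[: len(ref_f)].mean() == pytest.approx(0, abs=0.2)
        assert scores[len(ref_f):].mean() == pytest.approx(1, abs=0.2)


class TestScoreFaces:
    def _axis(self, rng, dim=16):
        F = rng.standard_normal((6, dim))
        M = rng.standard_normal((7, dim)) + 0.5
        return dimorphism_axis(F, M)

    def test_projection_endpoints(self, rng):
        ax = self._axis(rng)
        s = score_faces([ax.female_mean, ax.male_mean], ax, scale=False)
        np.testing.assert_allclose(s.raw, [0.0, 1.0], atol=1e-12)

    def test_midpoint_scores_half_by_linearity(self, rng):
        ax = self._axis(rng)
        mid = (ax.female_mean + ax.male_mean) / 2
        # independent dot-product oracle
        expect = float((mid - ax.female_mean) @ ax.axis / (ax.axis @ ax.axis))
        s = score_faces([mid], ax, scale=False)
        assert s.raw[0] == pytest.approx(0.5, abs=1e-12)
        assert s.raw[0] == pytest.approx(expect, abs=1e-12)

    def test_orthogonal_component_leaves_score_unchanged(self, rng):
        ax = self._axis(rng)
        x = rng.standard_normal(16)
        w = rng.standard_normal(16)
        w -= (w @ ax.axis) / ax.norm_sq * ax.axis
        s0 = score_faces([x], ax, scale=False).raw[0]
        s1 = score_faces([x + 5 * w], ax, scale=False).raw[0]
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_scaled_scores_are_zscores(self, rng):
        ax = self._axis(rng)
        X = rng.standard_normal((30, 16))
        s = score_faces(X, ax)
        assert s.scaled.mean() == pytest.approx(0, abs=1e-9)
        assert s.scaled.std(ddof=1) == pytest.approx(1, abs=1e-9)
        # orientation preserved: monotone transform of raw
        assert np.all(np.argsort(s.scaled) == np.argsort(s.raw))

    def test_single_target_with_scaling_rejected(self, rng):
        ax = self._axis(rng)
        with pytest.raises(ValueError, match="2 targets"):
            score_faces([ax.male_mean], ax, scale=True)


class TestEndToEnd:
    def test_male_refs_score_higher_than_female_refs(self):
        cfg = GeneratorConfig(seed=9, n_participants=10)
        rng = np.random.default_rng(9)
        ref_f, ref_m, _, _ = gen_faces(cfg, rng)
        s = dimorphism_pipeline(ref_f + ref_m, ref_f, ref_m, scale=False)
        nf = len(ref_f)
        assert s.raw[nf:].mean() > s.raw[:nf].mean()

    def test_recovery_of_true_positions_at_default_noise(self):
        cfg = GeneratorConfig(seed=5)
        rng = np.random.default_rng(5)
        ref_f, ref_m, participants, truth = gen_faces(cfg, rng)
        s = dimorphism_pipeline(participants, ref_f, ref_m)
        r = np.corrcoef(s.raw, truth["t_true"])[0, 1]
        assert r > 0.9
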