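import numpy as np
import pytest

from facevector.attractiveness import (
    ManipulationSpec,
    build_validation_set,
    fit_attractiveness_vector,
    load_vector,
    manipulate,
    save_vector,
)
from facevector.morphable import FaceCoefficients
from facevector.raters import (
    GroundTruthPreference,
    cronbach_alpha,
    mean_scores,
    rater_panel,
    simulate_ratings,
    standardize_ratings,
)


def faces_from_rows(shape_rows, refl_rows, sex="male"):
    return [
        FaceCoefficients(np.asarray(s, float), np.asarray(r, float), sex=sex)
        for s, r in zip(shape_rows, refl_rows)
    ]


class TestFitVector:
    def test_identity_matrix_picks_rated_face(self):
        faces = faces_from_rows([(1, 0), (0, 1)], [(1, 1), (1, -1)])
        v = fit_attractiveness_vector(faces, [2.0, 0.0], "male")
        np.testing.assert_allclose(v.t_shape, [2.0, 0.0])
        np.testing.assert_allclose(v.t_hat_shape, [1.0, 0.0])

    def test_matches_independent_matrix_multiply(self):
        faces = faces_from_rows([(1, 1), (1, -1)], [(0.5, 0), (0, 0.5)])
        v = fit_attractiveness_vector(faces, [1.0, 1.0], "male")
        np.testing.assert_allclose(v.t_shape, [2.0, 0.0])
        np.testing.assert_allclose(v.t_hat_shape, [1.0, 0.0])
        # reflectance block: F_r . r = (0.5, 0.5)
        np.testing.assert_allclose(v.t_reflectance, [0.5, 0.5])
        np.testing.assert_allclose(v.t_hat_reflectance, np.array([1, 1]) / np.sqrt(2))

    def test_random_fixture_matches_bruteforce(self, fx, rng):
        v = fx["vector"]
        F_s = np.column_stack([c.shape_coeffs for c in fx["pool"].candidates])
        F_r = np.column_stack(
            [c.reflectance_coeffs for c in fx["pool"].candidates]
        )
        r = fx["r"].to_numpy()
        np.testing.assert_allclose(v.t_shape, F_s @ r, atol=1e-12)
        np.testing.assert_allclose(v.t_reflectance, F_r @ r, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(v.t_hat_shape), 1.0, atol=1e-12)

    def test_degenerate_inputs_rejected(self):
        faces = faces_from_rows([(1, 0), (0, 1)], [(1, 0), (0, 1)])
        with pytest.raises(ValueError, match="all zeros"):
            fit_attractiveness_vector(faces, [0.0, 0.0], "male")
        with pytest.raises(ValueError, match="length"):
            fit_attractiveness_vector(faces, [1.0, 2.0, 3.0], "male")
        with pytest.raises(ValueError, match="at least 2"):
            fit_attractiveness_vector(faces[:1], [1.0], "male")
        # r orthogonal to the shape block leaves ||t_shape|| = 0
        orth = faces_from_rows([(1, 0), (-1, 0)], [(1, 0), (1, 1)])
        with pytest.raises(ValueError, match="direction undefined"):
            fit_attractiveness_vector(orth, [1.0, 1.0], "male")

    def test_scale_equivariance_of_unit_vector(self, fx):
        pool = fx["pool"].candidates
        r = fx["r"].to_numpy()
        a = fit_attractiveness_vector(pool, r, "male")
        b = fit_attractiveness_vector(pool, 37.5 * r, "male")
        np.testing.assert_allclose(a.t_hat_shape, b.t_hat_shape, atol=1e-12)
        np.testing.assert_allclose(
            a.t_hat_reflectance, b.t_hat_reflectance, atol=1e-12
        )


class TestManipulate:
    @pytest.fixture()
    def vector(self, fx):
        return fx["vector"]

    @pytest.mark.parametrize("mode", ["shape_and_reflectance", "shape_only",
                                      "reflectance_only"])
    def test_delta_zero_is_identity(self, vector, mode, rng):
        c = FaceCoefficients(rng.normal(size=2), rng.normal(size=2), sex="male")
        out = manipulate(c, vector, ManipulationSpec(delta=0.0, mode=mode))
        np.testing.assert_array_equal(out.shape_coeffs, c.shape_coeffs)
        np.testing.assert_array_equal(out.reflectance_coeffs, c.reflectance_coeffs)

    def test_unit_vector_step_from_origin(self, fx):
        v = fx["vector"]
        c = FaceCoefficients(np.zeros(2), np.zeros(2), sex="male")
        out = manipulate(c, v, ManipulationSpec(delta=2.0, mode="shape_only"))
        np.testing.assert_allclose(out.shape_coeffs, 2.0 * v.t_hat_shape, atol=1e-15)
        np.testing.assert_array_equal(out.reflectance_coeffs, 0.0)

    @pytest.mark.parametrize("mode", ["shape_and_reflectance", "shape_only",
                                      "reflectance_only"])
    def test_additivity_of_deltas(self, vector, mode, rng):
        c = FaceCoefficients(rng.normal(size=2), rng.normal(size=2), sex="male")
        spec = lambda d: ManipulationSpec(delta=d, mode=mode)
        two_step = manipulate(manipulate(c, vector, spec(1.2)), vector, spec(-0.7))
        one_step = manipulate(c, vector, spec(0.5))
        np.testing.assert_allclose(
            two_step.shape_coeffs, one_step.shape_coeffs, atol=1e-12
        )
        np.testing.assert_allclose(
            two_step.reflectance_coeffs, one_step.reflectance_coeffs, atol=1e-12
        )

    def test_mode_orthogonality_is_bit_exact(self, vector, rng):
        c = FaceCoefficients(rng.normal(size=2), rng.normal(size=2), sex="male")
        shape_only = manipulate(c, vector, ManipulationSpec(2.5, "shape_only"))
        assert shape_only.reflectance_coeffs.tobytes() == c.reflectance_coeffs.tobytes()
        refl_only = manipulate(c, vector, ManipulationSpec(2.5, "reflectance_only"))
        assert refl_only.shape_coeffs.tobytes() == c.shape_coeffs.tobytes()

    def test_gender_dial_never_modified(self, vector):
        c = FaceCoefficients(np.zeros(2), np.zeros(2), sex="male", gender_control=-3.3)
        out = manipulate(c, vector, ManipulationSpec(5.0, "shape_and_reflectance"))
        assert out.gender_control == -3.3

    def test_joint_normalization_flag(self, vector):
        c = FaceCoefficients(np.zeros(2), np.zeros(2), sex="male")
        out = manipulate(
            c, vector,
            ManipulationSpec(1.0, "shape_and_reflectance",
                             combined_normalization="joint"),
        )
        assert np.isclose(np.linalg.norm(out.concat()), 1.0)
        per_block = manipulate(
            c, vector, ManipulationSpec(1.0, "shape_and_reflectance")
        )
        assert np.isclose(np.linalg.norm(per_block.concat()), np.sqrt(2.0))

    def test_sex_mismatch_rejected(self, vector):
        c = FaceCoefficients(np.zeros(2), np.zeros(2), sex="female")
        with pytest.raises(ValueError, match="sex"):
            manipulate(c, vector, ManipulationSpec(1.0, "shape_only"))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ManipulationSpec(1.0, "texture_only")


class TestValidationSet:
    def test_default_design_counts(self, fx):
        records = build_validation_set(fx["model"], fx["vector"], seed=5)
        assert len(records) == 10 * 7 * 3
        deltas = {d for _, d, _, _ in records}
        assert deltas == {-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0}

    def test_delta_zero_identical_across_modes(self, fx):
        records = build_validation_set(fx["model"], fx["vector"], seed=6)
        by_face = {}
        for fid, d, mode, c in records:
            if d == 0.0:
                by_face.setdefault(fid, []).append(c)
        for group in by_face.values():
            assert len(group) == 3
            for c in group[1:]:
                np.testing.assert_array_equal(c.concat(), group[0].concat())

    def test_single_zero_delta_returns_base_faces(self, fx):
        records = build_validation_set(
            fx["model"], fx["vector"], n_faces=4, deltas=(0.0,), seed=7
        )
        assert len(records) == 4 * 3
        base = {fid: c for fid, _, m, c in records if m == "shape_only"}
        for fid, _, _, c in records:
            np.testing.assert_array_equal(c.concat(), base[fid].concat())

    def test_empty_deltas_rejected(self, fx):
        with pytest.raises(ValueError, match="non-empty"):
            build_validation_set(fx["model"], fx["vector"], deltas=(), seed=0)


class TestDirectionRecovery:
    def _fit_direction(self, d_shape, d_refl, n_faces, n_raters, noise_ratio, seed):
        rng = np.random.default_rng(seed)
        faces = [
            FaceCoefficients(
                0.5 * rng.standard_normal(d_shape),
                0.5 * rng.standard_normal(d_refl),
                sex="female",
            )
            for _ in range(n_faces)
        ]
        truth = GroundTruthPreference.random(
            d_shape, d_refl, 0.5, seed=seed + 1, sex="female"
        )
        panel = rater_panel(
            n_raters, truth.latent(faces).std(ddof=1), noise_ratio, seed=seed + 2
        )
        ratings = simulate_ratings(faces, truth, panel, seed=seed + 3)
        r = mean_scores(standardize_ratings(ratings)).to_numpy()
        vector = fit_attractiveness_vector(faces, r, "female")
        return vector, truth, ratings

    def test_desk_scale_training_recovers_direction(self):
        vector, truth, ratings = self._fit_direction(20, 20, 200, 20, 1.0, seed=31)
        assert cronbach_alpha(ratings) >= 0.9
        assert vector.t_hat_joint() @ truth.direction >= 0.80

    def test_noiseless_limit_with_many_faces(self):
        vector, truth, _ = self._fit_direction(20, 20, 2000, 3, 0.0, seed=33)
        assert vector.t_hat_joint() @ truth.direction >= 0.95

    def test_latent_monotone_in_delta(self, fx):
        """Under the generating truth, mean rating is nondecreasing in delta."""
        from facevector.attractiveness import AttractivenessVector

        model, truth = fx["model"], fx["truth"]
        ts, tr = truth.shape_direction, truth.reflectance_direction
        vector = AttractivenessVector(
            "male", ts, tr, ts / np.linalg.norm(ts), tr / np.linalg.norm(tr)
        )
        records = build_validation_set(model, vector, n_faces=8, seed=9)
        for mode in ("shape_and_reflectance", "shape_only", "reflectance_only"):
            stim = [(d, c) for _, d, m, c in records if m == mode]
            latent_sd = truth.latent([c for _, c in stim]).std(ddof=1)
            panel = rater_panel(16, latent_sd, 0.2, seed=10)
            ratings = simulate_ratings(
                [c for _, c in stim], truth, panel, seed=11
            )
            deltas = np.array([d for d, _ in stim])
            means = [
                ratings.ratings[:, deltas == d].mean()
                for d in sorted(set(deltas))
            ]
            assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))


def test_vector_container_round_trip(fx, tmp_path):
    v = fx["vector"]
    save_vector(v, tmp_path / "vec")
    loaded = load_vector(tmp_path / "vec")
    np.testing.assert_array_equal(loaded.t_shape, v.t_shape)
    np.testing.assert_array_equal(loaded.t_hat_reflectance, v.t_hat_reflectance)
    assert loaded.sex == v.sex and loaded.n_faces == v.n_faces
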