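import numpy as np
import pytest
from scipy.stats import spearmanr

from facevector.morphable import FaceCoefficients
from facevector.raters import (
    GroundTruthPreference,
    RaterProfile,
    RatingMatrix,
    cronbach_alpha,
    mean_scores,
    rater_panel,
    simulate_ratings,
    standardize_ratings,
    summarize_ratings,
)


def random_faces(n, k=4, scale=0.5, sex="male", seed=0):
    rng = np.random.default_rng(seed)
    return [
        FaceCoefficients(
            scale * rng.standard_normal(k), scale * rng.standard_normal(k), sex=sex
        )
        for _ in range(n)
    ]


def matrix_from_grid(grid, **kwargs):
    grid = np.asarray(grid, dtype=float)
    return RatingMatrix(
        ratings=grid,
        rater_ids=[f"r{i}" for i in range(grid.shape[0])],
        face_ids=[f"f{j}" for j in range(grid.shape[1])],
        **kwargs,
    )


class TestSimulateRatings:
    def test_noiseless_ratings_monotone_in_latent(self):
        faces = random_faces(30, seed=1)
        truth = GroundTruthPreference.random(4, 4, 0.5, seed=2, sex="male")
        rater = [RaterProfile(intercept=5.0, slope=1.0, noise_sd=0.0)]
        ratings = simulate_ratings(faces, truth, rater, seed=3)
        order = np.argsort(truth.latent(faces))
        assert (np.diff(ratings.ratings[0][order]) >= 0).all()

    def test_orthogonal_truth_gives_constant_ratings(self):
        faces = [
            FaceCoefficients(np.array([x, 0.0]), np.zeros(2), sex="male")
            for x in np.linspace(-2, 2, 10)
        ]
        truth = GroundTruthPreference(
            "male", np.array([0.0, 1.0]), np.zeros(2), 0.0
        )
        raters = [RaterProfile(5.0, 1.0, 0.0), RaterProfile(4.0, 2.0, 0.0)]
        ratings = simulate_ratings(faces, truth, raters, seed=4)
        for row in ratings.ratings:
            assert np.ptp(row) == 0

    def test_empty_faces_rejected(self):
        truth = GroundTruthPreference.random(4, 4, 0.5, seed=0)
        with pytest.raises(ValueError, match="empty"):
            simulate_ratings([], truth, [RaterProfile(5, 1, 0.1)], seed=0)

    def test_sex_mismatch_rejected(self):
        faces = random_faces(5, sex="male")
        truth = GroundTruthPreference.random(4, 4, 0.5, seed=0, sex="female")
        with pytest.raises(ValueError, match="sex"):
            simulate_ratings(faces, truth, [RaterProfile(5, 1, 0.1)], seed=0)

    def test_low_noise_panel_reaches_high_alpha(self):
        """Noise at 0.35x the signal s.d. keeps a 20-rater panel above 0.90."""
        truth = GroundTruthPreference.random(4, 4, 0.5, seed=5, sex="male")
        for seed in range(20):
            faces = random_faces(200, seed=100 + seed)
            latent_sd = truth.latent(faces).std(ddof=1)
            panel = rater_panel(20, latent_sd, noise_ratio=0.35, seed=seed)
            ratings = simulate_ratings(faces, truth, panel, seed=seed)
            assert cronbach_alpha(ratings) >= 0.90

    def test_global_discretization_mode(self):
        faces = random_faces(50, seed=6)
        truth = GroundTruthPreference.random(4, 4, 0.5, seed=7, sex="male")
        panel = rater_panel(4, truth.latent(faces).std(ddof=1), 0.5, seed=8)
        ratings = simulate_ratings(faces, truth, panel, seed=9,
                                   discretization="global")
        assert ratings.ratings.min() >= 1 and ratings.ratings.max() <= 9


class TestCronbachAlpha:
    def test_identical_raters_give_one(self):
        m = matrix_from_grid([[1, 4, 7, 9], [1, 4, 7, 9]])
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_toy_grid_matches_hand_computation(self):
        m = matrix_from_grid([[2, 4, 6, 8], [3, 4, 5, 9], [1, 5, 6, 7]])
        # item variances 20/3, 20.75/3, 20.75/3; totals (6,13,17,24) var 170/3
        expected = 1.5 * (1 - 20.5 / (170 / 3))
        assert cronbach_alpha(m) == pytest.approx(expected, abs=1e-12)
        assert cronbach_alpha(m) == pytest.approx(0.9573529, abs=1e-6)

    def test_matches_pingouin_reference(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(10)
        grid = rng.integers(1, 10, size=(6, 15)).astype(float)
        m = matrix_from_grid(grid)
        ref = pg.cronbach_alpha(data=pd.DataFrame(grid.T))[0]
        assert cronbach_alpha(m) == pytest.approx(ref, abs=1e-10)

    def test_pure_noise_alpha_centers_on_zero(self):
        alphas = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            m = matrix_from_grid(rng.integers(1, 10, size=(8, 60)).astype(float))
            alphas.append(cronbach_alpha(m))
        assert abs(np.mean(alphas)) < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cronbach_alpha(matrix_from_grid([[1, 2, 3]]))
        with pytest.raises(ValueError, match="zero total variance"):
            cronbach_alpha(matrix_from_grid([[5, 5, 5], [5, 5, 5]]))
        grid = np.array([[1.0, np.nan, 3.0], [2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="missing"):
            cronbach_alpha(matrix_from_grid(grid))

    def test_alpha_monotone_in_noise(self):
        """Mean reliability strictly decreases as rater noise grows."""
        truth = GroundTruthPreference.random(4, 4, 0.5, seed=11, sex="male")
        levels = [0.2, 0.5, 1.0, 2.0, 4.0]
        means = []
        for ratio in levels:
            vals = []
            for seed in range(10):
                faces = random_faces(100, seed=200 + seed)
                panel = rater_panel(
                    10, truth.latent(faces).std(ddof=1), ratio, seed=seed
                )
                vals.append(
                    cronbach_alpha(simulate_ratings(faces, truth, panel, seed=seed))
                )
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestStandardize:
    def test_symmetric_row(self):
        m = matrix_from_grid([[1, 5, 9], [2, 5, 8]])
        z = standardize_ratings(m)
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0])

    def test_shift_invariance(self):
        a = matrix_from_grid([[1, 3, 5], [2, 4, 6]])
        b = matrix_from_grid([[4, 6, 8], [2, 4, 6]])
        np.testing.assert_allclose(
            standardize_ratings(a).values, standardize_ratings(b).values
        )

    def test_constant_rater_rejected_by_name(self):
        m = matrix_from_grid([[4, 4, 4], [1, 5, 9]])
        with pytest.raises(ValueError, match="r0"):
            standardize_ratings(m)

    def test_idempotent(self):
        m = matrix_from_grid([[1, 4, 6, 9], [3, 2, 8, 5]])
        z1 = standardize_ratings(m).values
        z2 = (z1 - z1.mean(axis=1, keepdims=True)) / z1.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(z1, z2, atol=1e-10)
        assert np.abs(z1.mean(axis=1)).max() < 1e-10
        np.testing.assert_allclose(z1.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestMeanScores:
    def test_single_rater_returns_own_zscores(self):
        m = matrix_from_grid([[1, 5, 9], [1, 5, 9]])
        z = standardize_ratings(m)
        np.testing.assert_allclose(mean_scores(z).to_numpy(), [-1.0, 0.0, 1.0])

    def test_opposite_raters_cancel(self):
        m = matrix_from_grid([[1, 5, 9], [9, 5, 1]])
        np.testing.assert_allclose(
            mean_scores(standardize_ratings(m)).to_numpy(), 0.0, atol=1e-12
        )

    def test_toy_grid_matches_column_means(self):
        m = matrix_from_grid([[1, 4, 7], [2, 6, 9], [3, 5, 8]])
        z = standardize_ratings(m)
        np.testing.assert_allclose(
            mean_scores(z).to_numpy(), z.values.mean(axis=0), atol=1e-12
        )


class TestSummaries:
    def test_single_rater_two_faces(self):
        m = matrix_from_grid([[4, 6]], face_sex="male", rater_sex=["female"])
        table = summarize_ratings(m)
        row = table.iloc[0]
        assert row["mean"] == 5.0
        assert row["range_low"] == row["range_high"] == 5.0

    def test_identical_raters_sd_zero(self):
        m = matrix_from_grid([[2, 8], [2, 8]], face_sex="female",
                             rater_sex=["male", "male"])
        assert summarize_ratings(m)["sd"].iloc[0] == 0.0

    def test_default_config_cells_within_scale_bounds(self, fx):
        table = summarize_ratings(fx["ratings"])
        assert (table["mean"] >= 1).all() and (table["mean"] <= 9).all()
        assert (table["range_low"] >= 1).all() and (table["range_high"] <= 9).all()


def test_pipeline_recovers_latent_ordering():
    """simulate -> standardize -> mean recovers latent order when alpha >= 0.9."""
    truth = GroundTruthPreference.random(4, 4, 0.5, seed=13, sex="female")
    faces = random_faces(200, sex="female", seed=14)
    panel = rater_panel(20, truth.latent(faces).std(ddof=1), 1.0, seed=15)
    ratings = simulate_ratings(faces, truth, panel, seed=16)
    assert cronbach_alpha(ratings) >= 0.9
    r = mean_scores(standardize_ratings(ratings))
    rho = spearmanr(r.to_numpy(), truth.latent(faces)).statistic
    assert rho >= 0.9


def test_long_frame_round_trip():
    m = matrix_from_grid(
        [[1, 4, 7], [2, 6, 9]],
        face_sex="male",
        condition="shape_only",
        rater_sex=["male", "female"],
        delta_levels=np.array([-3.0, 0.0, 3.0]),
    )
    back = RatingMatrix.from_long_frame(m.to_long_frame())
    np.testing.assert_array_equal(back.ratings, m.ratings)
    assert back.face_sex == "male" and back.condition == "shape_only"
    np.testing.assert_array_equal(back.delta_levels, m.delta_levels)
    assert back.rater_sex == ["male", "female"]
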