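"""Continuous BART: structure prior, recovery, prediction contracts."""

import numpy as np
import pytest

from bartcate import BartConfig, fit_bart, predict, split_probability
from bartcate._forest import eval_frozen_tree

SMALL = BartConfig(m=25, n_chains=1, n_total=200, n_burn=80)


class TestSplitProbability:
    @pytest.mark.parametrize(
        "depth, base, power, expected",
        [
            (0, 0.95, 2.0, 0.95),
            (1, 0.95, 2.0, 0.2375),     # 0.95 * 2^-2
            (1, 0.25, 3.0, 0.03125),    # 0.25 * 2^-3
            (3, 0.5, 0.0, 0.5),
        ],
    )
    def test_values(self, depth, base, power, expected):
        assert split_probability(depth, base, power) == pytest.approx(expected)

    def test_decreasing_in_depth(self):
        ps = [split_probability(d, 0.95, 2.0) for d in range(6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("base", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_base_rejected(self, base):
        with pytest.raises(ValueError):
            split_probability(0, base, 2.0)

    def test_prior_depth_monotone_in_hyperparameters(self, rng):
        # simulate tree depths from the structure prior directly
        def mean_depth(base, power, reps=400):
            total = 0
            for _ in range(reps):
                frontier = [(0, 1)]  # (depth, count)
                maxd = 0
                while frontier:
                    d, k = frontier.pop()
                    maxd = max(maxd, d)
                    for _ in range(k):
                        if d < 8 and rng.random() < split_probability(d, base, power):
                            frontier.append((d + 1, 2))
                total += maxd
            return total / reps

        assert mean_depth(0.95, 1.0) > mean_depth(0.95, 2.0) > mean_depth(0.95, 3.0)
        assert mean_depth(0.95, 2.0) > mean_depth(0.25, 2.0)


class TestFit:
    def test_constant_outcome_recovered(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.full(60, 7.0)
        d = fit_bart(X, y, SMALL)
        np.testing.assert_allclose(d.posterior_mean(), 7.0, atol=0.01 * 7 + 0.01)

    def test_linear_function_recovery(self, rng):
        n = 500
        X = rng.uniform(-1, 1, size=(n, 3))
        y = 2 * X[:, 0] + rng.normal(0, 0.1, n)
        grid = np.zeros((50, 3))
        grid[:, 0] = np.linspace(-0.9, 0.9, 50)
        cfg = BartConfig(m=50, n_chains=1, n_total=300, n_burn=100)
        d = fit_bart(X, y, cfg, X_test=grid)
        rmse = np.sqrt(np.mean((d.test_preds.mean(axis=0) - 2 * grid[:, 0]) ** 2))
        assert rmse < 0.3

    def test_sigma_recovery_on_noise_only_data(self, rng):
        sigma0 = 2.5
        X = rng.normal(size=(500, 4))
        y = rng.normal(0, sigma0, 500)
        d = fit_bart(X, y, SMALL)
        assert abs(np.median(d.sigma) - sigma0) / sigma0 < 0.15

    def test_acceptance_rates_interior(self, rng):
        X = rng.normal(size=(200, 3))
        y = np.sin(X[:, 0] * 2) + rng.normal(0, 0.3, 200)
        d = fit_bart(X, y, SMALL)
        for rates in d.acceptance:
            for rate in rates.values():
                assert 0.0 < rate < 1.0

    def test_single_tree_truth_recovered(self, rng):
        # data from a one-split tree: mean 3 if x0 <= 0 else -1
        n = 400
        X = rng.uniform(-1, 1, size=(n, 2))
        truth = np.where(X[:, 0] <= 0, 3.0, -1.0)
        y = truth + rng.normal(0, 0.2, n)
        d = fit_bart(X, y, SMALL)
        err = np.abs(d.posterior_mean() - truth)
        assert np.mean(err) < 0.2

    def test_nonfinite_inputs_rejected(self):
        X = np.zeros((20, 2))
        y = np.zeros(20)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_bart(X, y, SMALL)

    def test_draw_bookkeeping(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        cfg = BartConfig(m=10, n_chains=2, n_total=60, n_burn=20, seed=5)
        d = fit_bart(X, y, cfg)
        assert d.preds.shape == (2 * 40, 50)
        assert np.all(np.isfinite(d.preds))
        assert list(np.unique(d.chain)) == [0, 1]


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X = rng.uniform(-1, 1, size=(120, 3))
    y = X[:, 0] ** 2 + rng.normal(0, 0.2, 120)
    return X, fit_bart(X, y, SMALL)


class TestPredict:

    def test_training_rows_match_stored_draws_exactly(self, fitted):
        X, d = fitted
        np.testing.assert_array_equal(predict(d, X), d.preds)

    def test_duplicated_rows_identical(self, fitted):
        X, d = fitted
        Xdup = np.vstack([X[:1], X[:1]])
        out = predict(d, Xdup)
        np.testing.assert_array_equal(out[:, 0], out[:, 1])

    def test_column_mismatch_rejected(self, fitted):
        _, d = fitted
        with pytest.raises(ValueError, match="column"):
            predict(d, np.zeros((4, 5)))

    def test_forest_prediction_is_sum_of_tree_contributions(self, fitted):
        X, d = fitted
        forest = d.forests[7]
        parts = np.zeros(X.shape[0])
        for frozen in forest:
            parts = parts + eval_frozen_tree(frozen, X)
        total = parts * d.y_scale + d.y_shift
        np.testing.assert_array_equal(total, predict(d, X)[7])

    def test_stump_forest_predicts_single_value(self, rng):
        # constant y degenerates to all-stump forests: same value for any x
        X = rng.normal(size=(30, 2))
        d = fit_bart(X, np.full(30, 2.0), BartConfig(m=5, n_chains=1, n_total=60, n_burn=30))
        out = predict(d, rng.normal(size=(10, 2)))
        for row in out:
            np.testing.assert_allclose(row, row[0], atol=1e-12)
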