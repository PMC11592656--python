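import numpy as np
import pytest

from ldwcnn.cnn import CNNSpec
from ldwcnn.gwo import (FeatureMask, GWOConfig, ParamRange, binarize_positions,
                        initialize_pack, optimize, select_features,
                        tune_hyperparameters, update_pack)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


# ---------------------------------------------------------------------------
# Pack initialisation and updates
# ---------------------------------------------------------------------------

def test_initialisation_reproducible_and_within_bounds():
    bounds = [(-5, 5)] * 4
    s1 = initialize_pack(sphere, 6, bounds, seed=42)
    s2 = initialize_pack(sphere, 6, bounds, seed=42)
    np.testing.assert_array_equal(s1.positions, s2.positions)
    assert np.all(s1.positions >= -5) and np.all(s1.positions <= 5)
    assert s1.evaluations == 6


def test_degenerate_bounds_pin_all_positions():
    s = initialize_pack(sphere, 4, [(0, 0)] * 3, seed=0)
    np.testing.assert_array_equal(s.positions, 0)


def test_three_wolves_are_exactly_the_ordered_leaders():
    s = initialize_pack(sphere, 3, [(-5, 5)] * 2, seed=1)
    order = np.argsort(s.fitness)
    np.testing.assert_array_equal(s.leader_positions, s.positions[order])
    assert s.leader_fitness[0] <= s.leader_fitness[1] <= s.leader_fitness[2]


def test_fewer_than_three_wolves_rejected():
    with pytest.raises(ValueError, match="n_wolves"):
        initialize_pack(sphere, 2, [(-1, 1)], seed=0)


def test_zero_step_at_convergence():
    # final iteration (a = 0) with the whole pack and all leaders at one point
    s = initialize_pack(sphere, 4, [(-5, 5)] * 3, seed=0, max_iterations=10)
    point = np.full(3, 1.25)
    s.positions[:] = point
    s.fitness[:] = sphere(point)
    s.leader_positions[:] = point
    s.leader_fitness[:] = sphere(point)
    s.iteration = 9  # a(t) hits 0 on this update
    update_pack(s, sphere)
    np.testing.assert_allclose(s.positions, np.tile(point, (4, 1)), atol=1e-12)


class ScriptedRNG:
    """Returns queued draws, emulating the documented r1/r2 order."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, size):
        out = np.asarray(self.draws.pop(0), dtype=float)
        assert out.shape == (size,)
        return out


def test_single_update_matches_hand_computed_formulas():
    s = initialize_pack(sphere, 3, [(-10, 10)], seed=3, max_iterations=2)
    # freeze a known configuration: leaders at 1, 2, 3; wolves at 4, 5, 6
    s.leader_positions = np.array([[1.0], [2.0], [3.0]])
    s.leader_fitness = np.array([1.0, 4.0, 9.0])
    s.positions = np.array([[4.0], [5.0], [6.0]])
    s.fitness = np.array([16.0, 25.0, 36.0])
    draws = [[0.5], [0.25]] * 9  # r1 = 0.5, r2 = 0.25 for every wolf/leader
    update_pack(s, sphere, rng=ScriptedRNG(draws))
    # t=0, T=2 -> a = 2 (1 - 1/2) = 1; A = 2 a r1 - a = 0; C = 2 r2 = 0.5
    # candidate_l = x_l - A |C x_l - x| = x_l, so new position = mean(1,2,3) = 2
    np.testing.assert_allclose(s.positions, 2.0)
    # leaders re-ranked over old leaders plus moved pack
    assert s.leader_fitness[0] == 1.0


def test_update_never_leaves_bounds_and_is_elitist():
    rng = np.random.default_rng(0)

    def rastrigin(x):
        x = np.asarray(x)
        return float(10 * x.size + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))

    s = initialize_pack(rastrigin, 8, [(-5.12, 5.12)] * 3, seed=7, max_iterations=30)
    best = s.leader_fitness[0]
    for _ in range(30):
        update_pack(s, rastrigin)
        assert np.all(s.positions >= -5.12 - 1e-12)
        assert np.all(s.positions <= 5.12 + 1e-12)
        assert s.leader_fitness[0] <= best + 1e-15
        best = s.leader_fitness[0]


# ---------------------------------------------------------------------------
# optimize()
# ---------------------------------------------------------------------------

def test_history_is_monotone_and_budget_respected(tmp_path):
    log = tmp_path / "run.csv"
    res = optimize(sphere, [(-5, 5)] * 5, n_wolves=12, T=40, seed=0, log_path=log)
    assert len(res.history) == 40
    assert np.all(np.diff(res.history) <= 1e-15)
    assert res.evaluations <= 12 * 41
    assert res.best_fitness < 0.1
    assert log.read_text().count("\n") == 41  # header + one row per iteration


def test_constant_objective_yields_flat_history():
    res = optimize(lambda x: 3.5, [(-1, 1)] * 2, n_wolves=5, T=7, seed=1)
    assert res.best_fitness == 3.5
    assert np.all(res.history == 3.5)


def test_single_iteration_history_and_t_validation():
    res = optimize(sphere, [(-1, 1)] * 2, n_wolves=4, T=1, seed=0)
    assert len(res.history) == 1
    with pytest.raises(ValueError):
        optimize(sphere, [(-1, 1)], n_wolves=4, T=0, seed=0)


def test_bit_exact_reproducibility():
    r1 = optimize(sphere, [(-5, 5)] * 4, n_wolves=10, T=25, seed=99)
    r2 = optimize(sphere, [(-5, 5)] * 4, n_wolves=10, T=25, seed=99)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)
    np.testing.assert_array_equal(r1.history, r2.history)


# ---------------------------------------------------------------------------
# Binary decoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("position,expected", [
    ([-10.0, -20.0, -30.0], [True, False, False]),  # repair rule: largest sigmoid
    ([0.0, 0.0], [True, False]),                     # strict threshold, then repair
    ([-10.0, 10.0], [False, True]),
])
def test_binarisation_threshold_and_repair(position, expected):
    mask = binarize_positions(np.array(position))[0]
    assert mask.bits.tolist() == expected
    assert mask.selected_count >= 1


def test_empty_mask_construction_rejected():
    with pytest.raises(ValueError):
        FeatureMask(np.zeros(3, dtype=bool))


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def _planted_evaluator(seed):
    """Validation error of a ridge linear model on 2 informative + 8 noise."""
    rng = np.random.default_rng(seed)
    n = 120
    X = rng.normal(size=(n, 10))
    y = X[:, 0] + X[:, 1] + 0.3 * rng.normal(size=n)
    tr, va = slice(0, 80), slice(80, n)

    def evaluator(mask):
        cols = mask.indices
        A = X[tr][:, cols]
        w = np.linalg.solve(A.T @ A + 1e-6 * np.eye(len(cols)), A.T @ y[tr])
        resid = X[va][:, cols] @ w - y[va]
        return float(np.mean(resid ** 2))

    return evaluator


def test_planted_informative_features_recovered_across_seeds():
    hits = 0
    for seed in range(10):
        mask = select_features(_planted_evaluator(seed), 10,
                               GWOConfig(n_wolves=10, iterations=15, seed=seed))
        hits += bool(mask.bits[0] and mask.bits[1])
    assert hits >= 9


def test_constant_evaluator_returns_some_nonempty_mask():
    mask = select_features(lambda m: 1.0, 6,
                           GWOConfig(n_wolves=5, iterations=3, seed=0,
                                     lambda_sparsity=0.0))
    assert mask.selected_count >= 1


def test_one_dimensional_problem_selects_the_only_feature():
    mask = select_features(lambda m: 0.0, 1)
    assert mask.bits.tolist() == [True]


def test_evaluator_failure_is_contained():
    def flaky(mask):
        if mask.bits[0]:
            raise RuntimeError("boom")
        return float(mask.selected_count)

    mask = select_features(flaky, 4, GWOConfig(n_wolves=5, iterations=4, seed=2))
    assert mask.selected_count >= 1


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

def test_collapsed_space_returns_that_point():
    space = {"learning_rate": ParamRange(1e-3, 1e-3, log=True),
             "dropout_rate": ParamRange(0.4, 0.4)}
    spec = tune_hyperparameters(space, lambda s: 0.9,
                                GWOConfig(n_wolves=3, iterations=1, seed=0))
    assert spec.learning_rate == pytest.approx(1e-3)
    assert spec.dropout_rate == pytest.approx(0.4)


def test_unimodal_surrogate_optimum_recovered_within_5_percent():
    # analytic surrogate with a closed-form optimum at lr = 1e-3, dropout = 0.4
    def surrogate(spec: CNNSpec) -> float:
        return 1.0 - ((np.log10(spec.learning_rate) + 3) ** 2
                      + (spec.dropout_rate - 0.4) ** 2)

    space = {"learning_rate": ParamRange(1e-4, 1e-2, log=True),
             "dropout_rate": ParamRange(0.2, 0.7)}
    spec = tune_hyperparameters(space, surrogate,
                                GWOConfig(n_wolves=12, iterations=30, seed=5))
    assert abs(np.log10(spec.learning_rate) + 3) <= 0.05 * 2  # 5% of the log range
    assert abs(spec.dropout_rate - 0.4) <= 0.05 * 0.5


def test_tuning_reproducible_and_integer_decoding():
    space = {"conv1_filters": ParamRange(8, 64, integer=True)}
    ev = lambda s: -abs(s.conv_layers[0].filters - 32)
    cfg = GWOConfig(n_wolves=6, iterations=10, seed=3)
    s1 = tune_hyperparameters(space, ev, cfg)
    s2 = tune_hyperparameters(space, ev, cfg)
    assert s1.conv_layers[0].filters == s2.conv_layers[0].filters
    assert isinstance(s1.conv_layers[0].filters, int)


def test_all_candidates_failing_raises():
    def broken(spec):
        raise RuntimeError("no")

    with pytest.raises(RuntimeError, match="failed"):
        tune_hyperparameters({"dropout_rate": ParamRange(0.2, 0.7)}, broken,
                             GWOConfig(n_wolves=3, iterations=1, seed=0))
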