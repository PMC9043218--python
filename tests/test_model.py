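"""Ordinal model: likelihood arithmetic, fitting, nesting, and the
parallel-assumption screen."""

import numpy as np
import pytest
from scipy.special import expit, logit

from adrtriage.model import (
    FitOptions,
    ModelPartition,
    PartialProportionalOdds,
    PPOParameters,
    PPOResults,
    fit_model,
    lr_test_parallel,
    select_partition,
)
from adrtriage.simulate import SimulationConfig, default_true_model, simulate_reports
from conftest import make_table

# logistic-CDF differences for theta = (0, 1, 2, 3), zero slopes (oracle)
PROBS_0123 = np.diff(np.concatenate([[0.0], expit([0.0, 1.0, 2.0, 3.0]), [1.0]]))


def results_from_params(params: PPOParameters) -> PPOResults:
    """Wrap a raw parameter set as an unfitted results object."""
    shell = PartialProportionalOdds(
        np.array([1]), np.zeros((1, len(params.var_names))),
        var_names=params.var_names, nonparallel=params.partition.nonparallel_vars,
    )
    k = len(params.theta) + len(params.beta) + params.tau.size
    return PPOResults(
        model=shell, params=params, llf=0.0, converged=True, monotone_ok=True,
        nobs=0, bse_flat=np.full(k, np.nan), cov_params=None,
        options=FitOptions(), n_iterations=0,
    )


def intercept_model(theta, n_vars=1) -> PPOResults:
    part = ModelPartition(tuple(f"x{i+1}" for i in range(n_vars)))
    params = PPOParameters(np.asarray(theta, float), np.zeros(n_vars),
                           np.zeros((4, 0)), part)
    return results_from_params(params)


def uniform_model(n_vars=1) -> PPOResults:
    return intercept_model(logit(np.arange(1, 5) / 5.0), n_vars)


# -- cumulative logit ---------------------------------------------------------

def test_zero_model_gives_zero_logits():
    m = intercept_model([0, 0, 0, 0])
    assert all(m.cumulative_logit([1.0], j) == 0.0 for j in range(1, 5))


def test_parallel_slope_identity():
    """With q = 0 the spacing of the logits is independent of x."""
    part = ModelPartition(("a", "b"))
    m = results_from_params(
        PPOParameters([-1.0, 0.0, 1.0, 2.0], [0.7, -0.3], np.zeros((4, 0)), part)
    )
    for x in ([0, 0], [1, 0], [1, 1]):
        for j in range(1, 4):
            gap = m.cumulative_logit(x, j + 1) - m.cumulative_logit(x, j)
            assert gap == pytest.approx(1.0)


def test_cumulative_logit_hand_value():
    part = ModelPartition(("a",))
    m = results_from_params(
        PPOParameters([-1.0, 0.0, 1.0, 2.0], [0.5], np.zeros((4, 0)), part)
    )
    assert m.cumulative_logit([1.0], 3) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        m.cumulative_logit([1.0], 5)
    with pytest.raises(ValueError):
        m.cumulative_logit([1.0], 0)


# -- category probabilities ---------------------------------------------------

def test_uniform_construction():
    probs = uniform_model().category_probabilities([0.0])
    assert probs == pytest.approx(np.full(5, 0.2), abs=1e-12)


def test_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    part = ModelPartition(("a", "b"), ("c",))
    m = results_from_params(PPOParameters(
        np.sort(rng.normal(0, 1, 4)), rng.normal(0, 1, 2),
        np.sort(rng.normal(0, 0.5, 4))[:, None], part,
    ))
    X = rng.integers(0, 2, (50, 3)).astype(float)
    probs = m.category_probabilities(X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


def test_probability_oracle_values():
    m = intercept_model([0.0, 1.0, 2.0, 3.0])
    probs = m.category_probabilities([0.0])
    assert probs == pytest.approx(PROBS_0123, abs=1e-12)
    assert probs == pytest.approx([0.5, 0.2311, 0.1497, 0.0718, 0.0474], abs=5e-5)


# -- log-likelihood -----------------------------------------------------------

def test_uniform_log_likelihood():
    table = make_table(np.zeros((10, 1)), y=[1, 2, 3, 4, 5, 1, 2, 3, 4, 5])
    m = uniform_model(11)
    m.params = PPOParameters(
        logit(np.arange(1, 5) / 5.0), np.zeros(11), np.zeros((4, 0)),
        ModelPartition.all_parallel(),
    )
    assert m.log_likelihood(table) == pytest.approx(10 * np.log(0.2))


def test_empty_data_log_likelihood_is_zero():
    table = make_table(np.zeros((0, 1)), y=[])
    m = uniform_model(11)
    m.params = PPOParameters(
        logit(np.arange(1, 5) / 5.0), np.zeros(11), np.zeros((4, 0)),
        ModelPartition.all_parallel(),
    )
    assert m.log_likelihood(table) == 0.0


def test_two_record_log_likelihood_hand_value():
    table = make_table(np.zeros((2, 1)), y=[1, 5])
    m = uniform_model(11)
    m.params = PPOParameters(
        [0.0, 1.0, 2.0, 3.0], np.zeros(11), np.zeros((4, 0)),
        ModelPartition.all_parallel(),
    )
    expected = np.log(0.5) + np.log(PROBS_0123[-1])
    assert m.log_likelihood(table) == pytest.approx(expected, abs=1e-12)


# -- fitting ------------------------------------------------------------------

def test_intercept_only_fit_matches_empirical_cumulative_frequencies():
    rng = np.random.default_rng(7)
    y = rng.integers(1, 6, 200)
    table = make_table(np.zeros((200, 1)), y=y)
    res = fit_model(table, ModelPartition(("casualty_assessment_1",)))
    emp = np.cumsum(np.bincount(y, minlength=6)[1:5]) / 200
    # beta is free but the covariate is constant zero, so theta is closed-form
    assert expit(res.theta) == pytest.approx(emp, abs=1e-8)


def test_parameter_recovery_within_three_se(sim_config, sim_table, fitted_model):
    truth = np.concatenate([
        sim_config.true_model.theta,
        sim_config.true_model.beta,
        sim_config.true_model.tau.ravel(),
    ])
    z = (fitted_model.params_flat - truth) / fitted_model.bse_flat
    assert fitted_model.converged
    assert np.abs(z).max() < 3.0


def test_ppo_with_empty_nonparallel_set_equals_po(sim_table):
    po = fit_model(sim_table, ModelPartition.all_parallel())
    ppo = fit_model(sim_table, ModelPartition(tuple(reversed(po.partition.all_vars)), ()))
    assert ppo.llf == pytest.approx(po.llf, abs=1e-6)


def test_nesting_llf_ordering(sim_table):
    po = fit_model(sim_table, ModelPartition.all_parallel())
    names = po.partition.all_vars
    ppo = fit_model(
        sim_table,
        ModelPartition(tuple(v for v in names if v != "casualty_assessment_5"),
                       ("casualty_assessment_5",)),
    )
    assert ppo.llf >= po.llf - 1e-8


def test_fit_is_deterministic(sim_table, sim_config):
    part = sim_config.true_model.partition
    a = fit_model(sim_table, part)
    b = fit_model(sim_table, part)
    assert (a.params_flat == b.params_flat).all()
    assert a.llf == b.llf


def test_empty_category_policy():
    rng = np.random.default_rng(3)
    y = rng.choice([2, 3, 4, 5], 300)  # category 1 never used
    X = rng.integers(0, 2, (300, 2))
    table = make_table(X, y=y)
    part = ModelPartition(("casualty_assessment_1", "casualty_assessment_2"))
    with pytest.raises(ValueError, match="category 1"):
        fit_model(table, part)
    res = fit_model(table, part, FitOptions(empty_category_policy="merge"))
    assert len(res.theta) == 3
    probs = res.category_probabilities(np.zeros(2))
    assert probs[0] == 0.0 and probs.sum() == pytest.approx(1.0)


def test_monotone_flag_and_crossing_floor():
    # tau chosen to force crossing cumulative curves at x = 1
    part = ModelPartition((), ("a",))
    m = results_from_params(PPOParameters(
        [-1.0, 0.0, 1.0, 2.0], np.zeros(0),
        np.array([[2.5], [0.0], [0.0], [0.0]]), part,
    ))
    probs = m.category_probabilities([1.0])
    assert m.n_crossing_events == 1
    assert (probs >= 0).all() and probs.sum() == pytest.approx(1.0)


def test_refuses_more_parameters_than_observations():
    table = make_table(np.zeros((5, 11)), y=[1, 2, 3, 4, 5])
    with pytest.raises(ValueError, match="free parameters"):
        fit_model(table, ModelPartition.all_parallel())


# -- prediction ---------------------------------------------------------------

def test_tie_breaks_toward_lower_category():
    assert uniform_model().predict_category([0.0]) == 1


def test_argmax_prediction():
    m = intercept_model([0.0, 1.0, 2.0, 3.0])
    assert m.predict_category([0.0]) == 1  # P(Y=1) = 0.5
    high = intercept_model([-4.0, -3.5, -3.0, -2.5])  # mass on category 5
    assert high.predict_category([0.0]) == 5


# -- parallel-assumption testing ----------------------------------------------

def _parallel_table(n, seed, beta=(0.8, -0.5, 0.3)):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, (n, 3))
    part = ModelPartition(("casualty_assessment_1", "casualty_assessment_2",
                           "casualty_assessment_3"))
    params = PPOParameters(logit(np.arange(1, 5) / 5.0), np.array(beta),
                           np.zeros((4, 0)), part)
    F = params.cumulative_probabilities(X.astype(float))
    P = np.diff(np.hstack([np.zeros((n, 1)), F, np.ones((n, 1))]), axis=1)
    y = 1 + (rng.random(n)[:, None] > np.cumsum(P, axis=1)[:, :-1]).sum(axis=1)
    return make_table(X, y=y), part


def test_lr_statistic_nonnegative_with_df_3():
    table, part = _parallel_table(600, 11)
    res = lr_test_parallel(table, "casualty_assessment_2", predictors=part.all_vars)
    assert res.statistic >= -1e-8
    assert res.df == 3
    assert 0 <= res.p_value <= 1
    assert res.reliable


def test_select_partition_alpha_zero_keeps_everything_parallel(sim_table):
    part = select_partition(sim_table, alpha=0.0)
    assert part.nonparallel_vars == ()


def test_select_partition_finds_planted_violation():
    """A strongly non-parallel variable (slope spread >= 1.5 across logits)
    is detected at n = 5000."""
    for seed in (101, 102, 103):
        part = ModelPartition(("casualty_assessment_1", "casualty_assessment_2"),
                              ("casualty_assessment_3",))
        params = PPOParameters(
            logit(np.arange(1, 5) / 5.0), np.array([0.5, -0.5]),
            np.array([[1.6], [0.9], [0.4], [0.1]]), part,
        )
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, (5000, 3))
        F = params.cumulative_probabilities(X.astype(float))
        P = np.diff(np.hstack([np.zeros((5000, 1)), F, np.ones((5000, 1))]), axis=1)
        y = 1 + (rng.random(5000)[:, None] > np.cumsum(P, axis=1)[:, :-1]).sum(axis=1)
        table = make_table(X, y=y)
        found = select_partition(table, alpha=0.05, predictors=part.all_vars)
        assert "casualty_assessment_3" in found.nonparallel_vars


# -- serialization ------------------------------------------------------------

def test_json_round_trip_predicts_identically(fitted_model, sim_table, tmp_path):
    path = tmp_path / "model.json"
    fitted_model.to_json(path)
    loaded = PPOResults.from_json(path)
    X = sim_table.predictors()[:20]
    assert np.allclose(
        loaded.category_probabilities(X), fitted_model.category_probabilities(X)
    )
    assert loaded.llf == fitted_model.llf


def test_small_dataset_llf_matches_generic_optimizer():
    """Quasi-Newton MLE agrees with a derivative-free oracle on tiny data."""
    from scipy.optimize import minimize

    table, part = _parallel_table(50, 21, beta=(0.6, -0.6, 0.0))
    nonpar = ModelPartition(part.all_vars[:2], (part.all_vars[2],))
    res = fit_model(table, nonpar)
    y = table.labels()
    X = table.df[list(nonpar.all_vars)].to_numpy(float)

    def nll(p):
        params = PPOParameters(p[:4], p[4:6], p[6:].reshape(4, 1), nonpar)
        F = params.cumulative_probabilities(X)
        P = np.diff(np.hstack([np.zeros((50, 1)), F, np.ones((50, 1))]), axis=1)
        pr = P[np.arange(50), y - 1]
        return 1e9 if (pr <= 0).any() else -np.log(pr).sum()

    # iterated Nelder-Mead restarts escape simplex stalls in 10 dimensions
    x = np.concatenate([logit(np.arange(1, 5) / 5.0), np.zeros(6)])
    best = np.inf
    for _ in range(8):
        fit = minimize(nll, x, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-13})
        x = fit.x
        if best - fit.fun < 1e-10:
            best = min(best, fit.fun)
            break
        best = fit.fun
    assert res.llf == pytest.approx(-best, abs=1e-4)
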