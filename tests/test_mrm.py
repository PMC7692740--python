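from itertools import permutations
from math import factorial

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from conftest import make_dm, random_distance_matrix
from seedpref.mantel import mantel_test
from seedpref.mrm import (mrm_fit, variance_partition,
                          vectorize_lower_triangle)


def ols_normal_equations_oracle(Xcols, y):
    """Independent OLS via the normal equations."""
    X = np.column_stack([np.ones_like(y)] + list(Xcols))
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    return beta, r2


def mrm_enumeration_oracle(Mresp, Xcols):
    """Exact term and model permutation p-values by refitting the regression
    for every relabeling of the response matrix."""
    n = Mresp.shape[0]
    iu = np.triu_indices(n, k=1)
    beta_obs, r2_obs = ols_normal_equations_oracle(Xcols, Mresp[iu])
    term_counts = np.zeros(len(Xcols))
    model_count = 0
    for perm in permutations(range(n)):
        p = np.asarray(perm)
        beta, r2 = ols_normal_equations_oracle(Xcols, Mresp[np.ix_(p, p)][iu])
        term_counts += np.abs(beta[1:]) >= np.abs(beta_obs[1:]) - 1e-12
        model_count += r2 >= r2_obs - 1e-12
    total = factorial(n)
    return term_counts / total, model_count / total


def test_vectorize_lower_triangle_order_and_length(rng):
    D = make_dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
    np.testing.assert_array_equal(vectorize_lower_triangle(D), [1, 2, 3])
    D28 = random_distance_matrix(rng, 28)
    v = vectorize_lower_triangle(D28)
    assert v.shape == (378,)
    np.testing.assert_array_equal(squareform(v), D28.values)


def test_single_predictor_r2_equals_squared_mantel_r(rng):
    resp = random_distance_matrix(rng, 10, "resp")
    pred = random_distance_matrix(rng, 10, "pred")
    fit = mrm_fit(resp, [pred], n_permutations=9, seed=0)
    r = mantel_test(resp, pred, n_permutations=9, seed=0).r
    assert fit.r_squared == pytest.approx(r ** 2, abs=1e-10)


def test_perfect_linear_combination_gives_r2_one(rng):
    E1 = random_distance_matrix(rng, 8, "e1")
    E2 = random_distance_matrix(rng, 8, "e2")
    resp = make_dm(0.25 + 2.0 * E1.values + 0.5 * E2.reorder(E1.labels).values,
                   labels=list(E1.labels), block_name="resp")
    np.fill_diagonal(resp.values, 0.0)
    fit = mrm_fit(resp, [E1, E2], n_permutations=9, seed=0)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
    assert fit.coefficients["e1"] == pytest.approx(2.0, abs=1e-8)
    assert fit.coefficients["e2"] == pytest.approx(0.5, abs=1e-8)


def test_ols_matches_normal_equations_oracle(rng):
    resp = random_distance_matrix(rng, 6, "resp")
    preds = [random_distance_matrix(rng, 6, f"e{k}") for k in range(3)]
    fit = mrm_fit(resp, preds, n_permutations=9, seed=0)
    cols = [p.reorder(resp.labels).condensed() for p in preds]
    beta_ref, r2_ref = ols_normal_equations_oracle(cols, resp.condensed())
    assert fit.intercept == pytest.approx(beta_ref[0], abs=1e-8)
    for k, p in enumerate(preds):
        assert fit.coefficients[p.block_name] == pytest.approx(
            beta_ref[k + 1], abs=1e-8)
    assert fit.r_squared == pytest.approx(r2_ref, abs=1e-8)


def test_exhaustive_permutation_p_matches_enumeration(rng):
    """n = 5 objects: all 120 relabelings of the response enumerated."""
    resp = random_distance_matrix(rng, 5, "resp")
    preds = [random_distance_matrix(rng, 5, f"e{k}") for k in range(2)]
    fit = mrm_fit(resp, preds, n_permutations=9999, seed=0)
    assert fit.exhaustive and fit.n_permutations == 120
    cols = [p.reorder(resp.labels).condensed() for p in preds]
    term_ref, model_ref = mrm_enumeration_oracle(resp.values, cols)
    for k, p in enumerate(preds):
        assert fit.term_p_values[p.block_name] == term_ref[k]
    assert fit.model_p_value == model_ref


def test_rank_deficient_design_raises(rng):
    resp = random_distance_matrix(rng, 7, "resp")
    E = random_distance_matrix(rng, 7, "e1")
    twin = make_dm(E.values.copy(), labels=list(E.labels), block_name="e2")
    with pytest.raises(ValueError, match="rank-deficient"):
        mrm_fit(resp, [E, twin], n_permutations=9, seed=0)


def test_adding_noise_term_never_decreases_r2(rng):
    resp = random_distance_matrix(rng, 9, "resp")
    E1 = random_distance_matrix(rng, 9, "e1")
    E2 = random_distance_matrix(rng, 9, "noise")
    r2_one = mrm_fit(resp, [E1], n_permutations=9, seed=0).r_squared
    r2_two = mrm_fit(resp, [E1, E2], n_permutations=9, seed=0).r_squared
    assert r2_two >= r2_one - 1e-12


def test_results_independent_of_term_order(rng):
    resp = random_distance_matrix(rng, 8, "resp")
    preds = [random_distance_matrix(rng, 8, f"e{k}") for k in range(3)]
    fit_a = mrm_fit(resp, preds, n_permutations=199, seed=5)
    fit_b = mrm_fit(resp, preds[::-1], n_permutations=199, seed=5)
    for p in preds:
        name = p.block_name
        assert fit_a.coefficients[name] == pytest.approx(
            fit_b.coefficients[name], abs=1e-10)
        assert fit_a.term_p_values[name] == fit_b.term_p_values[name]
    assert fit_a.r_squared == pytest.approx(fit_b.r_squared, abs=1e-12)


def test_label_mismatch_raises(rng):
    resp = random_distance_matrix(rng, 6, "resp")
    other = make_dm(np.zeros((6, 6)), labels=list("uvwxyz"),
                    block_name="other")
    with pytest.raises(ValueError, match="label mismatch"):
        mrm_fit(resp, [other], n_permutations=9, seed=0)


def test_partition_single_term_is_total(rng):
    resp = random_distance_matrix(rng, 8, "resp")
    E = random_distance_matrix(rng, 8, "e1")
    fit = mrm_fit(resp, [E], n_permutations=9, seed=0)
    part = variance_partition(resp, [E], fit=fit)
    assert part.unique_r2["e1"] == pytest.approx(part.total_r2, abs=1e-12)
    assert part.collinearity_r2 == pytest.approx(0.0, abs=1e-12)


def test_partition_orthogonal_predictors_share_nothing(rng):
    """Uncorrelated explanatory vectors leave no shared variance."""
    E1 = random_distance_matrix(rng, 9, "e1")
    x1 = E1.condensed()
    x2 = rng.uniform(0.05, 1.0, size=x1.size)
    x2 = x2 - x1 * ((x2 - x2.mean()) @ (x1 - x1.mean())) / \
        ((x1 - x1.mean()) @ (x1 - x1.mean()))
    x2 = x2 - x2.min() + 0.05  # keep it a valid non-negative distance
    assert abs(np.corrcoef(x1, x2)[0, 1]) < 1e-10
    E2 = make_dm(squareform(x2), labels=list(E1.labels), block_name="e2")
    resp = random_distance_matrix(rng, 9, "resp")
    part = variance_partition(resp, [E1, E2])
    assert part.collinearity_r2 == pytest.approx(0.0, abs=1e-6)


def test_partition_redundant_predictors_share_everything(rng):
    """Two near-identical matrices: uniques collapse, the shared part
    carries the model R^2."""
    E1 = random_distance_matrix(rng, 10, "e1")
    noise = rng.normal(scale=1e-4, size=E1.values.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0.0)
    E2 = make_dm(np.abs(E1.values + noise), labels=list(E1.labels),
                 block_name="e2")
    resp = make_dm(np.abs(E1.values + 0.1), labels=list(E1.labels),
                   block_name="resp")
    np.fill_diagonal(resp.values, 0.0)
    part = variance_partition(resp, [E1, E2])
    assert part.unique_r2["e1"] == pytest.approx(0.0, abs=0.01)
    assert part.unique_r2["e2"] == pytest.approx(0.0, abs=0.01)
    assert part.collinearity_r2 == pytest.approx(part.total_r2, abs=0.02)


def test_partition_identity_total_equals_sum(rng):
    resp = random_distance_matrix(rng, 9, "resp")
    preds = [random_distance_matrix(rng, 9, f"e{k}") for k in range(3)]
    part = variance_partition(resp, preds)
    total = sum(part.unique_r2.values()) + part.collinearity_r2
    assert part.total_r2 == pytest.approx(total, abs=1e-12)
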