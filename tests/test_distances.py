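import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import make_dm, random_distance_matrix
from seedpref.distances import (DistanceMatrix, bray_curtis_matrix,
                                categorical_distance, mahalanobis_matrix,
                                univariate_distance, validate_distance_matrix)
from seedpref.traits import ConsumptionTable, TraitTable


def _consumption(values, predators=None):
    values = np.asarray(values, dtype=float)
    predators = predators or [f"p{i}" for i in range(values.shape[1])]
    idx = pd.Index([f"s{i}" for i in range(values.shape[0])],
                   name="species_id")
    return ConsumptionTable(pd.DataFrame(values, index=idx,
                                         columns=predators),
                            standardized=True)


def bray_curtis_oracle(X):
    """Brute-force Bray-Curtis by explicit summation."""
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = sum(abs(X[i, c] - X[j, c]) for c in range(X.shape[1]))
            den = sum(X[i, c] + X[j, c] for c in range(X.shape[1]))
            D[i, j] = num / den if den else 0.0
    return D


@pytest.mark.parametrize("rows, expected", [
    ([[0.3, 0.7], [0.3, 0.7]], 0.0),        # identical rows
    ([[1.0, 0.0], [0.0, 1.0]], 1.0),        # disjoint support
    ([[1.0, 0.5], [0.5, 1.0]], 1.0 / 3.0),  # hand evaluation
])
def test_bray_curtis_pairs(rows, expected):
    D = bray_curtis_matrix(_consumption(rows))
    assert D.values[0, 1] == pytest.approx(expected)
    assert D.metric_name == "bray-curtis"


def test_bray_curtis_matches_brute_force(rng):
    X = rng.uniform(0, 1, size=(5, 7))
    X[:, 0] /= X[:, 0].max()
    D = bray_curtis_matrix(_consumption(X))
    np.testing.assert_allclose(
        D.reorder([f"s{i}" for i in range(5)]).values,
        bray_curtis_oracle(X), atol=1e-12)
    assert D.values.max() <= 1.0 + 1e-12


def test_bray_curtis_single_column_reduces_to_ratio(rng):
    x = rng.uniform(0.01, 1, size=5)
    D = bray_curtis_matrix(_consumption(x[:, None])).reorder(
        [f"s{i}" for i in range(5)])
    expected = np.abs(x[:, None] - x[None, :]) / (x[:, None] + x[None, :])
    np.testing.assert_allclose(D.values, expected, atol=1e-12)


def test_bray_curtis_both_zero_rows_defined_as_zero():
    X = [[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]
    with pytest.warns(UserWarning, match="both rows zero"):
        D = bray_curtis_matrix(_consumption(X))
    assert D.reorder(["s0", "s1", "s2"]).values[0, 1] == 0.0


def test_bray_curtis_preconditions(small_consumption):
    with pytest.raises(ValueError, match="standardized"):
        bray_curtis_matrix(small_consumption)
    std = _consumption([[1.0, 0.2], [0.5, 1.0]])
    with pytest.raises(ValueError, match="empty"):
        bray_curtis_matrix(std, predator_subset=[])
    with pytest.raises(KeyError):
        bray_curtis_matrix(std, predator_subset=["nope"])


def _trait_table(X, name="block"):
    idx = pd.Index([f"s{i}" for i in range(X.shape[0])], name="species_id")
    return TraitTable(name, pd.DataFrame(
        X, index=idx, columns=[f"t{j}" for j in range(X.shape[1])]))


def test_mahalanobis_duplicate_species_distance_zero(rng):
    X = rng.normal(size=(6, 3))
    X[1] = X[0]
    D = mahalanobis_matrix(_trait_table(X)).reorder(
        [f"s{i}" for i in range(6)])
    assert D.values[0, 1] == pytest.approx(0.0, abs=1e-8)


def test_mahalanobis_whitened_equals_euclidean(rng):
    """Columns with identity sample covariance: Mahalanobis == Euclidean."""
    X = rng.normal(size=(10, 3))
    S = np.cov(X, rowvar=False, ddof=1)
    W = np.linalg.cholesky(np.linalg.inv(S))
    Xw = X @ W  # sample covariance is now the identity
    D = mahalanobis_matrix(_trait_table(Xw)).reorder(
        [f"s{i}" for i in range(10)])
    np.testing.assert_allclose(D.values, squareform(pdist(Xw, "euclidean")),
                               atol=1e-8)


def test_mahalanobis_affine_invariance(rng):
    """Any invertible recoding of columns leaves the matrix unchanged."""
    X = rng.normal(size=(12, 4))
    A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
    D1 = mahalanobis_matrix(_trait_table(X))
    D2 = mahalanobis_matrix(_trait_table(X @ A))
    np.testing.assert_allclose(D1.values, D2.values, atol=1e-8)


def test_mahalanobis_single_column_is_scaled_difference(rng):
    v = rng.normal(size=8)
    D = mahalanobis_matrix(_trait_table(v[:, None])).reorder(
        [f"s{i}" for i in range(8)])
    expected = np.abs(v[:, None] - v[None, :]) / np.std(v, ddof=1)
    np.testing.assert_allclose(D.values, expected, atol=1e-8)


def test_mahalanobis_wide_block_pinv_is_simplex(rng):
    """p >= n-1 columns: pseudo-inverse whitening collapses all pairwise
    distances to sqrt(2(n-1)) — the documented degeneracy the pipeline
    avoids with a ridge."""
    n = 8
    X = rng.normal(size=(n, 12))
    d = mahalanobis_matrix(_trait_table(X)).condensed()
    np.testing.assert_allclose(d, np.sqrt(2 * (n - 1)), rtol=1e-8)
    d_ridge = mahalanobis_matrix(_trait_table(X), ridge=1.0).condensed()
    assert d_ridge.std() / d_ridge.mean() > 0.01


def test_mahalanobis_errors(rng):
    with pytest.raises(ValueError, match="constant"):
        mahalanobis_matrix(_trait_table(np.ones((5, 2))))
    with pytest.raises(ValueError, match="2 species"):
        mahalanobis_matrix(_trait_table(rng.normal(size=(1, 2))))


def test_univariate_distance_values():
    masses = pd.Series([0.08, 8.72], index=["light", "heavy"],
                       name="mass_100_seeds")
    D = univariate_distance(masses, block_name="seed_mass")
    assert D.values[0, 1] == pytest.approx(8.64)
    eq = univariate_distance(pd.Series([2.0, 2.0], index=["a", "b"]))
    assert eq.values[0, 1] == 0.0
    with pytest.raises(ValueError, match="missing"):
        univariate_distance(pd.Series([1.0, np.nan], index=["a", "b"]))


def test_univariate_distance_symmetry(rng):
    v = pd.Series(rng.normal(size=9), index=[f"s{i}" for i in range(9)])
    D = univariate_distance(v)
    np.testing.assert_array_equal(D.values, D.values.T)


def test_categorical_distance_values():
    fam = pd.Series({"Arctium lappa": "Asteraceae",
                     "Cichorium intybus": "Asteraceae",
                     "Capsella bursa-pastoris": "Brassicaceae"},
                    name="family")
    D = categorical_distance(fam, block_name="taxonomy")
    df = D.to_dataframe()
    assert df.loc["Arctium lappa", "Cichorium intybus"] == 0.0
    assert df.loc["Arctium lappa", "Capsella bursa-pastoris"] == 1.0
    same = categorical_distance(pd.Series(["x", "x", "x"],
                                          index=["a", "b", "c"]))
    assert np.all(same.values == 0.0)
    with pytest.raises(ValueError, match="missing"):
        categorical_distance(pd.Series(["x", None], index=["a", "b"]))


def test_validate_distance_matrix_invariants(rng):
    D = random_distance_matrix(rng, 6)
    checked = validate_distance_matrix(D)
    assert list(checked.labels) == sorted(D.labels)
    # round-trip: re-sorting an already canonical matrix changes nothing
    again = validate_distance_matrix(checked)
    np.testing.assert_array_equal(checked.values, again.values)

    bad = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="symmetry"):
        validate_distance_matrix(make_dm(bad, labels=["a", "b"]))
    neg = np.array([[0.0, -1.0], [-1.0, 0.0]])
    with pytest.raises(ValueError, match="non-negativity"):
        validate_distance_matrix(make_dm(neg, labels=["a", "b"]))
    diag = np.array([[0.5, 1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="diagonal"):
        validate_distance_matrix(make_dm(diag, labels=["a", "b"]))


def test_distance_matrix_long_format(rng):
    D = random_distance_matrix(rng, 4)
    long = D.to_long()
    assert len(long) == 6
    rebuilt = {(r.i, r.j): r.distance for r in long.itertuples()}
    assert rebuilt[(D.labels[0], D.labels[1])] == D.values[0, 1]


def test_distance_matrix_label_contracts():
    with pytest.raises(ValueError, match="duplicate"):
        DistanceMatrix(("a", "a"), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="square"):
        DistanceMatrix(("a", "b"), np.zeros((2, 3)))
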