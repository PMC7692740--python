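"""Multiple regression on distance matrices (MRM) with permutation inference.

The lower triangle of the response distance matrix is regressed by ordinary
least squares on the lower triangles of the explanatory distance matrices
(plus an intercept).  Because entries of a distance matrix sharing an object
are not independent, significance comes from object-relabeling permutations:
rows and columns of the *response* matrix are permuted simultaneously, the
model is refit, and permuted coefficients at least as extreme as the
observed ones are counted (two-sided on |coefficient| for terms; upper tail
on R^2 for the model).  Explanatory matrices stay fixed, the standard MRM
scheme.

Variance partitioning follows a leave-one-out commonality logic: the unique
contribution of a term is the drop in R^2 when it alone is removed, and the
explained variance not attributable to any single term — the shared,
"collinearity" portion — is the remainder of the model R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np

from .distances import DistanceMatrix

__all__ = ["MRMFit", "VariancePartition", "vectorize_lower_triangle",
           "mrm_fit", "variance_partition"]


@dataclass(frozen=True)
class MRMFit:
    response_name: str
    term_names: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    term_p_values: dict[str, float]
    model_p_value: float
    n_permutations: int
    alpha: float
    seed: int | None
    exhaustive: bool

    @property
    def significant_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.term_names
                     if self.term_p_values[t] < self.alpha)


@dataclass(frozen=True)
class VariancePartition:
    term_names: tuple[str, ...]
    unique_r2: dict[str, float]
    collinearity_r2: float
    total_r2: float


def vectorize_lower_triangle(D: DistanceMatrix) -> np.ndarray:
    """Distance vector of length n(n-1)/2 in row-major i<j order."""
    return D.condensed()


def _design(response: DistanceMatrix,
            explanatory: list[DistanceMatrix]) -> tuple[np.ndarray, np.ndarray,
                                                        tuple[str, ...]]:
    if not explanatory:
        raise ValueError("need at least one explanatory matrix")
    names = []
    cols = []
    for E in explanatory:
        if set(E.labels) != set(response.labels):
            raise ValueError(f"label mismatch for block {E.block_name!r}")
        cols.append(E.reorder(response.labels).condensed())
        names.append(E.block_name or f"term_{len(names)}")
    y = response.condensed()
    k = len(cols)
    if len(y) < k + 2:
        raise ValueError("too few distance pairs for the number of terms")
    X = np.column_stack([np.ones_like(y)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design among blocks {names}; "
                         "remove perfectly collinear matrices")
    return X, y, tuple(names)


def _fit_stats(P: np.ndarray, X: np.ndarray, y: np.ndarray,
               ss_tot: float) -> tuple[np.ndarray, float]:
    beta = P @ y
    resid = y - X @ beta
    r2 = 1.0 - (resid @ resid) / ss_tot
    return beta, r2


def mrm_fit(response: DistanceMatrix,
            explanatory: list[DistanceMatrix],
            n_permutations: int = 9999,
            alpha: float = 0.1,
            seed: int | None = None,
            use_ranks: bool = False) -> MRMFit:
    """Fit MRM and assess term/model significance by response permutation.

    ``use_ranks`` replaces every distance vector by its ranks before the
    regression (a rank-based MRM variant); the default regresses raw
    distances.  When n! does not exceed ``n_permutations`` the permutation
    set is enumerated exhaustively and p-values are exact.
    """
    X, y, names = _design(response, explanatory)
    M = response.values

    if use_ranks:
        from scipy.stats import rankdata
        y = rankdata(y)
        X = np.column_stack([X[:, 0]] +
                            [rankdata(X[:, j]) for j in range(1, X.shape[1])])

    n = response.n
    iu = np.triu_indices(n, k=1)
    ybar = y.mean()
    ss_tot = float((y - ybar) @ (y - ybar))
    if ss_tot == 0:
        raise ValueError("constant response distances")
    P = np.linalg.pinv(X)
    beta_obs, r2_obs = _fit_stats(P, X, y, ss_tot)

    tol = 1e-12
    exhaustive = factorial(n) <= n_permutations

    def perm_vector(p: np.ndarray) -> np.ndarray:
        yp = M[np.ix_(p, p)][iu]
        if use_ranks:
            from scipy.stats import rankdata
            yp = rankdata(yp)
        return yp

    term_counts = np.zeros(len(names))
    model_count = 0
    if exhaustive:
        total = 0
        for perm in iter_permutations(range(n)):
            beta_p, r2_p = _fit_stats(P, X, perm_vector(np.asarray(perm)),
                                      ss_tot)
            term_counts += (np.abs(beta_p[1:]) >= np.abs(beta_obs[1:]) - tol)
            model_count += r2_p >= r2_obs - tol
            total += 1
        term_p = term_counts / total
        model_p = model_count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        term_counts += 1  # observed is its own permutation
        model_count += 1
        for _ in range(n_permutations):
            beta_p, r2_p = _fit_stats(P, X, perm_vector(rng.permutation(n)),
                                      ss_tot)
            term_counts += (np.abs(beta_p[1:]) >= np.abs(beta_obs[1:]) - tol)
            model_count += r2_p >= r2_obs - tol
        term_p = term_counts / (n_permutations + 1)
        model_p = model_count / (n_permutations + 1)
        n_used = n_permutations

    return MRMFit(
        response_name=response.block_name or "response",
        term_names=names,
        intercept=float(beta_obs[0]),
        coefficients={t: float(b) for t, b in zip(names, beta_obs[1:])},
        r_squared=float(r2_obs),
        term_p_values={t: float(p) for t, p in zip(names, term_p)},
        model_p_value=float(model_p),
        n_permutations=n_used,
        alpha=alpha,
        seed=seed,
        exhaustive=exhaustive,
    )


def _r2(X: np.ndarray, y: np.ndarray, ss_tot: float) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return 1.0 - (resid @ resid) / ss_tot


def variance_partition(response: DistanceMatrix,
                       explanatory: list[DistanceMatrix],
                       fit: MRMFit | None = None,
                       use_ranks: bool = False) -> VariancePartition:
    """Leave-one-out unique contributions and the shared remainder.

    unique_r2[k] = R^2(full) - R^2(all terms but k); what the full model
    explains beyond the sum of uniques is reported as the collinearity
    share.  Negative uniques (possible numerically with suppressor
    structure) are reported as computed, with a warning.
    """
    X, y, names = _design(response, explanatory)
    if use_ranks:
        from scipy.stats import rankdata
        y = rankdata(y)
        X = np.column_stack([X[:, 0]] +
                            [rankdata(X[:, j]) for j in range(1, X.shape[1])])
    ybar = y.mean()
    ss_tot = float((y - ybar) @ (y - ybar))
    r2_full = _r2(X, y, ss_tot)
    if fit is not None and abs(fit.r_squared - r2_full) > 1e-8:
        raise ValueError("fit does not match these inputs")
    unique = {}
    for j, name in enumerate(names):
        keep = [0] + [c for c in range(1, X.shape[1]) if c != j + 1]
        r2_minus = _r2(X[:, keep], y, ss_tot) if len(keep) > 1 else 0.0
        unique[name] = float(r2_full - r2_minus)
    neg = [t for t, u in unique.items() if u < -1e-10]
    if neg:
        warnings.warn(f"negative unique contributions for {neg} "
                      "(suppressor structure); reported as computed")
    collinearity = float(r2_full - sum(unique.values()))
    return VariancePartition(names, unique, collinearity, float(r2_full))
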