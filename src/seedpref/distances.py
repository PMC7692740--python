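"""Typed distance matrices between seed species.

Each explanatory data block is converted to a seed-by-seed dissimilarity
matrix with the metric suited to its data type:

* standardized consumption (the response)  -> Bray-Curtis,
* multivariate continuous trait blocks     -> Mahalanobis,
* a single continuous trait (100-seed mass)-> absolute difference,
* categorical attributes (family, strategy)-> simple matching (0/1).

Mahalanobis whitens by the across-species covariance ``S`` of the block's
columns; when ``S`` is singular — the chemistry blocks have more columns
than species — the Moore-Penrose pseudo-inverse is used, optionally a ridge
``S + lambda * diag(S)``.

All matrices are validated (symmetry, zero diagonal, non-negativity) and
canonicalized to lexicographic species order so that blocks align
bit-reproducibly across the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .traits import CategoricalTable, ConsumptionTable, TraitTable

__all__ = [
    "DistanceMatrix",
    "bray_curtis_matrix",
    "mahalanobis_matrix",
    "univariate_distance",
    "categorical_distance",
    "validate_distance_matrix",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with provenance tags."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric_name: str = ""
    block_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle vector in row-major i<j order, length n(n-1)/2."""
        return squareform(self.values, checks=False)

    def reorder(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise ValueError("reorder labels must be a permutation of the "
                             f"matrix labels for block {self.block_name!r}")
        idx = [self.labels.index(l) for l in labels]
        return replace(self, labels=tuple(labels),
                       values=self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_long(self) -> pd.DataFrame:
        """Long format (i, j, distance) over i<j pairs."""
        rows = [(self.labels[i], self.labels[j], self.values[i, j])
                for i in range(self.n) for j in range(i + 1, self.n)]
        return pd.DataFrame(rows, columns=["i", "j", "distance"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metric_name: str = "",
                       block_name: str = "") -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(str(l) for l in df.index), df.to_numpy(dtype=float),
                   metric_name, block_name)


def validate_distance_matrix(D: DistanceMatrix,
                             tol: float = _SYM_TOL) -> DistanceMatrix:
    """Assert distance-matrix invariants and return the label-sorted matrix."""
    v = D.values
    asym = np.abs(v - v.T)
    if asym.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"symmetry violated for pair ({D.labels[i]}, {D.labels[j]}): "
            f"|d_ij - d_ji| = {asym[i, j]:.3g}")
    diag = np.abs(np.diag(v))
    if diag.max(initial=0.0) > tol:
        i = int(np.argmax(diag))
        raise ValueError(f"zero-diagonal violated for {D.labels[i]}")
    if v.min(initial=0.0) < -tol:
        i, j = np.unravel_index(np.argmin(v), v.shape)
        raise ValueError(
            f"non-negativity violated for pair ({D.labels[i]}, {D.labels[j]})")
    sym = (v + v.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    sym = np.clip(sym, 0.0, None)
    order = sorted(D.labels)
    return replace(D, values=sym).reorder(order)


def bray_curtis_matrix(consumption: ConsumptionTable,
                       predator_subset: list[str] | None = None,
                       block_name: str = "preferences") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between seed species over predator columns.

    d(i,j) = sum_c |x_ic - x_jc| / sum_c (x_ic + x_jc), bounded in [0, 1].
    A pair of seeds both unconsumed within the subset has an undefined
    ratio; it is defined as 0 with a warning.
    """
    if not consumption.standardized:
        raise ValueError("consumption must be standardized first")
    if predator_subset is not None:
        if len(predator_subset) == 0:
            raise ValueError("empty predator subset")
        consumption = consumption.subset_predators(predator_subset)
    X = consumption.data.to_numpy(dtype=float)
    num = pdist(X, metric="cityblock")
    row_sums = X.sum(axis=1)
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    den = row_sums[iu] + row_sums[ju]
    zero = den == 0
    if zero.any():
        pairs = [(consumption.species[i], consumption.species[j])
                 for i, j in zip(iu[zero], ju[zero])]
        warnings.warn(f"Bray-Curtis undefined (both rows zero) for {pairs}; "
                      "defined as 0")
    d = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    D = DistanceMatrix(tuple(consumption.species), squareform(d),
                       "bray-curtis", block_name)
    return validate_distance_matrix(D)


def mahalanobis_matrix(block: TraitTable,
                       ridge: float | None = None) -> DistanceMatrix:
    """Covariance-whitened distance between species trait profiles.

    d(i,j) = sqrt((x_i - x_j)^T S^+ (x_i - x_j)) with ``S`` the across-species
    covariance (n-1 denominator).  A singular ``S`` (more columns than
    species) falls back to the Moore-Penrose pseudo-inverse; ``ridge``
    switches to inverting ``S + ridge * diag(S)`` instead (1e-6 is a typical
    weight).
    """
    X = block.data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 species")
    if X.shape[1] < 1:
        raise ValueError("need at least 1 trait column")
    S = np.cov(X, rowvar=False, ddof=1).reshape(X.shape[1], X.shape[1])
    if np.allclose(S, 0.0):
        raise ValueError(
            f"trait block {block.name!r} is constant: covariance is zero "
            "and no metric can be formed")
    if ridge is not None:
        S = S + ridge * np.diag(np.diag(S))
    VI = np.linalg.pinv(S, hermitian=True)
    # squared distances via the Gram matrix; clip tiny negatives from
    # pseudo-inverse round-off before the sqrt
    XV = X @ VI
    G = XV @ X.T
    g = np.diag(G)
    d2 = g[:, None] + g[None, :] - (G + G.T)  # symmetrize float round-off
    D = DistanceMatrix(tuple(block.species), np.sqrt(np.clip(d2, 0.0, None)),
                       "mahalanobis", block.name)
    return validate_distance_matrix(D)


def univariate_distance(values: pd.Series,
                        block_name: str = "") -> DistanceMatrix:
    """Absolute difference |v_i - v_j| for a single continuous trait."""
    if values.isna().any():
        missing = sorted(values.index[values.isna()])
        raise ValueError(f"missing trait value for species: {missing}")
    v = values.to_numpy(dtype=float)
    D = DistanceMatrix(tuple(str(s) for s in values.index),
                       np.abs(v[:, None] - v[None, :]),
                       "absolute-difference", block_name or str(values.name))
    return validate_distance_matrix(D)


def categorical_distance(labels: pd.Series,
                         block_name: str = "") -> DistanceMatrix:
    """Simple matching distance: 0 for same category, 1 otherwise."""
    if labels.isna().any():
        missing = sorted(labels.index[labels.isna()])
        raise ValueError(f"missing category for species: {missing}")
    cats = labels.to_numpy()
    D = DistanceMatrix(tuple(str(s) for s in labels.index),
                       (cats[:, None] != cats[None, :]).astype(float),
                       "simple-matching", block_name or str(labels.name))
    return validate_distance_matrix(D)
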