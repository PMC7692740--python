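"""Mantel permutation test between two distance matrices.

The statistic is the Pearson correlation of the lower-triangle vectors.
The null distribution is generated by relabeling the objects of the second
matrix: each permutation is applied simultaneously to its rows and columns,
which respects the dependence structure of distances sharing an object.

For n objects with n! no larger than the requested permutation count the
permutation set is enumerated exhaustively and the p-value is exact;
otherwise random relabelings are sampled and the observed statistic counts
as its own permutation (+1 in numerator and denominator), which keeps the
p-value valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np

from .distances import DistanceMatrix

__all__ = ["MantelResult", "mantel_test"]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str
    exhaustive: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _tail_count(r_perm: float, r_obs: float, alternative: str,
                tol: float = 1e-12) -> bool:
    if alternative == "greater":
        return r_perm >= r_obs - tol
    return abs(r_perm) >= abs(r_obs) - tol


def mantel_test(D1: DistanceMatrix, D2: DistanceMatrix,
                n_permutations: int = 999,
                seed: int | None = None,
                alternative: str = "greater") -> MantelResult:
    """Permutation test of association between two distance matrices.

    ``alternative='greater'`` is the one-sided positive-association test
    used for redundancy screening; ``'two-sided'`` tests |r|.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if set(D1.labels) != set(D2.labels):
        raise ValueError(
            f"label mismatch between {D1.block_name!r} and {D2.block_name!r}")
    if D1.n < 3:
        raise ValueError("need at least 3 objects")
    D2 = D2.reorder(D1.labels)

    x = D1.condensed()
    M2 = D2.values
    y = M2[np.triu_indices(D2.n, k=1)]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant distance vector: Mantel r undefined, "
                      "reporting r=0, p=1")
        return MantelResult(0.0, 1.0, 0, seed, alternative, True)

    r_obs = _pearson(x, y)
    n = D1.n
    iu = np.triu_indices(n, k=1)

    exhaustive = factorial(n) <= n_permutations
    if exhaustive:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            p = np.asarray(perm)
            y_perm = M2[np.ix_(p, p)][iu]
            if _tail_count(_pearson(x, y_perm), r_obs, alternative):
                count += 1
            total += 1
        p_value = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 1  # observed counted as its own permutation
        for _ in range(n_permutations):
            p = rng.permutation(n)
            y_perm = M2[np.ix_(p, p)][iu]
            if _tail_count(_pearson(x, y_perm), r_obs, alternative):
                count += 1
        p_value = count / (n_permutations + 1)
        n_used = n_permutations
    return MantelResult(r_obs, float(p_value), n_used, seed, alternative,
                        exhaustive)
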