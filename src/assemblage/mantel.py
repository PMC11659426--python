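"""Mantel rank-correlation test between two labeled distance matrices.

The statistic is the Spearman correlation over the n(n-1)/2 distinct
pairs; significance comes from simultaneously permuting the rows and
columns of the second matrix, which respects the dependence structure
of distance data.  The p-value uses the add-one (include-identity)
convention, so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .dissimilarity import DistanceError, DistanceMatrix

__all__ = ["MantelResult", "mantel_test", "DegenerateMatrixError"]


class DegenerateMatrixError(ValueError):
    """Raised when a matrix has a constant lower triangle (rank
    correlation undefined)."""


@dataclass
class MantelResult:
    rho: float
    p_one_sided: float
    n_permutations: int
    seed: int


def _spearman(x_rank: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of ranks; ``x_rank`` is already ranked."""
    y_rank = rankdata(y)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / denom)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 1000,
    tail: str = "greater",
    seed: int = 0,
) -> MantelResult:
    """Permutation Mantel test of the Spearman correlation between two
    distance matrices.

    Matrices are aligned by label (not by position).  ``tail="greater"``
    tests for positive correlation, the distance-decay direction;
    ``tail="less"`` tests the opposite tail.

    Raises :class:`DegenerateMatrixError` if either lower triangle is
    constant, and :class:`DistanceError` on label mismatch.
    """
    if tail not in ("greater", "less"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set(d1.labels) != set(d2.labels):
        raise DistanceError("label sets of the two matrices differ")
    d2 = d2.reorder(d1.labels)
    x = d1.condensed()
    y = d2.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateMatrixError("constant lower triangle; rho undefined")
    x_rank = rankdata(x)
    rho = _spearman(x_rank, y)

    rng = np.random.default_rng(seed)
    n = d1.n
    vals2 = d2.values
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = vals2[np.ix_(perm, perm)][np.tril_indices(n, k=-1)]
        r = _spearman(x_rank, y_perm)
        if tail == "greater":
            hits += r >= rho
        else:
            hits += r <= rho
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(rho=rho, p_one_sided=float(p),
                        n_permutations=n_perm, seed=seed)
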