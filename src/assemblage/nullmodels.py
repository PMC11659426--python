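"""Co-distribution null-model tests for community tables.

Two complementary tests of whether taxa co-occur more or less often
than expected by chance:

* the checkerboard co-occurrence (CC) score on presence/absence data,

      CC = 1 - [ sum_{i<j} (N_i - N_ij)(N_j - N_ij) ]
             / [ sum_{i<j} (N_i - N p_i p_j)(N_j - N p_i p_j) ]

  where N is the number of samples, N_i the occupancy of taxon i,
  N_ij the co-occurrence count and p_i = N_i / N.  It is a normalized,
  sign-reversed relative of the classical C-score: larger CC means
  more co-occurrence, smaller CC means segregation.  Its null is the
  fixed-fixed ("SIM9") model, which preserves both the number of taxa
  per sample and the number of samples per taxon via a Markov chain of
  checkerboard swaps.

* the MA score (generalized Morisita similarity) on relative
  abundances,

      MA = sum_i [ (sum_j p_ij)^2 - sum_j p_ij^2 ]
           / [ (N-1) sum_i sum_j p_ij^2 ]

  which is 1 when all samples have identical composition and 0 when
  every taxon is confined to a single sample.  Its null is the "IT"
  model, which re-assigns reads to cells proportionally to the
  remaining per-sample and per-taxon read quotas until both marginal
  totals are met exactly.

Observed scores significantly *below* the null distribution indicate
taxon segregation (e.g. competitive exclusion); scores above indicate
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .table import CommunityTable, PresenceAbsenceMatrix, to_proportions

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "NullTestResult",
    "DegenerateScoreError",
    "FrozenMatrixError",
    "cc_score",
    "ma_score",
    "sim9_null",
    "it_null",
    "null_test",
    "bonferroni_threshold",
]


class DegenerateScoreError(ValueError):
    """Raised when a score's denominator is exactly zero."""


class FrozenMatrixError(ValueError):
    """Raised when a presence/absence matrix admits no checkerboard
    swap, so the fixed-fixed chain cannot move."""


@dataclass
class NullTestResult:
    observed: float
    null_scores: np.ndarray
    p_low: float
    p_high: float
    null_mean: float
    null_sd: float
    seed: int


# ---------------------------------------------------------------------------
# Scores

def cc_score(pa: PresenceAbsenceMatrix) -> float:
    """Checkerboard co-occurrence score of a binary taxa x samples matrix.

    Larger values mean taxa co-occur more; the score is unbounded below
    (a perfect 2x2 checkerboard gives -3).
    """
    Z = pa.values.astype(np.float64)
    M, N = Z.shape
    if M < 2:
        raise ValueError("need at least 2 taxa")
    Ni = Z.sum(axis=1)
    C = Z @ Z.T  # co-occurrence counts N_ij (diagonal = N_i)
    p = Ni / N
    A = (Ni[:, None] - C) * (Ni[None, :] - C)
    num = (A.sum() - np.trace(A)) / 2.0
    E = N * p[:, None] * p[None, :]
    B = (Ni[:, None] - E) * (Ni[None, :] - E)
    den = (B.sum() - np.trace(B)) / 2.0
    if den == 0:
        raise DegenerateScoreError("CC denominator is zero (degenerate matrix)")
    return float(1.0 - num / den)


def cc_score_bruteforce(pa: PresenceAbsenceMatrix) -> float:
    """Reference double-loop evaluation of the CC score (test oracle)."""
    Z = pa.values
    M, N = Z.shape
    Ni = Z.sum(axis=1)
    p = Ni / N
    num = 0.0
    den = 0.0
    for i in range(M):
        for j in range(i):
            nij = int((Z[i] & Z[j]).sum())
            num += (Ni[i] - nij) * (Ni[j] - nij)
            e = N * p[i] * p[j]
            den += (Ni[i] - e) * (Ni[j] - e)
    if den == 0:
        raise DegenerateScoreError("CC denominator is zero (degenerate matrix)")
    return 1.0 - num / den


def ma_score(t: CommunityTable) -> float:
    """Generalized Morisita similarity over a proportions table.

    1 when all samples are compositionally identical, 0 when every
    taxon is present in exactly one sample.
    """
    if t.mode != "proportions":
        raise ValueError("ma_score expects a proportions-mode table")
    P = t.values
    if P.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not P.any():
        raise ValueError("all-zero table")
    N = P.shape[1]
    row_sums = P.sum(axis=1)
    sq = (P ** 2).sum(axis=1)
    num = (row_sums ** 2 - sq).sum()
    den = (N - 1) * sq.sum()
    if den == 0:
        raise DegenerateScoreError("MA denominator is zero")
    return float(num / den)


# ---------------------------------------------------------------------------
# SIM9 (fixed-fixed) null

@njit(cache=True)
def _swap_chain(mat, n_trials, seed):  # pragma: no cover
    np.random.seed(seed)
    M, N = mat.shape
    done = 0
    for _ in range(n_trials):
        r1 = np.random.randint(0, M)
        r2 = np.random.randint(0, M)
        c1 = np.random.randint(0, N)
        c2 = np.random.randint(0, N)
        if r1 == r2 or c1 == c2:
            continue
        a = mat[r1, c1]
        b = mat[r1, c2]
        c = mat[r2, c1]
        d = mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            done += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            done += 1
    return done



def _has_checkerboard(Z: np.ndarray) -> bool:
    Zb = Z.astype(np.int64)
    A = Zb @ (1 - Zb).T  # A[i,j] = #cols with i present, j absent
    mask = (A > 0) & (A.T > 0)
    np.fill_diagonal(mask, False)
    return bool(mask.any())


def sim9_null(
    pa: PresenceAbsenceMatrix,
    n_null: int = 1000,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
) -> Iterator[PresenceAbsenceMatrix]:
    """Fixed-fixed randomizations of a binary matrix by checkerboard swaps.

    A single Markov chain proposes random 2x2 submatrices and flips
    those of checkerboard form; every matrix emitted has exactly the
    observed row and column sums.  ``burn_in`` and ``thin`` count
    *trial* swaps (proposals), not accepted ones: the lazy chain that
    stays put on rejected proposals has a symmetric transition kernel
    and hence a uniform stationary distribution over the fixed-marginal
    state space, whereas spacing emissions by accepted swaps would
    oversample states with many available checkerboards.  Defaults:
    burn_in = 50x the number of 1s, thin = 5x the number of 1s.
    """
    Z = pa.values.astype(np.int8)
    if not _has_checkerboard(Z):
        raise FrozenMatrixError(
            "matrix admits no checkerboard swap; the fixed-fixed null is degenerate"
        )
    ones = int(Z.sum())
    if burn_in is None:
        burn_in = 50 * ones
    if thin is None:
        thin = max(5 * ones, 1)
    rng = np.random.default_rng(seed)
    work = Z.copy()

    def advance(n_trials: int) -> None:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        _swap_chain(work, n_trials, sub_seed)

    advance(burn_in)
    for _ in range(n_null):
        advance(thin)
        yield PresenceAbsenceMatrix(
            list(pa.taxon_ids), list(pa.sample_ids), work.copy()
        )


# ---------------------------------------------------------------------------
# IT (abundance) null

def it_null(
    t: CommunityTable,
    n_null: int = 1000,
    seed: int = 0,
) -> Iterator[CommunityTable]:
    """Randomized count tables with both marginal totals fixed, reads
    assigned proportionally to remaining per-taxon and per-sample quotas.

    Reads are conceptually placed one at a time into cell (i, j) with
    probability proportional to (remaining row-i quota) x (remaining
    column-j quota).  Because the row and column components factorize,
    the row choices form an urn process — a uniformly random ordering
    of the multiset of row tokens — independent of the column choices,
    so the scheme is realized exactly by pairing a shuffled row-token
    sequence with the column-token sequence and histogramming the
    pairs.  Marginals are met exactly by construction.
    """
    if t.mode != "counts":
        raise ValueError("it_null expects a counts-mode table")
    X = np.round(t.values).astype(np.int64)
    if (np.abs(t.values - X) > 1e-9).any():
        raise ValueError("it_null requires integer counts")
    total = int(X.sum())
    if total <= 0:
        raise ValueError("table has no reads")
    R = X.sum(axis=1)
    C = X.sum(axis=0)
    M, N = X.shape
    row_tokens = np.repeat(np.arange(M), R)
    col_tokens = np.repeat(np.arange(N), C)
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        shuffled = rng.permutation(row_tokens)
        flat = shuffled * N + col_tokens
        counts = np.bincount(flat, minlength=M * N).reshape(M, N)
        yield CommunityTable(
            pd.DataFrame(counts, index=t.taxon_ids, columns=t.sample_ids),
            mode="counts",
        )


def it_fill_sequential(
    X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Literal sequential remaining-quota read placement (test oracle).

    Equivalent in distribution to the token-shuffle used by
    :func:`it_null`; kept as an independent, step-by-step reference.
    """
    R = X.sum(axis=1).astype(np.int64).copy()
    C = X.sum(axis=0).astype(np.int64).copy()
    out = np.zeros_like(X, dtype=np.int64)
    while R.sum() > 0:
        i = rng.choice(len(R), p=R / R.sum())
        j = rng.choice(len(C), p=C / C.sum())
        out[i, j] += 1
        R[i] -= 1
        C[j] -= 1
    return out


# ---------------------------------------------------------------------------
# Testing machinery

def null_test(
    score: str,
    data,
    null: str,
    n_null: int = 1000,
    seed: int = 0,
    **null_kwargs,
) -> NullTestResult:
    """Score observed data against a null-model score distribution.

    Supported combinations: ``score="cc", null="sim9"`` on a
    :class:`PresenceAbsenceMatrix`, and ``score="ma", null="it"`` on a
    counts-mode :class:`CommunityTable` (each null table is converted
    to proportions before scoring, as is the observed table).

    Tail probabilities use the add-one convention:
    ``p_low = (1 + #{null <= observed}) / (1 + n_null)`` and
    analogously for ``p_high``; a small ``p_low`` means the observed
    score is unusually low (segregation).
    """
    if (score, null) == ("cc", "sim9"):
        if not isinstance(data, PresenceAbsenceMatrix):
            raise TypeError("cc/sim9 requires a PresenceAbsenceMatrix")
        observed = cc_score(data)
        nulls = np.array(
            [cc_score(m) for m in sim9_null(data, n_null=n_null, seed=seed,
                                            **null_kwargs)]
        )
    elif (score, null) == ("ma", "it"):
        if not isinstance(data, CommunityTable) or data.mode != "counts":
            raise TypeError("ma/it requires a counts-mode CommunityTable")
        observed = ma_score(to_proportions(data)[0])
        nulls = np.array(
            [ma_score(to_proportions(m)[0])
             for m in it_null(data, n_null=n_null, seed=seed, **null_kwargs)]
        )
    else:
        raise ValueError(f"unsupported score/null combination {score!r}/{null!r}")
    p_low = (1 + int((nulls <= observed).sum())) / (1 + n_null)
    p_high = (1 + int((nulls >= observed).sum())) / (1 + n_null)
    return NullTestResult(
        observed=float(observed),
        null_scores=nulls,
        p_low=float(p_low),
        p_high=float(p_high),
        null_mean=float(nulls.mean()),
        null_sd=float(nulls.std(ddof=1)) if n_null > 1 else 0.0,
        seed=seed,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha / n."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
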