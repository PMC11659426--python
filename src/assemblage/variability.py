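"""Variability and coverage profiles: CV-vs-mean, core-biome curves and
collector's (rarefaction) curves.

These summarize two complementary facets of a community survey: how
stable each taxon's or gene group's proportion is across samples
(coefficient of variation against mean proportion), and how taxon sets
overlap across samples (expected number of taxa shared by n random
samples; expected richness at a given read depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .table import CommunityTable, FunctionalProfile, PresenceAbsenceMatrix

__all__ = [
    "CVProfile",
    "cv_profile",
    "core_biome_curve",
    "collectors_curve",
]


@dataclass
class CVProfile:
    """Per-unit mean proportion and coefficient of variation."""

    data: pd.DataFrame  # columns: mean, cv; index: taxon/group ids
    n_excluded_zero_mean: int


def cv_profile(t: CommunityTable | FunctionalProfile, ddof: int = 1) -> CVProfile:
    """Mean proportion and CV (= sd / mean) of each row across samples.

    Uses the sample standard deviation (``ddof=1``) by default; rows
    with zero mean are excluded and counted.  Requires a proportions
    table with at least two samples.
    """
    if isinstance(t, CommunityTable) and t.mode != "proportions":
        raise ValueError("cv_profile expects a proportions-mode table")
    values = t.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute a CV")
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=ddof)
    keep = means > 0
    ids = t.taxon_ids if isinstance(t, CommunityTable) else t.group_ids
    df = pd.DataFrame(
        {"mean": means[keep], "cv": sds[keep] / means[keep]},
        index=np.asarray(ids, dtype=object)[keep],
    )
    return CVProfile(df, n_excluded_zero_mean=int((~keep).sum()))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def core_biome_curve(
    pa: PresenceAbsenceMatrix,
    method: str = "exact",
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Expected number of taxa present in all of n randomly chosen
    samples, for n = 1..N.

    ``exact`` evaluates the hypergeometric identity
    ``value(n) = sum_i C(k_i, n) / C(N, n)`` with k_i the occupancy of
    taxon i — the average over all size-n sample subsets.  ``subsample``
    is the Monte-Carlo average over ``n_draws`` random subsets.  The
    curve is non-increasing; value(1) is the mean per-sample richness
    and value(N) the size of the strict core.
    """
    N = pa.n_samples
    occ = pa.occupancy
    if method == "exact":
        out = np.zeros(N)
        for n in range(1, N + 1):
            feasible = occ >= n
            if feasible.any():
                terms = np.exp(_log_comb(occ[feasible], n) - _log_comb(N, n))
                out[n - 1] = terms.sum()
        return out
    if method == "subsample":
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        Z = pa.values
        out = np.zeros(N)
        for n in range(1, N + 1):
            acc = 0.0
            for _ in range(n_draws):
                cols = rng.choice(N, size=n, replace=False)
                acc += (Z[:, cols].min(axis=1) > 0).sum()
            out[n - 1] = acc / n_draws
        return out
    raise ValueError(f"unknown method {method!r}")


def collectors_curve(
    t: CommunityTable,
    sample_id: str,
    depths: list[int],
    method: str = "exact",
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Expected number of distinct taxa discovered after d reads drawn
    without replacement from one sample, for each depth d.

    ``exact`` uses the rarefaction identity
    ``E[S(d)] = sum_i [1 - C(T - c_i, d) / C(T, d)]`` with T the sample
    total and c_i each taxon's count; ``subsample`` averages over
    ``n_draws`` random without-replacement draws.
    """
    if t.mode != "counts":
        raise ValueError("collectors_curve expects a counts-mode table")
    j = t.sample_ids.index(sample_id)
    counts = np.round(t.values[:, j]).astype(np.int64)
    counts = counts[counts > 0]
    T = int(counts.sum())
    depths_arr = np.asarray(depths, dtype=np.int64)
    if (depths_arr < 1).any() or (depths_arr > T).any():
        raise ValueError(f"depths must lie in [1, {T}]")
    if method == "exact":
        out = np.zeros(len(depths_arr))
        for k, d in enumerate(depths_arr):
            feasible = (T - counts) >= d
            miss = np.zeros(len(counts))
            miss[feasible] = np.exp(
                _log_comb(T - counts[feasible], d) - _log_comb(T, d)
            )
            out[k] = (1.0 - miss).sum()
        return out
    if method == "subsample":
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        reads = np.repeat(np.arange(len(counts)), counts)
        out = np.zeros(len(depths_arr))
        for k, d in enumerate(depths_arr):
            acc = 0
            for _ in range(n_draws):
                draw = rng.choice(reads, size=int(d), replace=False)
                acc += len(np.unique(draw))
            out[k] = acc / n_draws
        return out
    raise ValueError(f"unknown method {method!r}")
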