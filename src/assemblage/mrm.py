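"""Stepwise multiple regression on distance matrices (MRM).

The response is a pairwise community dissimilarity matrix; candidate
predictors are pairwise absolute differences in environmental variables
plus geographic distance.  Each unordered sample pair is one datapoint
(the unfolded lower triangle).  Predictors enter one at a time by
forward selection; a candidate is included only if its coefficient is
significant (P < alpha) under simultaneous row/column permutation of
the response matrix, the standard permutation scheme for regression on
distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dissimilarity import DistanceError, DistanceMatrix

__all__ = [
    "PredictorSet",
    "RegressionFit",
    "abs_diff_matrix",
    "stepwise_mrm",
    "loso_cv_r2",
]


class PredictorSet(dict):
    """Named collection of aligned DistanceMatrix candidates."""

    def aligned(self, labels: list[str]) -> dict[str, DistanceMatrix]:
        return {name: dm.reorder(labels) for name, dm in self.items()}


@dataclass
class RegressionFit:
    selected: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r2: float
    r2_cv: float | None
    step_p_values: list[float]
    n_perm: int
    seed: int
    alpha: float = 0.05
    candidate_names: list[str] = field(default_factory=list)


def abs_diff_matrix(values: Mapping[str, float]) -> DistanceMatrix:
    """Pairwise |v_a - v_b| over samples; missing values (NaN/None)
    yield NaN pairs, which downstream fits drop per candidate."""
    labels = list(values)
    v = np.array([np.nan if values[k] is None else float(values[k])
                  for k in labels])
    if np.isnan(v).all():
        raise ValueError("all values missing")
    D = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels, D)


def _condensed_perm_indices(n: int) -> np.ndarray:
    """Map (i, j) with i > j to its position in the condensed vector."""
    pos = np.zeros((n, n), dtype=int)
    k = 0
    for i in range(n):
        for j in range(i):
            pos[i, j] = pos[j, i] = k
            k += 1
    return pos


def _ols_t(X: np.ndarray, y: np.ndarray, col: int) -> tuple[np.ndarray, float]:
    """OLS fit; returns (beta, t-statistic of column ``col``)."""
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.full(X.shape[1], np.nan), np.nan
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        return beta, np.nan
    rss = float(resid @ resid)
    # an exact fit leaves only float noise in the residuals; treat it as
    # zero rather than dividing two roundoff artefacts
    if rss <= 1e-16 * max(float(y @ y), 1e-300):
        rss = 0.0
    sigma2 = rss / dof
    se = np.sqrt(max(sigma2 * XtX_inv[col, col], 0.0))
    if se > 0:
        t = beta[col] / se
    else:
        # exact fit: the coefficient is either genuinely nonzero
        # (infinitely significant) or numerically zero (no contribution)
        tol = 1e-8 * max(1.0, float(np.abs(beta).max()))
        t = np.inf * np.sign(beta[col]) if abs(beta[col]) > tol else 0.0
    return beta, float(t)


def stepwise_mrm(
    response: DistanceMatrix,
    candidates: PredictorSet,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> RegressionFit:
    """Forward stepwise regression on distance matrices.

    At each step every unselected candidate is tested by refitting the
    current model plus that candidate, with a two-sided permutation
    p-value for the candidate's coefficient obtained from ``n_perm``
    simultaneous row/column permutations of the response matrix.  The
    candidate with the smallest p enters if p < alpha (ties broken by
    larger |t|); otherwise selection stops.  Pairs with a missing value
    in the tested predictor are dropped for that candidate only.
    An empty selection is a legitimate outcome.
    """
    n = response.n
    if n < 4:
        raise ValueError("need at least 4 samples")
    labels = response.labels
    aligned = {name: dm.reorder(labels) for name, dm in candidates.items()}
    y_full = response.condensed()
    cond = {name: dm.condensed() for name, dm in aligned.items()}
    pos = _condensed_perm_indices(n)
    tril = np.tril_indices(n, k=-1)

    rng = np.random.default_rng(seed)
    # one shared pool of permutations per step keeps candidate p-values
    # comparable within the step
    selected: list[str] = []
    step_ps: list[float] = []
    remaining = list(candidates)

    while remaining:
        perms = [rng.permutation(n) for _ in range(n_perm)]
        best: tuple[float, float, str] | None = None  # (p, -|t|, name)
        for name in remaining:
            x_c = cond[name]
            ok = ~np.isnan(x_c)
            for s in selected:
                ok &= ~np.isnan(cond[s])
            m = int(ok.sum())
            k = len(selected) + 2
            if m < k + 1:
                continue
            X = np.column_stack(
                [np.ones(m)] + [cond[s][ok] for s in selected] + [x_c[ok]]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                warnings.warn(
                    f"candidate {name!r} is collinear with the selected set; skipped"
                )
                continue
            col = X.shape[1] - 1
            _, t_obs = _ols_t(X, y_full[ok], col)
            # inf is legitimate (noiseless exact fit); only NaN is unusable
            if np.isnan(t_obs):
                continue
            hits = 0
            for perm in perms:
                # permute response rows/columns simultaneously, re-unfold
                y_perm = y_full[pos[perm[tril[0]], perm[tril[1]]]]
                _, t_p = _ols_t(X, y_perm[ok], col)
                if not np.isnan(t_p) and abs(t_p) >= abs(t_obs):
                    hits += 1
            p = (1 + hits) / (1 + n_perm)
            key = (p, -abs(t_obs), name)
            if best is None or key < best:
                best = key
        if best is None or best[0] >= alpha:
            break
        p, _, name = best
        selected.append(name)
        step_ps.append(p)
        remaining.remove(name)

    # final fit on the selected set
    if selected:
        ok = np.ones(len(y_full), dtype=bool)
        for s in selected:
            ok &= ~np.isnan(cond[s])
        X = np.column_stack([np.ones(int(ok.sum()))] + [cond[s][ok] for s in selected])
        y = y_full[ok]
        beta, _ = _ols_t(X, y, 0)
        yhat = X @ beta
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        coefs = {"intercept": float(beta[0])}
        coefs.update({s: float(b) for s, b in zip(selected, beta[1:])})
    else:
        r2 = 0.0
        coefs = {"intercept": float(np.mean(y_full))}
    return RegressionFit(
        selected=selected,
        coefficients=coefs,
        r2=r2,
        r2_cv=None,
        step_p_values=step_ps,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        candidate_names=list(candidates),
    )


def loso_cv_r2(
    response: DistanceMatrix,
    fit: RegressionFit,
    candidates: PredictorSet,
) -> float:
    """Leave-one-sample-out cross-validated fraction of explained variance.

    For each sample s the model (intercept + the fit's selected
    predictors) is refit on all pairs not involving s and used to
    predict the pairs involving s; R2_cv = 1 - SS_pred / SS_tot pooled
    over all held-out pairs, with SS_tot taken about the grand mean of
    the response.  Can be negative when the model predicts worse than
    the mean.
    """
    if not fit.selected:
        raise ValueError("fit has no selected predictors")
    n = response.n
    if n < 4:
        raise ValueError("need at least 4 samples")
    labels = response.labels
    aligned = {s: candidates[s].reorder(labels) for s in fit.selected}
    y = response.values
    X_mats = {s: aligned[s].values for s in fit.selected}

    pairs = [(i, j) for i in range(n) for j in range(i)]
    y_cond = np.array([y[i, j] for i, j in pairs])
    grand_mean = y_cond.mean()
    ss_pred = 0.0
    ss_tot = 0.0
    for s_out in range(n):
        train = [k for k, (i, j) in enumerate(pairs) if i != s_out and j != s_out]
        test = [k for k, (i, j) in enumerate(pairs) if i == s_out or j == s_out]
        Xtr = np.column_stack(
            [np.ones(len(train))]
            + [np.array([X_mats[s][pairs[k][0], pairs[k][1]] for k in train])
               for s in fit.selected]
        )
        keep = ~np.isnan(Xtr).any(axis=1)
        Xtr = Xtr[keep]
        ytr = y_cond[train][keep]
        beta, *_ = np.linalg.lstsq(Xtr, ytr, rcond=None)
        Xte = np.column_stack(
            [np.ones(len(test))]
            + [np.array([X_mats[s][pairs[k][0], pairs[k][1]] for k in test])
               for s in fit.selected]
        )
        keep_te = ~np.isnan(Xte).any(axis=1)
        yte = y_cond[test][keep_te]
        pred = Xte[keep_te] @ beta
        ss_pred += float(((yte - pred) ** 2).sum())
        ss_tot += float(((yte - grand_mean) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance on held-out pairs")
    return 1.0 - ss_pred / ss_tot
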