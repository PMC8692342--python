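"""Reference local imputers: KNN, SKNN, IKNN, LLS and SLLS.

All five share the pairwise-complete rescaled distance of
:mod:`geximpute.graph` and return :class:`~geximpute.wknn.ImputationResult`
objects whose observed cells are untouched.

* knn   — per missing cell, inverse-distance-weighted mean over the k
          nearest genes that observe the sample.
* sknn  — genes imputed in ascending missing-rate order; previously
          imputed genes join the donor pool.
* iknn  — missing cells start at gene means, then full-matrix KNN
          re-imputation is iterated to a fixed point.
* lls   — the target gene is regressed on its k most similar complete
          genes over its observed samples; missing samples are predicted
          from the fit (ridge-regularized normal equations).
* slls  — lls in ascending missing-rate order with sequential donor reuse.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._exceptions import ParameterError, UnimputableAttributeError
from .graph import distances_to_row
from .io import (
    AvailabilityMask,
    ExpressionMatrix,
    availability_mask,
    split_complete_incomplete,
)
from .wknn import ImputationResult, impute_numeric, neighbor_weights

METHODS = ("knn", "sknn", "iknn", "lls", "slls")


def _knn_cell_value(
    m: ExpressionMatrix,
    donors_obs_u: np.ndarray,
    target: int,
    u: int,
    k: int,
    weighted: bool,
) -> float:
    """One KNN estimate for cell (target, u) from the given donor rows."""
    d = distances_to_row(m, target, donors_obs_u)
    defined = ~np.isnan(d)
    cand, dist = donors_obs_u[defined], d[defined]
    if cand.size == 0:
        raise UnimputableAttributeError(
            f"no overlapping donor observes sample {u} for gene {target}"
        )
    order = np.lexsort((cand, dist))[: min(k, cand.size)]
    cand, dist = cand[order], dist[order]
    vals = m.values[cand, u]
    if dist[0] == 0.0:
        return float(vals[0])
    if not weighted:
        return float(vals.mean())
    return impute_numeric(neighbor_weights(dist), vals)


def knn_impute(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    k: int = 15,
    weighted: bool = True,
) -> ImputationResult:
    """Plain KNN imputation over the whole gene set (no clustering)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    h = h or availability_mask(m)
    out = m.copy()
    all_idx = np.arange(m.n_genes)
    for i, u in zip(*np.nonzero(~h.h)):
        donors = all_idx[(all_idx != i) & h.h[:, u]]
        if donors.size == 0:
            raise UnimputableAttributeError(f"no gene observes sample {u}")
        out.values[i, u] = _knn_cell_value(m, donors, int(i), int(u), k, weighted)
    return ImputationResult(out, [], None)


def _missing_rate_order(h: AvailabilityMask) -> np.ndarray:
    """Incomplete-gene indices in ascending missing-rate order, ties by row."""
    miss = (~h.h).sum(axis=1)
    idx = np.flatnonzero(miss > 0)
    return idx[np.lexsort((idx, miss[idx]))]


def sknn_impute(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    k: int = 15,
    weighted: bool = True,
) -> ImputationResult:
    """Sequential KNN: least-missing genes first, imputed rows reused."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    h = h or availability_mask(m)
    complete, incomplete = split_complete_incomplete(m, h)
    if complete.size == 0 and incomplete.size > 0:
        raise ParameterError("sknn requires at least one complete gene")
    work = m.copy()
    donor_rows = complete.copy()
    for i in _missing_rate_order(h):
        for u in np.flatnonzero(~h.h[i]):
            # donor rows are fully observed at this point by construction
            work.values[i, u] = _knn_cell_value(
                work, donor_rows, int(i), int(u), k, weighted
            )
        donor_rows = np.append(donor_rows, i)
    return ImputationResult(work, [], None)


def iknn_impute(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    k: int = 15,
    max_iter: int = 20,
    tol: float = 1e-4,
    weighted: bool = True,
) -> ImputationResult:
    """Iterative KNN from a gene-mean start.

    Stops when the relative max-abs change of the imputed cells drops
    below ``tol`` or after ``max_iter`` sweeps.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    h = h or availability_mask(m)
    miss = ~h.h
    if not miss.any():
        return ImputationResult(m.copy(), [], None)
    work = m.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(work.values, axis=1)
    row_means = np.where(np.isnan(row_means), np.nanmean(work.values), row_means)
    ii, uu = np.nonzero(miss)
    work.values[ii, uu] = row_means[ii]
    scale = max(float(np.nanmax(np.abs(m.values))), 1e-12)
    all_idx = np.arange(m.n_genes)

    for _ in range(max_iter):
        prev = work.values[ii, uu].copy()
        new = work.copy()
        for i, u in zip(ii, uu):
            donors = all_idx[all_idx != i]
            new.values[i, u] = _knn_cell_value(work, donors, int(i), int(u), k, weighted)
        work = new
        change = np.max(np.abs(work.values[ii, uu] - prev)) / scale
        if change < tol:
            break
    else:
        warnings.warn("iknn did not converge within max_iter", stacklevel=2)
    return ImputationResult(work, [], None)


def _lls_gene(
    values: np.ndarray,
    donor_rows: np.ndarray,
    target: int,
    obs: np.ndarray,
    mis: np.ndarray,
    k: int,
    ridge: float,
    similarity: str,
) -> np.ndarray:
    """Predict the target gene's missing samples from its k most similar
    fully-observed donor rows via (ridge) least squares."""
    t_obs = values[target, obs]
    donors = values[donor_rows][:, obs]
    if similarity == "pearson":
        tc = t_obs - t_obs.mean()
        dc = donors - donors.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(dc, axis=1) * np.linalg.norm(tc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.abs(dc @ tc) / denom
        r[~np.isfinite(r)] = 0.0
        score = -r  # higher correlation = more similar
    else:
        score = np.sqrt(((donors - t_obs) ** 2).sum(axis=1))
    order = np.lexsort((donor_rows, score))[: min(k, donor_rows.size)]
    sel = donor_rows[order]
    A = values[sel][:, obs]  # k x m_obs
    b = t_obs
    if ridge > 0:
        gram = A @ A.T + ridge * np.eye(sel.size)
        w = np.linalg.solve(gram, A @ b)
    else:
        w, *_ = np.linalg.lstsq(A.T, b, rcond=None)  # minimum-norm
    return w @ values[sel][:, mis]


def lls_impute(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    k: int = 15,
    ridge: float = 1e-6,
    similarity: str = "l2",
) -> ImputationResult:
    """Local least squares: regress each incomplete gene on its k most
    similar complete genes."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    h = h or availability_mask(m)
    complete, incomplete = split_complete_incomplete(m, h)
    if incomplete.size == 0:
        return ImputationResult(m.copy(), [], None)
    if complete.size == 0:
        raise ParameterError("lls requires at least one complete gene")
    out = m.copy()
    for i in incomplete:
        obs = np.flatnonzero(h.h[i])
        mis = np.flatnonzero(~h.h[i])
        if obs.size == 0:
            raise UnimputableAttributeError(f"gene {i} observes no sample")
        out.values[i, mis] = _lls_gene(
            m.values, complete, int(i), obs, mis, k, ridge, similarity
        )
    return ImputationResult(out, [], None)


def slls_impute(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    k: int = 15,
    ridge: float = 1e-6,
    similarity: str = "l2",
) -> ImputationResult:
    """Sequential LLS: ascending missing-rate order, imputed genes join
    the regressor pool."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    h = h or availability_mask(m)
    complete, incomplete = split_complete_incomplete(m, h)
    if incomplete.size == 0:
        return ImputationResult(m.copy(), [], None)
    if complete.size == 0:
        raise ParameterError("slls requires at least one complete gene")
    work = m.copy()
    donor_rows = complete.copy()
    for i in _missing_rate_order(h):
        obs = np.flatnonzero(h.h[i])
        mis = np.flatnonzero(~h.h[i])
        if obs.size == 0:
            raise UnimputableAttributeError(f"gene {i} observes no sample")
        work.values[i, mis] = _lls_gene(
            work.values, donor_rows, int(i), obs, mis, k, ridge, similarity
        )
        donor_rows = np.append(donor_rows, i)
    return ImputationResult(work, [], None)
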