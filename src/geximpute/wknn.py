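"""Cluster-restricted weighted top-K' nearest-neighbour imputation.

For each missing cell the candidate donors are the genes sharing the
target's cluster that observe the missing sample; the closest K' of them
vote with inverse-distance weights.  Numeric cells take the weighted
mean; categorical cells take the category with the largest summed
weight.  A donor at distance exactly 0 short-circuits the weighting and
donates its value directly (the limit of the inverse-distance weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import (
    ContractError,
    ParameterError,
    UnimputableAttributeError,
)
from .graph import GraphConfig, distances_to_row
from .io import (
    CATEGORICAL,
    AvailabilityMask,
    ExpressionMatrix,
    availability_mask,
    split_complete_incomplete,
)
from .spectral import ClusterModel, spectral_cluster

WIDEN_TO_GLOBAL = "widen_to_global"
CLUSTER_CENTROID = "cluster_centroid"


@dataclass
class ImputerConfig:
    """Configuration of the proposed imputer."""

    k_prime: int = 15
    graph: GraphConfig = field(default_factory=GraphConfig)
    n_clusters: int | str = "auto"
    seed: int = 0
    fallback: str = WIDEN_TO_GLOBAL
    complete_only: bool = False
    k_max: int = 10

    def __post_init__(self) -> None:
        if self.k_prime < 1:
            raise ParameterError("k_prime must be >= 1")
        if self.fallback not in (WIDEN_TO_GLOBAL, CLUSTER_CENTROID):
            raise ParameterError(f"unknown fallback policy {self.fallback!r}")


@dataclass
class NeighborSet:
    """Donors selected for one missing cell."""

    target_gene: int
    attribute: int
    neighbor_indices: np.ndarray
    distances: np.ndarray  # ascending
    weights: np.ndarray  # sum to 1
    fallback_used: bool = False

    @property
    def k_prime(self) -> int:
        return len(self.neighbor_indices)


@dataclass
class CellProvenance:
    gene: int
    sample: int
    cluster: int
    k_used: int
    fallback: bool
    exact_match: bool


@dataclass
class ImputationResult:
    """A completed matrix plus per-cell provenance."""

    completed: ExpressionMatrix
    provenance: list = field(default_factory=list)
    model: ClusterModel | None = None


def neighbor_weights(distances: np.ndarray) -> np.ndarray:
    """Inverse-distance weights ``P_i = (1/d_i) / sum_j (1/d_j)``.

    All distances must be strictly positive; a zero distance must be
    handled by the caller's exact-match shortcut.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ContractError("empty distance list")
    if np.any(d <= 0):
        raise ContractError(
            "non-positive distance passed to neighbor_weights; apply the "
            "zero-distance shortcut upstream"
        )
    inv = 1.0 / d
    return inv / inv.sum()


def impute_numeric(weights: np.ndarray, neighbor_values: np.ndarray) -> float:
    """Weighted mean ``sum_i P_i * g_iu`` (a convex combination)."""
    w = np.asarray(weights, dtype=float)
    v = np.asarray(neighbor_values, dtype=float)
    if w.shape != v.shape:
        raise ContractError("weights and values must have equal length")
    return float(w @ v)


def impute_categorical(weights: np.ndarray, neighbor_categories) -> object:
    """Category with the largest total weight; ties break to the
    lexicographically smallest label."""
    w = np.asarray(weights, dtype=float)
    cats = list(neighbor_categories)
    if len(cats) == 0:
        raise ContractError("empty neighbor category list")
    if len(cats) != w.size:
        raise ContractError("weights and categories must have equal length")
    totals: dict = {}
    for wi, ci in zip(w, cats):
        totals[ci] = totals.get(ci, 0.0) + wi
    best = max(totals.items(), key=lambda kv: (kv[1], ))
    top = best[1]
    tied = sorted(c for c, t in totals.items() if t >= top - 1e-15)
    return tied[0]


def top_k_neighbors(
    m: ExpressionMatrix,
    h: AvailabilityMask,
    model: ClusterModel,
    target: int,
    u: int,
    k_prime: int,
    fallback: str = WIDEN_TO_GLOBAL,
    complete_only: bool = False,
) -> NeighborSet:
    """Rank the target's same-cluster genes that observe sample ``u`` and
    keep the closest ``k_prime``.

    With zero in-cluster candidates the fallback policy applies:
    ``widen_to_global`` ranks over all genes observing ``u``;
    ``cluster_centroid`` is resolved by the caller (this function then
    returns an empty set flagged as fallback).
    """
    if h.h[target, u]:
        raise ContractError(f"cell ({target}, {u}) is not missing")
    label = model.assignments[target]
    members = model.members(label)
    cand = members[(members != target) & h.h[members, u]]
    used_fallback = False
    if cand.size == 0:
        used_fallback = True
        if fallback == WIDEN_TO_GLOBAL:
            all_idx = np.arange(m.n_genes)
            cand = all_idx[(all_idx != target) & h.h[:, u]]
            if cand.size == 0:
                raise UnimputableAttributeError(
                    f"no gene observes sample {u}; attribute is unimputable"
                )
        else:
            return NeighborSet(
                target, u, np.empty(0, dtype=int), np.empty(0), np.empty(0), True
            )
    d = distances_to_row(m, target, cand)
    defined = ~np.isnan(d)
    cand, d = cand[defined], d[defined]
    if cand.size == 0:
        if fallback == WIDEN_TO_GLOBAL and not used_fallback:
            # in-cluster candidates had no overlap; widen
            ns = top_k_neighbors(
                m, h, _global_model(m), target, u, k_prime,
                fallback=fallback, complete_only=complete_only,
            )
            ns.fallback_used = True
            return ns
        raise UnimputableAttributeError(
            f"no overlapping donor observes sample {u} for gene {target}"
        )
    if complete_only:
        complete, _ = split_complete_incomplete(m, h)
        keep = np.isin(cand, complete)
        if keep.any():
            cand, d = cand[keep], d[keep]
    order = np.lexsort((cand, d))  # distance, then row index
    order = order[: min(k_prime, order.size)]
    cand, d = cand[order], d[order]
    if d[0] == 0.0:
        weights = np.zeros(d.size)
        weights[0] = 1.0
    else:
        weights = neighbor_weights(d)
    return NeighborSet(target, u, cand, d, weights, used_fallback)


def _global_model(m: ExpressionMatrix) -> ClusterModel:
    """Degenerate one-cluster model covering every gene."""
    n = m.n_genes
    return ClusterModel(
        K=1,
        eigenvalues=np.zeros(1),
        embedding=np.ones((n, 1)),
        assignments=np.zeros(n, dtype=int),
    )


def _impute_cell(
    m: ExpressionMatrix,
    h: AvailabilityMask,
    model: ClusterModel,
    i: int,
    u: int,
    cfg: ImputerConfig,
) -> tuple[float, CellProvenance]:
    ns = top_k_neighbors(
        m, h, model, i, u, cfg.k_prime,
        fallback=cfg.fallback, complete_only=cfg.complete_only,
    )
    label = int(model.assignments[i])
    if ns.k_prime == 0:  # cluster_centroid fallback
        members = model.members(label)
        obs = members[h.h[members, u]]
        if obs.size == 0:
            all_idx = np.arange(m.n_genes)
            obs = all_idx[h.h[:, u]]
        if obs.size == 0:
            raise UnimputableAttributeError(
                f"no gene observes sample {u}; attribute is unimputable"
            )
        value = float(np.mean(m.values[obs, u]))
        return value, CellProvenance(i, u, label, 0, True, False)
    exact = bool(ns.distances[0] == 0.0)
    vals = m.values[ns.neighbor_indices, u]
    if m.attr_kinds[u] == CATEGORICAL:
        if exact:
            value = float(vals[0])
        else:
            labels = m.categories.get(u)
            if labels:
                cats = [labels[int(v)] for v in vals]
                value = float(labels.index(impute_categorical(ns.weights, cats)))
            else:
                value = float(impute_categorical(ns.weights, vals))
    else:
        value = vals[0] if exact else impute_numeric(ns.weights, vals)
    return float(value), CellProvenance(i, u, label, ns.k_prime, ns.fallback_used, exact)


def impute_dataset(m: ExpressionMatrix, cfg: ImputerConfig | None = None) -> ImputationResult:
    """Impute every missing cell of ``m`` with the cluster-restricted
    weighted nearest-neighbour method.

    Phases: split complete/incomplete genes, spectral-cluster all genes
    jointly (pairwise-complete distances), then impute each missing cell
    independently from the original observed data.  Deterministic given
    ``cfg.seed``.
    """
    cfg = cfg or ImputerConfig()
    h = availability_mask(m)
    out = m.copy()
    if not np.isnan(m.values).any():
        return ImputationResult(out, [], None)
    if m.n_genes < 3 or (isinstance(cfg.n_clusters, int) and cfg.n_clusters < 2):
        model = _global_model(m)
    else:
        model = spectral_cluster(
            m, h, cfg.graph, K=cfg.n_clusters, seed=cfg.seed, k_max=cfg.k_max
        )
    provenance: list[CellProvenance] = []
    miss_i, miss_u = np.nonzero(~h.h)
    for i, u in zip(miss_i, miss_u):
        value, prov = _impute_cell(m, h, model, int(i), int(u), cfg)
        out.values[i, u] = value
        provenance.append(prov)
    return ImputationResult(out, provenance, model)
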