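"""Graph Laplacians, spectral embedding and K-means clustering.

The embedding uses the bottom-K eigenvectors of the random-walk
normalized Laplacian ``L_rw = D^-1 (D - W)``, computed via the symmetric
generalized problem ``L e = lambda D e`` so ``D^-1`` is never formed.
Rows of the embedding are not renormalized (random-walk formulation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._exceptions import ParameterError, SingularDegreeError
from .graph import GraphConfig, SimilarityGraph, build_graph
from .io import AvailabilityMask, ExpressionMatrix

#: above this vertex count the sparse eigensolver takes over from dense
_DENSE_LIMIT = 1500

DEFAULT_DEGREE_FLOOR = 1e-10


@dataclass
class ClusterModel:
    """Result of spectral clustering: embedding, eigenvalues and labels."""

    K: int
    eigenvalues: np.ndarray
    embedding: np.ndarray
    assignments: np.ndarray  # 0-based cluster label per gene
    seed: int | None = None
    clusters: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if not self.clusters:
            self.clusters = {
                int(c): np.flatnonzero(self.assignments == c)
                for c in np.unique(self.assignments)
            }

    @property
    def n_genes(self) -> int:
        return self.assignments.size

    def members(self, label: int) -> np.ndarray:
        return self.clusters.get(int(label), np.empty(0, dtype=int))


def degree_matrix(g: SimilarityGraph) -> sp.dia_matrix:
    """Diagonal matrix of vertex degrees (row sums of the adjacency)."""
    return sp.diags(g.degrees())


def laplacian(
    g: SimilarityGraph,
    normalized: bool = False,
    degree_floor: float | None = None,
) -> sp.csr_matrix:
    """Graph Laplacian ``L = D - W``; with ``normalized`` the random-walk
    form ``D^-1 L``.

    Raises
    ------
    SingularDegreeError
        Normalized form requested with a zero-degree vertex and no
        ``degree_floor``.
    """
    deg = g.degrees()
    lap = sp.diags(deg) - g.adjacency
    if not normalized:
        return lap.tocsr()
    if degree_floor is not None:
        deg = np.maximum(deg, degree_floor)
    elif np.any(deg == 0):
        raise SingularDegreeError(
            "graph has isolated vertices; drop them or pass degree_floor"
        )
    return (sp.diags(1.0 / deg) @ lap).tocsr()


def spectral_embed(
    g: SimilarityGraph,
    K: int,
    degree_floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bottom-K generalized eigenpairs of ``(L, D)``.

    Returns ``(embedding, eigenvalues)`` with eigenvalues ascending; the
    embedding columns are the corresponding eigenvectors of ``L_rw``.
    """
    n = g.n
    if not 1 <= K <= n:
        raise ParameterError(f"K must be in [1, {n}], got {K}")
    deg = g.degrees()
    if np.any(deg == 0):
        if degree_floor is None:
            raise SingularDegreeError(
                "graph has isolated vertices; drop them or pass degree_floor"
            )
        deg = np.maximum(deg, degree_floor)
    lap = sp.diags(g.degrees()) - g.adjacency

    if n <= _DENSE_LIMIT or K >= n - 1:
        lam, vec = scipy.linalg.eigh(
            lap.toarray(), np.diag(deg), subset_by_index=[0, K - 1]
        )
    else:
        try:
            lam, vec = spla.eigsh(
                lap.tocsc(), k=K, M=sp.diags(deg).tocsc(), sigma=-1e-5, which="LM"
            )
        except Exception as exc:  # pragma: no cover - solver-dependent
            raise ArithmeticError(
                "sparse eigensolver failed to converge; consider raising "
                "sigma or k_graph so the graph is better connected"
            ) from exc
    order = np.argsort(lam)
    return vec[:, order], lam[order]


def kmeans(
    points: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Lloyd's algorithm with greedy farthest-point seeding.

    Best of ``n_restarts`` by within-cluster sum of squares; deterministic
    given ``seed``.  An emptied cluster is reseeded at the point farthest
    from its assigned centroid.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= K <= n:
        raise ParameterError(f"K must be in [1, {n}], got {K}")
    rng = np.random.default_rng(seed)
    best_labels = None
    best_wcss = np.inf

    for _ in range(n_restarts):
        centroids = _farthest_point_init(points, K, rng)
        labels = None
        for _ in range(max_iter):
            d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            labels = d2.argmin(axis=1)
            new_centroids = centroids.copy()
            for c in range(K):
                members = points[labels == c]
                if members.size:
                    new_centroids[c] = members.mean(axis=0)
                else:
                    far = d2[np.arange(n), labels].argmax()
                    new_centroids[c] = points[far]
            shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
            centroids = new_centroids
            if shift < tol:
                break
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wcss = d2[np.arange(n), labels].sum()
        if wcss < best_wcss - 1e-15:
            best_wcss = wcss
            best_labels = labels
    return best_labels


def _farthest_point_init(points: np.ndarray, K: int, rng) -> np.ndarray:
    """One random seed point, then greedily the farthest from the chosen set."""
    n = points.shape[0]
    chosen = [int(rng.integers(n))]
    min_d2 = ((points - points[chosen[0]]) ** 2).sum(axis=1)
    while len(chosen) < K:
        nxt = int(min_d2.argmax())
        if min_d2[nxt] == 0.0:
            # all remaining points coincide with chosen ones; pick randomly
            nxt = int(rng.integers(n))
        chosen.append(nxt)
        min_d2 = np.minimum(min_d2, ((points - points[nxt]) ** 2).sum(axis=1))
    return points[np.array(chosen)].copy()


def choose_k(eigenvalues: np.ndarray, k_max: int | None = None) -> int:
    """Eigengap heuristic: the K maximizing ``lambda_{K+1} - lambda_K``.

    Searched over K in [2, k_max]; ties resolve to the smallest K.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ParameterError("need at least 3 eigenvalues for the eigengap")
    if k_max is None:
        k_max = lam.size - 1
    k_max = min(k_max, lam.size - 1)
    gaps = np.diff(lam)  # gaps[i] = lam[i+1] - lam[i], i 0-based
    candidates = np.arange(2, k_max + 1)  # K = number of small eigenvalues
    best = candidates[np.argmax(gaps[candidates - 1])]
    return int(best)


def spectral_cluster(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    gcfg: GraphConfig | None = None,
    K: int | str = "auto",
    seed: int = 0,
    k_max: int = 10,
    degree_floor: float | None = DEFAULT_DEGREE_FLOOR,
    n_restarts: int = 10,
) -> ClusterModel:
    """Full pipeline: similarity graph -> Laplacian embedding -> K-means.

    Incomplete genes participate through pairwise-complete distances, so
    every gene receives a cluster label.  ``K="auto"`` applies the
    eigengap heuristic over the first ``k_max + 1`` eigenvalues.
    """
    g = build_graph(m, h, gcfg)
    if K == "auto":
        n_eigs = min(k_max + 1, g.n)
        emb, lam = spectral_embed(g, n_eigs, degree_floor=degree_floor)
        K_eff = choose_k(lam, k_max=k_max)
        emb = emb[:, :K_eff]
        lam = lam[:K_eff]
    else:
        K_eff = int(K)
        if not 2 <= K_eff <= g.n:
            raise ParameterError(f"K must be in [2, {g.n}], got {K_eff}")
        emb, lam = spectral_embed(g, K_eff, degree_floor=degree_floor)
    if lam[0] > 1e-6:
        warnings.warn(
            f"smallest eigenvalue {lam[0]:.2e} is far from 0; the graph "
            "may be poorly conditioned",
            stacklevel=2,
        )
    labels = kmeans(emb, K_eff, seed=seed, n_restarts=n_restarts)
    return ClusterModel(
        K=K_eff, eigenvalues=lam, embedding=emb, assignments=labels, seed=seed
    )
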