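"""Pairwise gene distances and similarity-graph construction.

Distances are pairwise-complete Euclidean rescaled by ``sqrt(M / m_obs)``
where ``m_obs`` counts co-observed samples, so rows with different amounts
of missingness remain comparable.  Categorical samples contribute a 0/1
mismatch term.  Edge weights come from the Gaussian kernel
``exp(-d^2 / (2 sigma^2))``; graphs are stored sparsely and symmetrized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._exceptions import NoOverlapError, ParameterError
from .io import CATEGORICAL, AvailabilityMask, ExpressionMatrix

SIGMA_FLOOR = 1e-8
FULL_GRAPH_SIM_FLOOR = 1e-12
GRAPH_MODES = ("full", "knn_normal", "knn_mutual", "epsilon")

#: row-block size for chunked distance computation (keeps kNN / epsilon
#: construction from materializing the full N x N distance matrix)
_CHUNK = 256


@dataclass
class GraphConfig:
    """Similarity-graph construction parameters.

    ``mode`` selects the graph family; only the parameters relevant to the
    chosen mode are consulted.  ``sigma="auto"`` uses the median heuristic.
    """

    mode: str = "knn_normal"
    sigma: float | str = "auto"
    k_graph: int = 20
    epsilon: float | None = None
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.mode not in GRAPH_MODES:
            raise ParameterError(
                f"unknown graph mode {self.mode!r}; expected one of {GRAPH_MODES}"
            )
        if isinstance(self.sigma, str):
            if self.sigma != "auto":
                raise ParameterError("sigma must be a positive number or 'auto'")
        elif self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.mode in ("knn_normal", "knn_mutual") and self.k_graph < 1:
            raise ParameterError("k_graph must be a positive integer")
        if self.mode == "epsilon" and (self.epsilon is None or self.epsilon <= 0):
            raise ParameterError("epsilon mode requires epsilon > 0")


@dataclass
class SimilarityGraph:
    """Sparse, symmetric, loop-free weighted adjacency over ``n`` genes."""

    n: int
    adjacency: sp.csr_matrix
    sigma: float
    mode: str
    symmetric: bool = True

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        a.setdiag(0.0)
        a.eliminate_zeros()
        self.adjacency = a

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def edges(self) -> list[tuple[int, int, float]]:
        """Undirected edge list with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def gaussian_similarity(d, sigma: float):
    """Gaussian kernel ``exp(-d^2 / (2 sigma^2))``; ``d`` may be an array."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    d = np.asarray(d, dtype=float)
    out = np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def pairwise_distance(
    a: np.ndarray,
    b: np.ndarray,
    attr_kinds: list[str] | None = None,
) -> float:
    """Distance between two gene rows with missing entries.

    Euclidean over co-observed samples, rescaled by ``sqrt(M / m_obs)``;
    categorical samples contribute 0 (equal) or 1 (different).

    Raises
    ------
    NoOverlapError
        If no sample is observed in both rows.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = a.size
    both = ~np.isnan(a) & ~np.isnan(b)
    m_obs = int(both.sum())
    if m_obs == 0:
        raise NoOverlapError("gene rows share no co-observed sample")
    diff = a[both] - b[both]
    if attr_kinds is not None:
        kinds = np.asarray([k == CATEGORICAL for k in attr_kinds])[both]
        diff = np.where(kinds, (diff != 0).astype(float), diff)
    return float(np.sqrt(np.sum(diff**2) * (m / m_obs)))


def _prepare(values: np.ndarray, attr_kinds: list[str] | None):
    """Split into numeric part (NaN->0 with weights) and categorical codes."""
    obs = ~np.isnan(values)
    if attr_kinds is None:
        cat = np.zeros(values.shape[1], dtype=bool)
    else:
        cat = np.asarray([k == CATEGORICAL for k in attr_kinds])
    num = values[:, ~cat]
    num_obs = obs[:, ~cat]
    x = np.where(num_obs, num, 0.0)
    return x, num_obs.astype(float), values[:, cat], obs[:, cat]


def _block_sq_dist(
    xa, wa, ca, coa, xb, wb, cb, cob, m_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """Rescaled squared distances and overlap counts between row blocks."""
    x2a = xa**2
    x2b = xb**2
    pos = (x2a * wa) @ wb.T + wa @ (x2b * wb).T
    sq = pos - 2.0 * (xa * wa) @ (xb * wb).T
    n_obs = wa @ wb.T
    if ca.shape[1]:
        for j in range(ca.shape[1]):
            both = np.outer(coa[:, j], cob[:, j])
            mism = ca[:, j][:, None] != cb[:, j][None, :]
            sq += both * mism
            n_obs += both
    # the x^2-expansion cancels catastrophically for (near-)identical rows;
    # clamp anything within round-off of zero so duplicates measure exactly 0
    sq[sq <= 1e-12 * pos] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = sq * (m_total / n_obs)
    return scaled, n_obs


def pairwise_distance_matrix(
    m: ExpressionMatrix, h: AvailabilityMask | None = None
) -> np.ndarray:
    """Dense N x N matrix of pairwise-complete rescaled distances.

    Pairs with no co-observed sample get ``NaN``.  Intended for modest N
    (oracles, sigma selection, tests); graph construction chunks instead.
    """
    x, w, c, co = _prepare(m.values, m.attr_kinds)
    sq, n_obs = _block_sq_dist(x, w, c, co, x, w, c, co, m.n_samples)
    d = np.sqrt(sq)
    d[n_obs == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def distances_to_row(
    m: ExpressionMatrix, target: int, candidates: np.ndarray
) -> np.ndarray:
    """Distances from one gene row to each candidate row (NaN if no overlap)."""
    x, w, c, co = _prepare(m.values, m.attr_kinds)
    sq, n_obs = _block_sq_dist(
        x[[target]],
        w[[target]],
        c[[target]],
        co[[target]],
        x[candidates],
        w[candidates],
        c[candidates],
        co[candidates],
        m.n_samples,
    )
    d = np.sqrt(sq[0])
    d[n_obs[0] == 0] = np.nan
    return d


def auto_sigma(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    max_genes: int = 2000,
    seed: int = 0,
) -> float:
    """Median heuristic for the kernel bandwidth.

    Median of all defined pairwise distances; for N > ``max_genes`` a
    deterministic subsample of rows is used.  Degenerate all-zero
    distances return the floor 1e-8.
    """
    n = m.n_genes
    if n < 2:
        raise ParameterError("need at least two genes to select sigma")
    work = m
    if n > max_genes:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(n, size=max_genes, replace=False))
        work = ExpressionMatrix(
            m.values[keep],
            [m.gene_ids[i] for i in keep],
            list(m.sample_ids),
            list(m.attr_kinds),
            dict(m.categories),
        )
    d = pairwise_distance_matrix(work)
    iu = np.triu_indices(work.n_genes, k=1)
    vals = d[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise NoOverlapError("no gene pair shares a co-observed sample")
    med = float(np.median(vals))
    return max(med, SIGMA_FLOOR)


def resolve_sigma(m: ExpressionMatrix, cfg: GraphConfig) -> float:
    if cfg.sigma == "auto":
        return auto_sigma(m)
    return float(cfg.sigma)


def build_graph(
    m: ExpressionMatrix,
    h: AvailabilityMask | None = None,
    cfg: GraphConfig | None = None,
) -> SimilarityGraph:
    """Construct the similarity graph requested by ``cfg``.

    full
        every pair with kernel similarity above 1e-12 is an edge.
    knn_normal / knn_mutual
        edge kept if i is among the k nearest of j OR/AND vice versa;
        ties at the k-th distance keep all tied neighbours.
    epsilon
        edge kept iff the distance is strictly below ``epsilon``.

    Pairs with no co-observed sample are treated as similarity 0.  The
    result is stored sparsely; kNN/epsilon modes never materialize N^2.
    """
    cfg = cfg or GraphConfig()
    n = m.n_genes
    if n < 2:
        raise ParameterError("graph construction needs at least 2 genes")
    sigma = resolve_sigma(m, cfg)

    x, w, c, co = _prepare(m.values, m.attr_kinds)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []

    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        blk = slice(start, stop)
        sq, n_obs = _block_sq_dist(
            x[blk], w[blk], c[blk], co[blk], x, w, c, co, m.n_samples
        )
        d = np.sqrt(sq)
        d[n_obs == 0] = np.nan
        for r in range(stop - start):
            i = start + r
            di = d[r].copy()
            di[i] = np.nan  # no self-loop
            defined = ~np.isnan(di)
            if cfg.mode == "full":
                s = gaussian_similarity(di[defined], sigma)
                keep = s > FULL_GRAPH_SIM_FLOOR
                js = np.flatnonzero(defined)[keep]
                ss = s[keep]
            elif cfg.mode == "epsilon":
                sel = defined & (di < cfg.epsilon)
                js = np.flatnonzero(sel)
                ss = gaussian_similarity(di[sel], sigma)
            else:  # knn (directed for now; symmetrized below)
                js_def = np.flatnonzero(defined)
                if js_def.size == 0:
                    js = js_def
                    ss = np.empty(0)
                else:
                    dd = di[js_def]
                    k = min(cfg.k_graph, js_def.size)
                    kth = np.partition(dd, k - 1)[k - 1]
                    sel = dd <= kth  # keeps distance ties at rank k
                    js = js_def[sel]
                    ss = gaussian_similarity(dd[sel], sigma)
            if js.size:
                rows.append(np.full(js.size, i))
                cols.append(js)
                data.append(np.atleast_1d(ss))

    if rows:
        a = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        a = sp.csr_matrix((n, n))

    if cfg.mode == "knn_normal":
        a = a.maximum(a.T)  # i in kNN(j) OR j in kNN(i)
    elif cfg.mode == "knn_mutual":
        a = a.minimum(a.T)  # both directions required
    else:
        a = a.maximum(a.T)  # full/epsilon are symmetric already; harmless

    g = SimilarityGraph(n=n, adjacency=a, sigma=sigma, mode=cfg.mode)
    iso = int((g.degrees() == 0).sum())
    if iso:
        warnings.warn(
            f"similarity graph has {iso} isolated vertex(es); spectral "
            "steps will need a degree floor",
            stacklevel=2,
        )
    return g


def write_edge_list(g: SimilarityGraph, path) -> None:
    """Dump edges as a 3-column TSV (i, j, similarity), i < j."""
    with open(path, "w") as fh:
        fh.write("i\tj\tsimilarity\n")
        for i, j, s in g.edges():
            fh.write(f"{i}\t{j}\t{s!r}\n")
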