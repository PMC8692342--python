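"""Replicate RMSE evaluation under injected missingness.

The protocol: starting from a complete matrix, mask an exact fraction of
cells (MCAR, or MAR driven by an anchor sample), run each imputer on the
same masked matrix (paired design), score RMSE over the masked cells
only, and average over replicate masks.  A neighbour-count sweep repeats
the protocol across k values at a fixed rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import MaskingError, ParameterError
from .baselines import (
    iknn_impute,
    knn_impute,
    lls_impute,
    sknn_impute,
    slls_impute,
)
from .io import ExpressionMatrix
from .wknn import ImputerConfig, impute_dataset

MECHANISMS = ("mcar", "mar")
ALL_METHODS = ("proposed", "knn", "sknn", "iknn", "lls", "slls")


@dataclass
class MaskingSpec:
    """How to inject artificial missingness."""

    rate: float = 0.05
    mechanism: str = "mcar"
    mar_anchor: int = 0
    seed: int = 0
    n_replicates: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.rate < 1.0:
            raise ParameterError("rate must be in (0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ParameterError(f"mechanism must be one of {MECHANISMS}")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass
class MaskRecord:
    """Ground truth for one injected mask."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.rows.size


@dataclass
class EvalReport:
    """Tidy per-replicate RMSE records plus configuration echo."""

    records: pd.DataFrame  # columns: method, rate, replicate, rmse
    spec: MaskingSpec
    methods: list[str] = field(default_factory=list)

    def aggregates(self) -> pd.DataFrame:
        """Mean and sd of RMSE over replicates per (method, rate)."""
        return (
            self.records.groupby(["method", "rate"], as_index=False)["rmse"]
            .agg(mean_rmse="mean", sd_rmse="std", n="count")
        )

    def mean_rmse(self, method: str, rate: float) -> float:
        sel = self.records[
            (self.records["method"] == method) & (self.records["rate"] == rate)
        ]["rmse"]
        return float(sel.mean())


def inject_missing(
    m: ExpressionMatrix, spec: MaskingSpec, replicate: int = 0
) -> tuple[ExpressionMatrix, MaskRecord]:
    """Mask exactly ``round(rate * N * M)`` cells of a complete matrix.

    MCAR draws cells uniformly without replacement; MAR draws with
    probability proportional to a logistic transform of the anchor
    column (the anchor column itself is never masked).  No gene loses
    all of its cells; masks are deterministic in ``(spec.seed, replicate)``.
    """
    if np.isnan(m.values).any():
        raise MaskingError("inject_missing requires a complete matrix")
    n, M = m.shape
    count = int(round(spec.rate * n * M))
    if count == 0:
        return m.copy(), MaskRecord(
            np.empty(0, int), np.empty(0, int), np.empty(0)
        )
    max_maskable = n * (M - 1)
    if spec.mechanism == "mar":
        max_maskable = min(max_maskable, n * (M - 1))
    if count > max_maskable:
        raise MaskingError(
            f"cannot mask {count} cells while keeping >=1 observed value "
            f"per gene (max {max_maskable})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, replicate]))

    if spec.mechanism == "mcar":
        cand = np.arange(n * M)
        probs = None
    else:
        anchor = spec.mar_anchor
        x = m.values[:, anchor]
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        scale = iqr if iqr > 0 else max(np.std(x), 1e-12)
        z = (x - np.median(x)) / scale
        row_p = 1.0 / (1.0 + np.exp(-z))
        cell_p = np.repeat(row_p, M).astype(float)
        cols = np.tile(np.arange(M), n)
        keep = cols != anchor
        cand = np.arange(n * M)[keep]
        probs = cell_p[keep]
        probs = probs / probs.sum()

    chosen = rng.choice(cand, size=count, replace=False, p=probs)
    mask = np.zeros(n * M, dtype=bool)
    mask[chosen] = True

    # repair: no gene may lose every cell; swap offending cells elsewhere
    for _ in range(100):
        grid = mask.reshape(n, M)
        empty_rows = np.flatnonzero(grid.all(axis=1))
        if empty_rows.size == 0:
            break
        for i in empty_rows:
            unmask = rng.integers(M)
            mask[i * M + unmask] = False
            pool = cand[~mask[cand]]
            pool_rows = pool // M
            row_masked = mask.reshape(n, M).sum(axis=1)
            ok = row_masked[pool_rows] < M - 1
            pool = pool[ok]
            if pool.size == 0:
                raise MaskingError("mask repair failed; rate too high")
            if probs is not None:
                w = probs[np.searchsorted(cand, pool)]
                w = w / w.sum()
            else:
                w = None
            mask[rng.choice(pool, p=w)] = True
    grid = mask.reshape(n, M)
    rows, cols = np.nonzero(grid)
    record = MaskRecord(rows, cols, m.values[rows, cols].copy())
    masked = m.copy()
    masked.values[rows, cols] = np.nan
    return masked, record


def rmse(truth: MaskRecord, imputed: ExpressionMatrix) -> float:
    """Root mean squared error over the masked cells only."""
    if truth.n_cells == 0:
        raise ParameterError("RMSE undefined with zero masked cells")
    pred = imputed.values[truth.rows, truth.cols]
    if np.isnan(pred).any():
        raise ParameterError("imputed matrix still has missing masked cells")
    return float(np.sqrt(np.mean((truth.values - pred) ** 2)))


def get_method(name: str, k: int = 15, seed: int = 0, **kwargs):
    """Return ``masked_matrix -> ImputationResult`` for a method name."""
    if name == "proposed":
        cfg = ImputerConfig(k_prime=k, seed=seed, **kwargs)
        return lambda mm: impute_dataset(mm, replace(cfg, seed=cfg.seed))
    if name == "knn":
        return lambda mm: knn_impute(mm, k=k, **kwargs)
    if name == "sknn":
        return lambda mm: sknn_impute(mm, k=k, **kwargs)
    if name == "iknn":
        return lambda mm: iknn_impute(mm, k=k, **kwargs)
    if name == "lls":
        return lambda mm: lls_impute(mm, k=k, **kwargs)
    if name == "slls":
        return lambda mm: slls_impute(mm, k=k, **kwargs)
    raise ParameterError(f"unknown method {name!r}; expected one of {ALL_METHODS}")


def replicate_benchmark(
    m: ExpressionMatrix,
    methods: dict[str, object],
    rates: list[float],
    spec: MaskingSpec,
) -> EvalReport:
    """Run every method on the same replicate masks and collect RMSEs.

    ``methods`` maps a display name to a ``masked_matrix -> result``
    callable (see :func:`get_method`).  A method failure on a replicate
    is recorded as NaN and the run continues.
    """
    if np.isnan(m.values).any():
        raise MaskingError("benchmark requires a complete input matrix")
    rows = []
    for rate in rates:
        rspec = replace(spec, rate=rate)
        for rep in range(spec.n_replicates):
            masked, record = inject_missing(m, rspec, replicate=rep)
            for name, fn in methods.items():
                try:
                    result = fn(masked)
                    score = rmse(record, result.completed)
                except Exception as exc:  # noqa: BLE001 - keep the run going
                    warnings.warn(
                        f"{name} failed on rate={rate} replicate={rep}: {exc}",
                        stacklevel=2,
                    )
                    score = np.nan
                rows.append(
                    {"method": name, "rate": rate, "replicate": rep, "rmse": score}
                )
    return EvalReport(pd.DataFrame(rows), spec, list(methods))


def neighbor_sweep(
    m: ExpressionMatrix,
    method: str,
    k_values: list[int],
    spec: MaskingSpec,
    seed: int = 0,
    **method_kwargs,
) -> pd.DataFrame:
    """Mean RMSE as a function of neighbour count at a fixed rate.

    Masks are shared across k values (paired design), so the curve shape
    reflects k alone.
    """
    rows = []
    masks = [
        inject_missing(m, spec, replicate=rep) for rep in range(spec.n_replicates)
    ]
    for k in k_values:
        fn = get_method(method, k=k, seed=seed, **method_kwargs)
        scores = []
        for masked, record in masks:
            result = fn(masked)
            scores.append(rmse(record, result.completed))
        rows.append(
            {"method": method, "k": k, "mean_rmse": float(np.mean(scores))}
        )
    return pd.DataFrame(rows)
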