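"""Synthetic gene-expression matrices with planted cluster structure.

Each block has a prototype profile; gene rows are the prototype plus
i.i.d. noise.  Prototype scale is chosen so that the expected
between-block row distance is ``separation`` times the expected
within-block distance, making planted-partition recovery experiments
directly parameterizable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CATEGORICAL, NUMERIC, ExpressionMatrix


@dataclass
class SyntheticSpec:
    n_genes: int = 60
    n_samples: int = 15
    n_blocks: int = 3
    block_sizes: list[int] | None = None
    separation: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0
    heavy_tail: bool = False  # t(3) noise instead of Gaussian

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            base = self.n_genes // self.n_blocks
            sizes = [base] * self.n_blocks
            for i in range(self.n_genes - base * self.n_blocks):
                sizes[i] += 1
            self.block_sizes = sizes
        if sum(self.block_sizes) != self.n_genes:
            raise ValueError("block_sizes must sum to n_genes")
        if len(self.block_sizes) != self.n_blocks:
            raise ValueError("block_sizes length must equal n_blocks")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be >= 0")


def _prototype_scale(separation: float, noise_sd: float) -> float:
    """Prototype sd s with E between-dist ~= separation * E within-dist.

    E||rows in same block||^2 = 2 M sd^2; across blocks 2 M (s^2 + sd^2);
    solving gives s = sd * sqrt(sep^2 - 1).  With zero noise the scale is
    arbitrary, so s = separation.
    """
    if noise_sd == 0:
        return max(separation, 1.0)
    return noise_sd * float(np.sqrt(max(separation**2 - 1.0, 0.0)))


def generate_clustered_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Return a complete matrix and its planted 0-based block labels."""
    rng = np.random.default_rng(spec.seed)
    s = _prototype_scale(spec.separation, spec.noise_sd)
    prototypes = rng.normal(0.0, s, size=(spec.n_blocks, spec.n_samples))
    labels = np.repeat(np.arange(spec.n_blocks), spec.block_sizes)
    if spec.heavy_tail:
        noise = rng.standard_t(3, size=(spec.n_genes, spec.n_samples))
        noise *= spec.noise_sd / np.sqrt(3.0)  # t(3) variance is 3
    else:
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
    values = prototypes[labels] + noise
    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j + 1}" for j in range(spec.n_samples)]
    return ExpressionMatrix(values, gene_ids, sample_ids), labels


def generate_mixed_types(
    spec: SyntheticSpec,
    n_categorical: int = 0,
    n_levels: int = 3,
    category_noise: float = 0.0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Clustered matrix whose last ``n_categorical`` columns carry
    block-dependent category labels (per-block majority level).

    ``category_noise`` is the probability a cell deviates from its
    block's level to a uniformly random one.
    """
    if n_categorical > spec.n_samples:
        raise ValueError("n_categorical cannot exceed n_samples")
    m, labels = generate_clustered_expression(spec)
    if n_categorical == 0:
        return m, labels
    rng = np.random.default_rng(spec.seed + 1)
    level_names = [f"L{v}" for v in range(n_levels)]
    cat_cols = list(range(spec.n_samples - n_categorical, spec.n_samples))
    for j in cat_cols:
        codes = labels % n_levels
        if category_noise > 0:
            flip = rng.random(spec.n_genes) < category_noise
            codes = np.where(
                flip, rng.integers(0, n_levels, size=spec.n_genes), codes
            )
        m.values[:, j] = codes.astype(float)
        m.attr_kinds[j] = CATEGORICAL
        m.categories[j] = list(level_names)
    return m, labels
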