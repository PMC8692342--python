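import numpy as np
import pytest

from geximpute import ExpressionMatrix, SyntheticSpec, generate_clustered_expression


@pytest.fixture
def tiny_matrix():
    """2x3 matrix with one missing cell at (0, 2)."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0, np.nan], [4.0, 5.0, 6.0]]),
        ["g1", "g2"],
        ["s1", "s2", "s3"],
    )


@pytest.fixture
def complete_matrix():
    return ExpressionMatrix(
        np.arange(12, dtype=float).reshape(4, 3),
        [f"g{i}" for i in range(4)],
        [f"s{j}" for j in range(3)],
    )


@pytest.fixture
def block_matrix():
    """60x15 three-block synthetic matrix with its planted labels."""
    spec = SyntheticSpec(n_genes=60, n_samples=15, n_blocks=3, separation=5.0,
                         noise_sd=1.0, seed=11)
    return generate_clustered_expression(spec)


@pytest.fixture
def soft_text():
    """Minimal GDS SOFT file: 3 probes x 2 samples, one null cell."""
    return (
        "^DATASET = GDS0000\n"
        "!dataset_title = fixture\n"
        "!dataset_table_begin\n"
        "ID_REF\tIDENTIFIER\tGSM1\tGSM2\n"
        "p1\tGENE1\t1.5\t2.5\n"
        "p2\tGENE2\tnull\t3.5\n"
        "p3\tGENE3\t4.0\t5.0\n"
        "!dataset_table_end\n"
    )


def write_tsv(path, text):
    path.write_text(text)
    return path
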