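import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geximpute import (
    ContractError,
    ExpressionMatrix,
    GraphConfig,
    ImputerConfig,
    MaskingSpec,
    UnimputableAttributeError,
    availability_mask,
    impute_categorical,
    impute_dataset,
    impute_numeric,
    inject_missing,
    neighbor_weights,
    pairwise_distance,
    rmse,
    top_k_neighbors,
)
from geximpute.spectral import ClusterModel
from geximpute.synthetic import SyntheticSpec, generate_clustered_expression


def make_model(assignments):
    assignments = np.asarray(assignments)
    k = len(np.unique(assignments))
    return ClusterModel(
        K=k,
        eigenvalues=np.zeros(k),
        embedding=np.zeros((assignments.size, k)),
        assignments=assignments,
    )


class TestNeighborWeights:
    def test_symmetric_pair(self):
        assert np.allclose(neighbor_weights([1.0, 1.0]), [0.5, 0.5])

    def test_inverse_distance_values(self):
        w = neighbor_weights([1.0, 2.0, 4.0])
        assert np.allclose(w, [4 / 7, 2 / 7, 1 / 7], atol=1e-12)

    def test_zero_distance_rejected(self):
        with pytest.raises(ContractError):
            neighbor_weights([0.0, 1.0])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1,
                    max_size=20))
    def test_sum_to_one_and_order(self, dists):
        w = neighbor_weights(sorted(dists))
        assert abs(w.sum() - 1.0) < 1e-12
        assert (w > 0).all()
        assert (np.diff(w) <= 1e-12).all()  # closer -> larger weight


class TestImputeNumeric:
    def test_even_weights(self):
        assert impute_numeric([0.5, 0.5], [2.0, 4.0]) == 3.0

    def test_constant_invariance(self):
        assert impute_numeric([4 / 7, 2 / 7, 1 / 7], [7.0, 7.0, 7.0]) == pytest.approx(7.0)

    def test_weighted_combination(self):
        got = impute_numeric([4 / 7, 2 / 7, 1 / 7], [1.0, 2.0, 4.0])
        assert got == pytest.approx(12 / 7, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            impute_numeric([1.0], [1.0, 2.0])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(1e-3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=1, max_size=10))
    def test_convexity(self, pairs):
        dists = [d for d, _ in pairs]
        vals = np.array([v for _, v in pairs])
        w = neighbor_weights(dists)
        got = impute_numeric(w, vals)
        assert vals.min() - 1e-9 <= got <= vals.max() + 1e-9


class TestImputeCategorical:
    def test_plain_majority(self):
        assert impute_categorical([0.6, 0.4], ["A", "B"]) == "A"

    def test_summed_weights(self):
        assert impute_categorical([0.3, 0.3, 0.4], ["A", "A", "B"]) == "A"

    def test_tie_breaks_lexicographic(self):
        assert impute_categorical([0.5, 0.5], ["B", "A"]) == "A"

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            impute_categorical([], [])


class TestTopKNeighbors:
    def setup_method(self):
        # 5 genes, gene 0 missing at sample 2; gene 4 is a duplicate of gene 0
        vals = np.array([
            [1.0, 2.0, np.nan, 4.0],
            [1.1, 2.1, 9.0, 4.1],
            [5.0, 5.0, 5.0, 5.0],
            [1.3, 2.2, 8.0, 4.2],
            [1.0, 2.0, 7.0, 4.0],
        ])
        self.m = ExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                                  [f"s{j}" for j in range(4)])
        self.h = availability_mask(self.m)

    def test_duplicate_first_with_zero_distance(self):
        model = make_model([0, 0, 1, 0, 0])
        ns = top_k_neighbors(self.m, self.h, model, 0, 2, k_prime=3)
        assert ns.neighbor_indices[0] == 4
        assert ns.distances[0] == 0.0
        assert ns.weights[0] == 1.0

    def test_truncation_to_cluster_size(self):
        model = make_model([0, 0, 1, 1, 0])
        ns = top_k_neighbors(self.m, self.h, model, 0, 2, k_prime=200)
        assert ns.k_prime == 2  # only genes 1 and 4 share the cluster

    def test_brute_force_oracle(self):
        model = make_model([0, 0, 0, 0, 0])
        ns = top_k_neighbors(self.m, self.h, model, 0, 2, k_prime=3)
        cands = [1, 2, 3, 4]
        expect = sorted(
            (pairwise_distance(self.m.values[0], self.m.values[c]), c)
            for c in cands
        )[:3]
        assert ns.neighbor_indices.tolist() == [c for _, c in expect]
        assert np.allclose(ns.distances, [d for d, _ in expect])

    def test_observed_cell_rejected(self):
        model = make_model([0] * 5)
        with pytest.raises(ContractError):
            top_k_neighbors(self.m, self.h, model, 0, 0, k_prime=2)

    def test_widen_fallback_when_cluster_empty(self):
        # gene 0 alone in its cluster -> fallback ranks globally
        model = make_model([0, 1, 1, 1, 1])
        ns = top_k_neighbors(self.m, self.h, model, 0, 2, k_prime=2)
        assert ns.fallback_used
        assert ns.k_prime == 2


class TestImputeDataset:
    def test_duplicate_donor_exact_recovery(self):
        spec = SyntheticSpec(n_genes=40, n_samples=10, n_blocks=2,
                             separation=6.0, noise_sd=1.0, seed=8)
        m, _ = generate_clustered_expression(spec)
        m.values = np.vstack([m.values, m.values])  # every gene duplicated
        m2 = ExpressionMatrix(m.values, [f"g{i}" for i in range(80)],
                              [f"s{j}" for j in range(10)])
        truth = m2.copy()
        m2.values[3, 4] = np.nan
        m2.values[50, 2] = np.nan
        res = impute_dataset(m2, ImputerConfig(seed=0))
        assert np.allclose(res.completed.values, truth.values)

    def test_no_missing_identity(self, block_matrix):
        m, _ = block_matrix
        res = impute_dataset(m, ImputerConfig(seed=0))
        assert np.array_equal(res.completed.values, m.values)
        assert res.provenance == []

    def test_zero_noise_blocks_exact(self):
        spec = SyntheticSpec(n_genes=60, n_samples=12, n_blocks=3,
                             separation=5.0, noise_sd=0.0, seed=2)
        m, _ = generate_clustered_expression(spec)
        masked, record = inject_missing(m, MaskingSpec(rate=0.05, seed=3), 0)
        res = impute_dataset(masked, ImputerConfig(n_clusters=3, seed=0))
        assert rmse(record, res.completed) == pytest.approx(0.0, abs=1e-12)

    def test_observed_cells_preserved(self, block_matrix):
        m, _ = block_matrix
        masked, record = inject_missing(m, MaskingSpec(rate=0.1, seed=5), 0)
        obs = ~np.isnan(masked.values)
        res = impute_dataset(masked, ImputerConfig(seed=0))
        assert np.array_equal(res.completed.values[obs], masked.values[obs])
        assert not np.isnan(res.completed.values).any()

    def test_convexity_of_imputed_values(self, block_matrix):
        m, _ = block_matrix
        masked, _ = inject_missing(m, MaskingSpec(rate=0.1, seed=6), 0)
        lo, hi = np.nanmin(masked.values), np.nanmax(masked.values)
        res = impute_dataset(masked, ImputerConfig(seed=0))
        assert res.completed.values.min() >= lo - 1e-9
        assert res.completed.values.max() <= hi + 1e-9

    def test_deterministic(self, block_matrix):
        m, _ = block_matrix
        masked, _ = inject_missing(m, MaskingSpec(rate=0.1, seed=7), 0)
        a = impute_dataset(masked, ImputerConfig(seed=42))
        b = impute_dataset(masked, ImputerConfig(seed=42))
        assert np.array_equal(a.completed.values, b.completed.values)

    def test_permutation_equivariance(self):
        spec = SyntheticSpec(n_genes=30, n_samples=8, n_blocks=3,
                             separation=6.0, noise_sd=0.0, seed=9)
        m, _ = generate_clustered_expression(spec)
        masked, _ = inject_missing(m, MaskingSpec(rate=0.08, seed=1), 0)
        perm = np.random.default_rng(0).permutation(30)
        permuted = ExpressionMatrix(
            masked.values[perm], [masked.gene_ids[i] for i in perm],
            list(masked.sample_ids),
        )
        a = impute_dataset(masked, ImputerConfig(n_clusters=3, seed=0))
        b = impute_dataset(permuted, ImputerConfig(n_clusters=3, seed=0))
        inv = np.argsort(perm)
        assert np.allclose(a.completed.values, b.completed.values[inv])

    def test_unimputable_attribute(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, np.nan],
                         [1.5, np.nan]])
        m = ExpressionMatrix(vals, list("abcd"), ["s1", "s2"])
        with pytest.raises(UnimputableAttributeError):
            impute_dataset(m, ImputerConfig(seed=0))

    def test_categorical_cells_imputed(self):
        from geximpute.synthetic import generate_mixed_types

        spec = SyntheticSpec(n_genes=45, n_samples=10, n_blocks=3,
                             separation=6.0, noise_sd=0.5, seed=13)
        m, labels = generate_mixed_types(spec, n_categorical=2, n_levels=3)
        truth = m.copy()
        m.values[4, 9] = np.nan  # categorical cell
        m.values[20, 8] = np.nan
        res = impute_dataset(m, ImputerConfig(n_clusters=3, seed=0))
        assert res.completed.values[4, 9] == truth.values[4, 9]
        assert res.completed.values[20, 8] == truth.values[20, 8]

    def test_cluster_centroid_fallback(self):
        vals = np.array([
            [0.0, 1.0, np.nan],
            [0.1, 1.1, np.nan],
            [10.0, 11.0, 12.0],
            [10.1, 11.1, 12.1],
        ])
        m = ExpressionMatrix(vals, list("abcd"), ["s1", "s2", "s3"])
        cfg = ImputerConfig(n_clusters=2, seed=0, fallback="cluster_centroid",
                            graph=GraphConfig(mode="full", sigma="auto"))
        res = impute_dataset(m, cfg)
        # no in-cluster donor observes s3 for genes 0/1 -> centroid of observers
        assert res.completed.values[0, 2] == pytest.approx(12.05)
        assert res.completed.values[1, 2] == pytest.approx(12.05)
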