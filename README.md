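# geximpute

Missing-value imputation for gene-expression matrices (genes × samples).
The main method clusters genes by **spectral clustering** on a Gaussian
similarity graph and then fills each missing cell from its top-K′ nearest
**in-cluster** neighbours with inverse-distance weights (numeric cells:
weighted mean; categorical cells: largest summed weight).  Five local
baseline imputers and a replicate-RMSE benchmarking harness are included:

| method    | description |
|-----------|-------------|
| `proposed`| spectral clustering + cluster-restricted weighted top-K′ NN |
| `knn`     | inverse-distance-weighted K nearest neighbours, no clustering |
| `sknn`    | sequential KNN: least-missing genes first, imputed rows reused |
| `iknn`    | iterative KNN from a gene-mean start, to a fixed point |
| `lls`     | local least squares regression on the K most similar complete genes |
| `slls`    | sequential LLS with donor reuse |

Distances are pairwise-complete Euclidean rescaled by `sqrt(M / m_obs)` so
rows with different missingness remain comparable; similarity graphs
(full, normal/mutual kNN, ε-neighbourhood) are stored sparsely; the
random-walk Laplacian embedding is clustered with seeded K-means, with an
eigengap heuristic for choosing the cluster count.

## CLI

```sh
# generate a clustered synthetic matrix
geximpute simulate --genes 300 --samples 20 --blocks 3 --separation 5 \
    --noise 1 --seed 7 --out synth.tsv --labels labels.tsv

# impute a matrix with missing cells marked '?'
geximpute impute --input matrix.tsv --missing-marker "?" \
    --method proposed --k 15 --clusters auto --seed 42 \
    --output imputed.tsv --provenance prov.tsv

# replicate RMSE benchmark on a complete matrix
geximpute benchmark --input synth.tsv --methods proposed,knn,sknn,iknn,lls,slls \
    --rates 0.05,0.10,0.15,0.20,0.25 --replicates 30 --seed 7 --out report.tsv

# mean RMSE vs neighbour count at a fixed missing rate
geximpute sweep --input synth.tsv --method proposed --k 1:300 --rate 0.05 \
    --replicates 30 --seed 7 --out sweep.tsv
```

Input format: delimited text (TSV by default), first column the gene id,
header row of sample ids; missing markers default to `?`, `NA`, `null`
and the empty string.  GEO GDS SOFT files are read with
`geximpute.read_gds_soft` (only the dataset value table is parsed).

## Library sketch

```python
import geximpute as gx

m = gx.read_matrix("matrix.tsv")                      # NaN = missing
res = gx.impute_dataset(m, gx.ImputerConfig(k_prime=15, n_clusters="auto",
                                            seed=42))
gx.write_matrix(res.completed, "imputed.tsv")

# benchmarking on a complete matrix
spec = gx.MaskingSpec(rate=0.05, mechanism="mcar", seed=7, n_replicates=30)
masked, record = gx.inject_missing(complete_m, spec, replicate=0)
gx.rmse(record, gx.knn_impute(masked, k=15).completed)
```
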