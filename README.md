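# scstab

Estimating the number of cell types in a single-cell RNA-seq dataset by
**clustering stability**, together with the benchmark machinery needed to
evaluate such estimators: a labelled synthetic pool generator, a four-setting
subsampling design, pair-counting concordance metrics, and a
good/intermediate/poor performance rubric.

## Who this is for

Anyone who needs k — the number of distinct cell populations — before or
instead of a full clustering analysis: as input to clustering methods that
require k, as a sanity check on annotations, or to benchmark cluster-number
estimators on datasets with known composition.

## The method

Let X be the log-normalised genes × cells matrix. For each ensemble member
b = 1..B (default B = 20):

1. **random projection** — sample a fraction of the genes uniformly without
   replacement (default 10%, floored at 2 × the encoding dimension);
2. **encoding** — compress the projected matrix to a low dimension (default
   16) with a single-bottleneck autoencoder trained on reconstruction, or a
   PCA projection (`encoder="pca_fallback"`, deterministic and fast);
3. **clustering** — partition the encoded cells into k groups with k-means
   (or any plugged-in clusterer).

The **stability** of a candidate k is the median normalised mutual
information (NMI) over all B(B−1)/2 unordered pairs of member partitions at
that k:

    s(k) = median { NMI(P_i^k, P_j^k) : 1 ≤ i < j ≤ B }

and the estimate is k̂ = argmax_k s(k) over a grid (2..25 by default, ties
to the smallest k). The intuition: when k matches the real population
structure, clusterings of independently projected and encoded views of the
same data agree; at the wrong k they fragment or merge populations
inconsistently and agreement drops. A consensus partition at k̂ is obtained
by average-linkage hierarchical clustering of 1 − co-association (the
fraction of members placing each cell pair together).

Concordance with reference labels is measured by pair counts (N11, N00,
N01, N10 over all cell pairs) through ARI, Fowlkes–Mallows and Jaccard, and
by NMI = 2·I(U;V)/(H(U)+H(V)) from the contingency table.

## Worked example

```python
from scstab import SimPoolSpec, simulate_pool, log_normalise, StabilityKEstimator
from scstab import metrics

spec = SimPoolSpec(n_types=3, cells_per_type=[100, 100, 100], n_genes=500,
                   separation=4.0, dispersion=0.2, seed=1)
pool = simulate_pool(spec)          # 500 genes x 300 cells, 3 labelled types
nm = log_normalise(pool)            # size-factor log2 normalisation

est = StabilityKEstimator(k_min=2, k_max=6, ensemble_size=10,
                          encoder="pca_fallback", random_state=0).fit(nm.X)
print(est.k_hat_)
print({k: round(s, 3) for k, s in est.stability_profile_.score.items()})
print(metrics.ari(pool.labels, est.labels_))
```

prints

```
3
{2: 0.274, 3: 0.919, 4: 0.765, 5: 0.649, 6: 0.576}
1.0
```

The stability profile peaks sharply at the true k = 3 (score 0.919 against
0.274–0.765 elsewhere), and the consensus partition at k̂ = 3 matches the
simulated labels exactly (ARI = 1.0).

The same pipeline is available from the shell:

```bash
scstab simulate --n-types 3 --cells-per-type 100 --n-genes 500 \
       --separation 4 --seed 1 --out pool/
scstab estimate-k --input pool/ --kmin 2 --kmax 6 --ensemble-size 10 \
       --encoder pca_fallback --seed 0 --out result.json
scstab evaluate --truth pool/labels.tsv --pred result.json
```

plus `design`, `benchmark` and `summarise` subcommands for the full
benchmark workflow.

## The benchmark design

`enumerate_design` reproduces four dataset-sampling settings over any
labelled pool (cell types with ≤ 300 cells are excluded first):

| setting      | crossing                                             | datasets |
|--------------|------------------------------------------------------|----------|
| `type_sweep` | 5–20 types × 200 cells/type × 10 replicates          | 160      |
| `cell_sweep` | {5,10,15,20} types × {50..250} cells × 10            | 200      |
| `imbalance`  | {10,20} types × minor {100,50,20} cells × 10         | 60       |
| `large_n`    | {5,10} types × {500,1000} cells × 2 sources × 10     | 80       |

`run_benchmark` ties everything together: filter → enumerate → sample →
estimate → evaluate, with per-dataset failure isolation and a reproducible
manifest.

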