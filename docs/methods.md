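# Methods

## The estimation model

The estimator treats the number of cell types k as the resolution at which a
dataset's clustering is most reproducible under perturbation. The
perturbations are random gene-subspace projections followed by nonlinear (or
linear) compression: each of B ensemble members sees a different random
fraction of the genes, encoded to a low dimension, and clusters the encoded
cells into k groups. Stability at k is the median pairwise NMI among the B
member partitions; k̂ maximises it over a candidate grid. Two sources name
the aggregate differently (highest *average* score vs *median* of pairwise
scores); the median is the default because it is the more specific
statement and is robust to a single degenerate member, and the mean is
available via `aggregate="mean"`.

Assumptions worth stating: the data contain one dominant flat partition
(no hierarchy — nested subtypes will draw the profile toward either
resolution); populations are separable in expression space after log
normalisation; and the grid covers the truth (2..25 by default; the upper
bound is a config knob, not a detected quantity).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ensemble_size` (B) | 20 | members; pairwise scores need B ≥ 2; 10 suffices in simulations |
| `projection_fraction` | 0.1 | genes per member, floored at 2×`encode_dim` so the encoder is never over-parameterised |
| `encode_dim` | 16 | encoded dimensionality per member |
| `encoder` | autoencoder | single tanh bottleneck trained on reconstruction (Adam, MSE, standardised input); `pca_fallback` swaps in a full-SVD PCA with the same interface |
| `encoder_epochs` | 30 | autoencoder training epochs |
| `k_min`, `k_max` | 2, 25 | candidate grid (k = 1 is rejected: pairwise agreement is undefined as a selection signal there) |
| `aggregate` | median | aggregation of pairwise NMI at each k |
| `share_projections` | True | reuse the B encodings across all k; comparable scores and a B-fold speedup over re-encoding per k. Both modes exist because either is defensible; neither is asserted canonical |

The encoder is deliberately small: a single hidden bottleneck captures the
dominant low-dimensional structure that k-means needs, trains in seconds on
CPU, and is fully seeded (initialisation and minibatch order) so runs are
bit-reproducible. PCA is the right choice for tests and for data where the
structure is close to linear; the autoencoder is the default because
encoded-subspace ensembles are defined around nonlinear encoders.

Ties in the stability profile break to the smallest k (parsimony).

## Metrics conventions

Pair counts are computed from the contingency table in O(RC) and are
property-tested against brute-force pair enumeration. ARI uses the
pair-count formula 2(N00·N11 − N01·N10)/((N00+N01)(N01+N11)+(N00+N10)(N10+N11)),
cross-checked against scikit-learn's contingency-table implementation.
Entropies and mutual information are computed consistently in bits; NMI is
base-invariant under a consistent base.

Two printed-formula corrections are baked in and documented here: the
mutual-information summand uses |U_i ∩ V_j| (a cross-partition cell count —
the same-partition variant that sometimes appears in print is a typo), and
the default NMI normalisation is 2I/(H_U+H_V) so that identical partitions
score 1; the unscaled I/(H_U+H_V) form (which gives 0.5 for identical
partitions) remains available as `normalization="as_printed"` since it
cannot be ruled out that published values used it.

Degenerate cases: if both partitions have zero total entropy (both
single-cluster) NMI is 1, since they are identical up to relabelling. A
zero ARI denominator can only occur with N01 = N10 = 0, i.e. identical
partitions, scoring 1. FM and Jaccard score 1 when there are no
discordant pairs at all and 0 whenever N11 = 0 with discordance present.

Deviation statistics: deviation = estimate − truth (positive =
over-estimation), relative deviation divides by the truth, and variability
is the sample standard deviation (ddof = 1; defined as 0 for a single
replicate).

## The synthetic pool generator

The generator emulates a labelled atlas selection pool: T cell types, each
with its own disjoint block of marker genes whose mean is elevated
2^separation-fold in that type's cells over a constant background rate;
counts are negative-binomial with variance μ + dispersion·μ², scaled by
log-normal per-cell library-size factors with mean 1 and configurable CV.
Defaults (1,000 genes, 25 markers/type, separation 3, dispersion 0.3, base
rate 2, library CV 0.2) give overdispersed counts with clearly but not
trivially separated types.

Design choices: the background rate is constant across genes so that the
marker fold-change is exactly 2^separation in expectation (testable to
within sampling error); marker blocks are disjoint so the true k is
unambiguous; library-size factors are log-normal to exercise the
size-factor normalisation path. What real data have that this generator
does not: per-gene baseline heterogeneity, zero-inflation beyond NB zeros,
batch effects, doublets, correlated gene programs, and hierarchical
subtypes. Passing the recovery tests therefore shows the pipeline is
correct and self-consistent on flat, separable structure — not that the
estimator resolves subtle or nested populations in real tissue.

## Normalisation

One convention: per-cell size factor = library size / mean library size over
cells with nonzero counts; value = log2(count/size_factor + 1) (base e and
other pseudocounts via config). Cells with zero library size are kept as
all-zero columns with a warning rather than dropped, so cell indices remain
aligned with external labels. Scaling every cell's counts by a common
factor leaves size factors unchanged and, up to the pseudocount term,
shifts all values by a constant — which the downstream clustering is
insensitive to.

## The sampling design

The pool filter keeps cell types with strictly more than 300 cells
("no more than 300" read literally as exclusive: a 300-cell type is
excluded, a 301-cell type kept). The four settings enumerate to exactly
160 / 200 / 60 / 80 dataset recipes (each crossing × 10 replicates). Each
recipe's seed derives deterministically from the base seed and the recipe's
fields (CRC32 of the field string), so replicates are independent draws yet
the whole design replays exactly. In the imbalance setting the sampled type
order decides the major/minor split (first half major); the large-n setting
carries a `source` axis ("pool_a"/"pool_b") so its 2×2×2×10 = 80 count is
enumerable while the caller supplies the second pool. Types are re-drawn
independently per replicate. Sampling of types and of cells is uniform
without replacement, preserving raw counts.

## The rubric

Boundary convention for the categoriser: value ≤ good-cutoff → good, value
≥ poor-cutoff → poor, otherwise intermediate (concordance reversed). The
deviation criterion is judged on the magnitude of the relative deviation,
so over- and under-estimation are penalised symmetrically, and magnitudes
are averaged across datasets (a +40% and a −40% run must not cancel to
"good"). Aggregation across datasets is the mean; time and memory are
accepted only as externally measured numbers — this package does not claim
hardware-comparable measurement. Criteria without measurements are marked
"not assessed" and excluded from the (good-count, intermediate-count) rank
key.

## Problem sizes and numerical choices

The recovery study runs true k ∈ {3, 5, 8} with 100 cells per type, 1,000
genes, separation 4, dispersion 0.2, B = 10 PCA-encoded members over grid
2..12, ten seeds per k — about 30 s of compute in total, chosen as the
smallest design in which estimator failures would be visible rather than
drowned in sampling noise. k-means uses 5 seeded restarts per member;
consensus uses average linkage on 1 − co-association (the co-association
matrix is dense, so consensus is quadratic in cells — fine to ~10k cells).
Hierarchical cuts may return fewer than k non-empty clusters when the
dendrogram does not admit k; the partition is returned as cut.

## Known limitations

No hierarchical/multi-resolution estimation; no GPU; the co-association
consensus is O(n²) memory; the autoencoder is a minimal bottleneck network,
not a tuned deep architecture; and the 12 third-party clustering tools the
benchmark design was built to compare are out of scope — only the pluggable
base-clusterer interface (`clusterer_fn`) is provided for them.
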