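# nlnet — nonlinear gene coexpression network reconstruction

`nlnet` reconstructs an undirected gene network from an expression matrix
using a *nonlinear* measure of pairwise dependence, then decomposes the
network into communities (candidate co-regulated modules).  It is aimed at
transcriptomics data — microarray, bulk or single-cell RNA-seq — where
regulatory relations are often not linear: saturating responses, periodic
programs, magnitude effects.  Correlation-based pipelines miss these;
`nlnet` is built to find them while still capturing linear relations as a
special case.

## The method

**Distance.** For genes *g_i* (reference) and *g_j* (target) measured on
*n* samples, the Distance based on the Conditional Ordered List is

&nbsp;&nbsp;&nbsp;&nbsp;DCOL(g_j | g_i) = (1/(n−1)) Σ_{k=2..n} |g\*_{j,k} − g\*_{j,k−1}|,

where g\*_{j,·} is the target re-ordered so that the reference is
ascending.  If g_j = f(g_i) + noise for *any* reasonably smooth f,
neighbouring samples in the ordering have similar target values and the
distance is small; for independent genes it concentrates at the mean
absolute difference under a random ordering.  The measure is rank-based in
the reference and generally asymmetric.

**Inference.** A gene-specific null is estimated by permuting the sample
columns of the whole matrix B times (default B = 500), giving each gene a
null mean m_j and sd s_j.  One-sided p-values P_{ij} = Φ((D_{ij} − m_j)/s_j)
are computed against the asymptotically normal null, and each gene's
p-value column is converted to local false discovery rates — the posterior
probability that the pair is null — via a Grenander (monotone decreasing)
density estimate.

**Network and communities.** An edge is called when the pair's lfdr is
below a cutoff chosen so the network hits a target average degree
(default 15), clamped to the band [0.05, 0.2].  Communities come from
multilevel (Louvain-type) modularity optimization or label propagation;
communities below a minimum size are left unassigned.

A simulator generates benchmark data with hidden nonlinear modules
(hidden-controller, chain and two-parent designs; linear, sine, box-wave
and absolute-value links) and recovery is scored with the Adjusted Rand
Index.

## Worked example

Simulate 10 hidden modules of 100 genes (plus 10% pure-noise genes) under
the hidden-controller design at noise level 0.4, reconstruct the network,
and score recovery:

```sh
$ nlnet simulate --scenario 1 --dependency 0 --noise 0.4 --seed 7 --out sim/
wrote 1100 genes x 100 samples to sim

$ nlnet run --input sim/expr.tsv --out net/ --target-degree 15 \
      --n-perm 500 --seed 7 --min-community-size 5
genes: 1100  samples: 100
lfdr cutoff used: 0.0500  edges: 26125  average degree: 47.50
community sizes: {'0': 82, '1': 103, '2': 102, '3': 101, '4': 101, '5': 100, ...}

$ nlnet ari sim/truth.tsv net/membership.tsv
0.827026
```

The requested average degree of 15 would need a cutoff below 0.05, so the
cutoff clamps to the band's floor and the network comes out denser
(average degree 47.5) — within-module dependence is strong at this noise
level.  The largest recovered communities sit at ~100 genes, matching the
planted module size; the Adjusted Rand Index of 0.83 against the hidden
truth means the module structure is recovered nearly completely despite
40% relative noise and nonlinear links.  `net/` also contains the edge
list (`edges.tsv`, with each edge's supporting lfdr), the community
membership table, and a JSON run summary.

The same pipeline runs on real data; for sparse single-cell counts add
`--filter-fraction 0.667 --log-transform` to keep genes with non-zero
values in more than 2/3 of samples and work on log(x+1) values.

From Python:

```python
from nlnet import PipelineConfig, run_pipeline, read_expression

expr = read_expression("expr.tsv")
result = run_pipeline(PipelineConfig(n_perm=500, seed=7), expr)
result.network.edge_table()   # [(gene_a, gene_b, lfdr), ...]
result.partition.labels       # {gene_id: community_id}, 0 = unassigned
```

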