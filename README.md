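# cpba — cluster and propensity based approximation of networks

`cpba` decomposes a symmetric nonnegative adjacency matrix *A* into a small
set of interpretable parameters: a hard cluster assignment *c*, a per-node
**propensity** *p<sub>i</sub>* quantifying the node's tendency to form
connections, and a **cluster similarity** matrix *R* (unit diagonal) relating
the clusters to each other.  The model is

&nbsp;&nbsp;&nbsp;&nbsp;*A<sub>ij</sub>* ≈ *r*<sub>*c<sub>i</sub>c<sub>j</sub>*</sub> · *p<sub>i</sub>* · *p<sub>j</sub>*  (*i* ≠ *j*),

with *K*(*K*−1)/2 + *n* free continuous parameters.  It is aimed at anyone
working with general similarity data — co-expression and other weighted
biological networks, multigraphs of counted interactions (co-authorship,
shared-gene disease links), or any setting where the input is a similarity
matrix rather than raw feature vectors.

Two objectives are supported, both summed over ordered node pairs:

- **Poisson** (multigraph counts *n<sub>ij</sub>*): maximize
  Σ *n<sub>ij</sub>* ln *μ<sub>ij</sub>* − *μ<sub>ij</sub>* − ln *n<sub>ij</sub>*!,
  with *μ<sub>ij</sub>* = *r*<sub>*c<sub>i</sub>c<sub>j</sub>*</sub>*p<sub>i</sub>p<sub>j</sub>*.
  This is a degree-corrected Poisson block model; with *K* = 1 it reduces to
  the pure propensity Poisson (PPP) model.
- **Frobenius** (weighted similarities in [0, 1]): minimize
  Σ (*A<sub>ij</sub>* − *μ<sub>ij</sub>*)².  With *K* = 1 this recovers the
  conformity decomposition of an exactly factorizable network
  (*A<sub>ij</sub>* = *f<sub>i</sub>f<sub>j</sub>*).

Fitting alternates three monotone steps: an exact closed-form update of *R*,
minorize-maximize (MM) updates of the propensities accelerated by a
safeguarded secant-based quasi-Newton extrapolation, and greedy node
reassignment in seeded random order.  The Poisson branch additionally
provides upper-tail significance tests for edge counts
(P(X ≥ *n<sub>ij</sub>*) under Poisson(*μ<sub>ij</sub>*)) — flagging pairs
with more connections than their clusters and propensities explain — and
AIC/BIC guidance for the number of clusters.

## Worked example

Fit a 120-node multigraph with three dense blocks and 15 planted cross-block
edges, then rank the cross-block edges by significance:

```python
import numpy as np
from cpba import CPBA, test_all_edges
from cpba.simulate import simulate_block_multigraph

sim = simulate_block_multigraph(block_sizes=(30, 40, 50), n_switch_per_pair=5, rng_seed=0)
est = CPBA(n_clusters=3, objective="poisson", random_state=0).fit(sim.adjacency)
print("cluster sizes:", np.bincount(est.labels_)[1:])
print("log-likelihood:", round(est.objective_value_, 2))
print("cluster similarity:\n", np.round(est.cluster_similarity_, 4))
edges = test_all_edges(sim.adjacency, est.model_, alpha=0.01)
print(edges.head(3).to_string(index=False))
print("pairs with p < 0.01:", edges.attrs["n_significant"][0.01])
```

prints

```
cluster sizes: [30 40 50]
log-likelihood: -5080.86
cluster similarity:
 [[1.     0.0042 0.0033]
 [0.0042 1.     0.0025]
 [0.0033 0.0025 1.    ]]
 rank node1 node2  cluster1  cluster2  observed  expected  p_value  neg_log10_p  intra_cluster
    1    56   111         2         3       1.0  0.002591 0.002588     2.587036          False
    2    62   100         2         3       1.0  0.002591 0.002588     2.587036          False
    3    41    74         2         3       1.0  0.002644 0.002641     2.578264          False
pairs with p < 0.01: 15
```

The three blocks are recovered exactly; the tiny off-diagonal similarities
(~0.003) say the blocks are nearly disconnected; and exactly the 15 planted
cross-block edges are flagged at *p* < 0.01 — each is a single observed edge
where the fitted model expects ~0.0026.

The same analyses are available from the shell: `cpba fit`, `cpba ppp`,
`cpba edges`, `cpba select-k` and `cpba simulate` read/write labeled
adjacency TSVs and edge lists (`cpba --help`).

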