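# acolink

Ant-colony-clustering-enhanced bipartite network inference for
predicting lncRNA–protein interactions.

## The problem

Long non-coding RNAs (lncRNAs, >200 nt, non-protein-coding) act largely
by binding RNA-binding proteins, but experimentally mapping these
interactions is slow and expensive, so the known lncRNA–protein
interaction catalog is sparse. Given a binary bipartite network — an
`n x m` adjacency matrix `M` with `M[i, j] = 1` when lncRNA `l_i` is
known to bind protein `p_j` — the task is to rank the unobserved pairs
by how likely they are to interact, so that bench experiments can be
prioritized. `acolink` is for computational biologists who have such a
network (as an edge list or labeled adjacency CSV) and want ranked
candidate interactions plus a rigorous cross-validated estimate of
prediction quality.

## The method

Each lncRNA is represented by its **association profile**, the
corresponding row of `M`. The pipeline has three stages:

1. **Ant-colony clustering** of the profiles. Points are ants, cluster
   centers are food sources. Pheromone trails are initialized by
   thresholding distance at a radius `r` (`T_ij = 1` iff `d_ij <= r`),
   and the probability that point `i` joins center `j` is

   `p_ij = T_ij^α η_ij^β / Σ_j T_ij^α η_ij^β`,  with visibility `η_ij = 1/d_ij`.

   A point joins the best center when `max_j p_ij > p0`, otherwise it
   founds a new cluster, so the number of clusters is discovered. After
   each pass pheromone evaporates and is re-deposited,
   `T ← (1−ρ_evap) T + Q/d`, and an occasional single-point *mutation*
   is kept only if it lowers the best mean-squared-error objective
   `F_min` seen so far.
2. **Linear neighborhood similarity (LNS)**: each profile is expressed
   as the best convex combination of its neighbors
   (`min_w ‖x_i − Σ_j w_j x_j‖² + ridge‖w‖²` on the probability
   simplex), giving a row-stochastic similarity matrix `W`, which is
   then **cluster-enhanced**: within-cluster weights boosted by
   `1 + γ`, cross-cluster weights damped by `δ`, rows renormalized.
3. **Label propagation** over the lncRNA similarity graph:

   `P^t = ρ W P^{t−1} + (1−ρ) M`, `P^0 = M`,

   which converges geometrically to
   `P* = (1−ρ)(I − ρW)^{-1} M` (also available as an exact linear
   solve). `P*[i, j]` is the predicted interaction score.

Two standard baselines are included for comparison: random walk with
restart (RWR) on the joint bipartite graph and two-phase
degree-normalized resource allocation (LPBNI-style). A repeated k-fold
edge-masking cross-validation harness reports AUC, AUPR, sensitivity,
specificity, precision, accuracy and F1, refitting every stage on each
masked training network so no held-out information leaks.

## Worked example

```python
from acolink import AntColonyBipartite, BlockNetworkSpec, generate_block_network, run_cv

net, _ = generate_block_network(BlockNetworkSpec(seed=7))   # 100 x 50, 5 blocks
res = AntColonyBipartite(net, seed=7).fit()
print(res.summary())
print(res.predictions(top=5).to_string(index=False))
```

```
Ant-Colony-Clustering Bipartite Network Inference
====================================================
lncRNAs                                          100
proteins                                          50
known interactions                               359
clusters discovered                              100
clustering iterations                              3
clustering objective F                      0.000000
best objective F_min                        0.000000
similarity boost gamma                         0.500
cross-cluster retention delta                  1.000
absorption probability rho                     0.600
propagation iterations                            24
propagation converged                           True
====================================================

lncrna protein    score  rank
  L016     P10 0.239660     1
  L082     P43 0.239350     2
  L047     P27 0.235952     3
  L094     P43 0.230005     4
  L009     P06 0.224842     5
```

The top-ranked pairs are unobserved lncRNA–protein combinations whose
profile neighborhoods carry the strongest propagated evidence; a score
of 0.24 here means roughly a quarter of the maximum attainable label
mass (known pairs score at least `1 − ρ = 0.4`). On sparse binary
profiles the threshold rule fragments the colony into many small
clusters ("clusters discovered: 100"), in which case the enhancement
step reduces to the identity and the ranking is carried by the
LNS propagation; on well-separated data (see the methods note) the
clustering recovers the true groups.

Cross-validated quality on the same synthetic network:

```python
rep = run_cv(net, "accbn", k=5, repeats=1, seed=7)
print(rep.summary())
```

```
metric              mean        sd
----------------------------------
auc               0.7762    0.0142
aupr              0.0620    0.0067
sensitivity       0.1088    0.0350
specificity       0.9862    0.0006
precision         0.1088    0.0350
accuracy          0.9728    0.0012
f1                0.1088    0.0350
```

Here AUC ≈ 0.78 means a held-out true interaction outranks a random
non-interacting pair 78% of the time; sensitivity/precision/F1
coincide because the default operating point calls exactly as many
positives as there are held-out edges.

## Command line

```bash
acolink simulate --out-prefix data/sim --seed 0          # synthetic fixture
acolink predict  --input data/sim_edges.tsv --output ranked.tsv --seed 0
acolink cv       --input data/sim_edges.tsv --out-prefix cv_report \
                 --method accbn --k 5 --repeats 20 --seed 0
```

`--method {accbn,rwr,lpbni}` switches predictor; YAML config files plus
flag overrides are supported (`--config`); exit codes are 0/2/3 for
success / configuration error / data error.

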