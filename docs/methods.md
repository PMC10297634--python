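# Methods

## Curvature model

The package works with simple connected undirected graphs with strictly
positive edge weights. Node order is first-appearance order in the input and
fixes every matrix index and tie-break. Distances are Dijkstra shortest-path
lengths with weights as edge lengths; on unit-weight graphs this is the
hop-count SPD.

Each node `x` carries the lazy neighborhood measure `m_x^α` (mass `α` at `x`,
the rest spread over neighbors proportionally to a transform `γ` of the
incident weights; `γ` is configurable but identity everywhere in practice,
and with identity `γ` the measure is invariant under global weight
rescaling). The α-Ricci curvature is `κ_α(x,y) = 1 − W(m_x^α, m_y^α)/d(x,y)`
with `W` the Wasserstein-1 distance over the graph metric, and the Ollivier
curvature is `κ = lim_{α→1} κ_α/(1−α)`.

The implementation computes `κ` without the limit, as the optimum of a
sign-constrained coupling LP between the α = 0 measures (`κ*`, see README for
the constraint set). Both the transport LP and the ∗-coupling LP are solved
with HiGHS through `scipy.optimize.linprog` at default (interior
point/simplex) tolerances; observed agreement between `κ*` and the α-route
oracle at α = 0.999 is ~1e−13 on unweighted toy graphs, far inside the 1e−6
tolerance asserted by the tests.

Numerical and formulation choices:

* The printed marginal conditions of the transport coupling conflate bound
  variables; they are implemented as the standard optimal-transport row/column
  marginals, the only consistent reading.
* The strict constraint `B(x,y) > 0` is relaxed to `≥ 0`; LPs need closed
  feasible sets and the supremum over the closure is the same.
* Both LPs are restricted, without loss, to the star supports
  `S_x = {x} ∪ N(x)`, `S_y = {y} ∪ N(y)`: rows outside `S_x` have zero
  marginal and sign-constrained entries summing to zero, hence vanish
  identically (same for columns). Distances inside the LP are always
  full-graph distances, never subgraph distances.
* `κ(x,x)` is undefined; curvature matrices carry NaN on the diagonal and the
  encoding layer maps the diagonal to bias 0.
* Per-pair cost is one LP cubic in the degrees, i.e. `O(m·d̄³)` for all edges
  of a graph with mean degree `d̄`; curvature is therefore computed once per
  graph, cached on the graph object, and serialized — never recomputed inside
  a training loop.

Curvature matrices come in three modes: `edges` (adjacent pairs only), `all`
(the exact LP for every pair — the ∗-coupling LP is well defined for
non-adjacent pairs), and `path-mean` (exact on edges; non-adjacent pairs get
the mean of edge curvatures along the deterministic shortest path — a cheap
surrogate for larger graphs). The attention bias needs a value for every
attended pair; `all` is the default up to a few hundred nodes and
`path-mean` is the documented fallback above that.

Deterministic shortest paths break ties lexicographically on node indices.
Note that lexicographic tie-breaking is not permutation-equivariant when a
pair has several shortest paths, so the path-dependent quantities (`path-mean`
values for non-adjacent pairs, the Γ encoding off the edge set) are exactly
equivariant only where the shortest path is unique; the curvature values
themselves are exactly isomorphism-equivariant.

## Structural encodings

* **Degree encoding.** A formulation with one learnable vector per node
  cannot share parameters across graphs, so degrees index an embedding table
  (rows 0..max_degree, clamped above, plus a reserved virtual-node row); all
  nodes of equal degree share a row. `H(0) = X + D`, with raw node features
  passed through a learnable linear map to the model width first (the
  package's datasets carry low-dimensional features; when feature width
  already equals the model width this map is the only affine touch).
* **Edge-path encoding Γ.** For each unordered pair, the mean over the
  deterministic shortest path of per-position linear maps of edge features,
  `γ(i,j) = (1/N) Σ_k ⟨x_{e_k}, w_k⟩`. Position vectors exist up to
  `K_max = 20`; longer paths reuse the last vector (molecular-scale graphs
  rarely exceed that diameter). Featureless graphs get a constant scalar
  feature 1 per edge, so Γ degenerates to a learnable per-position mean.
* **Curvature encoding Φ.** A per-pair learnable scalar cannot generalize
  across graphs either; instead κ* is bucketed (32 uniform buckets over
  [−2, 2] plus two overflow buckets — κ* lies in [−2, 2] for unweighted
  graphs of the sizes used here) and each bucket owns a learnable scalar, so
  Φ is a monotone-in-structure step function of curvature. κ is rounded to
  9 decimals before bucketing so solver round-off cannot flip a value that
  sits exactly on a bucket edge. Diagonal → 0; virtual-node pairs → a
  dedicated learnable scalar (for Γ likewise).
* Bias parameters are independent per attention head (strictly more
  expressive; the per-head convention of the transformer lineage this
  follows). Γ and Φ are assembled per head as (n+1)×(n+1) matrices, virtual
  node last, by gathering from parameter vectors with integer slot matrices,
  so gradients flow into the encoders.

## Model and training

Pre-LN residual blocks exactly as `Ĥ = MHA(LN(H)) + H`,
`H' = FFN(LN(Ĥ)) + Ĥ`, biased multi-head attention
`softmax(QKᵀ/√d_K + Γ + Φ)V` per head with concatenated heads projected by
`W_O`, a virtual node attached to all nodes whose final representation feeds
a linear graph-level head. Desk-scale defaults: 4 layers, 4 heads,
`d_model` 64, FFN 128, dropout 0 (the determinism contract: identical seeds
give identical forward passes and loss traces in single-threaded float64).
A larger named preset (8 layers, 16 heads, width 256) mirrors the
full-benchmark configuration of the architecture family but is not exercised
by the tests.

Training uses AdamW with eps 1e−8, betas (0.99, 0.999), peak learning rate
2e−4 floored at 1e−9, L1 loss for regression, minibatches drawn without
replacement from a seeded generator. Everything — model init, data
generation, batching — derives from explicit integer seeds; the CLI derives
per-stage seeds from one global seed via a CRC32 stage-name mix.

The whole stack runs on a compact reverse-mode autodiff engine
(`curvgt.nn`): float64 numpy arrays, the exact op set the models need
(broadcasting arithmetic, 2-D matmul, relu/exp/log/pow, reductions,
gather-with-scatter-add, concatenation, layer norm, masked softmax), with
gradients verified against central finite differences in the test suite.

## Synthetic data

The generator emulates small attributed molecular-like graphs with community
structure: two planted-partition communities (sizes uniform in 5..10 each),
intra-community edge probability 0.6, inter 0.1 — a contrast strong enough
that bridges carry negative curvature, as in the two-clique toys — one-hot
categorical edge features (4 categories, standing in for bond types), a
constant node feature, and a graph-level regression target equal to the mean
edge curvature plus Gaussian noise with sd 0.05 (roughly a tenth of the
target's spread across graphs). Graphs are resampled until connected;
datasets are byte-identically reproducible from the seed.

What this emulates and what it does not: real molecular datasets have
informative node features, valence constraints, and target functionals not
expressible as a curvature statistic. Passing tests here show that the
pipeline is correct and that the curvature bias is learnable signal for a
curvature-derived target; they do not show benchmark-level accuracy gains on
real chemistry.

## Karate feature study

Binary faction classification on the 34-node Zachary karate club with a
2-layer GCN (`softmax(Â relu(Â X W₁) W₂)`, `Â` the symmetric-normalized
adjacency with self-loops), comparing node features: uniform(0,1) 34×16
random matrices, rows of the hop-count SPD matrix, rows of the all-pairs κ*
matrix (diagonal 0). Protocol (the source experiment prints none of these
details, so they are fixed here as the standard semi-supervised GCN demo
convention and surfaced as config): the two faction leaders (nodes 0 and 33)
are the only labeled nodes, hidden width 16, Adam lr 0.01, weight decay
5e−4, dropout 0, 200 epochs, accuracy over all 34 nodes, best of 10 seeded
runs.

Measured outcome: structure-bearing features (SPD, curvature) reach 97.1%
best-of-10 (33/34 nodes). Random features *also* reach ~97% under this
protocol — with only two labeled nodes, transductive propagation through `Â`
is decisive on a graph this small and separable, regardless of feature
content, and exploratory variants (other splits, full supervision, dropout,
plain gradient descent, smaller budgets) behave the same way in every
converged setting. The originally reported ~78% for random features is
therefore not recoverable from any converged standard protocol; the package
reports what the fixed protocol actually produces and keeps the qualitative
ordering check (curvature ≥ SPD ≥ random) which holds with equality.

## Known limitations

* All-pairs curvature is quadratic in node count with an LP per pair;
  beyond a few hundred nodes use `path-mean` or edges-only.
* The autodiff engine is single-threaded and keeps whole graphs of
  intermediate arrays; it is sized for desk-scale experiments, not
  benchmark-scale training.
* Γ's exact permutation-equivariance is limited by shortest-path tie-breaking
  (see above).
* The advisory learnability property (curvature-biased model beating its
  curvature-ablated twin on the synthetic task in most seeded runs) is a
  directional expectation, not an asserted invariant; the ablation hooks
  (zeroing the Φ encoder parameters reduces the model exactly to the
  degree+edge baseline) are tested instead.
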