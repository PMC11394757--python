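# Methods

## Model

The predictor treats binding-site detection as per-point binary
classification on the protein surface, followed by density clustering
of the positive points into ranked pockets.

**Surface.** The solvent-accessible surface is sampled by placing a
deterministic Fibonacci lattice on each atom's inflated sphere
(van der Waals radius + probe) and rejecting points strictly inside any
other atom's inflated sphere. Points exactly on a shared boundary
(coincident or tangent spheres) are assigned to the lower-index atom so
degenerate inputs do not duplicate surface area. Normals point away
from the owning atom. The sampler is deliberately simple: downstream
stages need only an oriented point cloud with roughly uniform density,
not a watertight mesh. Default probe 1.5 Å (water), default density
1.0 point/Å²; van der Waals radii from a fixed internal table
(C 1.70, H 1.20, O 1.52, N 1.55, S 1.80, Se 1.90, fallback 1.70 Å).

**Chemical features.** For each surface point, its 16 nearest atoms
within the [C, H, O, N, S, Se] alphabet contribute an embedding of
[one-hot(6) ⊕ 1/distance] through a 7→6→6 MLP (ReLU, batch
normalization on the hidden layer); contributions are summed and mapped
6→6. The network is trained end-to-end with the GNN — gradients flow
back into it through the vertex states. Inverse distances are clamped
at 1/10⁻³ to bound the input range; in practice surface points sit
≥ 2.7 Å from atom centers.

**Geometric features.** Mean (H) and Gaussian (K) curvature at five
scales, default σ ∈ {1, 2, 3.5, 6, 10} Å. At each point and scale, the
neighbors within σ are expressed in the tangent frame of the point's
normal and a full quadric h(u,v) = a u² + b uv + c v² + d u + e v + f
is least-squares fitted; H and K follow from the fundamental forms
(including the first-order terms, which absorb normal noise). The sign
convention makes convex regions positive: on an R = 10 Å sphere the
estimator recovers H within ~2% and K within ~4% of 1/R and 1/R².
Scales with fewer than 6 neighbors yield zeros (the quadric would be
underdetermined); this is logged, not an error.

**Labels.** A point is positive iff it lies within 4 Å of any ligand
site center (inclusive boundary, matching the DCC success rule). A
per-ligand-atom distance alternative is available behind a flag.

**Graph.** Voxel downsampling keeps, per occupied origin-anchored cube
(default edge 1.0 Å), the real surface point nearest the voxel centroid
— predictions must live on the actual surface for center–center
distances to be meaningful. Centroid distances are rounded to 1e-9 Å
before the argmin so exact geometric ties (any two-point voxel) break
to the lowest index reproducibly. Vertex labels are the representative
point's own label ("any positive in voxel" is a config flag). Initial
states: all dense points within r₀ = 2 Å of a vertex (always including
itself) are embedded by a two-layer MLP on [16-dim features ⊕ relative
coordinates] and reduced with an elementwise Max. The first-layer
weight is stored as a 16-row feature block and a 3-row coordinate
block — numerically identical to concatenating first (input 19), but
the feature block is applied once per point rather than once per pair.
Coverage note: every dense point is guaranteed to reach some vertex
when voxel ≤ r₀/√3 (diagonal bound for point representatives); the
defaults (1.0 vs 2.0 Å) satisfy this.

Edges connect vertices strictly closer than r = 4 Å, truncated to the
32 nearest per source vertex (distance ties by lower index), stored as
a directed list sorted by (i, j). Translation invariance of the graph
stage is exact for shifts that are integer multiples of the voxel size;
the network itself (below) is translation-invariant for any shift of a
fixed graph.

**GNN.** Three unshared layers. Each computes a per-vertex
auto-registration offset Δx = MLP_ω(h) (300→64→3), edge features
MLP_f([x_j − x_i + Δx_i ⊕ h_j]) (303→300→300, with the same
block-matrix trick), an elementwise Max over each vertex's out-edges,
and a residual update h' = MLP_g(Max) + h (300→300→300). Vertices with
no in-range neighbor keep their state (the Max over an empty set is
defined as "skip the update"). A 4-layer head 300→128→64→1 with
logistic output scores each vertex. The neighbor state h_j (not h_i)
enters the edge MLP; offsets are not clipped.

**Initialization.** Kaiming throughout, with two deliberate
exceptions: the output layer of each MLP_g is scaled by 0.1 and the
classifier's output layer by 0.01. Max-aggregation selects upper-tail
activations, so an unscaled residual stack roughly doubles state
magnitude per layer and saturates the head at initialization; the
near-identity start keeps the initial loss at chance level for balanced
labels and lets early training move probabilities smoothly.

**Training.** Weighted BCE on per-vertex labels; the positive-class
weight defaults to the train-split negative/positive ratio (~15–20 on
the synthetic data). Adam, lr 5·10⁻⁴, weight decay 10⁻⁵ applied to
gradients, batches of 4 structures. A batch is processed graph by graph
with gradient accumulation weighted by vertex count — mathematically
identical to a disjoint-union batch (the loss is a weighted mean and no
edges cross graphs) at single-graph peak memory. Early stopping on
validation loss with patience 10 inside a 50-epoch cap; the
best-validation checkpoint is returned. All randomness (init, batch
order, splits, generator) flows from explicit integer seeds; two runs
with the same seed produce identical loss curves and weights on CPU.

**Inference.** Vertices with probability strictly above 0.5 are
clustered with OPTICS (min_samples 5, max_eps 6 Å). Cluster extraction
defaults to the DBSCAN-style reachability cut at max_eps rather than
xi-extraction: the xi method produces spurious splits when points are
exactly duplicated (zero reachabilities), violating the requirement
that duplicating a blob point-for-point must double its score and
nothing else; xi remains available via config. Pocket score = sum of
member probabilities; center = unweighted member mean
(probability-weighted center is a flag); ranks by score descending.

**Evaluation.** DCC is the Euclidean distance between a predicted
pocket center and the true site center; success iff ≤ 4 Å (inclusive).
Sites and top-n pockets are paired greedily by best available DCC, each
pocket used at most once; unpaired sites are missing. TP/FP are matched
pockets at ≤/> 4 Å; FN are missing sites. DVO voxelizes both the
predicted pocket's member points and the site's positively-labeled
surface points on an origin-anchored 2 Å grid and takes the Jaccard
ratio; it is undefined (excluded from the mean) when either set is
empty.

## Numerical choices

Geometry (surfaces, curvature, graphs, metrics) runs in float64; the
network in float32 on BLAS sgemm. The autodiff core implements exactly
the required ops (affine with fused bias/ReLU, gather/scatter rows,
sorted segment sum/max, batchnorm, weighted BCE from logits) with a
topological-order backward that frees intermediate gradients as soon as
they are consumed. Segment-max ties share the gradient equally (a valid
subgradient; relevant only for exactly duplicated inputs). Gradients
were verified against central finite differences for every op.

## Synthetic data: what it emulates and what it does not

Each structure is a jittered 1.8 Å grid of pseudo-atoms inside a ball
(radius 5.5–7.0 Å ⇒ 100–400 atoms) with realistic heavy-atom element
frequencies (C 62%, N 16%, O 20%, S 2%). Each pocket removes the atoms
inside a spherical cap (half-angle 0.55 rad) centered on the ball
boundary and biases the cavity lining (a 2.5 Å shell) to oxygen with
probability 0.85; the pseudo-ligand is a single atom 1 Å inside the cap
mouth, so the site center is exact and DCC ground truth unambiguous.
Structures sharing a radius archetype share a split-group key, so the
8:1:1 splits are leakage-free by construction. The generator plants
exactly the two signals the model is designed to exploit — concavity
and a chemical microenvironment — which makes passing tests evidence
that the pipeline can learn and localize such signals, not evidence
about real proteins: there are no side chains, no partial burial of
ligands, no multi-scale surface texture, no crystallographic noise, and
pocket sizes are narrower than the natural range.

## Benchmark problem sizes

The study run by the test suite and `scripts/acceptance.py` uses 60
structures, surface density 0.6 point/Å² and 2.0 Å voxels
(≈ 150–350 vertices and ≈ 2–5k edges per graph), training ≤ 30 epochs —
sizes chosen so the full study (data generation, training, evaluation,
ablation) completes in minutes on a single CPU while keeping the
architecture at its full dimensions (300-dim states, 3 layers). The
package-level defaults stay at 1.0 point/Å² and 1.0 Å voxels. The
downsampling ablation trains one model per input configuration (all
points / downsampling with aggregation / downsampling without
aggregation) on a 24-structure subset for 8 epochs each: the three
configurations present different input distributions (vertex density,
degree, aggregation statistics), so evaluating a single model across
them measures distribution shift rather than the value of downsampling.

## Known limitations

- The solvent-accessible point sampler is not a solvent-excluded mesh;
  deep narrow channels that a rolling probe would close off are
  represented only as far as inflated-sphere geometry allows.
- Rotation invariance is not claimed: relative coordinates are
  rotation-covariant, and the per-atom sampling lattice is lab-frame,
  so predictions can vary slightly under rotation (features of a fixed
  point set are exactly invariant; the resampled point set differs).
- Greedy DCC matching is not globally optimal for >2 sites (optimal
  assignment can differ); the rule is fixed and documented, and
  pocket-level comparisons use the same rule on all methods.
- OPTICS parameters assume pockets ≥ ~10 Å apart; adjacent shallow
  sub-pockets may merge under the 6 Å reachability cut.
- The xi extraction alternative, probability-weighted centers, and
  ligand-atom-distance labels are exposed but not exercised by the
  benchmark.
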