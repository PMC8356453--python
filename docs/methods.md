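# Methods

## The model

A drug–target instance is a (drug, protein, expression-signature) triple
described by 1412 features in fixed block order: 300 drug, 300 protein, 512
binding-site and 300 network-environment coordinates. The classifier is a
feedforward network

L_n = σ_n(W_n · L_{n−1} + b_n),

with two hidden layers of 128 rectified linear units and a 2-neuron softmax
output returning the probability pair (P, N) of a positive and negative
interaction. Training is mini-batch stochastic gradient descent on the
cross-entropy loss with L2 weight decay. Defaults: learning rate 1e-4,
batch size 32, weight decay 1e-5, 30 epochs, He-uniform initialization
seeded from the configuration, seeded epoch shuffling. A repeated seed
reproduces the weights bit for bit; models serialize to JSON and round-trip
exactly.

Two training conventions are the package's own choices (the architecture and
hyperparameters above leave them open):

- **Gradient reduction.** The mini-batch gradient sums the per-sample
  cross-entropy terms rather than averaging them — the classical SGD
  convention. At the scale this package targets (thousands of instances,
  so ~1.7k optimizer steps in 30 epochs) an averaged gradient at learning
  rate 1e-4 moves the logits by a few hundredths and the model never leaves
  its initialization; the summed convention keeps the default rate
  effective. The reported loss curve remains the mean per-sample loss.
- **Input scaling.** No standardization by default; an optional per-column
  z-score (fit on the training split) exists for embedding-derived inputs,
  whose ~0.06-scale entries would otherwise stall the optimizer.

The input layer is sized to the data everywhere; the 400-input configuration
is the post-feature-selection operating point (top-400 ranked features of
1412).

## Network environments and their embedding

The PPI graph is undirected; an edge with STRING-style confidence c ∈
[150, 999] has weight 1/c, so confident interactions are short. The local
environment of a target is its N nearest nodes by Dijkstra distance, ranked
ascending, ties broken by (distance, identifier) so results never depend on
hash order. Targets with fewer than N reachable nodes are padded with
sentinel entries (infinite distance, no expression, a dedicated PAD token);
a strict mode rejects them instead. Missing expression values are treated as
0 (no differential change) with the missingness flag retained.

Environments are tokenized by Weisfeiler–Lehman relabeling (default depth 2):
iteration-0 labels concatenate the node's expression bin — five moderated-Z
bins with edges at ±0.5 and ±2 — with a fixed-width distance-rank bucket
(ranks 1–5 → bucket 1, 6–10 → 2, …, capped at 10). Buckets are absolute
rather than N-relative so the same neighbor at the same rank produces the
same token in environments of different sizes; with N-relative deciles,
embeddings of different-sized environments are incomparable and the expected
growth of between-target separation with N disappears. Deeper labels hash
(own label, sorted neighbor labels). The document — the token multiset over
all iterations — is embedded by signed feature hashing into 300 dimensions
and L2-normalized; identical environments give identical vectors with no
training corpus. A corpus-trained alternative (randomized-SVD document
embedder over hashed token counts, seeded) is provided for fidelity to
learned document embeddings but is not required anywhere.

## Similarity primitives and dataset rules

Tanimoto similarity is |A∩B|/|A∪B| over fingerprint on-bit sets (undefined
for two empty sets). Global identity uses Needleman–Wunsch with match +2,
mismatch −1, linear gap −2; the identity denominator includes gap columns,
and traceback ties resolve diagonal > up > left so the reported identity is
deterministic even among co-optimal alignments. The scoring scheme is a
package default — what matters downstream is thresholding at 40% — and the
implementation is checked against exhaustive alignment enumeration and an
independent aligner's scores.

Negative candidates are (drug, protein) combinations for which no single
positive pair triggers both cuts (TC ≥ 0.4 to its drug AND identity ≥ 40% to
its protein); an entity-wise strict mode is available for sensitivity
analysis. Expression augmentation assigns a profile-less drug its
maximum-TC donor at TC ≥ 0.85 (ties by identifier), taking the donor's
highest-concentration signature; both positive and negative pairs pass
through the identical path. Bioassay outcomes map active → 1, inactive → 0,
anything else dropped. Class balance is restored by seeded down-sampling of
the majority class.

## Cross-validation protocols

Random split: unique pairs are dealt round-robin from a seeded permutation
into K folds (sizes differ by at most 1). Cluster-based split: pairs are
clustered by k-medoids on one of three distances — FMD (Euclidean over the
600 concatenated drug+protein features), PMD = sqrt((1−TC)² + (1−TM)²) with
range [0, √2], or scaled PMD = PMD/(√2 − PMD), which stretches the scale
near the identical-pair end. PMD values within 1e-8 of √2 are rejected as at
the pole. The k-medoids variant is the alternating (Voronoi) iteration with
seeded random medoid initialization, max 300 iterations; the within-cluster
objective is asserted nonincreasing at every step. Clustering quality is the
mean silhouette coefficient over 50 seeded repetitions (standard error
sd/√reps; singleton clusters contribute 0), and the cluster count is chosen
by the silhouette sweep's argmax. Clusters are then shuffled with the seed
and merged largest-first into the currently smallest fold, so folds stay
comparable in size and no cluster is ever split. In every protocol all
instances (signatures) of a pair inherit the pair's fold, so expression
replicates never straddle folds. TM-score similarity is consumed as a
pre-symmetrized matrix in [0, 1]; computing it from structures is out of
scope.

## Feature selection

Permutation importance of feature j is the drop in accuracy on a held-out
evaluation matrix after shuffling column j only: I_j = S_ori − S_perm,j,
averaged over 5 seeded repeats by default (a single permutation is
high-variance). Importance is computed as the mean of per-repeat drops so a
no-op shuffle (constant column) scores exactly 0. A batched implementation
exploits the layered network — shuffling one input column is a rank-one
update of the first hidden pre-activation — and is tested to reproduce the
naive per-column computation exactly. Features are ranked descending (ties
by index), and the feature-count sweep retrains a fresh model per size,
reporting AUC and the per-block composition of the retained set.

## Evaluation

ROC curves sweep thresholds over the positive-class softmax probability;
AUC is the trapezoidal area and is tested to equal the Mann–Whitney
pair-counting statistic including the half-credit tie term. Cross-validation
trains per fold from a fresh seeded initialization; a fold whose evaluation
half lacks a class is excluded from the summary (flagged, warned) rather
than scored 0.5.

## Synthetic data: what it emulates and what it does not

All generators are bit-reproducible from a seed.

- **Networks**: Erdős–Rényi graphs with uniform integer confidences in
  [150, 999], made connected by spanning-tree augmentation. Real PPI
  networks are scale-free; where hub structure matters (the
  separability-vs-N study) a Barabási–Albert topology with
  confidence-weighted hubs is used instead.
- **Expression**: per-signature values ~ Normal(0, 1) per protein
  (MODZ-like), optional mean shifts on designated perturbed proteins,
  several concentrations per drug with a unique maximum.
- **Entities**: fingerprint families sharing core bit sets (within-family
  TC = core/(core+2·extra) ≥ 0.85 by the bit budget, cross-family cores
  disjoint so TC ≤ 0.4) and sequence families as point mutants of a family
  base (within-family identity ≥ 40% by construction); constraints are
  asserted on the generated entities.
- **Planted-signal instances** (the "signal" preset): 2000 instances of
  width 1412. The 20 informative columns are independent normals of sd 3;
  coefficients have random signs and magnitudes uniform in [0.5, 1.5]
  (bounded away from zero so every planted feature is genuinely
  informative), scaled so the latent logit has sd 8; labels are Bernoulli
  through the logistic link. The remaining columns are correlated low-rank
  noise (100 shared factors plus iid jitter of relative sd 0.2, columns
  scaled to sd 0.3) — embedding-derived features are strongly correlated,
  and an isotropic iid design at d ≈ n is both unrealistic and statistically
  unlearnable: no linear rule exceeds ~0.85 AUC there at any effect size. At
  these conditions an independent L2-logistic fit reaches ~0.97 held-out
  AUC and the default classifier 0.96–0.97.
- **Leakage families** (the "leakage" preset): 250 families of 8
  near-duplicate pairs (4 drugs × 2 proteins), features = family vector +
  perturbation of sd 0.05, one family-level label draw at cross-family
  effect sd 1.5, high within-family TC/TM and low noisy cross-family
  similarities. Random 10-fold splits scatter every family across folds;
  scaled-PMD k-medoids folds keep them together.

What passing these tests shows: the pipeline's algorithms are correct, the
optimizer works at its stated scale, importance recovers genuinely used
features, and the leakage mechanism behaves as the theory predicts. What it
does not show: performance on real chemistry or biology — synthetic
molecules have no chemical meaning, expression has no co-regulation
structure, and the planted signal geometry is chosen to be learnable.

## Numerical choices and degenerate inputs

Distance ties in environments break lexicographically; duplicate network
edges keep the maximum confidence; self-loops are dropped. Both-empty
fingerprints raise rather than return 0. Silhouette requires ≥ 2 clusters.
Down-sampling requires both classes. scaled-PMD rejects inputs within 1e-8
of √2. Model serialization stores floats via repr round-trip, so reloaded
models predict identically.

## Reference experiment sizes

The acceptance checks use: 100 random graphs (≤ 8 nodes) for the Dijkstra
oracle, 25 instances (≤ 50 points) for silhouette, 500 trials (≤ 100 scores)
for AUC, 200 random pairs (lengths ≤ 6) for alignment, a 12 × 10 universe
for the negative rule, 100 seeded k-medoids runs, 10 seeds for the
importance-recovery and leakage studies (n = 2000 instances each, full
30-epoch training throughout), and 50 seeds for the noise-importance check
on a small 6-feature problem.

## Known limitations

The hashed graph embedder emulates the document construction of learned
graph embeddings but not their corpus-level contrast; its between-target
separation grows with N only on hub-dominated networks. The Needleman–Wunsch
scoring scheme is fixed rather than substitution-matrix based. k-medoids
uses the alternating heuristic, not PAM's swap search, so it can stop at a
local optimum — mitigated by the repeated-seeds protocol. The MLP runs on
one CPU in numpy; it is not meant for corpus-scale training.
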