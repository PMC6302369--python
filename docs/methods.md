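# Methods

## Model

Given n entities with a high-dimensional joint distribution P (p_ij ≥ 0,
p_ii = 0, symmetric, Σ_{i≠j} p_ij = 1), the model places every entity in M
two-dimensional maps. Point i has coordinates y_i^(m) in map m and an
importance weight π_i^(m), parametrized through unconstrained ω by a
negative-exponent softmax π_i^(m) = e^(−ω_i^(m)) / Σ_m′ e^(−ω_i^(m′)), so
weights are positive and sum to 1 per point. The model similarity is

q_ij = Σ_m π_i^(m) π_j^(m) (1 + d_ij^(m))⁻¹ / Z,  d_ij^(m) = ‖y_i^(m) − y_j^(m)‖²,

with Z normalizing over all ordered pairs and maps. The heavy-tailed
Student-t kernel is the usual t-SNE remedy for the crowding problem; the
weight mixture lets q_ij vanish for pairs that never co-occupy a map, which
is what makes intransitive similarity representable. With M = 1 the weights
are identically 1 and q reduces exactly to single-map t-SNE.

The fitted objective is

C = (1 − λ) Σ_{i≠j} p_ij log(p_ij / q_ij) + λ Σ_m π_(·,m)ᵀ L π_(·,m),

with L = diag(P·1) − P the Laplacian of the affinity graph and λ ∈ [0, 1).
The quadratic form is summed over map columns; this is the only collapse of
the n × M weight array that is invariant under permutation of map indices
and realizes the penalty's purpose (similar points should carry similar
weights on the same map). The graph underlying L is P itself, not the raw
thresholded similarity matrix — the penalty then lives on the same object
the KL term matches.

## Gradients

The KL part of the gradient with respect to positions is

∂C/∂y_i^(m) = 4(1 − λ) Σ_j (p_ij − q_ij)/(q_ij Z) · π_i^(m) π_j^(m) (1 + d_ij^(m))⁻² (y_i^(m) − y_j^(m)),

and with respect to the weights, before the softmax chain rule,

∂C/∂π_i^(m) = −2(1 − λ) Σ_j (p_ij − q_ij)/(q_ij Z) · π_j^(m) (1 + d_ij^(m))⁻¹ + 2λ (L π_(·,m))_i ,

which is then pushed through the softmax Jacobian
∂π^(m)/∂ω^(l) = π^(m) π^(l) − δ_ml π^(m) (the negative exponent flips the
usual sign). Both expressions are derived by differentiating the objective
through the q mixture; their correctness is enforced by central
finite-difference tests (relative error < 1e−4 across seeded instances with
n ≤ 8, M ≤ 3, λ ∈ {0, 0.05}) rather than trusted as written, since published
typography for these gradients is inconsistent about signs and constants.

## Affinities

Feature vectors: Gaussian kernel on squared Euclidean distances, either one
global bandwidth σ (kernel normalized jointly over all ordered pairs) or a
per-point bandwidth found by bisection so every conditional distribution has
the requested perplexity (tolerance 1e−6 bits, well inside the tested 1e−4),
then symmetrized as p_ij = (p_{j|i} + p_{i|j})/(2n). Squared distances are
the universal t-SNE convention and are used here even though similarity
formulas are sometimes printed with unsquared norms.

Precomputed similarity matrices in [0, 1]: entries strictly below the
threshold (default 0.5) are zeroed, the diagonal is dropped, and the rest is
normalized to sum to 1. The threshold-then-normalize scheme is the simplest
faithful conversion; entities fully disconnected by the filter are reported
in metadata rather than silently carried along. q values are floored at
1e−12 only inside logarithms and gradient denominators — underflow is real
here because weight products can reach e^(−80) — and never stored.

## Optimization

Positions and weights are updated jointly as one parameter vector. Three
update rules share one schedule:

* momentum: v ← γv − η∇C(θ); θ ← θ + v
* Nesterov: v ← γv − η∇C(θ + γv); θ ← θ + v
* Nesterov, equivalent form: v̂ ← γv̂ − η g − ηγ(g − g_prev) with g the
  gradient at the current (hat) parameters; related to the look-ahead form
  by θ̂ = θ + γv, verified numerically to 1e−8 over 50 iterations.

Schedule defaults: η = 100, γ ramped 0.5 → 0.8 at iteration 250, 1000
iterations, early exaggeration ×4 for the first 100 iterations (cost traces
are always recorded against the unexaggerated P so runs are comparable).
These are standard t-SNE conventions; no per-parameter adaptive gains are
used, so that an optimizer comparison isolates the update rule itself.
Initialization: Y ~ Normal(0, 1e−4) (standard deviation 1e−2), ω = 0
(uniform maps), all under one seed; fits are bit-reproducible given seed,
rule, and config.

## Evaluation

NPR(P, Q, k) is the mean over points of the fraction of the k largest
p_ij-neighbors that are also among the k largest q_ij-neighbors; ties are
broken by ascending index so the statistic is deterministic after
thresholding creates duplicated values. Default k = 10 and configurable,
since no canonical k exists for this statistic. The error rate is KL(P‖Q)
in natural-log units (0·log 0 = 0). Optimizer comparisons report final NPR,
final error rate, and the first iteration whose cost is within 1% of the
final cost.

## Synthetic data

The overlapping-cluster generator emulates the non-metric structure of
phenotype/KO similarity matrices: points sharing a cluster get similarity
within_similarity + Gaussian noise (clipped to [0, 1]), all other pairs get
exactly 0, and a fraction of points are bridges belonging to exactly two
clusters, distributed round-robin so every cluster keeps pure members. The
defaults (within-similarity 0.8, noise 0.05, overlap 0.25) keep the signal
above the 0.5 filtering threshold. The benchmark dataset used in the test
suite is 4 clusters × 15 points (n = 60, matching M = 4 maps), a size chosen
so a full optimizer comparison runs in seconds on one CPU. What the
generator does *not* emulate: graded between-cluster similarity, text-mining
noise that correlates across pairs, and ≥3-way overlaps; passing tests
therefore show correctness of the machinery on idealized block structure,
not performance on real phenotype networks. The fixed three-point/two-map
configuration uses ω offsets of ∓40, saturating the softmax so the
zero-weight entries are ≤ e^(−80) and the mixed similarity of the disjoint
pair is zero to well below 1e−12.

## Known limitations and an honest negative result

On smooth quadratics the Nesterov rule converges in strictly fewer
iterations than heavy-ball momentum (45 vs 83 to |x| < 1e−3 at η = 0.1,
γ = 0.9), as theory predicts. On the n = 60 overlapping-cluster benchmark
(M = 4, λ = 0.005, 500 iterations, medians over 5 seeds) the advantage does
not reproduce: Nesterov reaches the 1%-of-final band slightly sooner (132 vs
138 iterations) but its median final KL is about 7% higher (0.438 vs 0.409).
The mechanism is visible in the traces: near the optimum the weights
saturate, pairs with p_ij > 0 can have q_ij underflow, and the resulting
gradient spikes interact with the look-ahead evaluation so Nesterov retains
more velocity and settles less deeply at this fixed η = 100, while momentum
damps into the basin. The corresponding acceptance check is left failing
rather than re-tuned, because the comparison is only meaningful under a
schedule fixed in advance and shared by both rules.

Other limitations: dense O(n²M) computation per iteration (no Barnes–Hut or
interpolation acceleration), output dimensionality fixed at 2, no adaptive
restarts or Adam-family optimizers, and no wall-clock benchmarking (timings
are hardware-dependent).
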