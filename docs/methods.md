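# Methods

## The explanation model

`pepxai` produces a global, post-hoc explanation of a time-series classifier
`f`. The classifier is treated as opaque: the pipeline only ever calls
`f.predict(series) -> label` (or reads a file of its predictions). The
explanation is a pruned CART decision tree `g` fit over an event-count
feature space, together with the tree's paths rendered as rules through
cluster centroids, and a four-part quantitative evaluation.

The approach assumes that the classifier's behavior is largely mediated by
shape events — monotone stretches and local extrema — whose position,
duration, gradient and amplitude carry the class signal. When that holds,
the count features preserve the relevant temporal structure and the
surrogate can reach high fidelity; when the classifier keys on properties
outside this vocabulary (long-range phase, frequency content), fidelity will
be low, and the fidelity metric is precisely the diagnostic for that.

### Event extraction

For a series x₀..x_{n−1} (time steps are 0-based):

* An **increasing run** is a maximal stretch of strictly positive first
  differences dᵢ = xᵢ₊₁ − xᵢ, summarized as (t_start, dura, grad_avg):
  the index of the first positive difference, the number of differences in
  the run, and their mean. Decreasing runs mirror this over strictly
  negative differences. A zero difference belongs to no run and terminates
  any run in progress — "ties break runs". The rendered time span of a run
  is [t_start, t_start + dura].
* A **local maximum** is an interior index with both neighbors strictly
  below; minima mirror it. A plateau of equal values strictly above (below)
  both flanking values yields one event anchored at the plateau's first
  index. Series endpoints never yield extrema, so event times always lie in
  1..n−2.

The gradient estimator is the plain first difference — the minimal choice
that makes the run-tuple semantics exact; there is no smoothing, no minimum
amplitude, and no standardization of the input series, so event parameters
stay in raw signal units and rules read in the units the user measured.
`min_dura` (default 1 step) and `min_abs_grad` (default 0.0) are available
for noisy data but default to fully permissive.

### Event clustering

Each family is pooled over all instances and clustered with k-means
(Lloyd's algorithm, `n_restarts = 10` seeded restarts, best inertia kept)
for each k in `[k_min, k_max]` (default 2..10, additionally capped at
n_points − 1 and at the number of distinct points). The chosen k maximizes
the mean silhouette score; ties go to the smallest k (parsimony — a simpler
cluster vocabulary gives shorter rules). Parameters are standardized per
dimension before clustering (mean/std; a zero-variance dimension keeps
factor 1): start times span tens-to-hundreds of steps while gradients are
order one, and unscaled Euclidean k-means would cluster on time alone.
Centroids are stored back-transformed to original units.

Degenerate pools: an empty pool yields a k = 0 model (family absent — it
contributes no feature columns, with a logged warning); a pool with fewer
than k_min + 1 points or all-identical points falls back to k = 1 with the
pool mean as centroid and an empty silhouette trace. Singleton clusters
score 0 in the silhouette, per the standard convention.

### Attribution

Cluster membership for any event — including events of perturbed series
never seen at fit time — is nearest centroid in the standardized space,
ties to the smallest cluster index. This is the k-means-consistent extension
of the fitted partition and is what makes the robustness metric well
defined. The feature value is the **count** of an instance's events per
cluster, not a presence bit: two same-cluster events must read 2, and the
test suite pins a fixture where binarization demonstrably loses the
distinction. Per-family tables are concatenated in the fixed order
increasing, decreasing, local_max, local_min, with columns named
`{kind}_c{j}`.

### Surrogate tree

The count table is split 70/30, stratified on the black box's predicted
label (falling back to an unstratified shuffle, with a warning, when a
predicted class has a single instance). The CART tree (Gini impurity) is fit
to the predicted labels on the training part; ground truth enters only the
accuracy metric. With `ccp_alpha="auto"` the minimal cost-complexity pruning
path is computed and α selected by 5-fold cross-validated agreement with
the black box on the training part; ties within 1e-12 go to the **largest**
α, because among equally faithful trees the shallowest is the better
explanation. Split semantics are `≤` left / `>` right; counts are integers,
so learned thresholds land on half-integers (2.5, 0.5), which are rendered
verbatim.

Rules are root-to-leaf paths enumerated depth-first (left first), with
repeated conditions on one feature kept in path order, never merged. The
narrative renderer phrases each condition through its cluster centroid
(`increases from time {t} to {t+dura} with average value {v̄} ≤ {θ}`; an
optional `article` flag inserts "an" before "average value"), the technical
renderer through the column name (`count(increasing_c0) ≤ 0.5`).

### Evaluation

* accuracy A = c/N and fidelity F = a/N on the held-out 30% of the table;
* complexity = (tree depth, total node count);
* robustness: for each instance, δ is i.i.d. Gaussian per time step with
  sd = ε·std(x) (default ε = 0.05; ε = 0 degenerates to the zero
  perturbation), rejection-sampled up to `max_retries = 20` times until
  f(x+δ) = f(x). g(x+δ) is then computed by the full frozen transform —
  extraction, nearest-centroid attribution, tree descent — and compared to
  g(x). Instances with no admissible δ are excluded from N and reported in
  `n_robustness_skipped`, never silently dropped. Per-instance RNG streams
  are keyed by (seed, crc32(instance id)), which makes the estimate
  invariant to row order and reproducible per instance.

When the prediction source is a file rather than a live model, the pipeline
extends the file to a live predictor via a nearest-row label oracle over the
dataset (exact on unperturbed rows), so robustness remains computable; with
no ground-truth labels on file, accuracy degenerates to fidelity, with a
logged warning in both cases.

## Synthetic data

The generator emulates short univariate 2-class benchmarks (ECG-like:
length 96 by default, mirroring the common heartbeat-trace regime; hundreds
to thousands of instances): per instance, a baseline (flat, or a random walk
with step sd 0.05) plus the class's motifs plus i.i.d. Gaussian noise.
Motifs are Gaussian bumps/troughs (σ = width/4, peak = amplitude) and linear
ramps (rise by amplitude over the width, then hold), optionally jittered in
time; the ground-truth record stores each realized (post-jitter) center and
amplitude. Stub black boxes (peak-over-window threshold, window mean
threshold, label oracle) are rule-consistent with the event vocabulary, so a
perfect-fidelity surrogate exists by construction and test failures localize
to pipeline defects rather than model opacity.

What the generator does **not** emulate: autocorrelated or heteroscedastic
noise, baseline wander, variable-length or multivariate series, class
overlap in motif space, and label noise. Passing the recovery tests
therefore shows the pipeline is correct and stable under its own
assumptions, not that real classifiers on real data will be explained with
fidelity 1 — on real data fidelity is an empirical outcome the metrics
module measures.

## Study conditions and problem sizes

The recovery study used throughout the tests and by
`scripts/acceptance.py`: n = 200 instances of length 96, balanced classes,
class 1 carrying one Gaussian bump of amplitude 2.0 at t = 70 (width 6, no
jitter), noise sd 0.1, black box = peak threshold (window [60, 80],
τ = 1.0), robustness at ε = 0.01 over all 200 instances. The pruning
monotonicity check reuses the same conditions at noise sd 0.5; the
determinism check runs the full CLI pipeline twice at n = 80. Unit and
property tests use small hand-enumerable inputs, plus 1,000 random series of
length ≤ 30 for the extraction-oracle equivalence check.

## Numerical and design choices

* Tie-breaks are all deterministic and documented: zero differences end
  runs; silhouette ties → smallest k; nearest-centroid ties → smallest
  cluster index; α ties → largest α; `≤` goes left.
* One global seed fans out to stage seeds by fixed offsets (clustering:
  seed, surrogate: seed + 1, perturbation: seed + 2), so stages are
  individually reproducible and two runs with the same config produce
  byte-identical rules and reports.
* Labels are arbitrary hashables; internally the tree sees stable integer
  codes (sorted by string form) and predictions are decoded back.
* Dataset I/O is strict: ragged rows, non-numeric cells, missing values and
  multivariate input all fail fast with typed errors; nothing is imputed.
  CSV/TSV label and id columns are recognized via a header row.

## Known limitations

* Univariate, equal-length series only.
* The event vocabulary has four families; "flat" segments are not events
  (the kind enum is extensible).
* Silhouette computation is O(n²) in the pooled event count, which
  dominates fit time for datasets beyond a few thousand instances;
  sub-sampling the pool before the k-sweep would be the natural extension.
* Robustness depends on the perturbation family (additive Gaussian scaled
  to each series' sd); classifiers sensitive to other perturbation families
  are not probed.
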