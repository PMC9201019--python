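# Methods

## Scope and data model

`metabreduce` operates on wide metabolite concentration tables: rows are
metabolites (d ≈ 47), columns are individual GC-MS analyses, each
annotated with an origin (geographic source), a region (one independent
sample of that origin) and a replicate index. Regions nest inside
origins. Raw concentrations are non-negative, span roughly 10⁻⁴–10 in
instrument units, and contain exact zeros where a metabolite fell below
the detection floor. Raw GC-MS signal processing (peak detection,
identification, annotation) is out of scope; the package starts from the
quantified table.

## Preprocessing

Two rules, applied in order:

1. **Zero replacement.** Exact zeros become `zero_fill` (default 10⁻⁵,
   one order of magnitude below the 10⁻⁴ detection floor). Only exact
   zeros are touched: a measured value smaller than the fill is genuine
   data and passes through. Below-detection metabolites are retained
   rather than dropped because they may be biomarkers of an origin.
2. **Log transform** (default base 10), mapping the dynamic range
   [10⁻⁴, 10] to [−4, 1] and fills to −5. The base is configurable; base
   10 matches the order-of-magnitude character of the data. Distances on
   the log scale weight relative (fold) changes rather than being
   dominated by the few most abundant metabolites.

No autoscaling, Pareto scaling or batch correction is applied; replicate
aggregation is the package's subject, not normalisation.

## Geometric-median reduction (modified Weiszfeld)

A region's replicate block (d × n_rep, log scale) is reduced to the
weighted geometric median of its columns: y* minimising
C(y) = Σ η_i ‖y − x_i‖ with the *unsquared* Euclidean norm. Reduction
deliberately uses the unsquared norm (robust, 50 % breakdown) while the
later clustering stage uses the squared norm (tight assignments).

The classical Weiszfeld operator
T(y) = Σ η_i x_i/‖y−x_i‖ / Σ η_i/‖y−x_i‖ is a convex combination of the
data and is undefined at the data points themselves. The Vardi–Zhang
modified step is total:

* T̃(y): the same operator summed over non-coincident points only;
* R̃(y) = Σ_{x_i≠y} η_i (x_i−y)/‖x_i−y‖, the negative gradient of C away
  from the data; r(y) = ‖R̃(y)‖;
* η(y): the weight of the coincident data point if y sits on one, else 0;
* update y ← (1−ψ) T̃(y) + ψ y with ψ = min(1, η(y)/r(y)), convention
  0/0 = 0.

Off the data ψ = 0 and the step is exactly classical Weiszfeld. On a data
point x_k, ψ < 1 moves the iterate off a non-optimal vertex, and ψ = 1
(η_k ≥ r(x_k)) certifies the vertex as the optimum and fixes it.

Numerical choices:

* **Coincidence tolerance** 10⁻¹² (Euclidean): guards the division by
  ‖y − x_i‖; configurable.
* **Start** y⁰ = 0 by default (log-scale metabolite vectors essentially
  never equal the zero vector). A start that *does* coincide with a data
  point is handled by the modified step itself rather than perturbed off
  the data: with a stopping threshold ε = 10⁻⁵, a 10⁻⁶ perturbation off a
  non-optimal vertex produces first moves smaller than ε and a false
  convergence right next to that vertex, whereas the modified step leaves
  it in one stride. This was verified on the 1-D instance {0, 1, 10}
  started at 0, whose optimum is 1.
* **Stopping** when ‖y(t+1) − y(t)‖ < ε (Euclidean), default ε = 10⁻⁵,
  max 100 iterations — the same tolerances the clustering stage uses.
* **Degenerate sizes**: n = 1 returns the single column; for n = 2 every
  point of the segment is optimal and the iteration's limit is accepted
  (tests assert only the objective value there).
* The objective trace is recorded per iteration and is non-increasing —
  a monotonicity the alternating bound of the modified step guarantees
  and the test suite checks to 10⁻¹².

## Comparator reducers

The spectral comparators view the d metabolites as points in replicate
space R^{n_rep} and embed them in one dimension, which also yields a
length-d representative (the block shape d × n_rep → d × 1 admits only
this orientation for point-embedding methods; the geometric median
instead aggregates the n_rep replicate vectors in R^d):

* **PCA**: column-center the d × n_rep point matrix, return first-PC
  scores.
* **CMDS**: double-center the squared-distance matrix,
  B = −½ J D² J, return √λ₁ · (top eigenvector). For Euclidean distances
  this equals the centered PC scores up to sign, which the tests assert
  to 10⁻⁸.
* **Laplacian eigenmaps**: union-symmetrised kNN graph (default k = 5,
  suited to ~47 points; binary weights by default, heat kernel
  exp(−d²/2σ²) optional), generalised eigenproblem L f = λ D f, the
  eigenvector of the smallest non-zero eigenvalue. Disconnected graphs
  raise an error advising a larger k.
* **LLE**: per-point reconstruction weights from the local Gram system,
  regularised by 10⁻³ · trace (applied unconditionally — the standard
  practice — rather than only on singularity; the perturbation is O(10⁻³)
  and keeps the row-sum-1 constraint), then the second-smallest
  eigenvector of (I−W)ᵀ(I−W).
* **median/mean**: per-metabolite across replicates.

Eigenvector sign is fixed by non-negative correlation with the
metabolite-wise mean across replicates (falling back to a
first-nonzero-positive rule in the zero-correlation corner), making every
reducer deterministic. A block of identical columns short-circuits to
that common column with a warning. Embedding coordinates live on the
component scale, not the original log-concentration scale; they preserve
geometry for clustering, not units — one reason the geometric median,
which stays on the data scale, is the package's default.

## Fuzzy c-means

J_m(U, V) = Σ_k Σ_i u_ik^m ‖z_k − v_i‖² is minimised by Picard
(alternating) iteration of the stationary updates for U and V, stopping
when the Frobenius norm of the center change drops below ε (default
10⁻⁵, max 100 iterations). The fuzzifier defaults to m = 2, the midpoint
of the commonly recommended 1.5–2.5 range. Constraints (memberships in
[0, 1], columns summing to 1, no empty cluster) hold for every returned
partition to 10⁻¹².

* **Zero distances**: the membership update divides by d_ik²; a point at
  distance < 10⁻¹² from one or more centers splits its membership equally
  among those centers and gets 0 elsewhere.
* **Initialisation**: centers are c distinct rows of Z sampled without
  replacement from a seeded generator. Because random initialisation can
  land in local minima, the fit runs `restarts` times (default 10) and
  keeps the lowest final J_m; `restarts=1` mimics a single-run protocol.
* A cluster losing all membership mass raises a degenerate-cluster error
  and that restart is redrawn.
* After the center iteration stops, one final membership update leaves
  (U, V) mutually consistent; the recorded J_m trace is non-increasing
  (tested to 10⁻¹⁰).

## Validity indices and the sweep

* **TSS** (argmin): fuzzy compactness Σ u_ik² d_ik² plus the punishing
  mean-pairwise-separation term, both over min-center-separation + 1/c.
  The membership exponent is 2 *by definition*, independent of the
  fuzzifier used in fitting. At c = n with crisp U = I, V = Z the index
  equals the closed form
  Σ_{i≠j} ‖z_i−z_j‖² / (n(n−1) min‖z_i−z_j‖² + (n−1)), a strictly
  positive limit — the feature that prevents the degenerate pull toward
  c = n − 1.
* **Silhouette** (argmax): crisp labels by maximal membership (ties to
  the smallest cluster index); a_k excludes the point itself; singleton
  clusters score 0. A fuzzy-weighted silhouette variant is deliberately
  not implemented.
* **Xie–Beni** (argmin, optional): compactness / (n · min separation);
  errors on coincident centers (it has no +1/c guard). Included to
  demonstrate its weak resistance to large c: on planted four-group data
  the TSS growth ratio from the true c to c = n − 1 exceeds the Xie–Beni
  ratio by well over 5× in every tested seed.

`sweep_validity` fits FCM for each c in [c_min, c_max] (default 2…11 for
a 12-region study, i.e. up to n − 1) with an independent child seed per
c, evaluates the requested indices, and returns per-index curves with
the optimal c (ties to the smaller c — parsimony). If a partition
collapses to fewer than two non-empty crisp clusters at some c, the
silhouette there is NaN and excluded from the argmax rather than
aborting the sweep.

## Synthetic data generator

The generator is first-class, tested code that defines the conditions
under which the pipeline's claims are validated. Defaults: 4 origins × 3
regions × 8 replicates × 47 metabolites. In log10 space: a base profile
uniform on [−4, 1]; per origin, each metabolite independently carries a
±1.5 shift with probability 0.3 (`shift_fraction`, chosen so each origin
is marked by ~14 of 47 metabolites — a clear multivariate signature that
no single metabolite gives away); per region a Gaussian offset (sd 0.2);
per replicate i.i.d. Gaussian noise (sd 0.3, i.e. multiplicative noise of
roughly a factor 2 in concentration — generous for replicate agreement);
optional contamination adds a Δ log-unit shift to a random half of the
metabolites of selected replicates, modelling a partial measurement
error. Concentrations below 10⁻⁴ are censored to exact zero. Everything
derives from one seed and is bit-reproducible.

What the generator does *not* emulate: correlated metabolite covariance,
retention-time or peak-shape artefacts, batch drift, missing-at-random
dropouts. Passing tests therefore demonstrate the pipeline's behaviour
under idealised log-Gaussian group structure with censoring and gross
outliers — not its performance on any particular instrument's data.

## Pipeline and reproducibility

`run_no_reduction` clusters all replicate columns directly (each analysis
one point) — the design that exposes stray replicates. `run_reduced`
reduces per region with each requested method and sweeps per method.
Reports are written as CSVs (validity matrices with c as rows and methods
as columns, membership tables at each index's optimum, objective traces,
reduced datasets) plus the resolved config and a log; identical config
and seed reproduce every file bit-identically. Child seeds derive from
the master seed as `SeedSequence(master, spawn_key=(method_index, c))`.

Default problem sizes throughout (12 regions, 47 metabolites, 10
restarts, c = 2…11, 10-seed recovery batches, 200-trial robustness
duels) keep any single experiment in the seconds-to-minutes range on one
CPU while leaving the planted structure comfortably identifiable.

## Known limitations

* The geometric median of two points is non-unique (any point of the
  segment); the iteration's limit is reported as-is.
* Step-size stopping can in principle halt near a non-optimal vertex if
  an iterate lands extremely close to it mid-run; the coincidence
  tolerance mitigates the exact case, and none of the randomized suites
  encounter the near-miss case.
* LE/LLE results depend on k and weighting; with ~47 points and k = 5
  the kNN graph is usually but not always connected, and conclusions
  about these embeddings' clustering quality are settings-dependent, so
  the package reports them without asserting their inferiority.
* FCM finds local minima; restarts reduce but do not eliminate the risk.
  The sweep's per-c refits make validity curves piecewise-independent,
  so a poor local minimum at one c does not contaminate its neighbours.
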