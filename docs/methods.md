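# Methods

## The predictor: label propagation and co-training

Patients are encoded into a Euclidean feature space — discrete variables
one-hot expanded, continuous variables z-scored — and connected by a
symmetrized k-nearest-neighbor graph with Gaussian weights
w_ij = exp(−‖z_i − z_j‖²/α²).  The union rule (an edge exists if either
endpoint lists the other among its k nearest) keeps the graph connected at
small k; duplicate rows get weight-1 edges and no self-edges are stored.
The bandwidth default α = mean distance to the k-th nearest neighbor adapts
the kernel to the data scale; it is configurable.

A member classifier solves (I + μL) f = y with L = D − W.  The coefficient
matrix is a symmetric positive-definite M-matrix with unit row sums, so each
f_i is a convex combination of the entries of y (the maximum principle), the
fully labeled constant vector is a fixed point for every μ, and μ → ∞ drives
f to the label mean on a connected graph.  Systems below n = 200 are solved
densely; larger ones by conjugate gradients at relative tolerance 1e−8.
Labels are read off as sign(f − threshold) with threshold 0 by default;
exact ties abstain.  A class-mass mode (threshold placed so that a given
fraction of points is predicted positive) is available when the label prior
is known and very unbalanced.

Co-training runs m ≥ 2 members that differ in (k, μ) and optionally in the
feature subset their graph sees; the default pair is (k, μ) = (7, 1) and
(15, 0.01) — one tight, heavily smoothed graph and one wide, label-faithful
one.  Per iteration every member predicts the unlabeled rows; unanimous
nonzero votes become hard ±1 pseudo-labels with the same loss weight as
true labels (a majority rule and a confidence gate |f_i| ≥ τ, default off,
are provided as options).  Graphs depend only on the features and are built
once; only y changes across iterations.  Original labels are immutable and
the unlabeled set never grows, so the loop terminates within nu + 1
iterations; in practice it stops much earlier at the first iteration that
adds nothing.  The final ranking score is the mean of the members' f-vectors
from one last solve on the augmented labels.

Class balance matters: with a heavily skewed labeled set and threshold 0,
the label mass drags every f_i toward the majority sign and pseudo-labels
flood one class.  The evaluation protocol therefore balances the labeled
classes by undersampling the majority (the "equipoise" step) before
learning, which is also how the benchmark below is run.

## The descriptor: CART with surrogate splits

The descriptor consumes fully labeled rows — training labels joined with
the predictor's labels for the rest; the handful of rows the ensemble never
resolved are assigned by the sign of the final score and dropped if that is
exactly zero.  No validation or test split is used: the tree describes the
predictor's output rather than predicting.

The tree is binary CART with Gini impurity (entropy is a config option).
Continuous variables split on midpoint thresholds (`value ≤ t` goes left);
discrete variables split on code subsets, searched exhaustively up to 10
distinct codes per node and by the classic positive-fraction-ordering
shortcut (optimal for binary Gini) above that.  Growth stops at max_depth
(default 6, matching the depth at which registry-scale trees level off),
min_leaf (default 20), purity, or no positive improvement.  The improvement
of a split is the parent-weighted impurity decrease
ΔI = (n_t/n)·[i(t) − p_L i(t_L) − p_R i(t_R)].  Equal-improvement candidates
are resolved by lower variable index, then lower threshold or
lexicographically smaller code subset, making fitted trees deterministic.

At each internal node, every non-primary variable contributes its best
*surrogate*: the split that maximizes agreement with the primary partition
in either orientation.  A surrogate is admitted only if its agreement
strictly exceeds the majority-direction baseline; it is ranked by the CART
association λ = (agree − maj)/(n_t − maj) and capped at 5 per node.  Its
ΔI is the surrogate split's own impurity decrease at that node, unweighted
by association — the convention is isolated in one function should a
weighted variant ever be wanted.  Variable importance sums primary ΔI where
the variable splits the node and surrogate ΔI elsewhere (no double count),
then normalizes by the maximum; a depth-0 tree yields all-zero VI by
convention.  One caveat of surrogate search mirrors classic CART: a
continuous noise variable with many candidate thresholds can marginally
beat a weak baseline by chance, so very small associations should not be
over-read.

Segments are the leaves; path conditions are simplified to the tightest
lower/upper bound per continuous variable and the intersection of allowed
codes per discrete variable.  Group profiles are per-variable means scaled
to [0, 1] by the full cohort's observed range (zero-range variables map to
0.5), with discrete variables entering through their numeric codes.

## The synthetic generator

The generator emulates a registry-style breast-cancer schema: 11 discrete
variables at their declared cardinalities (race 16, radiation 6, primary
site 9, histological type 30, behavior 2, grade 5, site-specific surgery 12,
stage 10, extension 16, lymph-node involvement 7, marital status 4) drawn as
ordinal codes with mildly skewed geometric(0.85) masses, and 5 continuous
variables as truncated normals at their declared moments (age 63.64 ± 14.25
years, tumor size 116.78 ± 286.64, positive nodes 27.29 ± 42.26, nodes
examined 13.61 ± 17.49, primaries 0.54 ± 1.29), truncated below at 0.  The
printed moments of tumor size and number of primaries are inconsistent with
their nominal units (registry-coded values); the generator reproduces the
declared numbers as-is rather than second-guessing them.

Survival is planted linearly: a latent score sums per-variable standardized
values weighted by effect sizes β plus Gaussian noise (sd 0.5), and the
label cut is placed at the score quantile that realizes the positive prior
0.7906 (the registry's 128,469 : 34,031 class ratio).  The default β puts
all the signal on the five top-tier prognostic markers — lymph-node
involvement (−1.0), positive nodes (−0.9), stage (−0.8), tumor size (−0.7),
site-specific surgery (−0.6) — with the negative sign encoding that worse
pathology lowers survival.  The magnitudes make the latent mechanism
strongly learnable (signal variance ≈ 3.3 against noise 0.25), i.e. the
regime in which semi-supervised prediction is meaningfully above chance, as
it is on the real problem.  A `label_fraction` of the rows keeps its label
(default 20%); the ground truth is returned in a sidecar frame.

What the generator does *not* model: joint dependence among predictors
(stage and tumor size are drawn independently), nonlinear or interaction
effects, label noise, and missing values.  Passing tests therefore show the
machinery recovers a planted monotone mechanism under clean conditions, not
that it matches registry performance.  Two special cohorts exercise single
stages: well-separated two-Gaussian blobs for the co-training loop, and a
cohort whose dead class mixes two mechanisms (very high number of
primaries vs. few primaries with late stage and large tumor) for
segmentation.

## Evaluation harness

AUC is the tie-aware Mann–Whitney statistic computed from average ranks.
The experiment harness draws disjoint groups without replacement from a
labeled table, balances each by undersampling, and scores each model's
hyperparameter grid by k-fold cross-validation inside the group (validation
folds are stripped of labels and scored transductively); the group's
reported AUC is the best grid point's mean validation AUC.  One seed drives
group draws, folds and the generator.

The co-training benchmark used by `scripts/acceptance.py` draws cohorts of
n = 600 with the default planted mechanism and 20% labels, equipoises,
runs the default two-member ensemble for up to 10 iterations, and scores
the originally-unlabeled rows against the ground truth; single members are
scored from their own solve on the initial labels.  Ten replicate draws are
averaged.  Problem sizes (600 for the benchmark and segmentation cohorts,
800 for importance recovery) are chosen so the full recomputation runs in
seconds while keeping fold and group sizes large enough for stable AUCs.

## Known limitations

* The descriptor's subset-split shortcut above 10 codes is optimal for the
  split search but only near-optimal for surrogate agreement search.
* Disconnected graph components containing no labels get f = 0 and abstain;
  this is documented behavior, not an error.
* Pseudo-labels are hard and never revised; a wrong early pseudo-label
  propagates (the confidence gate τ mitigates but defaults to off).
* No pruning or cost-complexity search; the descriptor tree is depth-capped
  instead.
* Missing predictor values are rejected rather than imputed.
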