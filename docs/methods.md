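# Methods

## Connectivity estimation

**Pearson (PC).** Edge weights are the centered cosine between two ROIs'
series; the raw matrix has unit diagonal and entries in [−1, 1]. An ROI with
zero temporal variance cannot be correlated: its off-diagonal weights are set
to 0 with a logged warning naming the ROI, so real cohorts containing a flat
regressor still process.

**Sparse representation (SR).** For each target ROI i the row W_{i·}
minimizes ‖x_i − Σ_{j≠i} W_ij x_j‖² + λ Σ_{j≠i} |W_ij| with W_ii = 0. The
penalty is the L1 norm: the objective written without absolute-value bars has
no minimizer, and the method is a lasso-style sparse regression by intent.
The solver is cyclic coordinate descent on the Gram form with
soft-thresholding at λ/2; the objective carries no 1/(2t) factor, so the
equivalent scikit-learn `Lasso` penalty is α = λ/(2t) (used as an independent
cross-check in the tests, never as the implementation). Convergence is
declared when the largest per-sweep coefficient change falls below
`tolerance` (default 1e-8, at most 500 sweeps); non-convergence sets a flag
and warns rather than raising, and the per-sweep objective is monotonically
non-increasing by construction. Default λ = 1, the value a sensitivity sweep
identifies as best; `sweep_lambda` re-examines it. Coordinate descent
handles the underdetermined t < n regime without modification.

**Granger causality mapping (GCM).** For the ordered pair (x → y), the
restricted model regresses y_t on an intercept and its own `lag_order` lags;
the unrestricted model adds the same lags of x; both use least squares over
the common effective sample of t − lag_order points. We define
G_{x→y} = ln(RSS_restricted / RSS_unrestricted), which is non-negative
because the unrestricted model nests the restricted one. (Written the other
way around, the statistic would be non-positive and could not serve as a
connection strength; magnitude-based symmetrization presumes non-negative
parts.) Default lag order 1, configurable. Normal equations receive a ridge
jitter of 1e-8 × mean(diag(Z'Z)) so exactly collinear designs stay solvable;
an exactly-fitting unrestricted model is capped at strength 30 with a
warning, and a constant target yields 0 with a warning. The directed matrix
is symmetrized as A_ij = |G_{i→j} + G_{j→i}| with zero diagonal.

## Canonicalization

All raw estimates pass through the same normalization, in order: symmetrize
by (W + Wᵀ)/2 (only SR is asymmetric; averaging is the undirected analogue
of the additive symmetrization used for GCM), absolute value, zero diagonal,
rescale to unit maximum, then zero entries strictly below the threshold
while keeping surviving weights — thresholded graphs stay weighted because
the propagation rule consumes weighted adjacencies. Defaults per pattern:
0.1 (PC), 0.2 (SR), 0.2 (GCM). Thresholds apply to rescaled magnitudes;
because the maximum rescales to exactly 1, no threshold below 1 can empty a
graph, so the threshold-sweep driver treats grid points ≥ 1 as the fully
edge-free regime and flags such rows degenerate instead of failing.
Canonicalization is idempotent at a fixed threshold.

Node features are the rows of the canonical adjacency (the node's
connectivity profile). This makes the feature width equal n, keeps the
branch input well-typed for any ROI count, and ties each node's
representation to its observed connectivity rather than to an arbitrary
one-hot identity.

## Network architecture and training

Per branch: two bias-free graph convolutions of width 32 with ReLU, using
the self-loop renormalized operator P = D̂^{−1/2}(A + I)D̂^{−1/2}
(symmetric, spectrum within [−1, 1]; the normalized Laplacian is exposed
separately as a derived quantity for testing). Readout concatenates
columnwise mean and max of the final node embeddings → 64 per branch. Branch
embeddings concatenate in the fixed order PC, SR, GCM; the head is three
affine layers [64·branches, 32, 16, 2] with ReLU between them, biases in the
head only (the convolution equations carry none), and dropout 0.5 after each
of the first two head layers, active only in training mode.

Training: cross-entropy, Adam with learning rate 0.0025 and coupled L2
weight decay 1e-5, 150 epochs, full-batch gradient steps (cohorts at desk
scale are a few dozen subjects; full batch removes an undocumented batching
degree of freedom — mini-batching is available through `batch_size`).
Initialization is Glorot-uniform from a single seeded generator. After each
epoch the validation accuracy is computed in eval mode; the checkpoint keeps
the epoch with the highest validation accuracy, ties broken by lower
validation loss, then by earlier epoch. All arithmetic is numpy on a single
thread of control, so identical seed and data reproduce weights and metrics
bitwise. One seed drives three spawned substreams (split, initialization,
dropout), so changing, say, only the number of epochs does not perturb the
split.

The forward/backward passes and the optimizer are implemented explicitly in
numpy. The max half of the readout routes its gradient to the first argmax
node per channel, the standard subgradient choice; finite-difference tests
confirm the analytic gradients.

## Evaluation protocol

Stratified 70/10/20 train/validation/test splits; within each class, indices
are shuffled and apportioned by largest remainder (ties favour train, then
validation), keeping every subset within one subject of exact
stratification. Metrics come from confusion counts with the case class
positive; AUC is the rank-based Mann–Whitney probability with ties credited
1/2. Repeated runs resample both the split and the initialization, and
aggregates report mean ± sample standard deviation (ddof = 1, stated in
output headers). Cross-validation is stratified k-fold (default 5); inside
each fold, 1/8 of the training portion is held out for checkpoint selection,
mirroring the 70/10 ratio. The ablation driver trains all 7 non-empty
pattern subsets under identical seeds and therefore identical partitions,
with head widths adapting to the branch count.

## Grad-CAM attribution

Hooked at each branch's final convolution layer, before readout. Channel
weights are node-averaged gradients of the chosen class's pre-softmax logit
(making α global per channel by design); node scores are the rectified
channel-weighted sums, normalized within each subject by the maximum score
so they lie in [0, 1] while preserving zeros and relative magnitudes. The
target class defaults to the case class and is configurable. A subject whose
map is rectified entirely to zero is returned unnormalized with a degenerate
flag. Cohort-level rankings average normalized scores across subjects (and
models, when aggregating over repeated seeds), with ties broken by ROI
index. The report includes pairwise top-k overlaps between patterns, which
quantify how much the discriminative regions differ across connection
patterns.

## Synthetic cohorts

Each subject is an independent draw from a group-specific stationary VAR(1),
x_t = A_g x_{t−1} + e_t with e_t ~ N(0, Σ_g); 200 burn-in steps are
discarded and columns are z-scored per subject (correlation-based networks
are scale-free, so units carry no information). Config validation rejects
lag matrices with spectral radius ≥ 1 and non-positive-definite covariances.
One root seed spawns per-subject substreams, so cohorts are bitwise
reproducible and a subject's draw does not depend on cohort ordering.

Default study conditions: 20 ROIs, 30 subjects per group, 232 time points,
self-memory 0.25 on the diagonal. Eight affected ROIs split into two
disjoint halves: ROIs 0–3 differ in contemporaneous innovation correlation
(0.05 control vs 0.25 case — a symmetric effect visible to PC and SR), and
ROIs 4–7 carry a directed chain ROI k → k+1 of lag strength 0.3 in cases
only (visible to GCM). The placement is deliberate: no single estimator sees
the whole group difference, which is the premise that makes fusing
complementary patterns worthwhile, and it is what the end-to-end tests
verify — the fused model matches or beats every single-pattern model while
each branch's attribution highlights "its" ROIs. Effect sizes were fixed
once, by pilot simulation, at the weakest level where the fused model is
reliably near ceiling while single patterns remain imperfect. Full-scale
116-ROI, 232-time-point cohorts are supported by the same code path.

What the simulator does **not** emulate: hemodynamic response convolution,
scanner and physiological noise spectra, motion artifacts, multi-site batch
effects, and any claim about which anatomical regions differ in a real
disorder — effect placement is a free parameter of the benchmark, not
biology. Passing tests therefore demonstrate that the estimators, network
and attribution recover planted linear-Gaussian structure; they do not
certify accuracy on clinical data.

## Problem sizes in tests and the acceptance script

Unit tests run at 8–12 ROIs and 100–150 time points with shortened training;
the end-to-end experiments run the full default conditions (20 ROIs,
30/group, t = 232, 150 epochs). The acceptance script uses 5 fresh-cohort
repetitions for the ablation experiment, 10 shuffled-label repetitions for
the null, 100 seeds for Granger directionality, and one 5-fold
cross-validation — sizes chosen so the whole script completes in well under
a minute on one CPU while keeping Monte-Carlo noise far from the decision
boundaries it reports against.

## Known limitations

- Pairwise (bivariate) Granger causality, not conditional multivariate
  Granger; indirect paths can inflate strengths.
- Eq-level choices documented above (L1 reading of the SR penalty, RSS-ratio
  orientation, profile node features) are the package's own resolutions of
  genuinely open design points.
- Full-batch Adam at desk scale; very large cohorts would want mini-batching
  and a streaming graph store.
- The dropout mask stream advances once per epoch; comparing runs that
  differ only in epoch count therefore compares different mask sequences.
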