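# Methods

## Model

For one pathway, member-gene expression is standardised per gene
(z-scores; population convention, divisor *n*) and the pathway activity of
sample *s* is the signed weighted sum pa_s = Σ_m G_sm (rp_m − rn_m).  The
mixed-integer linear program chooses the weights, one activity interval
[LO_c, UP_c] per class, and binary enclosure flags E_s, minimising the
number of samples whose activity falls outside their own class interval.
Constraints: per gene at most one of rp_m, rn_m positive (binary L_m);
Σ(rp + rn) = 1; at most NoG active genes (binaries W_m); intervals of
different classes disjoint with an ε gap (order binaries Y_kc); big-U
constraints tie E_s to interval membership.

Assumptions worth stating explicitly:

* The discriminative signal of a pathway is expressible as **one linear
  axis** of its member genes' z-scores, on which classes occupy disjoint
  intervals.  Multi-modal classes (one class in two separate activity
  regions) are penalised because each class owns a single interval.
* Standardisation statistics transfer from training to held-out samples,
  i.e. the test distribution per gene matches the training one up to the
  affine map the z-score removes.
* A class's interval may be empty (UP < LO): the model may sacrifice an
  entire class when that minimises total misclassification.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| NoG | 10 | cap on genes with non-zero weight per pathway; the sensitivity sweep (5, 10, 15, 20, all) shows robustness on planted data; 10 is a sensible compromise between using the informative genes and over-fitting small training sets |
| ε | 1e−3 | minimum gap between class intervals on the standardised activity scale; activities live in [−max\|G\|, max\|G\|] (≈ a few units), so 10⁻³ is far above solver tolerance (10⁻⁷) yet negligible relative to the data scale |
| U | auto | 2·max\|G\| + 2ε + 1; since Σ\|weights\| = 1 implies \|pa_s\| ≤ max\|G\|, this provably deactivates enclosure/ordering constraints when their binary is off, while staying small enough to avoid big-M numerical slack |
| mip_gap | 0 | prove optimality (relative gap) |
| time_limit_s | 200 | per-pathway wall clock; on timeout the incumbent is returned with `status="feasible_time_limit"` so batch runs over large collections always complete |

LO_c/UP_c are boxed to [−U, U]: any sample-enclosing interval fits in that
box, and finite variable bounds are required by practical solvers.

## Numerical choices

* **Solver.**  HiGHS branch-and-bound via `scipy.optimize.milp`, behind a
  small backend protocol so another MILP solver honouring variable boxes,
  gap and time limit can be plugged in.  HiGHS is deterministic for a fixed
  model; the `solver_seed` field exists for backends that expose a seed.
* **Sparsity tie-break.**  Weight optima are highly degenerate: when a
  pathway is separable, infinitely many weight vectors reach the same
  misclassification count, including ones that smear weight onto
  uninformative genes.  The objective therefore carries a lexicographic
  term δ·ΣW with δ = 0.5/M — strictly less than one misclassified sample,
  so the primary optimum is untouched — which selects, among
  misclassification-optimal solutions, one with the fewest active genes.
  This makes the active-gene frequency analysis interpretable; reported
  objectives are always the enclosure count #{E_s = 0}.
* **Zero-variance genes** standardise to 0 for every sample rather than
  raising: a constant gene is never discriminative, and dropping it would
  silently change pathway membership.
* **Degenerate inputs.**  All-identical samples leave every activity equal;
  only one class interval can contain that value, so the optimum is
  S − (largest class size).  Pathways with no member genes in the matrix
  are skipped with a warning, not errors.
* **PCA sign** is fixed by making the largest-magnitude loading entry
  positive; covariance uses divisor n − 1.
* **Ties** in gene rankings keep input (file) order; ties in pathway
  information-gain rankings break by pathway name.
* **Enclosure tolerance.**  Recomputing activities from the cleaned weight
  vector can drift from the solver's internal values by ~10⁻⁹–10⁻⁷;
  interval-membership predictions use a 10⁻⁶ tolerance, well below ε.

## Evaluation protocol

Stratified 70/30 splits: per class, floor(0.7·n_c) samples go to train
(never fewer than 1, never all), then leftover slots are topped up in class
order to the global round(0.7·S) target; the published protocol only says
"randomly", but stratification prevents empty-class training sets in small
cohorts.  Standardisation, activity fitting (including the MILP) and
classifier training see training samples only; held-out samples are
z-scored with training parameters.  Mean accuracies over repeats are
normalised per classifier by the best method's rate (the best method maps
to exactly 1).  Shipped classifiers: 5-nearest-neighbours and multinomial
logistic regression, plus a majority-class dummy for sanity checks; SMO,
the 2-hidden-layer neural network (learning rate 0.1, momentum 0.2, 10000
epochs) and the Hyperbox MILP classifier used in some published comparisons
remain pluggable rather than shipped.

Pathway significance: per repeat, training-profile activities are ranked by
information gain with Fayyad–Irani MDL discretisation (the WEKA default);
a pathway counts when it appears among the top-k (k_top, default 1 — the
frequency window is parameterised because "most discriminative" can
reasonably mean top-1 or a wider window), and pathways counted in strictly
more than 20 of 50 repeats are reported, with genes active in strictly more
than 10 repeats.

The single-gene (SG) baseline ranks genes by the aggregated pairwise
absolute difference of class means of the z-scores — a deliberate, simple
stand-in for the original multiclass distance-based filter, whose exact
algorithm is not reproducible from its one-line description; selection
happens per split, on training samples only, taking as many genes as there
are pathways.  CORGs follows the original description (t-statistic ranking,
bidirectional greedy growth, Σz/√k scaling, stop when |t| stops improving);
√k scaling and bidirectionality are exposed as flags since summaries of the
method leave them open.  CORGs is restricted to two-class problems.

## Synthetic data

The generator plants exactly the structure the model assumes: per
informative pathway a latent axis z_s = offset(class) + N(0, noise_sd),
signal genes reading ±z_s + N(0, background_sd), all other genes standard
normal, and a random per-gene affine corruption (scale U(0.5, 2), shift
U(−5, 5)) so the standardisation path is exercised non-trivially.  Defaults:
3 classes × 20 samples, 8 pathways of 5–30 genes, 3 informative pathways
with 3 signal genes each, offsets (−3, 0, +3), noise_sd 0.3, background_sd
0.1 — a separation margin far wider than the noise, so informative pathways
are separable by construction and recovery of the planted genes is a
meaningful test of the MILP rather than luck.

What the generator does **not** emulate: overlapping pathways, correlated
background genes, batch effects, heavy-tailed microarray noise, class
imbalance between informative axes.  Passing tests therefore demonstrate
correctness of the optimisation and protocol machinery, not expected
accuracy on real cohorts.

## Verification strategy and problem sizes

The MILP is checked against an independent brute-force oracle that shares no
code with it: for a fixed activity direction the problem reduces to placing
disjoint ε-separated class intervals on a line, solved exactly by dynamic
programming over sorted distinct values.  Single-gene problems (the weight
is ±1) must match the oracle exactly; for two-gene problems the MILP must
dominate a 41 × 41 signed-weight grid scored by the oracle; and the oracle
itself is validated against exhaustive enumeration of interval layouts on
instances small enough to enumerate.

Test and acceptance runs use deliberately small instances — single/two/
three-gene MILPs with S ≤ 30, planted designs of 24–36 samples over 2–5
pathways, 10–20 repeats/replicates, and short per-solve time limits (2–3 s)
for pipeline runs where uninformative pathways need not be solved to proven
optimality (the incumbent-on-timeout behaviour is itself part of the
design).  Separable pathways are always proven optimal almost instantly
because their lower bound (0) meets the incumbent.

## Known limitations

* Proving optimality on uninformative (noise) pathways is slow — the LP
  relaxation of the enclosure constraints is weak — so large collections
  rely on the time limit + incumbent path, exactly as the per-run resource
  cap in the original protocol anticipates.
* Weights are not unique even after the sparsity tie-break; tests and
  analyses rely on objectives, constraint invariants and active-gene sets,
  never on specific weight values.
* Gene matching between GMT and matrix is exact, case-sensitive string
  equality; no probe collapsing or alias resolution is attempted.
* CLS label files are matched to samples by position; inconsistent label
  files (wrong count, unknown samples, partial coverage) are hard errors,
  never silent subsetting.
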