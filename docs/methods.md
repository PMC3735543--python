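# Methods note

## Problem and model

Intronic endogenous retrovirus (ERV) insertions of the mouse IAP and
ETn/MusD families sometimes disrupt transcription of the enclosing gene
(aberrant splicing, premature polyadenylation) and sometimes are tolerated.
`ervpredict` models the probability of disruption from four factors of the
insertion site:

1. relative orientation of the ERV to the gene (sense = 1, antisense = 0),
2. ERV family (ETn/MusD = 1, IAP = 0),
3. size of the enclosing intron (bp),
4. distance from the insertion to the nearest exon boundary (bp).

The classifier is a 4–3–1 multilayer perceptron (MLP) with logistic
activations on the hidden and output layers — 19 trainable parameters. The
output is read as a disruption likelihood in (0, 1). Training minimizes the
summed squared error E = Σ (y − t)² / 2 over the training cases with
full-batch back-propagation.

## Feature encoding

The two length factors are heavily right-skewed, so they are log-compressed
and mapped to [0, 1]:

    u = log10(clamp(L, 1, cap)) / log10(cap)

with cap = 100,000 bp for intron size and cap = 50,000 bp for exon distance.
Values above the cap saturate at 1; lengths below 1 bp clamp to 0. The two
binary factors are encoded directly. Targets are 1 (disrupting/positive) and
0 (tolerated/negative).

## Cross-validated ensemble

A single 19-parameter MLP trained on ~150 cases is unstable, so predictions
come from a consolidated ensemble:

- **Stratified 3-fold cross-validation.** The positive and negative classes
  are shuffled and cut into 3 near-equal subgroups each; fold k's test set is
  the union of the k-th positive and negative subgroups. With 33 positives
  and 117 negatives every test set has exactly 50 cases and every training
  set 100.
- **10 random permutations** of the stratified split (30 train/test splits).
- **100 random reinitializations** per split, giving 3000 trained networks
  by default. Initial weights are uniform on (−0.5, 0.5).
- **Consolidation** is the arithmetic mean of the member outputs. For a new
  case all members contribute; for cross-validated evaluation each held-out
  set is scored only by the 100 members trained on the complementary
  training set, so no network ever scores a case it saw in training.

Cross-validated performance is the mean (and sample standard deviation,
ddof = 1) over the 30 per-split test AUCs.

## Training algorithm and defaults

The default optimizer is iRprop− (resilient back-propagation without
weight-backtracking): each parameter keeps its own step size, multiplied by
1.2 when the gradient sign repeats and by 0.5 on a sign flip (the gradient is
zeroed on a flip); steps are clipped to [1e−6, 50] with initial step 0.1.
Rprop's sign-based updates suit this tiny full-batch problem: plain gradient
descent at practical learning rates stalls on plateaus of the squared-error
surface and needs orders of magnitude more epochs for the same fit. Plain
gradient descent remains available (`algorithm="gd"`, default learning rate
0.05).

Defaults and rationale:

- `max_epochs = 5000`: cross-validated AUC on the default synthetic data
  saturates well before this budget; more epochs only add runtime.
- `stop_threshold = 0.001` on the maximum absolute gradient component: a
  member whose gradient is below this is frozen (converged) while the rest
  of its batch keeps training.
- `init_range = 0.5`: uniform (−0.5, 0.5) initial weights.
- Thresholds for calls default to τ = 0.5, with 0.4 (sensitive) and 0.8
  (specific) reported alongside by `ervpredict evaluate`.

All training is deterministic given the seeds. Member seeds are derived from
a master seed through `numpy.random.SeedSequence.spawn`, masked to < 2³¹.
Members are trained in vectorized batches (all reinitializations of all
splits with equal training-set size advance in lock-step via batched matrix
products); this is bit-identical to training each member alone, which the
test suite verifies.

## In-silico grid and prediction plots

For each family × orientation combination the normalized input plane is
divided into 100 × 100 bins and the consolidated output is evaluated at every
bin midpoint u = (i − 0.5)/100 — 40,000 artificial insertions per full run.
The prediction plot renders this matrix in ordered color bins (rainbow
colormap, bins of width 0.1) with normalized exon distance on x and
normalized intron size on y, large introns at the bottom. Cells whose
denormalized distance exceeds half the intron size are geometrically
impossible (an insertion cannot be farther from the nearest exon than the
intron midpoint) and are masked out, producing the characteristic triangle.
Labeled cases can be overlaid (cyan circles = positive, white squares =
negative).

## Synthetic data generator

The package ships no real genomic data. `synthetic_fixtures` generates
tables that emulate the class-conditional *structure* of curated mutagenic
versus tolerated intronic ERV insertions:

- class counts default to 33 positives, 117 negatives, and 134 unlabeled
  "polymorphic" records;
- orientation and family are Bernoulli per class (positives sense-enriched:
  p_sense 0.8 vs 0.2; ETn/MusD share 0.4 vs 0.1);
- intron size and exon distance are log-normal, 10^Normal(mean, sd) bp, with
  positives in smaller introns (log10 mean 3.6 vs 4.5) and closer to exons
  (log10 mean 2.8 vs 3.8), sd 0.5 throughout;
- the exon distance is drawn from its log-normal truncated above at half the
  intron size by inverse-CDF sampling, enforcing the geometric constraint
  exactly without rejection failures;
- the polymorphic set is mostly negative-like with a small positive-like
  admixture (7%) and an IAP-dominated family mix.

What the generator does **not** emulate: real intron-size distributions of
the mouse genome, linkage between the four factors beyond the geometric
distance constraint, gene-level effects, or any particular curated dataset.
Class overlap is controlled by the configured means/sds; the attainable
separability of the synthetic problem is bounded by that overlap, not by the
model. Quantitative behavior on this generator is whatever the test suite
and `scripts/acceptance.py` compute — no further performance figures are
claimed here.

## Numerical choices

- All floating point is float64.
- Logistic activations use `scipy.special.expit` for stable evaluation.
- ROC curves and AUC use `scikit-learn` (`roc_curve` with
  `drop_intermediate=False`, trapezoidal `auc`); the suite cross-checks the
  trapezoidal AUC against brute-force pair counting.
- The equality-of-proportions test is the continuity-corrected chi-squared
  test (`scipy.stats.chi2_contingency`) on the 2×2 table; the two-sample
  t-test is pooled-variance (`scipy.stats.ttest_ind`).
- Model archives serialize weights as JSON decimal strings produced by
  `repr`, which round-trips float64 bit-exactly.
- Gradients are validated against central finite differences (relative error
  ≤ 1e−5).

## Limitations

- The model sees only the four site factors; it cannot capture sequence
  context, splice-site strength, expression level, or strain background.
- Results on synthetic data characterize the pipeline, not mouse biology;
  absolute performance numbers depend on the generator's configured class
  overlap.
- The squared-error MLP output is a score, not a calibrated probability.
- Length factors saturate at the caps (100 kb introns, 50 kb distances);
  insertions beyond the caps are indistinguishable from cap-valued ones.
- The annotation step assigns one enclosing intron per gene model and skips
  exon-overlapping insertions; genes with overlapping isoforms are reduced
  to their exon union.
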