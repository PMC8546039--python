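# Methods

This note records the model, the numerical conventions, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Labels and training-set structure

Variants are labeled per source: clinical assertions (pathogenic / likely
pathogenic / the combined class ⇒ positive; the benign counterparts ⇒
negative; review stars are recorded as a quality property but never gate the
label), literature annotations (deleterious ⇒ positive, polymorphism ⇒
negative), disease-mutation collections (always positive), rescaled
functional-assay scores (0 ≈ nonsense-like, 1 ≈ synonymous-like; above 0.5 ⇒
negative, below ⇒ positive), and population data (at least one homozygote ⇒
negative). A variant present in several sources takes its label from the
first source in a configurable precedence list (clinical > disease-mutation >
literature > assay > population by default); label assignment therefore
depends on the precedence, never on annotation order.

Conventions chosen where the rules leave gaps: an assay score of exactly 0.5
labels negative; a MAF exactly at the 0.5% cutoff is moderately rare and
exactly at 10⁻⁶ is moderately rare (the "common" stratum stays strictly
above the threshold); a missing MAF counts as 0 (undetected ⇒ extremely
rare); population variants never seen homozygous are unlabeled and dropped by
default, with an opt-in flag that admits them as putatively benign (used by
the degradation experiment). Core membership: flavor `R` pools moderately +
extremely rare clinically asserted variants; flavor `ER` keeps only the
extremely rare ones and demotes the rest to add-ons. Negative add-on sets
except the assay-derived one are split at the 0.5% MAF cutoff. The emitted
sets partition the labeled input.

## Quality properties

**Mutational accessibility** of an amino acid change is the probability that
a single-nucleotide edit of a codon encoding the reference residue yields the
alternate residue: each sense codon has exactly nine edits, each carrying
`usage(codon)/9`. Codon usage is normalized **per amino acid** (relative
synonymous usage), so the outcome masses over the 20 residues plus stop plus
the synonymous class sum to exactly 1 for every reference residue, and the
result is invariant to the absolute scale of the supplied frequency table. A
bundled human table ships with the package; any table in the same TSV schema
can be substituted (genome-wide per-1000 frequencies are normalized on load).

**Label confidence** of an assay score `s` is `min(s, 1 − s)` clamped below
at zero — the distance from the labeling threshold, largest (0.5) for the
most ambiguous scores. Scores outside [0, 1] (possible after rescaling) clamp
to confidence 0.

## Weighting

Each training set has zero or more (property, transform, logistic) triples.
The logistic is the standard three-parameter form `L/(1 + e^{−k(x−x₀)})` with
`L ∈ (0, 1]` (so weights stay in (0, 1] before rebalancing), `x₀` on the
transformed property scale, and `k` of free sign, letting the optimizer pick
the direction of the quality trend. Allele frequency enters as −log₁₀(MAF)
because frequencies span orders of magnitude; a missing/zero MAF maps to
−log₁₀ of half the smallest observed positive frequency (one notch rarer
than anything detected). A record missing a configured property contributes
the neutral factor L/2 rather than being dropped, keeping set sizes stable
across tuning trials. After weighting, positive weights are rescaled by
(total negative)/(total positive); negatives are untouched.

## Metrics

The precision-recall sweep uses descending unique score thresholds with tied
scores collapsed into one curve point. AUPRC is interpolation-free average
precision (recall-increment-weighted mean of precision). Balanced precision
maps each precision to the value expected at a 50% prior through the
likelihood ratio, which is prior-invariant. Two AUBPRC estimators are
computed and reported: the **pointwise** transform (balance each precision,
then take the weighted mean — the canonical estimator here) and the
**closed-form** transform of AUPRC. They coincide exactly when precision is
constant along the curve but differ on stepped curves (the three-point
worked example gives 0.75 vs 5/7); both are reported because either reading
is defensible and the difference itself is informative. R90BP takes the
*largest* recall at which the (non-monotone) balanced curve crosses the
target from above, linearly interpolated between adjacent points — 1 if the
curve ends at or above the target, 0 if it never reaches it. AUROC comes from
the rank statistic with tie correction. Comparisons: a one-sided Z test over
bootstrap resamples of a shared test set (resamples drawn until both classes
are present), and a one-sided paired t test over fold-wise metric values;
zero-variance differences short-circuit to p ∈ {0, 1} with a degenerate flag.

## Moving-window analysis

Add-on examples are ordered by a candidate property (missing values last) and
swept with `n_windows` windows of size `round(X·fraction)`, stepping
`max(1, floor(X(1−fraction)/(n_windows−1)))` and clipping at `X` (short final
windows are expected; empty ones are dropped). The bracket in the step
formula is read as floor, clamped to ≥ 1. Full index coverage is guaranteed
exactly when the step does not exceed the window size **and**
`(n_windows−1)·step + size ≥ X`; outside that regime (very small fractions
with very few windows, or floor shortfall at small X) interior or tail gaps
are unavoidable under this scheme, which the tests assert precisely.

A window's utility is the mean validation AUBPRC of a k-fold core
cross-validation in which every training fold is supplemented by the window's
examples, unweighted, at fixed default learner settings; validation folds
contain core examples only. Informativeness compares the Pearson correlation
of (window index, utility) against ten seeded random orderings via
`Z = (r_obs − mean)/sd`; |Z| > 1 flags the property, the sign giving the
trend direction. Note a statistical property of this design: under the null
(property unrelated to utility) the observed ordering is exchangeable with
the random orderings, so the distribution of Z — and hence the ~1/3 rate at
which |Z| exceeds 1 by chance with ten references — does not depend on data
sizes or the learner. The screen is a ranking device, not a calibrated test.

## Learner and validation protocols

The learner is XGBoost with the binary-logistic objective; per-example
weights scale the first- and second-order gradients. The base score is pinned
at 0.5 (zero base margin) and the default tree method is `exact`, which makes
two contracts hold bit-exactly with subsampling off: zero-weight examples
never influence the fit, and weight 2 equals duplication with weight 1.
Histogram-based growth (`hist`) is available for large benchmark runs where
those contracts are not being asserted. Folds are label-stratified and
seeded. Cross-validation holds out only core examples; all add-ons supplement
every training fold, and weights (including rebalancing) are recomputed per
fold's training pool. The training-side AUBPRC used by the early-stopping
selector is computed, unweighted, on the fold's core training portion.
Nested cross-validation runs the full search per outer fold on the
outer-training core; outer-held-out records never reach any inner stage.
Leave-one-variant-out retrains once per non-zero-weight variant with fixed
hyperparameters and seed; zero-weight variants take the full-model score
(exact by the zero-weight contract).

## Hyperparameter search

All dimensions — learner settings and every logistic (L, x₀, k) — are tuned
jointly by a seeded sequential model-based optimizer in the
tree-structured-Parzen-estimator family: uniform random start-up, then a
good/bad split of finished trials (top 25% by objective), per-dimension
Gaussian-kernel Parzen densities, candidates drawn from the good density and
ranked by the good/bad log-density ratio (equivalent to expected-improvement
maximization). Integer dimensions round, log-uniform dimensions are modeled
in log space, and every trial is evaluated on the same seeded folds so
objectives are paired across trials. Failed trials record a −∞ objective and
the search continues. Default ranges: trees 50-500, depth 3-10, learning
rate log-uniform 0.01-0.3, min child weight 0.5-10, subsample/colsample
0.6-1; weight functions L ∈ [0.1, 1], x₀ spanning the property's 1st-99th
percentile (transformed scale), k ∈ [−20, 20].

The final trial is *not* the best objective: trials are sorted by mean
training AUBPRC ascending (stable sort; failed trials first, unelectable), a
stride-1 moving average of validation AUBPRC over blocks of `window` trials
is scanned for the first strict descent, and the best-validation trial inside
that window is selected (last window if no descent; a single all-trial window
when there are fewer trials than the window). "Begins to descend" is a strict
decrease; equal consecutive means do not trigger stopping. The stride was an
open choice; stride 1 stops more conservatively than stride-`window`.

## Explanations

Shapley interaction values are computed by the tree ensemble itself
(path-dependent traversal with cover-weighted expectations) on the log-odds
scale; per variant they form a symmetric feature×feature matrix (diagonal:
main effects; off-diagonal: halved pairwise interaction shares) satisfying
`base + Σ matrix = lod`. Performance contributions multiply the matrix by the
training weight and by the label sign (negated for putatively benign
variants). Group aggregation folds within-group interactions into the group's
individual term; the pairwise differential between two groups is the single
cross-block sum of the weighted-mean matrix — half of the full symmetric
interaction mass, identical in both directions — so that the sum of group
totals conserves the weighted mean of the signed (lod − base). An exhaustive
subset-enumeration oracle (all 2^M coalitions with the same cover-weighted
value function) verifies the matrices to 1e-6 in the test suite.

## Synthetic benchmarks

The generator draws a balanced latent truth; features are independent unit
Gaussians whose class-conditional means differ by `class_separation / 2` per
feature (for the default six features the class centroids are
`class_separation·√6/2 ≈ 1.22·class_separation` apart in Mahalanobis
distance). Core labels equal the truth. Each add-on set has a quality
property uniform on [0, 1]; its labels flip independently with probability
linear in the property, and its features may drift with the property either
along a random direction (representativity shift) or along the class axis —
the latter models *systematic contamination*, where poorly labeled examples
concentrate where they distort the decision boundary, as when truly damaging
variants hide among putatively benign population variants. Tables carry
synthetic accessions, amino acid changes, MAFs and per-source annotation
columns, so the dataset layer ingests them unchanged.

The default benchmark uses `class_separation = 1.5`, at which a model trained
on the clean core alone reaches held-out AUROC around 0.9 — comparable to
published missense predictors, and hard enough that add-on quality matters.
It has a 2,000-variant core and three 3,000-variant add-ons: one with label
noise rising 0.05 → 0.45 in its property plus class-axis covariate shift 3.0
(the contaminated set), one with flat 10% noise, and one nearly clean with
random-direction shift. What the synthetic data deliberately lacks: realistic
allele-frequency spectra, feature correlations of real conservation scores,
per-protein structure, and asymmetric class-conditional noise. Passing tests
therefore demonstrate that the machinery behaves as specified under its own
assumptions, not that any particular real-data performance level is attained.

## Benchmark protocol sizes

Desk-scale sizes were fixed once for the standing benchmarks: the
moving-window screen uses a 600-variant core, one 2,000-variant add-on,
eight windows of a quarter of the examples, five core folds, ten random
orderings, and a 100-tree histogram learner; the weighting ablation uses the
default benchmark above with 30 search trials, 5 outer folds, 3 inner folds,
and a reduced search space (trees 60-150, depth 3-5, learning rate 0.05-0.3,
learner-only for the unweighted arm plus one logistic triple on the
contaminated set's property for the weighted arm — the property the window
screen flags). The weighted arm's selector uses a window equal to the trial
count (a single block, i.e. best-validation selection), appropriate at 30
trials.

## Known limitations

- The moving-window Z is exchangeable under the null (see above), so its
  false-positive rate at |Z| > 1 is ≈ 1/3 per screen regardless of
  problem size; multiple candidate properties should be read as a ranking.
- With 30 trials the tuner recovers the sign and rough shape of the
  contaminated set's weight function but not precise parameter values;
  parameter *recovery* claims are limited to the decile ordering the tests
  assert.
- The closed-form and pointwise AUBPRC estimators genuinely differ on
  stepped curves; published figures computed with one are not exactly
  comparable to the other. Both are always reported.
- Bootstrap comparisons redraw until both classes appear, slightly biasing
  resamples at extreme priors.
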