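# Methods

## The model

`cgpromoter` treats promoter recognition as binary classification of
fixed-length DNA windows. Its three scientific components are the
statistical-parameter encoding, the redundancy-aware feature filter, and a
tuned random forest; everything else (I/O, splitting, metrics) is protocol.

### Positional dinucleotide-statistics encoding

A window of length L contains L−1 overlapping dinucleotide steps. Rather
than carrying all K physicochemical property values per step (K = 90 in
the standard published table), each of the 16 dinucleotides is summarised
once as the 5-vector (min, max, mean, variance, sum) of its property row,
and a sequence is the position-wise concatenation of these 5-vectors:
5(L−1) features, 400 for L = 81. The encoding is a pure table lookup —
at most 16 distinct 5-vectors appear anywhere — so its discriminative
power comes entirely from *which* dinucleotide sits at *which* position.
Feature ids (`pos017_var`) make the position-major, stats-minor layout
auditable; dinucleotide i covers bases i and i+1, 1-based.

Two genuinely open choices are exposed as flags, defaults documented here:

- **Variance denominator** (`sample_variance`, default off): population
  variance (divide by K) is used because it is the descriptive-statistics
  reading of "variance of the K property values" and keeps a constant
  property row at exactly 0. The K−1 form is available for sensitivity
  analysis.
- **Property standardization** (`standardize`, default off): the
  statistics are computed on the property values as distributed, since the
  distributional differences between dinucleotides (CG lowest, TA highest,
  different spreads) are the signal being summarised. A z-scoring flag
  exists because some published tables ship pre-normalised.

### ANOVA + first-level-pair feature selection

Each feature gets a two-group one-way ANOVA F value, F = MS_between /
MS_within with df (1, n−2), computed from explicit sums of squares.
Degenerate columns are resolved deterministically: a feature constant
across all samples has 0/0 and is assigned F = 0 with a logged warning; a
feature with zero within-class variance but distinct class means separates
the classes perfectly and is assigned a +inf sentinel that outranks every
finite F (two sentinels tie).

Features (not samples) are then clustered agglomeratively. A *first-level
pair* is read structurally from the full linkage tree: any merge whose two
children are both leaves. This matches the pairing arithmetic (2·pairs +
singletons = d, retained = d − pairs) rather than a fixed-cluster-count
cut, which would not guarantee two-member clusters. Within each pair the
larger-F member is kept; exact ties are broken by a seeded uniform coin,
with the seed and every decision recorded in the JSON selection report.

Three clustering axes are configurable because no single convention is
canonical:

- **Linkage** (default Ward) and **metric** (default Euclidean; Ward
  requires it). Ward/Euclidean is the common default of mainstream
  agglomerative-clustering implementations. `complete`, `average`,
  `single` and correlation distance are available.
- **Feature scaling before clustering** (default on): each feature column
  is z-scored across samples. The five statistics live on wildly
  different scales — the sum features are ~K times the means — so raw
  Euclidean distances would pair almost exclusively by the sum block.
  This is the largest replication risk of the whole pipeline and is
  logged in every selection run; `--no-scale` disables it.

### Random forest and grid search

The classifier is a Gini-criterion random forest
(scikit-learn `RandomForestClassifier`, seeded). The default search grid
is n_estimators 80–150 step 5, max_depth 15–20, min_samples_leaf 1–8,
min_samples_split 2–5, max_features fraction 0.1–1.0 step 0.1 — all
endpoints inclusive, 15·6·8·4·10 = 28,800 combinations. The sub-unit
max_features value is interpreted as a fraction of the feature count,
resolved as ceil(fraction·d) features per split (at least 1).

Each combination is scored by the mean of a chosen objective (accuracy by
default; MCC and AUC available) over stratified five-fold
cross-validation; folds are assigned per class by seeded shuffle and
round-robin, so per-class fold sizes differ by at most one. Ties on the
mean objective go to the earliest combination in canonical enumeration
order — fewer trees, then shallower depth, then lexicographic on the
remaining axes — making the search deterministic given its seeds. The full
grid is expensive (tens of CPU-hours at realistic n); the CLI defaults to
a reduced grid and puts the full search behind `--grid paper-defaults`.

The fitted model is serialized as a joblib binary plus a JSON sidecar
(hyperparameters, training feature ids, seeds, and a SHA-256 of the
selection report it was trained behind); prediction refuses a selection
report whose hash does not match, and realigns — never silently accepts —
permuted feature columns.

### Evaluation

Sn, Sp, Acc and MCC are computed exactly from the confusion table; MCC is
set to 0 with a warning when any denominator factor vanishes. Reports
print two-decimal percentages (MCC included, per the field's reporting
convention) while machine outputs keep raw fractions. ROC curves sweep
the unique score thresholds; tied scores collapse into single steps, so
the trapezoidal area equals the probabilistic AUC
P(s⁺ > s⁻) + ½P(s⁺ = s⁻). Cross-validated reports give one metric row
per fold plus their arithmetic mean; because per-fold AUC and the AUC of
all pooled held-out scores answer different questions, both are emitted.

## Synthetic data: what it emulates and what it does not

The generator emulates the contrast between real promoter windows and
length-matched genome fragments at desk scale. Positives receive a
consensus box (default TATAAT, the sigma-70 −10 element analogue) at a
fixed offset (default 60 of an 81 bp window, placing it near where the
−10 element sits when the window ends shortly after the transcription
start), with independent per-base corruption: each motif column matches
the consensus with probability `match_prob` (default 0.95), otherwise the
background base stays. Negatives are i.i.d. background — uniform by
default, with a preset matching the ~53.8% GC content of the
*C. glutamicum* genome. Property tables are drawn per dinucleotide as
Normal(locᵢ, scale) with locᵢ ~ Normal(0, loc_spread), giving the
controlled between-dinucleotide separation that real physicochemical
descriptors show; pathological variants (constant rows, duplicated rows)
exercise encoder edge cases.

Default study sizes are 200+200 sequences — large enough that a strongly
planted motif is learned nearly perfectly and a null spec sits at chance
within ±5%, small enough that the full pipeline runs in seconds.

What passing tests on this generator show: that the encoding transmits a
positional compositional signal, that ANOVA ranks motif-overlapping
features highest, that selection halves paired features without losing
the signal, and that the protocol's bookkeeping (splits, folds, metrics)
is exact. What they do not show: performance on real promoters, whose
signal is degenerate, position-variable, strand-asymmetric and entangled
with genome-wide composition — none of which the i.i.d.-plus-one-box
model imitates. Reported CV numbers on real data therefore cannot be
inferred from synthetic runs.

## Numerical choices and degenerate inputs

- Stratified 8:2 splitting is per class (floor rounding of the test
  share, remainder to train), since pooled splitting would only
  approximate per-class balance. The test share is rounded before
  flooring so binary-float ratios (1000 × 0.2) cannot drop a record.
- z-scoring (encoder and selector) maps zero-spread columns to 0 rather
  than dividing by zero.
- ANOVA requires both classes present with ≥ 2 members each (the
  within-class mean square needs df ≥ 2 overall).
- Correlation distance on a constant column is non-finite and rejected
  with a diagnostic rather than propagated.
- Empty datasets, mixed sequence lengths, non-ACGT characters (default:
  abort naming the record; optional drop-with-warning), missing or
  duplicate dinucleotide rows, and feature-id mismatches all fail fast
  with specific errors.
- All randomness — splits, fold assignment, forest bootstrap, tie-breaks,
  synthetic draws — flows from named integer seeds recorded in run
  manifests and artifacts.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data:
oracle comparisons use matrices up to 30 × 12 (selection) and n = 200
(AUC); end-to-end runs use 200+200 sequences of 81 bp with K = 90 and the
reduced grid. These sizes were chosen so the signal regimes of interest
(strong motif vs null) are unambiguous while a full run stays in the
seconds-to-minutes range.

## Known limitations

- Only dinucleotide (k = 2) encodings; no pseudo-nucleotide composition
  variants, no reverse-complement augmentation.
- First-level pairing only; no recursive multi-level pruning, no MRMD.
- The comparison classifiers one might benchmark against (KNN, SVM, MLP)
  are not implemented.
- Exact replication of any externally deposited feature subset may
  require toggling the documented flags (variance form, standardization,
  linkage, scaling), since those conventions vary between toolchains.
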