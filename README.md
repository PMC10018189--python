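# cgpromoter

Promoter prediction for *Corynebacterium glutamicum* — the industrial
amino-acid producer whose promoters are still mostly annotated by laborious
sigma-factor experiments. `cgpromoter` classifies fixed-length DNA windows
(81 bp by convention) as promoter or non-promoter from the physicochemical
character of their dinucleotide steps, for anyone screening candidate
regulatory regions or strain-engineering promoter libraries in GC-rich
actinobacteria.

## Method

**Encoding.** A sequence *s* of length *L* is read as its *L*−1 overlapping
dinucleotides *a*₁…*a*₍L−1₎. Each of the 16 dinucleotides carries *K*
published physicochemical property values (twist, rise, hydrophilicity, …;
*K* = 90 in the standard table), summarised once per dinucleotide as

  *aᵢ* → (p_min, p_max, p_mean, p_var, p_sum)

over its *K* properties. Concatenating the 5-vectors position by position
gives a (L−1) × 5 descriptor — 400 features for an 81 bp window.

**Feature selection.** Each feature *j* gets a two-group one-way ANOVA
F value, F = S²_B / S²_W (between- over within-class variance, df 1 and
n−2). The feature columns are then clustered agglomeratively (Ward linkage
on Euclidean distance over z-scored columns by default); every merge of two
original features is a *first-level pair* of near-redundant columns, and
only the pair member with the larger F is kept. Unpaired features survive
outright, so d features become d − (#pairs).

**Classifier.** A Gini random forest, grid-searched over
n_estimators 80–150 (step 5), max_depth 15–20, min_samples_leaf 1–8,
min_samples_split 2–5 and per-split feature fraction 0.1–1.0 (28,800
combinations) by mean accuracy under stratified five-fold cross-validation.

**Evaluation.** Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy, Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)), and trapezoidal
ROC/AUC, reported per fold, as a fold mean, and on a held-out independent
split.

A synthetic-data module generates seeded property tables and labeled
sequence sets with a planted consensus box (TATAAT-style, per-base
corruption) so the whole pipeline is exercisable without any download.

## Worked example

One command simulates a study, encodes it, selects features, tunes and fits
the forest, and evaluates both by cross-validation and on an untouched
20% independent split:

```
cgpromoter --seed 1 --out-dir demo pipeline --n-pos 100 --n-neg 100
```

prints (plus a `metrics_report.tsv`, a selection report and the model
artifact in `demo/`):

```
                 Sn      Sp     Acc     MCC     AUC  AUC (pooled)
fold 1        93.75  100.00   96.88   93.93  100.00           NaN
fold 2        93.75   93.75   93.75   87.50   99.22           NaN
fold 3       100.00  100.00  100.00  100.00  100.00           NaN
fold 4       100.00  100.00  100.00  100.00  100.00           NaN
fold 5       100.00  100.00  100.00  100.00  100.00           NaN
mean          97.50   98.75   98.13   96.29   99.84         99.86
independent   90.00   95.00   92.50   85.11   98.25           NaN
retained 283 of 400 features; best params {'n_estimators': 80, ...}
```

Rows are percentages: each fold's Sn/Sp/Acc/MCC/AUC on its held-out fifth
of the training split, their arithmetic mean (with the AUC of all pooled
held-out scores), and the final model's performance on the independent
split it never saw. The synthetic positives carry a strongly planted
TATAAT box, so near-ceiling numbers are expected; 283 of 400 features
survive because 117 first-level pairs each lost their lower-F member.

Metric arithmetic can also be checked directly from printed confusion
counts — e.g. 181/200 promoters and 174/200 non-promoters correct:

```
$ cgpromoter evaluate --counts 181,26,174,19
Sn      Sp      Acc     MCC
90.50   87.00   88.75   77.55
```

Every stage is also available as its own subcommand (`simulate`, `encode`,
`select`, `train`, `evaluate`, `predict`) on standard FASTA/TSV/JSON files,
and as plain library functions (`cgpromoter.encode_dataset`,
`cgpromoter.select_pipeline`, …).

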