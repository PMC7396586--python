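# Methods

## Feature extraction

Transcripts enter as FASTA records whose headers optionally carry genomic
coordinates (`>name chrom start end strand`, 1-based inclusive — the
circBase convention). All interval arithmetic inside the package uses BED
semantics (0-based half-open); the conversion happens exactly once, in
`seqio`, to prevent off-by-one drift. Sequences are upper-cased, U is
mapped to T, and any other non-ACGT character rejects the record outright
rather than being masked — a transcript with ambiguity codes is not a
valid input to composition features. Records without coordinates are
accepted, but every coordinate-dependent feature (conservation, ALU, SNP,
A-to-I) is 0 for them and a warning is logged.

### Composition (70 features)

The 64 overlapping trinucleotide frequencies (counts divided by the
window count, len − 2; all zero below 3 nt), sequence length in nt, GC
fraction, and the frequencies of AG, GT, AGGT and GTAG. Motif frequency
is defined as overlapping occurrences divided by the number of windows of
the motif's length (len − m + 1); this denominator choice is ours — only
the motif list itself is fixed by convention.

### Graph features (101)

Secondary-structure graph-kernel features are *ingested, never computed*:
the upstream kernel produces a 32,768-dimensional vector per transcript
and published work reuses a random-forest importance ranking to keep the
top 101 columns. The contract here is therefore (matrix, ranking list) →
top-k columns in ranking order, with k = 101 by default. The synthetic
generator fabricates stand-in matrices of configurable width (≥ 101) with
a seeded ranking permutation.

### Conservation (12 summaries)

Per-base phyloP-style scores are resolved over the transcript span from a
bedGraph track; positions without coverage score 0.0 (configurable on the
track). The block always contains the seven canonical statistics — mean,
maximum, variance, and the fractions of bases with score > 0.3, > 0.6,
> 0.9 and < 0.9 — and is padded to the conventional 12-statistic width
with min, median, standard deviation and the fractions > 0.1 and > 0.5.
Which five statistics originally completed the block of 12 is not
recoverable from the literature; our padding is a documented assumption
and each statistic is individually switchable in `ConservationConfig`.
A span with zero coverage yields an all-zero block (rather than the
degenerate "fraction < 0.9 = 1" that literal evaluation of the filled
zeros would give), matching the coordinate-free case.

### ATOS and the three newer features

ALU-repeat count and SNP count come from BED-interval overlap (an
interval counts if it intersects the span by ≥ 1 base); SNP and A-to-I
densities divide the count by sequence length. The longest ORF scans the
three forward frames only — transcripts are sense-strand sequences — for
ATG to the first in-frame stop, stop codon included in the length; ORF
propensity is that length over the transcript length. Tandem-repeat
frequency uses a built-in detector (maximal runs of a 1–6 nt unit with at
least 2 full copies and ≥ 6 nt total, counted once per span at its
primitive period, divided by sequence length); an external repeat
finder's region count can be supplied per transcript and then replaces
the detector. The IRES score is always externally supplied (clipped to
[0, 1], 0 when absent): re-training an IRES predictor is out of scope, so
the feature is an ingestion point with a neutral default. "Frequency" of
tandem repeats is interpreted as a per-nucleotide rate, configurable.

### Assembly and normalization

`assemble_circlgb` emits 70 + 101 + 12 + 5 = 188 features (baseline) or
191 with A-to-I count, A-to-I density and IRES appended (full);
`assemble_circmrt` emits 71 + 101 + 7 + 3 = 182 (sequence, graph,
genome-context, regulatory groups), where genome context is conservation
mean/SD, ALU count, SNP density, A-to-I count, and the back-splice
junction and miRNA-binding-site flags, and the regulatory group is the
TF, methylation and H3K27ac flags. Missing annotations encode as 0. Every
feature is min–max scaled to [0, 1]; `normalize(table, fit_rows)` fits
min/max on a caller-chosen row subset (training rows, to avoid leakage
into held-out folds) and the stored parameters are reusable on new rows
with clipping; constant features map to 0. Assembly normalizes over all
assembled rows by default (`do_normalize=False` defers the choice).

## Feature optimization

mRMR ranking uses the greedy MID (difference) scheme: the first pick
maximizes relevance I(f; y); each later pick maximizes I(f; y) −
mean I(f; s) over already-selected s. MID rather than the quotient
variant because it is the canonical default and division-safe. Mutual
information is computed on equal-frequency 5-bin discretizations
(columns with ≤ 5 distinct values are used as categories directly, so a
binary feature's relevance is exactly the label entropy when it equals
the label); ties in binning break by value-then-input order and ties in
the greedy argmax break by input column order, so the ranking is
deterministic without a seed.

The sequential forward search evaluates each ranked prefix k = 1..K by
mean MCC under repeated stratified k-fold cross-validation and returns
the *smallest* k attaining the maximum (parsimony at ties), together
with the full MCC trace. A fold whose test split contains one class
scores MCC 0 — consistent with the metrics module's 0/0 convention — so
degenerate folds never abort a search. `max_k` truncates the search when
only the head of the ranking is of interest.

## Models

The main classifier is LightGBM with the tuned configuration
learning-rate 0.1, 60 leaves, feature fraction 0.5, bagging fraction 0.6,
L1 0.01, L2 0.001, binary objective, AUC metric, 100 boosting rounds and
early-stopping patience 10 (active when a validation table is supplied).
Six comparison learners are library-backed behind the same interface:
GBDT, XGBoost, random forest (20 trees), linear SVM (C = 1.0, from the
grid 1.0–1.4), SGD logistic regression and Gaussian naive Bayes. All run
single-threaded with fixed seeds; LightGBM additionally sets
`deterministic=True` and `force_row_wise=True`, so every fit is
bit-reproducible.

Hyperparameter search mirrors the batched protocol: (learning rate ∈
{0.01–0.1 by 0.01, 0.2}, leaves ∈ {20–50 by 5}) first, then the two
sampling fractions ∈ {0.5–0.9}, then the two regularizers ∈ {0.001,
0.01, 0.03, 0.05}, each batch scored by 5-fold CV AUC with winners
carried forward. Note the tuned 60-leaf optimum lies outside the printed
leaf grid; we keep both the printed grid and the printed optimum as
defaults rather than reconciling them.

The interaction ensemble holds three binary classifiers with per-class
tuned configurations (leaves 20/40/35, feature fraction 0.6, bagging
0.6/0.6/0.5, L1 0.01/0.001/0.01, L2 0.03/0.001/0.01) and per-class
optimal-feature lists (conventional sizes 21/26/15; on synthetic data the
lists come from a fresh SFS run). Fusion of the three probabilities is by
*union* by default: every class whose probability reaches the threshold
(0.5, configurable) is assigned, so zero, one, or several labels are
possible — matching the observation that one circRNA can interact with
both miRNA and RBP. A majority mode (single top-probability label when ≥ 2
classifiers fire, union semantics otherwise) is provided because the two
fusion descriptions in the source material conflict; union is the default
since multi-label outputs are documented behavior. Union fusion is
monotone: raising any probability can only add labels.

Data splits are stratified 75/10/15 (tool-comparison mode) or 60/20/20
(independent-test mode), seeded. Cross-validation is repeated stratified
k-fold (5 folds × 10 repeats by default), with repeat r reseeded as
seed + r.

## Metrics

SE = TP/(TP+FN), SP = TN/(TN+FP), PRE = TP/(TP+FP),
F1 = 2·SE·PRE/(SE+PRE), ACC = (TP+TN)/N and the MCC, with every 0/0 case
defined as 0 so degenerate folds are scored, not fatal. (Two of the
printed formulas in the source literature — SP with TP+FP in the
denominator, F1 written with "SN"/"FRE" — are treated as typographical
errors and implemented in their standard forms.) AUC uses the
rank/trapezoid formulation with midrank tie handling; the test suite
checks it against an O(n²) pairwise-concordance oracle.

## Synthetic benchmark

The generator defines the study conditions for all tests:

* **Sequences** — 300 transcripts per class by default, lengths uniform
  in 200–1200 nt (nothing shorter than 200 nt, mirroring the standard
  length filter for circRNA/lncRNA collections), drawn as i.i.d.
  trinucleotides; class 1 perturbs the uniform trinucleotide distribution
  multiplicatively by δ with a fixed alternating pattern. δ = 0.5 was
  fixed once by `scripts/calibrate_synth.py` (composition-only held-out
  AUC ≈ 0.99 at the default sample size; δ = 0 gives chance).
* **Tracks** — Poisson-placed 1-bp sites at 2 / 10 / 5 expected sites per
  kb for ALU / SNP / A-to-I, with an optional class-dependent density
  multiplier to plant signal in overlap features; conservation is
  piecewise-constant uniform [0, 1] over 50 nt segments.
* **Planted-signal tables** — standard-normal columns with a subset mean-
  shifted by the effect size in class 1 (5 informative among 50 by
  default). The effect size 1.25 was calibrated by the same script as the
  smallest value at which a default LightGBM reaches held-out AUC ≥ 0.9
  across seeds and the optimizer recovers all planted columns.
* **Interaction datasets** — three single-label pools whose training
  tables pair each class's transcripts with another class's transcripts
  as negatives (miRNA vs TR, RBP vs TR, TR vs a miRNA/RBP mix —
  reproducing the cross-class negative scheme of the real corpora,
  including its property that negatives carry their own class's planted
  signal), plus an independent test set containing fresh single- and
  two-label transcripts.

What the benchmark does *not* emulate: real back-splice sequence context,
realistic phyloP score distributions, linkage between tracks and sequence
content, or graph features with biological meaning. Passing tests
therefore demonstrate that the machinery — extraction arithmetic,
optimizer, models, fusion — behaves correctly and recovers known signal;
they say nothing about classification accuracy on real transcripts, which
depends on downloading the real corpora and computing real graph
features.

## Numerical and design notes

* Determinism: every stage is a pure function of (inputs, config, seed);
  seeds below 2³¹; single-threaded by default. Parallelism is
  deliberately not enabled anywhere results could reorder.
* Degenerate inputs: sequences shorter than a window yield zero-valued
  frequency features; empty tracks yield zero counts; constant features
  normalize to 0; single-class training labels raise.
* The acceptance script scales repeated CV to 2 repeats and SFS CV to 3
  folds × 1 repeat (full 10-repeat CV is the library default) — the
  package's own choice of problem size for a from-scratch reproduction
  that completes in about a minute.
* Known limitations: the tandem-repeat fallback is a simple run detector,
  not a full alignment-scored repeat finder; IRES has no built-in
  predictor; graph features must be provided externally; the mRMR
  discretization (equal-frequency, 5 bins) and variant (MID) are
  config-exposed assumptions where the literature is silent.
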