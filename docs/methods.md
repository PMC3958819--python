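# Methods

## Sequence model

Input windows are DNA strings over {A,C,G,T}; anything else — including N
and the other IUPAC ambiguity codes — is rejected per record rather than
skipped, because one undefined base corrupts every overlapping 3-mer and
every codon it touches. Lowercase input is accepted and upcased;
whitespace inside sequence lines is stripped before validation.

The encoder produces, for a window of length L:

1. **Trinucleotide composition.** All L−2 overlapping 3-mer windows are
   counted and divided by the window count, giving 64 frequencies in
   lexicographic order (A < C < G < T) that sum to exactly 1. Overlapping
   counting is the standard convention for nucleotide composition and is
   required for the simplex normalization below.
2. **Translation.** Codons are read in frame 0 on the given strand in
   non-overlapping triplets; 1–2 trailing bases are discarded. Because
   the windows are genomic rather than coding, stop codons (TAA, TAG,
   TGA) carry no residue: they are **removed from the chain** — not used
   to truncate it, which would discard most of a ~1 kb window, and not
   retained as a 21st symbol, which the property table could not serve.
   The effective chain length L* used everywhere downstream is the
   stop-free length. This policy is a deliberate design choice for
   non-coding DNA and the single place where reasonable implementations
   of this encoding can differ.
3. **Correlation tiers.** θ_k averages the pairwise property distance
   Θ(a,b) (mean squared difference of six standardized physicochemical
   properties) over all residue pairs k apart, for k = 1..λ. The tier
   sum pattern fixes the k-th tier's upper summation bound at L*−k.
   Computing θ requires λ < L*, i.e. a DNA window of at least 3(λ+1) nt
   plus any stop-codon loss; shorter windows raise a sizing error that
   reports the minimum.
4. **Assembly.** The 64 frequencies and the w-weighted tiers share the
   normalizer 1 + w·Σθ, so every encoded vector is nonnegative and sums
   to 1 (verified to 1e−12 in tests over thousands of random windows).

Defaults λ = 5 and w = 1.1 are the published operating point of the
original benchmark study and are kept as package defaults.

## Property standardization

The six raw scales (hydrophobicity, hydrophilicity, side-chain mass, pK1,
pK2, PI) are column-standardized over the 20 amino acids using the
**sample** standard deviation (n−1 = 19 denominator). The convention is
pinned empirically: the raw hydrophobicity scale already has zero mean and
unit sample SD, so only the n−1 convention leaves it unchanged, matching
the published 2-decimal table; the population SD would shift A's 0.62 to
≈0.64. Downstream computations use the freshly computed full-precision
values; the rounded 2-decimal rendition is retained
(`standardized_table(rounded=True)`) as a cross-check and for
compatibility experiments, since whether the original study used rounded
or unrounded values downstream is not knowable. Standardization is
idempotent and refuses constant columns.

## Classifier

scikit-learn's `SVC` (the libsvm engine) with an RBF kernel; labels are
+1 hotspot / −1 coldspot, a decision score > 0 means hotspot, and a score
of exactly 0 resolves to coldspot (deterministic, conservative).

**Feature rescaling.** Before the kernel, each feature is min-max rescaled
to [0,1] with offsets/spans fitted on the training split and stored in the
model. This step is load-bearing. The raw encoded components live on very
different scales — composition entries are O(10⁻³..10⁻²) while tier
entries are O(10⁻¹) — and all pairwise squared distances between raw
vectors are ~10⁻⁴. At γ of order 1 an RBF kernel over such vectors is
numerically constant, the decision collapses toward the training majority
class, and leave-one-out — where the held-out sample's class is always the
training minority — anti-learns to 0% accuracy even on strongly separated
data. With [0,1] rescaling (the standard libsvm preprocessing
recommendation) the default operating point C = 32, γ = 0.5 behaves well:
jackknife accuracy 1.0 on GC 0.3-vs-0.7 synthetic classes and ~0.5 on
null data. The [0,1] range was chosen over [−1,1] and z-scoring after
comparing all three on synthetic validation sets; [0,1] keeps typical
squared distances of these 69-dim vectors in the O(1–10) band where
γ = 0.5 is informative.

**Grid search.** Exhaustive CV accuracy over the conventional log2 grids
C ∈ {2⁻⁵..2¹⁵}, γ ∈ {2⁻¹⁵..2³}, stratified folds fixed by a seed so every
grid point sees identical splits; ties break toward the smallest C, then
the smallest γ, making the search reproducible. Caveat: on easily
separated data many grid points tie at the maximum, and the small-(C, γ)
preference can select a near-flat kernel that aces balanced K-fold splits
(it degenerates to a nearest-centroid rule) yet degrades under
leave-one-out's systematic one-sample imbalance. Re-checking the chosen
point on fresh folds, as `examples/04_grid_search.py` does, is recommended.

## Evaluation

Sn, Sp, Acc and MCC are computed from the 2×2 confusion table; the
miss-count identities Sn = 1 − N⁻⁺/N⁺ and Sp = 1 − N⁺⁻/N⁻ are asserted
against the ratio forms on every call, and the agreement is additionally
verified exhaustively over all tables with margins ≤ 20. MCC uses the
standard product-of-marginals formula; when a marginal is zero MCC is
undefined and reported as 0 with an explicit flag. (The intuitive
miss-count rendition of MCC circulating in the applied literature is
internally inconsistent in its boundary cases, so it is not used.)

The jackknife trains on all samples but one and predicts the held-out
sample, for every sample, with (C, γ) held fixed across folds — no nested
re-optimization — so the outcome is unique for a dataset. A fold whose
training split degenerates to a single class is surfaced in the
per-sample report and excluded from the aggregate; if that leaves an
entire class unevaluated the aggregate metric set is reported as
undefined. Stratified K-fold (seeded) is provided as the cheaper
subsampling test and reduces exactly to the jackknife at folds = n.

## Synthetic data generator

The generator emulates a two-class benchmark of genomic windows whose
classes differ in composition. Each class is sampled from a first-order
Markov chain whose stationary base frequencies follow the class GC
content (A/T and C/G split evenly) and whose rows can be blended toward
self-transition (`persistence`) to inject dinucleotide structure beyond
mononucleotide content. Lengths are uniform over 300–3000 nt by default,
matching the scale on which recombination events concentrate. Sequences
are reproducible byte-for-byte from the spec and seed.

What it does **not** emulate: real hotspot biology — motif content
(hotspots lack a consensus), chromatin context, GC-biased gene conversion,
or phylogenetic correlation between windows. Passing the synthetic
pipeline checks therefore demonstrates that the encoder captures
composition signal and that the machinery is sound, not that the
advertised benchmark accuracies transfer to any particular genome.

## Problem sizes and numerics

The bundled checks run the full pipeline at 30 sequences per class
(jackknife = 60 model fits) and the encoder contract at 1,000 sequences —
sizes chosen so the whole suite completes in seconds while leaving the
law-of-large-numbers and signal-recovery margins wide. The benchmark
reproduction path (1,081-fold jackknife) is exercised only when the
curated dataset is supplied by the user (`data/benchmark/`), since it is
not redistributable; on one CPU it takes on the order of minutes.

Numerical conventions: encoded vectors are float64 throughout and
bitwise-reproducible; SVM fitting involves no random subsampling; model
serialization (joblib) preserves predictions bitwise; constant features
rescale to 0 rather than dividing by zero.

## Known limitations

* The stop-codon policy and the rounded-vs-unrounded property choice are
  both unstated in the original description of this encoding; either
  choice changes encoded vectors slightly. Both are exposed
  (`translate_dna` reports removed stops; `standardized_table(rounded=…)`).
* Published benchmark figures (Sn 87.14%, Sp 79.59%, Acc 83.72%,
  MCC 0.671) can only be checked with the user-supplied dataset, and
  exact equality additionally depends on the original SVM build's
  scaling convention.
* The predictor is a binary classifier over fixed windows; it does not
  localize hotspot boundaries within a window and offers no probability
  calibration (decision scores are margins, not probabilities).
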