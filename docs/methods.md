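# Methods

## Feature model

A peptide S = A₁…A_L over the standard 20-letter amino-acid alphabet
(alphabetically ordered, A…Y including T) is encoded as dipeptide
frequencies. Three encoders share one surface:

- **Traditional n-gram** (`extract_ngram`): counts of the L−n+1 contiguous
  windows divided by their number. Restricted to n ≤ 2; at n = 3 the
  20³-dimensional space overfits short peptides.
- **k-skip-n-gram** (`extract_skipgram`): for n = 2, every ordered position
  pair (i, j) with interval length DT = j − i − 1 between a_min and k
  contributes the dipeptide A_iA_j; counts are multiset (multiplicity kept)
  and normalized by the multiset size, so a non-empty vector always sums to
  one. For n = 1 the model degenerates to amino-acid composition, since a
  single residue carries no distance.
- **Adaptive variant** (`extract_adaptive`): k set to the sequence's own
  length. Distances above L−2 contribute empty sets, so this is exactly
  "all C(L,2) pairs" and the model is parameter-free — the right default
  for datasets whose lengths vary widely (real CPPs span 5–30 residues, so
  any single fixed k either truncates long-range structure or is undefined
  for the shortest sequences).

Two conventions differ in whether contiguous pairs (DT = 0) belong to the
skip set. The package includes them by default
(`include_zero_distance=True`): the skip model is then a strict superset of
the contiguous dipeptide model, which matches the intent of *adding*
distance information to composition. The flag's `False` setting counts only
DT ≥ 1 pairs for comparison. Both paths are verified against a brute-force
enumerator in the tests.

Index bounds: for n = 2 the pair (A_i, A_{i+a+1}) exists only for
i ≤ L − a − 1; the implementation iterates that tight bound so no index
ever exceeds L.

## Classifier

`ForestModel` wraps a random forest: t trees (default 150, any integer
> 1), bootstrap resampling per tree, and √400 = 20 candidate features per
split (the standard forest default; configurable). The per-tree vote
fraction for the positive class is the prediction score; the reported
confidence is the winning fraction, hence in [0.5, 1], and an exact 50/50
split is resolved to the negative class — the conservative direction when
the positive call would promote a peptide into experimental follow-up.
Models are deterministic given the seed and persist as a versioned bundle
(tree count, seed, feature names, fitted trees) that round-trips through
save/load.

## Evaluation

SE, SP and ACC are percentages; MCC is kept on [−1, 1] (reported MCC values
in this field, e.g. 0.8-ish for a strong predictor on ~900 balanced
samples, are on that scale). When an MCC denominator factor is zero the
value is reported as 0 with a `mcc_degenerate` flag; SE/SP are `None` when
their class is absent.

Cross-validation pools held-out predictions from all folds into a single
confusion matrix before scoring. Pooling (rather than averaging per-fold
metrics) is forced by the jackknife protocol, whose folds hold one sample
each; applying it uniformly makes the jackknife *exactly* k-fold with
k = n, and the test suite asserts that identity bit-for-bit. Folds are
stratified by dealing a seeded per-class shuffle round-robin, so per-fold
class counts differ by at most one. Per-fold model seeds are master seed +
fold index: deterministic overall, independent across folds.

ROC/AUC sweeps all distinct score thresholds and integrates by trapezoid,
which equals the Mann–Whitney pair statistic with ties worth 1/2; the test
suite checks that equality against an exhaustive pair counter. The
tree-count sweep evaluates each t (default 10..500 step 10) with the chosen
validation scheme and recommends the highest-ACC t, ties toward fewer trees.

## Feature ranking

Continuous frequency columns are discretized by Fayyad–Irani recursive
entropy minimization with the MDL stopping rule, the method most attribute
evaluators apply to numeric features; a column whose best split fails the
MDL test collapses to one bin and scores IG = 0. Information gain
IG(x, c) = H(c) − H(c|x) uses base-2 logarithms (bits), so a balanced
binary problem bounds IG at 1. Ranking is descending IG with alphabetical
tie-breaks — fully deterministic. Equal-width binning and other log bases
are deliberate non-defaults; the MDL/bits choice is documented here so its
scores can be compared across datasets.

## Dataset construction

`reduce_redundancy` is a greedy longest-first clusterer: survivors are
pairwise below the identity threshold (default 0.8). Identity is the
length of the longest common subsequence (equivalently, the optimal global
alignment score with match = 1 and mismatches/gaps 0) divided by the
shorter sequence's length. This is deliberately simple and gap-agnostic;
the exact identity definition used by word-filter clustering tools differs
in heuristics, so the `identity` argument is a hook for substituting any
other pairwise definition while keeping the greedy contract (no surviving
pair at or above the threshold, idempotent on its own output).

`generate_negative_pool` draws sequences with length uniform on [5, 50] and
residues i.i.d. uniform over the 20 letters — the minimal-assumption
reading of "randomly generated" negatives. `match_length_distribution`
then samples the pool without replacement so the selection's length
histogram (5-wide bins: (0,5), [5,10), …) is proportional to a target
histogram, with largest-remainder rounding to hit the requested count
exactly; per-bin deviation from the proportional ideal is at most one.

## Synthetic benchmark

`generate_synthetic_benchmark` is the package's study-condition generator.
Positives draw each residue from {R, K} with probability `enrichment`
(default 0.5) and uniformly otherwise; their lengths come from a rounded
normal centred at 16 residues (sd 6) truncated to [5, 30], a unimodal shape
matching the observed length range of validated CPPs. Negatives are fully
uniform and reuse the positives' lengths (shuffled), so length carries no
class signal — the only signal is compositional, with expected positive
R+K fraction `enrichment + (1 − enrichment)·0.1` (0.55 at the default)
against 0.10 for negatives. At `enrichment = 0` the classes are identically
distributed, giving an exact null for calibration tests.

What the generator does **not** emulate: real CPPs have positional motifs,
amphipathic periodicity, and family structure (shared ancestry between
sequences); negatives drawn uniformly are far from the composition of real
non-penetrating peptides. Passing tests on this benchmark therefore
demonstrate that the pipeline recovers compositional signal and is
correctly calibrated under the null — not that it attains any particular
accuracy on biological data.

## Problem sizes and numerical choices

The test suite evaluates the null benchmark at 100 peptides per class and
the enriched benchmark at 200 per class with t = 150 (the default), the
tree sweep at t ∈ {10, 50, 150, 300} with 5-fold CV, and the
jackknife/k-fold identity on 30 samples — sizes chosen so the full
leave-one-out runs remain interactive on a single core. Feature vectors
are validated to sum to 1 within 1e-12. The brute-force oracle sweep covers
the complete 3-letter-alphabet sequence space through length 8 and random
samples beyond, under both zero-distance conventions.

## Known limitations

- The redundancy reducer is O(n²) in sequence count and is intended for
  curating thousands, not millions, of peptides.
- MDL discretization can accept no split on weak-but-real signals at small
  n; such features score 0 and rank alphabetically among themselves.
- Vote-fraction confidences from small forests are coarse (multiples of
  1/t); use more trees when calibrated scores matter.
- Non-standard residues (B, J, O, U, X, Z, modifications) are rejected or
  skipped, never imputed; peptides shorter than 2 residues cannot be
  featurized by any dipeptide model.
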