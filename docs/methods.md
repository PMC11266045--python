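# Methods

## Problem and model

`pspi` classifies peptide sequences of at most 100 amino acids as small
proteins (SPs) or not.  Small proteins were historically excluded by the
≥303 nt open-reading-frame convention of gene callers, so sequence-level
classifiers — which need no genome context — are the practical route to
finding them in fragmented or unassembled prokaryotic data.

The classifier consumes two representations of a peptide:

1. **Padded one-hot coding.** Each position is a 20-dimensional indicator
   of the residue (alphabetical ordinal over the one-letter codes);
   peptides shorter than 100 residues are zero-padded, giving a fixed
   2000-entry binary block.

2. **Gapped (n,k)-mer counts.** An (n,k)-mer is an ordered k-tuple of
   residues at positions `i₁ < … < i_k` with span `i_k − i₁ + 1 ≤ n`.
   Identity is the residue tuple only; the gap arrangement inside the span
   is free.  `ACD`, `AC.D` and `A.C.D` are one (7,3)-mer; `A....C.D`
   (span 8) is not.  This mimics short linear motifs: order-determined
   functional patterns of 3–10 residues in unstructured regions, which is
   why n runs over 3..10.  Counting is by occurrence — every qualifying
   index tuple adds one — not binary presence.  For k ≤ 2 tuples are
   counted over the plain 20-letter alphabet (20^k entries); for k > 2 the
   space would be too large to train on, so residues are first reduced to
   9 physicochemical groups (9^k entries): [AGILPV], [FW], [M], [C], [ST],
   [Y], [DE], [HKR], [NQ].  Note the acidic group is [DE]: a 9-group
   partition of the 20 canonical residues requires glutamate to live with
   aspartate, its closest chemical neighbour.  The default configuration
   is one-hot + (4,2) counts: 2000 + 400 = 2400 features.

The network is an LSTM over the 100 one-hot time steps (20 channels per
step); its final hidden state (default 128 units, grid 16/32/64/128) is
concatenated with the count block — counts carry no order, so they bypass
the recurrence — then dropout (default 0.25, grid 0.25/0.5) and a single
dense unit with a sigmoid produce a score in [0,1].  A peptide is called
positive when its score is ≥ 0.75 (closed at the threshold; configurable).

### Why this input shaping

A recurrent layer needs a time axis, while the flat feature vector
(2000 + counts) has none.  We reshape the one-hot block to 100×20 and
feed only it to the LSTM; the count block joins after the recurrence.
This preserves both printed widths (2000-entry coding, 128-unit summary)
and is the only architecture-sound reading; feeding counts through the
recurrence would impose a fictitious order on them.

### Training

Binary cross-entropy, Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), 20
epochs, batch 64, no early stopping, no class weighting (training sets
are roughly balanced by construction).  Padding positions are all-zero
inputs and are not masked.  The implementation is plain numpy: exact
forward equations, full backpropagation through time, inverted dropout on
the concatenated summary+count vector.  Initialization follows common
recurrent-layer practice: Glorot-uniform input weights, orthogonal
recurrent blocks per gate, zero biases except a unit forget-gate bias.
Correctness of the analytic gradients is pinned by a central-difference
numerical check in the test suite (tolerance 1e-4 relative).  All
randomness — init, batch order, dropout masks — derives from one integer
seed, so a fixed seed reproduces the training log and weights exactly on
a given platform.

## Negative (null) sequences

Two generators, matching the two ways a candidate can fail to be an SP:

* **Permuted ORFs.** The peptide is back-translated choosing each codon
  uniformly from its synonymous set (standard codon table, NCBI table 1;
  bacterial table 11 differs only in initiation codons, which this
  pipeline does not model), a stop codon is appended (uniform over
  TAA/TAG/TGA), the nucleotides strictly between the first codon and the
  final stop are shuffled uniformly at the single-nucleotide level, any
  internal in-frame stop codon is replaced by a uniform draw from the 61
  sense codons, and the result is re-translated.  Length and first
  residue are conserved; amino-acid composition generally is not — that
  is the point of shuffling nucleotides rather than residues, since a
  residue permutation shares the source's composition and could still be
  a real SP.  Because repairs draw from sense codons only, one repair
  pass terminates.  A repaired codon may share letters with the stop it
  replaces, so the internal nucleotide multiset is conserved up to (at
  most) 3 letters per repair.  Codon-level shuffling is available as an
  option but off by default.  Existing ORFs can be permuted directly
  (`permute_orf`), skipping back-translation.

* **Noncoding-RNA fragments.** All input RNA records are concatenated;
  fragment lengths are drawn uniformly on [30, 300] nt walking left to
  right (clamped to the remainder; a final remainder under 30 nt is
  discarded); each fragment is read in frame 0 with a trailing partial
  codon dropped, in-frame stops are replaced by uniform sense codons, and
  translation yields stop-free pseudo-peptides of 10–100 residues.  No
  start codon is prepended.  Frame 0 is an arbitrary but fixed choice;
  fragment boundaries are already random, so the frame adds no
  information.

## Synthetic data

Real SP collections cannot be bundled, so `synthdata` generates labeled
sets with the structure the method assumes.  Positives: 'M'-initial
peptides, lengths uniform on 30–100, residues i.i.d. from a uniform
background composition, then planted ordered pairs — default (C, D) with
span ≤ 4 — overwrite positions at a per-position rate (default 0.3), with
the gap uniform inside the span.  Negatives: 50% permuted copies of the
positives and 50% RNA-derived pseudo-peptides from a random nucleotide
pool, mirroring the finding that training against a single negative
source inflates error against the other.  Train and test splits are built
from disjoint freshly drawn source peptides.  Everything is a pure
function of the seed.

What passing on this data shows — and does not.  The planted-pair
mechanism produces a genuine order-dependent, gap-tolerant signal at the
(n,k)-mer scale, so end-to-end learnability (held-out AUROC ≥ 0.9 at
n=1000/1000, rate 0.3) demonstrates that featurization, training and
evaluation compose correctly.  It does not emulate real codon usage,
phylogenetic redundancy, taxon-specific composition, or the unknown real
SP motif inventory, so synthetic metric values say nothing quantitative
about accuracy on biological data.

## Metrics

Precision, sensitivity, specificity and F1 from the 2×2 confusion table
at the chosen threshold; zero denominators yield 0.0 plus a
`RuntimeWarning` (not NaN) so batch tables stay numeric.  AUROC is the
rank (Mann–Whitney) statistic with average ranks on ties — equal to the
probability a random positive outscores a random negative with ties at ½
— and is cross-checked in the tests against an O(P·N) pairwise oracle.
AUPR is average precision (sum of precision at each positive's recall
step), not trapezoidal PR interpolation, which over-estimates the area;
it is cross-checked against an explicit step-sum oracle.  The ablation
harness trains one model per feature configuration (baseline one-hot,
1-mers, (4,k) blocks, all together) with per-cell fixed seeds and reports
a tidy table.

## Numerical and design choices

* Residue ordinal order is alphabetical; tuple order lexicographic.  Any
  fixed order works, but it is frozen for model-file portability.
* k=1 counts are raw occurrences, not length-normalized frequencies; a
  normalization switch exists, default off, keeping features
  integer-exact against the enumeration oracle.
* Only the total span is constrained in (n,k)-mers (no per-gap bound) —
  the only reading consistent with the span-boundary worked example.
* Model files are a single zip archive holding the config (JSON), the
  training log and the weights, so prediction needs no extra flags;
  loading validates weight shapes against the declared configuration.
* Scores are pure functions of (weights, peptide): batch membership
  cannot change a score.
* Thresholding is closed at the cutoff (score ≥ t ⇒ positive).

## Problem sizes

Unit and property tests use reduced models (4–16 units, ≤ 30 epochs,
tens-to-hundreds of sequences) chosen so the whole non-end-to-end suite
runs in seconds.  The end-to-end learnability check and the acceptance
script use the full default model (128 units, 20 epochs) on 1000+1000
training sequences with a 30% held-out split — a few minutes of CPU —
which is the scale at which the planted-signal conditions are stated.

## Known limitations

* The recurrent layer is CPU-bound numpy; it is deliberately sized for
  desk-scale experiments, not for training on hundreds of thousands of
  sequences.
* Determinism is per-platform (BLAS reduction order may differ across
  builds); within one environment, seeded runs are bit-identical.
* The 0.75 threshold was chosen for prokaryote-style score
  distributions; evaluation on other taxa may warrant retuning, which is
  why every entry point exposes it.
* Ambiguity codes are rejected, not skipped: records containing unknown
  residues must be filtered upstream.
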