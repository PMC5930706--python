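# Methods

## Feature construction

A sequence S of length M over alphabet Σ is mapped to a fixed-length real
vector in three stages.

**k-mer standardization.** A sliding window of length k yields M − k + 1
k-mers, counted into the |Σ|^k lexicographically sorted slots. Each slot is
then z-scored *across the collection being encoded*: S_t = (X_t − X̄_t)/sd_t,
where X̄_t and sd_t are the mean and standard deviation of slot t's count
over all sequences. The standardized profile therefore measures how a
sequence's k-mer usage deviates from the collection norm; it is a relative,
not absolute, representation, and the same sequence encodes differently in
different collections by design. sd uses the sample convention (ddof = 1,
switchable via the `ddof` argument); the choice only rescales slots slightly
and never changed any qualitative result in our tests. Slots with sd = 0
carry no information and are set to S_t = 0 rather than dividing by zero.

**Unit-circle encoding.** The slots are distributed evenly counterclockwise
around the unit circle, slot t (1-based) at φ_t = 360/|Σ|^k · t degrees, and
slot t contributes the pair S_t·(sin φ_t, cos φ_t). Two conventions are fixed
deliberately: t is 1-based (the first slot sits at 360/|Σ|^k degrees, not at
0°), and sine is the *real* part while cosine is the *imaginary* part — the
transpose of the usual complex convention, kept for fidelity to the method's
definition. Because every slot's point has modulus 1, the encoding is an
isometry of the score vector: Euclidean distances between encoded series
equal distances between S_t profiles. The encoded series CODE_S is defined
over the |Σ|^k slots (one complex value per distinct k-mer, zero-count slots
included), *not* one value per sequence position; this is what makes the
representation length-independent and is the pivotal interpretation fixed in
this implementation.

**Stationary Haar transform.** The real and imaginary channels are
decomposed independently with the undecimated (à-trous) Haar transform:
at level j, with stride s = 2^(j−1) and circular indexing,

    approx[i] = (x[i] + x[(i+s) mod N]) / √2
    detail[i] = (x[i] − x[(i+s) mod N]) / √2.

Levels j = 1..L are cascaded on the approximation; all detail coefficients
are discarded; the two channels' level-L approximations are concatenated
(real block first) into the feature vector of length Vec = 2·|Σ|^k. Keeping
only the approximation retains the coarse, smoothed structure of the profile
and discards local/noise detail. Because the transform is undecimated it is
shift-invariant (rotating the input rotates each level's output) and every
level keeps the input length, so N must be divisible by 2^L; with N = |Σ|^k
and the default L = k this always holds for DNA and protein. Boundary
handling is periodic and the neighbour is taken at +stride; any consistent
alignment permutes coefficients without changing Euclidean distances, so the
choice is fixed purely for reproducibility. The orthonormal filter scaling
(1/√2, not the (1/2, 1/2) averaging variant) makes the constant-input
response c·√2 per level and preserves channel energy. The implementation
agrees exactly with PyWavelets' `swt(..., 'haar')` at all tested levels; the
test suite keeps that agreement as an independent cross-check while the
shipped transform remains self-contained.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | ⌈log_\|Σ\|(mean length)/2⌉, min 1 | k-mer window; the default balances slot count against sequence length |
| L | k | SWT decomposition level; deeper levels smooth more aggressively |
| ddof | 1 | sd convention for z-scoring |
| restarts | 200 | k-means random initializations; mean score reported (best-of via flag) |
| repeats | 100 | stratified 80/20 splits for classification; mean metrics reported |

## Frozen statistics

When classifying held-out sequences, slot statistics (X̄, sd) are learned on
the training subset only and reused to encode the test subset
(`SSAWEncoder.fit` / `.transform`). This keeps the encoding a pure function
of the reference statistics and prevents test-set leakage. Whether the joint
or frozen convention is used changes 1-NN decisions only through slightly
different slot weights; the frozen form is the defensible one and is the
default throughout.

## Evaluation statistics

Clustering is scored against known families with the dominating rule: each
cluster j takes the label lb(j) of the family contributing most of its
members (ties to the lowest family index). For family i, precision pools the
clusters labelled i (Σ C_ij over Σ cluster sizes), recall divides the same
numerator by the family size C_i, F(i) is their harmonic mean, and the
overall scores weight families by C_i/C. A family that dominates no cluster
scores zero on all three (its pooled sums are empty; 0/0 := 0). k-means is
Lloyd's algorithm with random data-point initialization (scikit-learn,
`init='random'`, one initialization per restart, max 300 iterations,
tolerance 1e-4), per-restart seeds derived from a master seed; the mean over
restarts is reported, matching the repeated-random-initialization protocol,
with best-of available behind a flag.

Classification is 1-nearest-neighbour under Euclidean distance (distance
ties go to the earliest training index). Accuracy is micro (fraction
correct); precision, recall and F are one-vs-rest per class and
macro-averaged — the averaging convention is a documented choice, and the
per-class values are exposed for any other aggregation. The stratified split
sends ⌈0.8·n⌉ of each class to training with at least one member held out.

## Validity oracles

Levenshtein distance is computed by dynamic programming (row-vectorised with
a running-minimum pass). Needleman–Wunsch identity uses match = +1,
mismatch = −1, gap = −1 — the simplest classical scheme, chosen because no
canonical parameterisation is dictated by the problem — with identity
defined as matches / alignment length and a deterministic traceback
preference (diagonal, then gap in the second sequence). Where several
optimal alignments exist their identities can differ; the deterministic
traceback picks one reproducibly, and the test suite checks the value
against an exhaustive enumeration of optimal alignments. `validity_check`
samples at most 100 sequences (seeded), computes all pairwise SSAW, edit and
identity values, and reports the two Pearson correlations; a valid distance
correlates positively with edit distance and negatively with identity.

## Simulated read generator

The generator plants a known cluster structure: `n_classes` centroid reads
of length `read_length` whose pairwise Levenshtein distance is *exactly*
`centroid_pairwise_distance` (the stricter reading of "distance D among
them"), each with `members_per_class − 1` members within
`max_member_radius`. Defaults — 8 classes × 65 reads of length 47,
separation 10, radius 4 — give 520 reads with disjoint edit balls
(2·4 < 10, so cross-class reads are always ≥ 2 apart by the triangle
inequality).

Centroids are found by seeded local search: a candidate starts as the first
centroid with D substitutions, then single-base moves drive the summed
Hamming deviation Σ|ham − D| to zero (sideways moves accepted with
probability 0.3 to escape plateaus); since Levenshtein ≤ Hamming, a final
dynamic-programming pass verifies every pair exactly and rejects candidates
whose edit distance collapses below D. Attempts are bounded at 10,000.
Members apply r substitutions at distinct positions, r uniform on
{1..radius}, each substituted base forced to differ from the original, and
every member's true Levenshtein distance to its centroid is re-verified.
Substitutions only — no indels — because all reads must keep the configured
length; consequently the generator emulates substitution-type read variation
but not sequencing indels, homopolymer errors, quality structure or coverage
bias. Passing tests on this data demonstrate recovery of substitution-style
edit-distance clusters at short read length, not performance on real
genomic families with length variation.

## Problem sizes and reproducibility

The shipped experiments use the generator's default 520-read dataset, ten
stratified splits for classification and a 100-sequence sample for the
validity correlations — sizes chosen so the whole pipeline, including the
exact edit-distance verification of all 28 centroid pairs and 512 members,
runs in seconds on a laptop while exercising every stage at full fidelity.
All randomness (centroid search, member radii, splits, k-means
initializations, subsampling) flows from explicit integer seeds, and equal
seeds reproduce byte-identical artifacts.

## Known limitations

- Mean 1-NN accuracy on the default simulated data is sensitive to the
  planted centroid configuration (observed ≈ 0.85–0.93 across generator
  seeds at k = 2, L = 2): the level-2 approximation is a four-slot moving
  average that smooths away part of the between-class 2-mer signal
  (pre-transform z-score profiles score ≈ 0.94). Deeper levels trade
  discrimination for smoothness.
- The z-scoring is collection-relative; feature vectors from different
  collections are not directly comparable unless encoded against the same
  frozen statistics.
- The circle places lexicographically adjacent k-mers at adjacent angles, so
  the smoothing mixes slots that are textually, not biologically, similar;
  alternative slot orderings are out of scope.
- Ambiguity codes (N etc.) are rejected by default; `--drop-ambiguous` skips
  affected windows during counting rather than modelling them.
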