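# Methods

## Estimator

A sample is represented by the set of canonical 31-mers it contains.
Canonical means min(kmer, reverse-complement) lexicographically, so
presence is strand-insensitive; any window containing a non-ACGT character
is skipped (no IUPAC expansion), and input is uppercased. Within a sample,
k-mers seen fewer than `min_abundance = 2` times are discarded as likely
sequencing errors.

The source collection becomes a binary matrix `M_s` (K k-mers × L−1
samples), with two cross-sample filters applied to the rows:

* **Partition subsetting.** Each k-mer is deterministically assigned to one
  of `num_partitions` buckets by a salted 64-bit blake2b hash modulo the
  bucket count. Selecting a single bucket yields a reproducible random
  subset of the k-mer space (default 700 buckets, matching the regime in
  which a ~0.1% row subsample already discriminates environments well).
  The buckets are disjoint and jointly exhaustive by construction; a
  chi-square test in the suite checks occupancy uniformity.
* **Recurrence.** Rows present in fewer than `min_recurrence = 3` samples
  are dropped; only recurrent content helps distinguish environments. Toy
  collections in the tests lower this to 2 because they have only 2–3
  samples per class.

Matrices are built from sources only; a sink is vectorized against the
fixed row index afterwards, so the recurrence filter never counts sinks.

Labels live in a fixed ordered class set, default
`(aOral, mOral, skin, sediment/soil)`, one-hot encoded as `H` with
`H[i, j] = 1` iff sample i has label j. The counting step is the integer
matrix product `w = mᵀ · M_s · H`; the suite verifies it against a
brute-force triple loop, and its algebraic consequences (linearity in
source columns, permutation invariance, null-column neutrality,
single-cell monotonicity) are property-tested. Proportions are
`p′ = w / Σw`; when `Σw = 0` the result is null, a `NoMatchWarning` is
emitted and the hard label is `"unassigned"` rather than an arbitrary
class. Argmax ties are broken by class order and flagged explicitly.

The **unknown fraction** — sink k-mers present in no source, whether the
row is absent from the index or all-zero — is reported as a separate
column and never enters the normalization: ball counts are
(k-mer × source) pairs while unmatched k-mers are single k-mers, and
mixing the two scales would make the known-class proportions incoherent.

## Evaluation harness

*Leave-one-out*: each sample in turn is the sink; its column is removed
from the sources and from the one-hot before estimation.

*Group-stratified k-fold*: samples from one group (a BioProject-like
initiative id) never straddle folds, so a sink is never scored against
sources from its own initiative. The splitter is greedy: groups are
processed largest-first (seeded shuffle breaks size ties) and each goes to
the fold whose squared deviation from the ideal per-fold class counts
increases least, with remaining ties resolved toward the smallest fold and
then the lowest index. The group constraint is exact and test-enforced;
the class stratification is best-effort, which is all any group-respecting
splitter can promise.

*Metrics*: accuracy is the global fraction of exact matches; precision,
recall and F1 are one-vs-rest per class, macro-averaged by default
(`average="weighted"` and balanced accuracy are available, since
"averaged across classes" is ambiguous for accuracy). Classes with no
predicted positives get precision 0. `"unassigned"` predictions count as
wrong for every class. The implementation delegates to scikit-learn; the
test suite checks it against an independent hand-written confusion-matrix
oracle on 1000 random label vectors.

*Curves*: one-vs-rest ROC and precision-recall per class, scored by the
class proportion (null proportions score 0 everywhere); the macro ROC
averages per-class TPR on a fixed 101-point FPR grid. Classes absent from
the truth are skipped with a warning.

*Mono/multi-source*: a sample whose top proportion strictly exceeds 0.75
is called mono-source, otherwise multi-source.

## Synthetic collections

The generator emulates the structure the estimator assumes and nothing
more: each environment owns a pan-genome pool of i.i.d. uniform ACGT
sequence (default 100 kb); configured pairs share a contiguous block
(default 10% between adjacent environments, mimicking the observed
aOral/mOral and mOral/skin sharing); each sample draws a random contiguous
80% window of its pool; reads (100 bp, coverage 5) are sampled uniformly
with i.i.d. substitution errors at 0.005 per base, constant FASTQ quality;
mixture sinks allocate reads across pools by largest-remainder rounding of
the weights. Pure samples are assigned round-robin to a configurable
number of pseudo-BioProject groups per environment. Everything is
deterministic given the seed.

What this deliberately does not model: realistic taxonomic composition,
fragment-length and C→T deamination profiles of ancient DNA, indels, and
host contamination. Presence/absence counting is insensitive to where on
a fragment an error falls, so these omissions do not change the logic
under test — but passing tests consequently demonstrate correctness of
the machinery and rank/argmax recovery under the generator's assumptions,
not field performance on real metagenomes.

Because counting is presence/absence over (k-mer × source) pairs,
estimated proportions track shared-k-mer mass rather than read mass and
compress toward uniformity relative to true mixture weights. Tests
therefore assert argmax and rank recovery (e.g. the 0.7 component of a
0.7/0.3 mixture wins in ≥ 95% of seeds), never exact weight recovery.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script run on reduced
collections — pools of 6–12 kb, 2–3 samples per environment, coverage 3 —
chosen so the whole suite completes in well under a minute while leaving
k-mer overlap statistics (thousands of shared 31-mers per pair) far above
noise. The generator's *defaults* keep the full-size values above.

K-mers are packed into 2-bit uint64 codes for extraction; the A<C<G<T code
order makes numeric comparison agree with lexicographic order, so
canonical selection and row sorting are exact. Proportion sums are checked
to 1e−9. The matrix TSV dialect (header `#kmer`, literal 0/1 cells, LF
endings, sorted rows, sidecar metadata TSV and provenance JSON) round-trips
bit-exactly and rejects malformed cells with a line number.

## Known limitations

* Duplicating a source column doubles its class's ball count: the
  estimator is sensitive to per-class source imbalance by design.
* The unknown fraction depends on the recurrence filter (rows dropped from
  the matrix count as unknown), so it is an upper bound on truly novel
  content.
* The hash partitioner reproduces the "random row subset" contract, not
  any particular external tool's minimizer-based partition boundaries, so
  partition contents are not interchangeable with matrices built
  elsewhere.
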