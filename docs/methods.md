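# Methods

## Problem and model

Housekeeping (σ70) transcription in bacteria initiates at promoters whose
distinguishing sequence features are the −35 box (consensus `TTGACA`) and
the −10 box (consensus `TATAAT`), separated by a spacer of roughly 15–19
nt. sig70scan classifies a candidate site purely from the twelve box
nucleotides, one-hot encoded as a 12 × 4 binary matrix with fixed channel
order A,C,G,T (the order is arbitrary but must be identical at training and
prediction time; it is recorded in the model container).

The classifier is a fully connected network with two hidden stages and one
sigmoid output node:

- **Layer 1 ("grid" wiring, default).** A dense 12 → 30 transform applied
  along the position axis independently per one-hot channel:
  H₁ = ReLU(W₁X + b₁) with W₁ ∈ ℝ³⁰ˣ¹², giving a 30 × 4 activation grid
  whose depth of 4 is a remnant of the encoding. The weight matrix is
  shared across channels; the bias is per-unit, broadcast across channels.
- **Layer 2.** The grid is flattened and mapped 120 → 16 with ReLU.
- **Output.** A single sigmoid node, so scores lie strictly in (0, 1).

An alternative "flat" wiring (48 → 120 → 16 → 1, the one-hot matrix
flattened at the input) is available via `NetworkConfig(architecture="flat")`
for users who prefer an unstructured first layer; both have a few thousand
parameters. Scores are nudged inward only at the float-representable edges
of (0, 1) (sigmoid underflows to exactly 1.0 for logits above ~37);
anything stronger would create artificial ties between distinct inputs and
visibly distort the empirical p-value distribution.

## Training

Binary cross-entropy minimised by minibatch Adam (learning rate 10⁻³,
batch 64, up to 50 epochs), with early stopping on a 10% stratified
validation split (patience 5, best-validation weights restored). None of
these values is critical at this problem size; all are exposed in
`NetworkConfig`. Initialisation is He-scaled Gaussian, fully seeded.

**Class imbalance and class weighting.** The training set mirrors genomes:
promoter sites are rare (about 1:96 here). The *data* are left imbalanced,
but the loss weights samples inversely to class frequency (on by default).
The reason is an operating-point argument, not a convergence one: trained
unweighted, the sigmoid output estimates the *imbalanced* posterior, so a
0.5 cutoff corresponds to a likelihood-ratio threshold of ~96 and caps the
true-positive rate well below what the model's ROC supports (for the
synthetic generative model below, the exact posterior itself only reaches
~0.67 sensitivity at that cutoff). With inverse-frequency weighting the
output approximates the balanced posterior and the conventional 0.5 cutoff
becomes a sensible operating point; the genome scanner ignores thresholds
entirely and works on p-values.

Evaluation reports sensitivity TP/(TP+FN) and specificity TN/(TN+FP) —
accuracy would be dominated by the majority class. A rate whose class is
absent is NaN, never 0. Stratified fivefold cross-validation (scikit-learn
`StratifiedKFold`, seeded) trains a fresh network per fold.

## Significance

The p-value of a score *s* is the probability that a random 12-mer scores
≥ *s*, estimated as the tail fraction of a seeded Monte-Carlo sample of
network scores on i.i.d. random sequences (default sample 10⁷, so the
smallest resolvable p is 10⁻⁷; a reported 0.0 means "< 1/N"). Ties count
into the tail; the tail count is a binary search on the sorted sample, and
a (k+1)/(N+1) conservative estimator is available behind a flag. Random
sequences are uniform over A/C/G/T by default; `base_probabilities` admits
a composition-matched null (e.g. 61% GC). The null sample is persisted
(sorted float32 scores + metadata) and fingerprinted to the exact model
weights; a fingerprint mismatch at p-value time is an error, not a warning.
No multiple-testing correction is applied across scanned candidates — the
scan cutoff (default 2×10⁻⁴) is per candidate, a documented limitation.

## Genome scanning

Intergenic regions are the maximal intervals not covered by annotated
gene/CDS features, including contig ends. Every spacer s in 15–19 (the
canonical σ70 range, configurable) and every window of length 12+s yields
one candidate per strand: first six window bases (5′→3′ on that strand) as
the −35 box, last six as the −10 box. Windows containing ambiguity codes
are skipped rather than imputed. Candidates are scored in bounded batches,
filtered at the p cutoff, and overlapping same-strand survivors (midpoints
within 5 nt, configurable) collapse to the lowest-p candidate.

Coordinates are 0-based half-open internally and in BED; GFF3 output is
1-based inclusive. A site starting at internal coordinate 912 is therefore
written with BED start 912 and GFF3 start 913.

## Dataset construction

GenBank extraction pairs each `minus_35_signal` feature with the nearest
strand-aware downstream `minus_10_signal` whose spacer falls in 10–25 nt
(each −10 used once); boxes are read 5′→3′ on the coding strand, minus-
strand features reverse-complemented. Background sampling draws 6+spacer+6
windows uniformly over intergenic space on both strands, spacer drawn from
a configurable distribution (default: the canonical 17 nt, or the empirical
positive-spacer distribution). Positive sites must be unique on their
concatenated 12-mer — the feature the model sees — so a degenerate
generator that cannot supply the requested number of unique positives is an
error rather than a silent duplication.

Dataset QC reports per-class GC content and mean pairwise conservation:
the mean, over unordered pairs of distinct sites, of the number of
positions (of 12) at which two concatenated 12-mers agree, computed from
per-position base counts in O(n·12). For i.i.d. uniform sequences the
expectation is 12 × ¼ = 3; curated *Pseudomonas* promoter sets sit near
5.6/12 with ~47% GC against a ~61% GC genomic background — usefully far
from the 17% GC of the consensus itself.

## Synthetic data generator

The generator emulates those study conditions so the full pipeline can be
exercised and calibrated without redistributing curated data. Defaults: 170
positives and 16,000 background sites. Each positive box position emits the
consensus base with probability w = 0.5811 and otherwise draws from a
background at GC fraction 0.8909; these two numbers were solved jointly
(closed-form expected pairwise-match and GC equations) so the expected
positive statistics are exactly 5.6/12 conservation and 47% GC. The high
off-consensus GC is biologically coherent — deviations from the AT-rich
consensus trend toward the GC-rich genome. Negatives are i.i.d. at 61% GC,
which implies conservation 12·Σp² ≈ 3.15/12, matching the ~3.2/12 level of
real intergenic background. Spacers default to a fixed 17 nt (the network
never sees the spacer sequence, only its length as metadata).

What the generator does **not** emulate: position-specific conservation
structure (real motifs concentrate information at a few positions; the
generator spreads it uniformly), spacer-length/score interactions,
correlations between neighbouring positions, and genuine genomic
repetition. Passing tests on synthetic data therefore demonstrate that the
pipeline recovers a signal of the curated set's aggregate strength and
composition — not field performance on real genomes.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; datasets, training, nulls and scans are reproducible bit-for-bit
  given (inputs, seed).
- Model container: versioned JSON (config + named weight arrays + training
  log + fingerprint), portable across languages; null container: versioned
  `.npz` with sorted float32 scores.
- Held-out checks of synthetic recovery use a fresh, larger draw from the
  same generative model (600 positives / 6,000 negatives) rather than the
  17-positive test split of a 9:1 partition, whose binomial noise (sd ≈ 9
  percentage points on sensitivity) would swamp the property being
  measured. The 9:1 split remains the training workflow.
- Problem sizes in the test suite and acceptance script (null samples
  10⁴–2×10⁵, contigs of a few hundred nt, 10 planted-site fixtures) are
  chosen so the whole suite runs in a few minutes on one CPU while leaving
  every statistical check well-powered.
- Tie-breaks: overlap collapsing prefers lower p, then higher score;
  output ordering is (contig, start, strand); `evaluate` calls a site
  positive when score > threshold (so threshold 0 calls everything
  positive).
- Degenerate inputs: empty sequences, ambiguity codes, single-class
  datasets, fully annotated contigs, undersized null samples and empty
  spacer ranges all raise typed errors with the offending item named.

## Known limitations

Only the 12 box nucleotides are modelled — no UP element, extended −10, or
spacer composition. The classifier is specific to the composition contrast
it was trained on; retraining is required for other genera or sigma
factors. Empirical p-values inherit Monte-Carlo error O(1/√N) and are
uncorrected for multiple testing across a genome scan.
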