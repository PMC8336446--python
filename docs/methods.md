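# Methods

## Problem setting

Enrichment-based epitranscriptome profiling yields intervals ("peaks") that
contain at least one modified nucleotide at roughly 100–300 nt resolution.
Labels therefore exist at the region level only. peakmil formulates site
prediction as multi-instance learning (MIL): a peak or matched negative
region is a *bag* with a binary label; the overlapping windows cut from it
are *instances*; a positive bag is assumed to contain at least one
signal-carrying (witness) instance, while every instance of a negative bag
is negative.

## Bags and instances

A window of length `c` slides with stride `s` over a bag of length `l`,
giving `K = ceil((l - c) / s) + 1` instances. Window `i` starts at
`min(i*s, l - c)`: when `l - c` is not divisible by `s` the last window is
clamped to end exactly at `l`, so every instance lies on real sequence (the
alternatives — dropping the partial window or padding the bag — lose signal
or fabricate sequence). Defaults `c = 50`, `s = 10` trade localization
resolution against the number of highly correlated instances.

One-hot channels are ordered A, C, G, U; T is aliased to U at ingest so
genomic FASTA works directly, and N becomes an all-zero row (absence of
information). Bags with more than 10% N are rejected at ingest
(configurable). Minus-strand regions are reverse-complemented before
encoding, so all sequences are in transcript orientation.

## Dataset construction from peaks

Negatives are sampled only from non-peak territory of peak-carrying genes —
using genes without peaks would confound the label with expression — with
lengths drawn from the positive-length multiset so the two classes match in
width. Two validation constructions probe localization without
base-resolution truth:

* **peak margins**: 600 nt straddling each peak boundary, 300 nt inside and
  300 nt outside. The modification should fall in the known (peak-side)
  half: the second half for a 5′ margin, the first half for a 3′ margin.
  5′/3′ are transcript-strand notions, so for a minus-strand peak the
  genomic-left margin is the 3′ margin.
* **centered sites**: where single-base truth exists, 601-nt sequences with
  the known site at offset 300.

All interval logic is 0-based half-open (BED convention), and extraction is
genomic-linear (no exon-aware projection of peaks to transcript space).

## Network

Each instance is encoded by a shared-weight stack: convolution (32 filters,
width 15 nt) → ReLU → max-pool (width 4) → dropout 0.2 → convolution
(32 filters, width 5) → ReLU → global max-pool, giving a 32-dim embedding
`h_k`. The first convolution scans for motifs; the second captures local
dependencies among them; global max-pooling makes the embedding a
motif-presence summary. These sizes are deliberately small — they train on
a single CPU in seconds — and are all configurable.

The gated-attention head computes
`a_k = softmax_k( w^T ( tanh(V h_k^T) * sigm(U h_k^T) ) )` over the real
(unmasked) instances of a bag, the bag embedding `z = sum_k a_k h_k`, and a
fully connected sigmoid classifier on `z`. The tanh/sigmoid gate lets the
scorer express non-monotone interactions that tanh alone flattens. Padded
instances are excluded from the softmax and receive weight zero, so padding
never changes a bag's probability. Baseline heads score each instance with
a shared sigmoid unit and pool by max, average, or noisy-and
`(sigm(a(m - b)) - sigm(-ab)) / (sigm(a(1-b)) - sigm(-ab))` of the mean
score `m`, slope `a = 10` and a learnable threshold `b = sigm(beta)`.

The whole network, including reverse-mode gradients with respect to both
parameters and inputs, is written in numpy; unit tests verify every
gradient against central finite differences. Parameters are initialized
with fan-in-scaled normal noise from a recorded seed.

## Training

Binary cross-entropy, Adam, mini-batches of padded bags. Defaults:
30 epochs, batch size 8, learning rate 5e-3, early stopping on validation
average precision with patience 15, model restored to the best-validation
checkpoint. The batch size and learning rate are chosen for the desk-scale
datasets this package targets (a few hundred bags): with only tens of
updates per epoch, smaller batches and a larger step are what make Adam
converge inside a 30-epoch budget; both are configurable. Runs are
reproducible bit-for-bit from the seed on a single CPU thread.

With augmentation on (default), every epoch replaces each bag longer than
400 nt by a uniformly placed fragment of ⌊3l/4⌋ nt with the same label.
The floor keeps the fragment inside the source. Cropping applies to
negatives as well as positives: any sub-sequence of a negative region is
still negative, and symmetric treatment avoids a length-conditional
artifact between the classes.

Evaluation reports AUROC, average precision and accuracy at threshold 0.5
(probability exactly 0.5 counts as a positive call), on held-out data only;
single-class evaluation sets report AUROC/AP as undefined rather than a
number. Stratified 10-fold cross-validation (per-fold class counts within
one of each other) reports per-fold metrics and mean ± sd; an 8:1:1
stratified split is the single-run alternative.

## Localization and attribution

For each bag the model calls positive (probability ≥ 0.5), the instance
with the maximal attention weight is selected (ties broken toward the
smallest start offset, recorded in the output). Its signed distance is
measured from the span *center* to the reference point — the central known
site of a 601-nt sequence, or the peak boundary at offset 300 of a margin
sequence; span-center vs span-start is an arbitrary convention and is
recorded in the output metadata. Margin results also record whether the
top span lies wholly in the expected half. Summaries report the fraction
of top spans containing the reference and the mode of a 10-nt-binned
distance histogram.

Attribution uses trapezoidal integrated gradients on the whole bag with
attention active (gradients flow through the attention weights): with `m`
steps the gradient of the model output is evaluated at the `m + 1`
equispaced points on the straight path from reference `x'` to input `x`,
endpoint-weighted ½, averaged, and multiplied by `x - x'`. The attributed
output is the bag probability (the quantity used for prediction); the
logit is available as an option. For linear models the rule is exact at
any `m ≥ 2`. Because the network is piecewise linear in its ReLU/max-pool
regions, the completeness residual `|sum(IG) - (F(x) - F(x'))|` decays
like O(1/m) with an alignment-dependent oscillation rather than smoothly —
comparisons across step counts should use widely separated `m`. Note also
that a dinucleotide-shuffled reference of a composition-biased sequence can
itself score high, making the *relative* completeness error meaningless
when `F(x) - F(x')` is near zero.

References are dinucleotide-shuffled copies of the input (default 50
references, 20 steps), generated by an Euler-path construction that
preserves the exact 2-mer count table and the first and last characters;
zero-matrix and fixed-letter-frequency references are selectable. Final
maps average the per-reference maps; per-instance normalization scales each
instance's collapsed scores to max |score| = 1 (overlapping instances give
a K × c track array; the raw map is kept alongside).

## Synthetic benchmark

The generator emulates the *structure* of FRIP-seq training data: positive
bags of uniform length 200–600 nt carry ≥ 1 planted occurrence of a
degenerate 6-mer ([A/G] A G A C U) whose fixed G is the recorded "modified
base"; bags wider than 400 nt carry 2–3 occurrences, mirroring wide peaks
formed by clustered sites; negatives are rejection-sampled to contain no
exact motif occurrence and, with probability 0.2, carry a one-mismatch
decoy emulating near-motif false positives. Background is uniform
mononucleotide by default. Defaults (200 + 200 bags) are sized so the full
train–evaluate–localize cycle runs in well under a minute on one CPU.

The centered-site evaluation sequences are built as fresh motif-free
background with the recorded motif planted so its fixed G sits at offset
300, re-drawn until the planted occurrence is the unique exact match.
Re-using the original bag context would place the *other* planted sites of
wide bags inside the 601-nt window, making the distance-to-reference
ill-defined.

What passing on this benchmark shows — and what it does not: the pipeline
can recover a short degenerate motif and localize it through attention
under realistic bag-length and multiplicity structure. Real peaks add
composition bias, positional biases from fragmentation and peak calling,
imperfect negatives, and motifs that are weaker and longer-range than a
6-mer; performance numbers on the benchmark do not transfer to real data.

## Numerical and degenerate-input choices

* Masked softmax subtracts the per-bag max before exponentiation;
  probabilities are clipped to [1e-7, 1 − 1e-7] inside the loss.
* All-masked bags, empty instance lists, single-class metric inputs,
  sub-window bags and malformed BED/FASTA records raise informative errors
  rather than propagating NaN; a non-finite training loss aborts with
  diagnostics.
* All-zero spans stay zero under per-instance normalization; `x = x'`
  yields an exactly zero attribution map.
* The label-permutation null control evaluates on a full-sized freshly
  generated dataset with independently permuted labels, because a
  chance-level AUROC estimated on a small test split has sampling error
  comparable to the width of any sensible acceptance band.

## Known limitations

* No exon-aware coordinate projection; peaks spanning splice junctions are
  extracted as genomic-linear sequence.
* The encoder has no recurrent layer; dependencies longer than the second
  convolution's receptive field are invisible within an instance.
* Training is single-threaded CPU numpy; it is sized for datasets of
  hundreds to a few thousand bags, not for genome-scale corpora.
* Noisy-and uses a single global threshold (one class), and the baseline
  heads share one instance-level classifier.
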