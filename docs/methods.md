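# Methods

## Problem setting

Given aligned reads, a reference, and (for training) a truth set of
variants, the package learns a function from a summarised pileup window
to four joint predictions — alternative allele, zygosity, variant type
and indel length — and uses it to call SNPs and small indels genome-wide.
The design targets single-molecule sequencing error regimes (5–15% per
base, indel-enriched), where per-column frequency thresholds alone cannot
separate variants from noise.

## Input encoding

A site tensor covers 2·flank+1 positions (flank = 16, so 33). For each
position and base the four channels hold:

* channel 0 — count of reads whose aligned base equals the reference
  base, stored at the reference base's row (all other rows zero); this
  simultaneously encodes the reference sequence and its support;
* channels 1–3 — inserted-base counts, deleted-base marks and
  substitution counts, stored **relative** to channel 0 (raw count minus
  the channel-0 value in the same cell). A pure-reference column
  therefore shows −depth at the reference row of channels 1–3, and a
  heterozygous SNP shows a positive substitution entry at the alternate
  row next to a negative one at the reference row.

Conventions: insertions are anchored at the reference position
immediately left of the inserted sequence, and the first four inserted
bases are spread over positions anchor+0 … anchor+3 so the allele can be
read back from channel 1; deletions mark the deleted reference bases'
rows (one right of the anchor onward); reads contribute no counts at `N`
bases; both strands are counted together; base and mapping qualities are
never used (noisy long reads carry little usable base quality, and
low-quality mappings are left in deliberately so the model can learn
which contexts are untrustworthy).

One consequence of the relative encoding worth knowing: a *heterozygous*
deletion's channel-2 marks sit at the deleted reference rows, where the
other haplotype's reference support cancels them almost exactly; the net
signal is the channel-0 depth drop. Homozygous deletions show a clean
positive channel-2 block.

## Network

Input 33×4×4 → conv 1×4, 16 filters → conv 2×4, 32 → conv 3×4, 48 (all
SAME padding, stride 1, each followed by SELU and a stride-1 valid
max-pool of 5×1, 4×1, 3×1 respectively) → flatten (24×4×48 = 4608) →
FC4 336 (SELU, dropout 0.5 in training) → FC5 168 (SELU). Heads: allele
(4, sigmoid) off FC4; zygosity (2), type (4), indel length (6), each
softmax off FC5. Total parameters: 1,631,496. SELU keeps hidden
activations self-normalising, so there is no batch normalisation
anywhere. Weights are drawn from N(0, σ²), σ = 1/√(d_in/2) with d_in the
node in-degree; biases start at zero.

The implementation is plain NumPy (im2col convolutions, explicit
backpropagation, Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e−8). Parameters
are float32 by default; float64 is available and used by the
gradient-check tests (numeric vs analytic agreement to 1e−4 relative).
A fixed preconditioning factor of 0.1 is applied to the raw count tensor
inside the forward pass (stored in the model config) so that activations
start near unit scale at typical depths (~30); it is a constant, never
data-dependent. Probabilities are clamped to [1e−10, 1] inside logs.

## Cost and training

The per-batch cost is the mean over samples of squared error on the
allele group plus cross-entropy (natural log) on the other three groups.
The L2 penalty λ·Σw² is added over weight matrices only, with λ tied to
the current global learning rate. Samples are split 90/10 into
train/validation (seeded); truth variants are paired 1:2 with
reference-labelled sites.

*Negative ("non-variant") sites* are drawn uniformly from positions with
an ACGT reference base, depth ≥ 1, outside the affected span of every
truth variant (its position, plus a deletion's deleted bases). Sites
*near* a variant stay eligible by design: the candidate scan constantly
produces positions whose window contains a real variant 1–16 bp
off-center, and the model must learn to answer "reference" there. An
earlier draft excluded a 5-bp radius around variants and the dominant
false-positive mode on held-out data was exactly those flanking
positions.

*Fast mode*: start at 1e−3; when the validation cost fails, for five
consecutive epochs, to improve the best value seen since the last decay
by more than `min_rel_improvement` (default 1%), multiply the rate by
0.1; stop at the plateau after the second decay, or at `max_epochs`.
*Nonstop mode*: a fixed schedule of (epoch bound, rate) pairs — default
(1000, 1e−3), (1500, 1e−4), (2000, 1e−5) — with a checkpoint at each
bound; resuming from a checkpoint reproduces the rate and shuffle trace.

Defaults follow the full-scale regime (batch 500); at desk scale the
suite trains on ~1,500 samples, where batch 16 and
`min_rel_improvement = 0.002` give the optimiser a comparable number of
steps before the plateau rule fires. Those are the values used in the
end-to-end test and the worked example.

## Calling and decoding

Candidates are positions with depth ≥ 4 whose non-reference support
(substitutions plus insertions and deletions anchored there) is ≥ the
frequency cutoff (default 0.2). A candidate is then kept only if it is a
local maximum of the support track within ±3 bp (ties to the left): a
variant's signal appears off-center in its neighbours' windows and would
otherwise be re-called at shifted positions. Because this filter depends
only on the support track, raising the cutoff always yields a subset of
the lower-cutoff calls. The trade-off is that two genuinely distinct
variants within 3 bp collapse to the stronger one — acceptable for the
spacing of common variants, wrong for dense haplotypes.

Decoding: the type head is authoritative (argmax; Reference → no call;
ties break to the lowest class index). Zygosity maps to 0/1 or 1/1. For
SNPs the alternate is the allele head's argmax excluding the reference
base. Insertion alleles up to 4 bp are reconstructed as the per-position
consensus of channel 1 (+ channel 0); deletion alleles are read from the
reference window at the predicted length (the deleted bases *are*
reference bases, so no consensus is needed); longer indels get symbolic
`<INS>`/`<DEL>` alleles, mirroring the policy of exact alleles only for
indels ≤ 4 bp. Internal disagreements (e.g. allele head maximal at the
reference base, or a zero-length head under an indel type) are resolved
in favour of the type head and flagged `HD` in the VCF INFO field.

Quality is −10·log₁₀(1 − p_min), capped at 999, where p_min is the
minimum winning probability over the heads involved in the call (z, t, l
always; a for reference/SNP types). The scale supports sweeping a
quality cutoff to maximise F1; it makes no attempt to reproduce any
specific external quality scale.

## Evaluation semantics

A true positive requires exact agreement on position, allele, type,
zygosity and indel length. A call at a truth site that disagrees on any
of these counts as one false positive *and* leaves the truth record a
false negative (vcfeval-style accounting, so TP+FN equals the number of
truth records evaluated). Indels > 4 bp are removed from both truth and
calls before counting. True negatives exist only in site-restricted mode
(a supplied list of evaluated sites); genome-wide, FPR is reported blank.
Metrics: FPR, FNR, precision, recall, F1 = 2TP/(2TP+FN+FP); any
zero-denominator metric is defined as 0 and flagged. Matching is
position-exact: representation-level equivalence of indels (same
haplotype, different anchor) is not resolved — a documented limitation.

Auxiliary operations mirror the downstream analyses the caller supports:
a best-quality-cutoff sweep (exhaustive over observed qualities, ties to
the lowest), a two-caller consensus filter on the geometric mean of
qualities, transition/transversion ratio, and sequence-context
classification (homopolymer = run ≥ 5 covering the site or the base
after it; short tandem repeat = ≥ 3 tandem copies of a 2–6 bp motif;
homopolymer wins; thresholds chosen so the classes are non-trivial in
33-bp windows).

## Synthetic data

The simulator emulates a diploid sample: a uniform-random reference at a
requested GC; SNPs and indels (length distribution defaulting to
0.40/0.22/0.14/0.10/0.06/0.04/0.04 over 1,2,3,4,5,6,9 bp) planted at
≥ 40 bp spacing, heterozygous variants on one random haplotype; reads
drawn uniformly from both haplotypes with i.i.d. per-base substitution /
insertion / deletion errors. Two stock profiles: `illumina`
(0.01/0.0005/0.0005, 148 bp) and `sms` (0.05/0.04/0.05, 1000 bp — a
~14% total error, indel-enriched regime). The default variant mix is
86% SNPs, 7% insertions, 7% deletions, matching the composition of the
human truth sets this class of caller trains on. Reads are emitted at
their true coordinates with exact CIGARs — no aligner runs — and a
per-position ledger of emitted aligned bases provides an independent
oracle for the pileup code.

What this does *not* emulate: alignment artifacts, reference repeats,
homopolymer-conditional error rates, strand effects, coverage biases and
base-quality structure. Passing the end-to-end test therefore shows the
method works under idealised mapping with realistic error *rates*; it
does not certify performance on real genomes, where context-dependent
errors and misalignment dominate the hard cases.

## Problem sizes used by the tests

The end-to-end check trains the fast mode on one 50-kb contig (500
planted variants, depth 30, `sms` profile, fixed seeds; 1,500 training
samples) and calls two held-out 30-kb contigs (300 variants each) at the
0.2 cutoff, pooling SNP confusion counts across both. Under these
conditions the pooled SNP F1 is ≈ 0.95 and the suite requires ≥ 0.90;
indel F1 remains low (< 0.3), consistent with indel calling being the
weak spot of pileup-tensor callers at this error rate and training size.
Unit tests run on 4–6 kb fixtures at depth 15–25.

## Known limitations

* Indel recall/precision at high error rates is poor at desk-scale
  training sizes; the length head and allele reconstruction are exercised
  by the tests but not claimed to be performant.
* Multi-allelic sites are excluded from training and collapse to the
  single best alternate in calling.
* The ±3 bp local-maximum filter merges genuinely adjacent variants.
* Site matching is representation-naive (no haplotype-aware
  normalisation).
* The quality scale is internally consistent but not calibrated to any
  external caller's scale.
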