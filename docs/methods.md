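# Methods

## The problem

Most human multi-exon genes are alternatively spliced. An internal exon can
be constitutively included (CON), skipped as a cassette exon (ES), or
spliced through an alternative 3' (acceptor, ALT3) or 5' (donor, ALT5)
splice site. EST-based exon catalogs annotate each internal exon with an
inclusion level (fraction of transcripts that include it) and alternative
3'/5' splice-site usage levels, all in [0, 1]. `splicecnn` asks whether the
splicing class of an exon is predictable from its immediate sequence
context alone — the two exon/intron junctions plus the exon/intron length
architecture — and which sequence elements a model trained this way relies
on.

## Event model and filtering

An event is one internal exon. Classification from the three levels is a
total function: all levels equal to 1 is CON; an interior inclusion level
(0 < incl < 1) with full splice-site usage is ES; a reduced 3' (resp. 5')
usage level with everything else at 1 is ALT3 (resp. ALT5); any combination
evidencing more than one AS type is EXCLUDED and never enters a dataset.
Two readings the level semantics do not fix: an exon with inclusion level
exactly 0 is not a cassette exon (it is never included, so it shows no
evidence of both outcomes) and is EXCLUDED; and an ALT3/ALT5 exon that also
shows skipping evidence violates the single-AS-type rule and is likewise
EXCLUDED.

Quality filters, all inclusive ("at least N" means >= N): cassette exons
need >= 20 inclusion+exclusion ESTs; alternative splice sites need >= 4
supporting ESTs; every exon must be >= 25 nt and both flanking introns
>= 80 nt. Rejections report the first failing rule in the fixed order EST
support -> exon length -> intron length, so audit logs are reproducible.
Constitutive exons carry no EST minimum by default (`min_est_con=0`
disables the optional threshold).

Test-time strata: the relevant level (inclusion for ES, site usage for
ALT3/ALT5) partitions alternative events into HEvents (level strictly
> 0.8) and MREvents (the rest). "More than 80%" is read strictly, so a
level of exactly 0.8 is an MREvent. Constitutive exons have no stratum.

## Features

Each event contributes two 140-nt windows: ±70 nt around the acceptor
junction and around the donor junction, in transcript orientation
(minus-strand events are reverse-complemented and the acceptor/donor roles
follow the transcript). Windows are pure genomic context around the
junction point and are *not* clamped at exon boundaries — with a 25-nt
minimum exon this is the only convention that yields fixed-size inputs,
and it implies that the two windows of exons shorter than 140 nt overlap.
One-hot encoding uses column order A, C, G, T; U is a synonym for T; N
encodes to an all-zero row (keeping matrices binary, rather than a 0.25
smear).

The three length features are the upstream-intron, exon and
downstream-intron lengths (L1, L2, L3), z-normalized. Exon statistics are
computed over exon lengths and intron statistics over the pooled multiset
of both flanks, with sample (ddof=1) standard deviations. Reference
statistics for the human genome are not bundled; by default the statistics
are computed from the dataset at hand, persisted to a JSON sidecar, and an
externally supplied set can be loaded instead for parity with genome-wide
numbers.

## Architectures

One convolution block design is shared everywhere: three stages of
conv -> ReLU -> dropout 0.2 -> max-pool (size 2, stride 2), with 32, 8 and
8 filters of widths 7, 4 and 3. Convolution padding is not determined by
the published layer table; we default to length-preserving ("same")
padding, giving pooled lengths 140 -> 70 -> 35 -> 17 and a flattened block
dimension of 17 x 8 = 136, and keep "valid" (140 -> 67 -> 32 -> 15,
dimension 120) behind a configuration switch.

Architecture A applies one block to a single window; architecture B applies
two blocks with independent (untied) weights, one per window. Flattened
block outputs are concatenated with the 3 length features and passed
through a fully connected layer (ReLU, dropout 0.5) and the head:

| task     | architecture | inputs            | fc  | head       |
|----------|--------------|-------------------|-----|------------|
| CON-ES   | B            | acceptor + donor  | 64  | sigmoid    |
| CON-ALT3 | A            | acceptor          | 32  | sigmoid    |
| CON-ALT5 | A            | donor             | 32  | sigmoid    |
| DSC      | B            | acceptor + donor  | 64  | softmax(4) |

For the four-class DSC model the concatenated feature dimension is
136 + 136 + 3 = 275. Losses are implied by the heads: binary cross-entropy
for the sigmoid tasks, categorical cross-entropy for DSC. No class
weighting is applied by default; inverse-frequency weighting was considered
and rejected as the default because per-class accuracy differences in this
setting track class abundance, which is informative in itself.

The network engine is a small NumPy implementation (float32, exact
backpropagation, CPU). Weights are initialized from a Gaussian with
configurable σ (default 0.05 — the published description fixes the family
but not the scale) and biases start at exactly zero; everything is driven
by explicit seeded generators, so initialization, dropout masks and batch
order are bit-reproducible.

## Training protocol

10-fold cross-validation: the dataset is split into k folds, stratified by
class (stratification protects the small ALT3/ALT5 classes; plain random
splitting is available behind a flag). In rotation r, fold r is the test
set, fold (r+1) mod k the early-stopping set, and the remaining k−2 folds
the training set; the rotation rule is fixed for determinism. Training uses
Adam with learning rate 5e-4 and minibatch size 100. Early stopping
monitors the early-stopping-fold loss with patience 10 within a 150-epoch
budget and restores the best epoch's weights; the monitored metric,
patience and budget are implementation choices (the published AUCs cannot
pin them down). Binary tasks reuse the full CON set as negatives in every
rotation; negative subsampling is available but off by default. Running
all four tasks over 10 rotations trains 40 models; each event appears in
exactly one rotation's test set per task, and a leakage assertion verifies
role disjointness on every run.

## Evaluation

AUC is the Mann–Whitney pair statistic (ties credited ½), computed by the
mid-rank formula; an independent brute-force pair-counting oracle checks
it in the tests to 1e-12. Fold aggregation reports mean and standard error
(sample sd / √k), formatted `0.899 (±0.008)`.

Stratified reports restrict the *alternative* class only: HEvents/MREvents
scopes keep every constitutive negative, since the scientific question is
how well e.g. highly included cassette exons separate from all
constitutive exons. DSC is scored one-vs-rest per class on its softmax
probabilities, plus the unweighted macro average. Cassette-exon
predictions can additionally be binned by inclusion level into 5 or 10
half-open bins [i/n, (i+1)/n) (last bin closed), each scored against the
full CON negative set; empty scopes are flagged not-computable rather than
dropped.

## Motif extraction

First-layer filters are converted to motifs by activation scanning: each
width-7 filter is evaluated at every full-width offset of a scanning set
(by default held-out test windows, mirroring reporting on unseen data);
subsequences at offsets where the activation exceeds 0.5 × the filter's
global maximum are stacked into a position frequency matrix. Filters whose
maximum activation is not positive, or that collect fewer than 10 sites,
are dropped; both constants are exposed in the API. PFMs normalize to PWMs
with a pseudocount and export in MEME minimal format (DNA by default; RNA
mode relabels T as U) for downstream comparison with TOMTOM against motif
databases — running TOMTOM itself is out of scope. An internal similarity
measure (best mean column-wise Pearson correlation over ungapped offsets
with >= 4 overlapping columns, both orientations for DNA) stands in for
TOMTOM in the tests only.

## Synthetic data

The generator emulates the structure of an EST-derived exon catalog so the
whole pipeline is testable without downloads. Defaults: class abundances
proportional to 39128 : 11590 : 2332 : 2172 (CON : ES : ALT3 : ALT5),
scalable; exon lengths truncated normal (mean 140 nt, sd 50, min 25);
intron lengths log-normal (median 1000 nt, log-sd 0.6, min 80);
inclusion/usage levels from an equal mixture of Beta(1, 9) and Beta(9, 1),
matching the strongly bimodal (<10% / >90%) shape of real inclusion-level
distributions; uniform background base composition; one synthetic
chromosome per 1000 events with 200-nt spacers so windows never collide;
EST counts from Poisson distributions shifted above the filter floors.

Planted structure per class: every junction carries an acceptor consensus
(12-nt pyrimidine tract + AG) and a donor consensus (GTAAGTT), sampled at
per-position match probability 0.9. ALT3 events add a secondary acceptor
ending 6–30 nt downstream of the junction (inside the exon); ALT5 events
add a secondary donor 6–30 nt upstream of theirs; ES events carry a
CU-rich silencer (CTCTCTC) in the upstream-intron flank and a U-rich
silencer (TTTATTT) in the downstream-intron flank — loosely modeled on
PTBP1/TIA1-class binding elements — together with primary sites weakened
by a factor 0.85. Secondary sites are written before primary sites so the
primary consensus is never clobbered. In difficulty-gradient mode,
silencers of cassette exons with inclusion > 0.8 are planted at strength
0.55 instead of 0.9, making highly included exons statistically closer to
constitutive ones; this reproduces, by construction, the qualitative
HEvents-vs-MREvents performance gap. All planted PWMs are emitted in the
ground-truth bundle.

What the generator does **not** emulate: realistic genome composition
(GC content, repeats), branch points, splice-site strength continua,
co-transcriptional and tissue-specific regulation, or correlated EST
sampling noise. Passing tests therefore demonstrate that the pipeline is
correct and that the models can learn and localize planted junction
signals — not that real hg38 accuracy is reproduced, which would require
the external exon catalog and genome.

## Numerical choices and degenerate inputs

Tie handling in AUC is mid-rank; single-class inputs raise rather than
return a default. Length statistics with zero variance raise a
degenerate-stats error. Fold plans require |events| >= k; classes smaller
than k are spread as evenly as possible. Divergent (non-finite) training
loss raises a training error naming the epoch. `max_epochs=0` returns the
initialized network unchanged. Checkpoints are JSON (spec + weights), so
any checkpoint is self-describing and text-diffable.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data at
sizes chosen to exercise every code path while staying desk-scale: the
campaign check uses a 0.02-scale dataset (~1100 events, 40 trained
models); learnability, permutation-control and stratum-gap checks use
n = 4000 (2000 CON + 2000 ES); motif recovery uses 1500 events per class.

## Known limitations

* No GPU path; the NumPy engine is adequate for the shipped problem sizes
  but not for genome-scale training.
* The "same"-vs-"valid" padding ambiguity is resolved by configuration,
  not evidence; both conventions are implemented.
* Real HEXEvent exports need a thin column-mapping step to the documented
  TSV schema before use.
* The motif similarity score is a test-oriented stand-in, not a calibrated
  statistical match test like TOMTOM's.
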