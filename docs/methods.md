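# Methods

## Scope and design

`retrodetect` detects and classifies the internal protein-coding domains of
LTR retrotransposons (GAG, AP, INT, RT, RH, ENV; 13 plant lineages) in long
DNA windows with a single-shot convolutional detector, and provides the
surrounding machinery: synthetic training-data generation, grid-label
encoding/decoding, non-max suppression and clustering post-processing, and
evaluation (nucleotide-basis metrics, PR sweeps, parity, mAP@0.5,
inter-domain distances, track plots). Running external boundary tools
(LTRharvest, RepeatMasker) is out of scope; the package only writes their
inputs (extended-region FASTA) and standard formats.

## Coordinates and label schema

Internally every interval is 0-based half-open; all emitted text formats
(prediction table, GFF3) are 1-based inclusive. Input sequences are
upper-cased on read; soft-masking is ignored. Non-ACGT symbols one-hot
encode to all-zero columns.

A window of `L` bp (default 50,000) is tiled into `C = L/100` cells of
100 bp. The cell containing a domain's *start* carries its full label:
presence 1, fractional start offset `x = (start mod 100)/100`, normalized
length `w = min(length / max_length[type], 1)` where `max_length` is the
per-type maximum over the reference library, and one-hot type and lineage
blocks (22 coordinates per cell in total). Cells covered only by a domain's
interior stay zero: the label marks beginnings, the `w` coordinate carries
extent. Decoding inverts this with nearest-integer rounding (ties away from
zero); because encoding divides by the same constants, an encode→decode
round trip is exact for any annotation set with one start per cell and
lengths within the class maxima (property-tested on 1,000 random sets).

Degenerate inputs: if two domains start in the same cell — impossible in
the generator, possible in user data — the longer is kept and a warning
logged. A domain longer than its class maximum clips to `w = 1` and decodes
to the class maximum. Calls that would start inside encoder padding (the
zero-padded tail of a terminal partial window) are discarded; calls whose
decoded length overruns the end of the source sequence are clipped to it.

The lineage index order follows the exhaustive numbered vocabulary
(Ale/Retrofit = 0 … Tork/Tar = 12); type order is GAG, AP, INT, RT, RH,
ENV.

## Synthetic data generator

A window is assembled left to right: background gap, element, gap, element,
…, with gaps drawn uniformly from [3,000, 4,000] bp (full scale) and
placement stopping when the next element would not fit. Inserted elements
overwrite the background at their interval, keeping the window length fixed.
The leading gap is drawn from the same distribution as inter-element gaps —
only inter-element spacing is structurally required, but uniform treatment
avoids an edge bias. Elements are dealt without replacement in shuffled
order until the library is exhausted, then reshuffled; an element that does
not fit the current window is left for the next one. A configurable
fraction of windows (default 0.1; `round(fraction · n)` exactly) contains
background only, emulating genomic stretches devoid of LTR-RTs. Nested or
fragmented insertions, target-site duplications and LTR flanks are not
simulated: whole library elements are planted as-is.

The fixture library stands in for a curated TE database so nothing is
downloaded. Each domain type has one conserved random profile sequence
(lengths 400/220/300/350/180/250 bp for GAG/AP/INT/RT/RH/ENV); each lineage
derives its own variant by a fixed 15% substitution load; each element
instance takes a 60–100% prefix of the lineage profile further mutated at
10% per position. Domains are joined by 50–150 bp random linkers in the
canonical superfamily order; ENV is appended with probability 0.25 (forced
on one element so every type is represented even in tiny libraries).
Background is drawn AT-rich (A=T=0.35, C=G=0.15) versus the uniform-GC
profiles. These rates are plumbing calibrated so that a small network can
learn the task on a CPU — they are not a claim about real TE divergence.
Consequently, passing the learning test shows the architecture, codec,
training loop and post-processing work end to end; it does not certify
performance on real genomes, where domains diverge far more, insertions
nest, and backgrounds are repetitive.

## Detector and loss

Six stages: a 4×50×16 stem convolution; four residual blocks downsampling
by 5, 2, 5, 2 (product = cell size, so output length = cell count) with
channel doubling; a 1×1 convolution to 22 channels; then logistic
activations on presence/start/length and separate softmaxes over the type
and lineage groups (bounded regression targets; one-hot class targets).
Block internals are two convolutions (kernel 9, the first strided by the
block factor) with batch normalization and ReLU, plus a strided 1×1
projection shortcut; downsampling by strided convolution keeps the block
uniform. All of this is exposed in `ModelConfig`. No dropout.

The loss is weighted sum-squared error: object cells contribute squared
errors on presence, start, length and all 19 class coordinates with weight
λ_obj = 1; background cells contribute only the presence error with
λ_nonobj = 0.06; the batch mean is returned. The size term is implemented
as (w − ŵ)² — a difference, as "sum-squared error" requires; a sum would
penalize exact predictions. Zero loss iff presence matches everywhere and
the object cells' coordinates match; background start/length/class
coordinates are unconstrained, matching the indicator structure.

The network is pure numpy: im2col convolutions (the input-gradient scatter
loops over kernel taps, never positions), analytic backward passes, Adam,
Xavier-normal initialization. Training in float32; a float64 configuration
exists for gradient checking, where backprop agrees with central finite
differences to 1e-4 relative (tested end to end across every parameter
tensor). Batch-norm running statistics (momentum 0.9) are used at
inference. All randomness — init, split, shuffling — derives from explicit
seeds; runs are bit-reproducible on one device.

Full-scale training defaults: Adam, lr 0.001, batch 128, 100 epochs,
80/10/10 train/validation/test split.

## Post-processing

Two-stage thresholding: a permissive raw filter (0.1) before NMS and a
reporting threshold (default 0.8, the full-scale precision×recall optimum)
after. NMS is greedy on descending probability with suppression at interval
IoU > 0.1; in one dimension genuinely stacked objects cannot occur, so the
threshold could be 0, but a small margin tolerates boundary error (0 is
allowed). Ties break to the smaller start, then the longer call —
deterministic output; NMS is idempotent and is tested against a brute-force
simulation.

Clustering scans start-sorted calls once: a new cluster opens when the gap
to the running maximum end (spacer semantics, `next.start − prev.end`)
exceeds `max_gap` (default 3,000 bp); clusters with fewer than
`min_domains` (default 3) members are dropped. Spacer semantics was chosen
because observed inter-domain distances are spacer-like magnitudes
(hundreds of bp), not start-to-start. Regions extend by 8,000 bp per side,
clipped to the sequence, for LTR-boundary handoff (recorded LTRharvest
parameters: `-seqids yes -maxlenltr 3000 -similar 80`).

## Evaluation

Nucleotide-basis confusion: predictions and truths are unioned per
sequence before counting (a double-covered base counts once), then
TP/FP/FN are overlap/space set sizes in bp and TN the remainder of the
evaluated length. Undefined precision (nothing predicted) is reported as
missing, never 0, so PR-curve maxima stay meaningful. Detection is scored
regardless of classification.

The PR sweep filters raw calls at each threshold, applies NMS, and reports
the threshold maximizing precision × recall. Parity matches predictions to
overlapping truths greedily (descending probability, nearest start,
one-to-one); R² = 1 − SSres/SStot over matched pairs only — unmatched
calls are plotted on the axes but excluded from the statistic, since axis
points would force arbitrary zero-coordinates into it. mAP uses 101-point
interpolated AP at a single IoU of 0.5, greedy same-class matching, and an
unweighted mean over classes with at least one truth instance;
truth-instance fractions are reported alongside as class contribution.

Inter-domain distances are spacer lengths (`downstream.start −
upstream.end`) over the canonical consecutive pairs per superfamily, plus
`NEXT` (last core domain to whatever follows) and `PRE-LTR-3'` (last
domain to the 3' LTR, when LTR coordinates exist). Elements whose core
domains are out of canonical order are skipped with a warning and counted.
When elements are derived from predicted clusters, the superfamily is
inferred from the INT position relative to RT.

## Desk-scale preset and problem sizes

The package's tests and worked example run a 10×-reduced configuration:
5,000 bp windows with gaps scaled by the same factor to [300, 400] bp
(the full-scale gap range is tied to 50 kb windows), a 60-element fixture
library, 200 windows, and 20 epochs. Because 160 training windows give only
one batch-128 update per epoch, the desk preset uses batch 16 and lr 0.005
to keep the update count and effective step size comparable; the full-scale
defaults are untouched. The reporting threshold is selected on the
validation split by the same precision×recall rule as at full scale, and
test-split domain-level F1 (IoU ≥ 0.5, class-agnostic) is the headline
number (≈ 0.94 at seed 0; ≥ 0.88 across spot-checked seeds). The run takes
about two minutes on one CPU.

## Known limitations

- Forward-strand scan by default; `--reverse` additionally scans the
  reverse complement and reports forward coordinates, but the synthetic
  generator only plants forward-strand elements.
- One domain per 100 bp cell by construction of the label format.
- The numpy engine targets this architecture; it is not a general autodiff
  framework, and large-genome inference is CPU-bound.
- The fixture task is deliberately easier than real annotation (see the
  generator section); full-scale performance claims require a real library
  and genome-scale evaluation.
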