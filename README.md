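# retrodetect

Single-shot detection and classification of LTR-retrotransposon internal
protein-coding domains in long DNA sequences, with a residual 1D
convolutional network.

## The problem

LTR retrotransposons (LTR-RTs) dominate plant genomes. Their internal
region carries the *gag* and *pol* protein-coding domains — capsid protein
(GAG), aspartic proteinase (AP), integrase (INT), reverse transcriptase
(RT), ribonuclease H (RH), and sometimes an envelope remnant (ENV) — whose
order distinguishes the two plant superfamilies (Ty1/copia: GAG–AP–INT–RT–RH;
Ty3/gypsy: GAG–AP–RT–RH–INT). Conventional annotation pipelines find these
domains by homology search, which is slow on gigabase genomes and limited
by database coverage.

`retrodetect` treats the task as *object detection on DNA*: a convolutional
detector reads a 50,000 bp window in one pass and predicts, for every
100 bp grid cell, whether a domain starts there, where exactly, how long it
is, and which of 6 domain types and 13 lineages it belongs to. This is the
1D analogue of single-shot image detectors: detection and classification in
a single network evaluation.

## Model

A window of length $L$ (default 50,000 bp) is one-hot encoded as a
$4 \times L$ matrix (rows A, C, G, T; other IUPAC symbols are zero
columns) and tiled into $C = L/100$ cells. Each cell $i$ carries a
22-coordinate label
$(p_i,\; x_i,\; w_i,\; \mathbf{c}_i)$: presence $p_i \in \{0,1\}$, relative
start $x_i \in [0,1)$ within the cell, length $w_i \in (0,1]$ normalized by
the per-type maximum over the reference library, and a 19-long one-hot
block $\mathbf{c}_i$ (6 domain types + 13 lineages).

The detector is six stages: a $4\times50\times16$ stem convolution, four
residual blocks that downsample by factors 5, 2, 5, 2 (product = the 100 bp
cell size) while doubling channels, and a 1×1 output convolution with
logistic activations on $(p, x, w)$ and group softmaxes on the classes.
Training minimizes the weighted sum-squared detection loss

```math
\mathcal{L} = \lambda_{obj}\sum_{i}\mathbb{1}_i^{obj}\Big[(p_i-\hat p_i)^2 + (x_i-\hat x_i)^2 + (w_i-\hat w_i)^2\Big]
 + \lambda_{obj}\sum_{i}\mathbb{1}_i^{obj}\sum_j (c_{ij}-\hat c_{ij})^2
 + \lambda_{nonobj}\sum_{i}\mathbb{1}_i^{nonobj}(p_i-\hat p_i)^2
```

with $\lambda_{obj}=1$, $\lambda_{nonobj}=0.06$ (background cells vastly
outnumber object cells), averaged over the batch. Optimization is Adam
(lr 0.001, batch 128, 100 epochs, Xavier-normal init, no dropout, 80/10/10
split) at full scale; see `docs/methods.md` for the desk-scale preset.

Raw per-cell calls are filtered at a permissive presence threshold (0.1),
de-duplicated by greedy 1D non-max suppression (interval IoU > 0.1
suppresses), and reported above a stricter threshold (default 0.8). Nearby
calls (≥ 3 domains separated by ≤ 3,000 bp) are clustered into candidate
LTR-RT internal regions, optionally extended by 8,000 bp per side for
handoff to an external LTR-boundary tool.

The network is implemented in pure numpy (strided im2col convolutions,
batch norm, analytic backprop, Adam), verified against finite differences
in the test suite.

## Worked example

The package includes a seeded synthetic-data generator that plants
annotated elements from a generated fixture library into TE-free background
windows, so no external database is needed. The desk-scale experiment —
200 windows of 5,000 bp, 20 epochs on one CPU (about two minutes) — trains
the detector end to end and evaluates on an untouched test split:

```python
from retrodetect.pipeline import run_desk_experiment

result = run_desk_experiment(seed=0)
h = result["history"]
print(f"training loss {h.train_loss[0]:.4f} -> {h.train_loss[-1]:.4f}")
print(f"selected threshold {result['best_threshold']}")
cc = result["test_counts"]
print(f"test P {cc.precision:.4f} R {cc.recall:.4f} F1 {cc.f1:.4f}")
```

prints

```
training loss 18.3103 -> 0.0245
selected threshold 0.2
test P 0.9409 R 0.9317 F1 0.9363
```

i.e. the training loss falls by three orders of magnitude, the reporting
threshold chosen on the validation split (argmax of precision × recall) is
0.2, and on held-out windows 94% of reported domain calls match a true
domain at IoU ≥ 0.5 while 93% of true domains are recovered, ignoring
classification.

The same pipeline is available from the shell:

```bash
retrodetect generate --seed 7 --n-windows 50 --out-dir data/
retrodetect train    --data-dir data/ --model-out model
retrodetect predict  --model model --fasta genome.fasta --out calls.tsv
retrodetect cluster  --predictions calls.tsv --out-dir regions/
retrodetect evaluate --predictions calls.tsv --truth data/truth.gff3 \
                     --total-len 2500000 --out metrics.json
retrodetect distances --predictions calls.tsv --out distances.json
```

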