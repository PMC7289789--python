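# rnaloci

A multi-branch convolutional classifier and sliding-window scanner for
locating small non-coding RNA loci (hairpin-type precursors, snoRNA-like
elements) in genomic regions.

Three feature blocks feed separate convolutional branches — raw sequence
(one-hot), dot-bracket secondary structure (one-hot), and per-base
evolutionary conservation (raw) — which are concatenated into a dense head
with a single logistic output.  Training uses a two-step iterative
background-selection scheme: an ensemble of models is trained on random
length-matched negatives (1:4 positive:negative), the ensemble scans large
background regions, consensus false positives ("hard cases" flagged by at
least half the ensemble by default) are mined, and the best member's
training set — enhanced with those hard negatives — trains the final model.
Evaluation supports both pre-labelled candidate sets and scanning mode with
a fractional-overlap hit rule, sensitivity-anchored thresholds, PR curves,
false-positive spacing, and a naive expression-ranked baseline.

The network is implemented directly in numpy (im2col convolutions, Adam,
class-weighted binary cross-entropy) so the package has no deep-learning
framework dependency and is bit-reproducible per seed on CPU.  Secondary
structure comes either from precomputed dot-bracket files (e.g. RNAfold
output) or from a built-in maximum-base-pair folder (Nussinov-style DP,
numba-accelerated).

## Command line

```bash
# generate a synthetic benchmark (FASTA, wiggle, BED)
rnaloci simulate --spec spec.json --seed 1 --out sim/

# two-step iterative training (branches: any subset of S, F, C)
rnaloci train --positives positives.bed --genome genome.fa \
    --conservation conservation.wig --candidates background.bed \
    --branches SFC --models 50 --support 25 --out run/

# scan regions with a trained model
rnaloci scan --model run/model.npz --regions peaks.bed --genome genome.fa \
    --conservation conservation.wig --peaks --threshold 0.84 --out scan/

# evaluate calls against annotated targets
rnaloci evaluate --windows scan/windows.tsv --targets annotations.bed \
    --mode scanning --at-sensitivity 0.5 --out eval/
```

Exit codes: 0 success, 2 usage/configuration error, 3 requested sensitivity
unattainable.  Every command writes its fully resolved configuration next to
its outputs; identical configs and seeds give byte-identical BED/TSV output.

## Layout

| module | role |
| --- | --- |
| `rnaloci.intervals` | strand-aware interval arithmetic, BED6 I/O, windows, overlap hit rule |
| `rnaloci.encoding` | one-hot sequence/structure, internal folder, conservation tracks (wiggle) |
| `rnaloci.model` | the multi-branch convolutional classifier (numpy, seeded) |
| `rnaloci.background` | random negative sampling, ensemble, consensus hard-negative mining |
| `rnaloci.scanner` | sliding-window scanning, window-to-call merging |
| `rnaloci.evaluation` | scanning/pre-labelled metrics, PR curves, thresholds, baselines |
| `rnaloci.synthetic` | synthetic genome/track/annotation generator, holdout benchmark |
| `rnaloci.bench` | desk-scale end-to-end benchmark harness |
| `rnaloci.cli` | `rnaloci simulate / train / scan / evaluate` |
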