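# mirtarnet

A hybrid CNN–BiLSTM classifier for predicting whether a miRNA targets a
candidate binding site, built from raw sequence alone. The package covers
the full pipeline:

- **codec** — normalization (case folding, T→U), miRNA re-orientation
  (5′→3′ to 3′→5′), per-slot right-padding with `N`, concatenation and
  integer encoding over the `{A,U,G,C,N}` alphabet. Two built-in schemas:
  26+53 nt (input length 79) and 26+40 nt (input length 66).
- **model** — the six-layer architecture: trainable 5-dim embedding →
  1D convolution (320 kernels, width 12, ReLU, valid boundary) → max
  pooling (2/2) → bidirectional LSTM (32 hidden units, ReLU cell
  activation with a tanh fallback) → dense(16, ReLU) → dense(1, sigmoid),
  with dropout after the convolution, the pooling, the BiLSTM and between
  the dense layers. Implemented as a small NumPy engine with explicit
  forward/backward passes (no deep-learning framework is available in the
  target environment); every layer's gradients are verified against finite
  differences in the test suite.
- **train** — stratified 64/16/20 train/validation/test splitting,
  mini-batch Adam with binary cross-entropy, early stopping (stop when
  validation accuracy fails to improve by 0.1% within the patience
  window, best weights restored), grid search over learning rate ×
  dropout × batch size, repeated random re-splits, and composition of a
  unified dataset from two source pools (90% draw capped at a 3:1 ratio).
- **metrics** — accuracy, sensitivity, specificity, F-score, PPV, NPV and
  Brier score; undefined ratios are flagged NaN; 95% CIs are the 2.5/97.5
  empirical percentiles over repeated runs.
- **scan** — sliding-window scanning of long gene sequences (50% overlap
  by default, end-anchored tail window, N-padding for short genes),
  per-window probability calls, per-gene target calls by positive-site
  count, FASTA export of positive sites.
- **synth** — seed-reproducible synthetic datasets with planted seed
  complementarity (canonical 2–7/3–8 Watson–Crick sites, non-canonical
  variants with G–U wobbles and one bulge or mismatch) and three negative
  constructions (miRNA shuffling, pool-miRNA swap, seed-free random
  sites), with per-pair provenance for independent verification.
- **ablation** — layer-removal variants (max pooling; CNN+pooling; RNN;
  hidden dense; all dropouts) and seed-matched repeated-run comparisons.

## CLI

```bash
# generate a synthetic pair table
mirtarnet synth --n-pos 1000 --n-neg 1000 --seed 1 --out pairs.tsv

# train (single run; add --grid grid.yaml for a search, --repeats N for re-splits)
mirtarnet train --pairs pairs.tsv --schema miraw --lr 0.005 --batch-size 30 \
    --max-epochs 100 --patience 20 --seed 0 --out run/

# scan genes for binding sites of one or more miRNAs
mirtarnet predict --model run/model.npz --mirna mirnas.fa --genes genes.fa \
    --threshold 0.5 --min-sites 1 --out-fasta sites.fa --out-table scan.tsv

# layer-removal comparison on synthetic data
mirtarnet ablate --synth --n-synth 1000 --repeats 5 --seed 0 --out ablation.tsv
```

Pair tables are tab- or comma-separated with columns
`mirna_id, mirna_seq, site_seq, label`; FASTA inputs are 5′→3′ (DNA
alphabets are normalized automatically).

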