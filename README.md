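# ppitex

Sequence-based prediction of protein–protein interactions (PPIs) from
evolutionary profiles. Each protein sequence is encoded as a 20×M
position-specific scoring matrix (PSSM), summarized into a 256-dimensional
local-texture histogram (LOOP codes built from Kirsch-mask response ranks),
paired with a partner by concatenation (512 features per pair), and
classified with a from-scratch rotation-forest ensemble. Evaluation follows
five-fold cross-validation with accuracy, sensitivity, precision,
specificity, MCC and ROC/AUC.

A deterministic pseudo-PSSM generator and a synthetic PPI benchmark
generator make the full pipeline runnable and testable offline; parsing
real PSI-BLAST `-out_ascii_pssm` files is supported (running PSI-BLAST
itself is optional and untested).

## Package layout

| module | contents |
|---|---|
| `ppitex.pssm` | FASTA reading, PSI-BLAST ASCII PSSM parsing/writing, pseudo-PSSM generation, minimum-length filter |
| `ppitex.loop` | Kirsch mask bank, LOOP texture codes, 256-bin histograms, descriptor TSV I/O |
| `ppitex.rotation_forest` | feature partitioning, per-subset bootstrap PCA rotations, ensemble fit/predict, model archive |
| `ppitex.dataset` | pair featurization, compartment-aware negative sampling, k-fold splits, synthetic PPI generator |
| `ppitex.evaluation` | confusion metrics, MCC, ROC/AUC, cross-validation driver, (L, K) grid search |
| `ppitex.cli` | `ppitex` command with the subcommands below |

## CLI

```sh
# simulate a synthetic dataset (FASTA + PSSM files + pairs.tsv + manifest)
ppitex simulate --n-prot 120 --n-pos 30 --n-neg 30 --seed 1 --out data/

# compute per-protein texture descriptors
ppitex features --fasta data/proteins.fasta --pssm-dir data/pssm --out desc.tsv

# five-fold cross-validation with the default ensemble (L=3 trees, K=10 subsets)
ppitex eval --pairs data/pairs.tsv --descriptors desc.tsv --seed 1 --out-prefix report

# train / predict with a persisted model
ppitex train --pairs data/pairs.tsv --descriptors desc.tsv --model model.joblib
ppitex predict --pairs data/pairs.tsv --descriptors desc.tsv --model model.joblib --out pred.tsv

# grid search over ensemble sizes
ppitex grid --pairs data/pairs.tsv --descriptors desc.tsv --l-grid 1,3,5 --k-grid 5,10 --out grid.tsv
```

Exit codes: 0 success, 1 usage error, 2 data error. All commands are
deterministic given a `--seed`; `eval` draws and echoes a seed when none is
given.

## Conventions and caveats

- PSSM rows follow the PSI-BLAST amino-acid order `ARNDCQEGHILKMFPSTWYV`;
  log-odds scores are used raw (columns 1–20 of the ASCII file).
- Texture histograms are normalized to frequencies, so sequence length is
  not encoded in the features.
- Pairs are split into folds at the pair level; the same protein may appear
  in both training and test pairs. This mirrors the evaluation protocol
  being reproduced and can flatter absolute numbers on real data.
- The synthetic generator's `signal_strength` is the standard deviation of
  the additive motif patch; it must out-contrast the BLOSUM62 background
  (entries roughly −4..11) for the classes to be separable.
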