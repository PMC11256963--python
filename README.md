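# fmcadti

Fragment-based drug–target interaction (DTI) prediction. Drug SMILES
strings are fragmented by **branch chain mining** (BCM: branch chains,
common substructures, short synthetic fragments); protein sequences by
**category fragment mining** (CFM: amino acids mapped onto eight
physicochemical categories A–H, then partitioned into k-grams). Fragment
id sequences feed an embedding layer, two parallel CNN blocks
(1D conv → batch norm → ELU, ×3), a **shared-weight multihead cross
attention** module (the same Q/K/V projection parameters serve both the
drug→protein and protein→drug passes), a residual mix with the original
CNN features, and an adaptive-max-pool + 3-layer FCN classifier trained
with binary cross-entropy.

The network runs on a small NumPy reverse-mode autodiff engine
(`fmcadti.autograd`) — no deep-learning framework required. Gradients
are verified against finite differences in the test suite.

## Layout

| module | contents |
| --- | --- |
| `fmcadti.bcm` | SMILES tokenizer + branch-chain / common-substructure / synthetic fragmentation |
| `fmcadti.cfm` | amino-acid category mapping + k-gram splitting, FASTA reader |
| `fmcadti.vocab` | fragment vocabularies, fixed-length id encoding, TSV/CSV dataset reader |
| `fmcadti.autograd` / `fmcadti.nn` | tensor engine and layers (conv, batch norm, dropout, attention, Adam) |
| `fmcadti.model` | `ModelConfig`, `FMCAModel`, loss, checkpoints |
| `fmcadti.train` | stratified splits, 5-fold CV, training loop, AUC/AUPR/accuracy/precision/recall |
| `fmcadti.synth` | synthetic planted-rule dataset generator |
| `fmcadti.experiment` | the canonical desk-scale synthetic benchmark run |

## CLI

```bash
fmca fragment --drug "CC(=O)Oc1ccccc1"        # ftype<TAB>text lines
fmca fragment --protein MKTAYIAK --k 3
fmca synth --n 400 --seed 11 --out data.tsv   # planted-rule dataset
fmca train --data data.tsv --config config.yaml --out run/
fmca evaluate --checkpoint run/checkpoint.npz --data data.tsv
fmca predict --checkpoint run/checkpoint.npz --drug CCO --protein MKTAYIAK
```

`config.yaml` holds optional `model:` (fields of `ModelConfig`) and
`train:` (fields of `TrainConfig`) sections; defaults are the published
full-scale settings (embedding 512, 4 heads, drug kernels 3/3/3,
protein kernels 4/6/8, lr 1e-5, batch 64, weight decay 1e-4,
dropout 0.1). `ModelConfig.small()` is the desk-scale variant used in
the tests. Ablation variants are config switches:
`ablation: no_cross_attention` removes the attention module,
`ablation: no_original_feature` drops the residual mix.

## Acceptance

The acceptance contract is property-based (attention oracle
equivalence, weight-sharing identity, atom conservation, metric
oracles, end-to-end learnability on synthetic data); it lives in
`tests/test_acceptance.py`, one test per criterion. The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an installation smoke check and writes the (empty) numeric-target
report — there are no headline numbers to recompute at desk scale.

## Data formats

Interaction tables are TSV/CSV with header columns
`smiles, sequence, label` (label ∈ {0,1}). Pattern and category tables
are JSON (`src/fmcadti/data/patterns.json`, `categories.json`) and can
be overridden per call or via CLI flags. Checkpoints are single `.npz`
files containing parameters, config, and both vocabularies.
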