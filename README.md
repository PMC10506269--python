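# deepcac

Multi-label DNA sequence classification with **concatenated
attention-augmented convolution** layers, implemented from scratch on NumPy
(forward and backward passes, SGD training — no deep-learning framework
required).

Each feature-extraction layer runs several parallel branches over the same
input; every branch concatenates, channel-wise, a stride-1 "same" 1-D
convolution with multi-head scaled dot-product self-attention
(`d_conv + d_v = d_out`), so the network captures local motif features and
long-range dependencies in one layer. Three such layers (with max pooling
after the first two) feed a two-layer sigmoid classifier head trained with
per-class binary cross-entropy.

The package ships a seeded simulator of motif-embedded multi-label DNA
datasets (PWM motifs planted on random backgrounds, labels exactly matching
the embeddings), so the whole pipeline is testable end to end without any
external data download.

## Layout

| module | contents |
|---|---|
| `deepcac.data_io` | FASTA / label-TSV readers, one-hot encode/decode (`L×4`, channels A,C,G,T, `N` → zero row), 92/8 train-val split, dataset containers |
| `deepcac.attention_core` | row-softmax, single-head scaled dot-product self-attention, multi-head concat + output mix (pure functions on `L×D` maps) |
| `deepcac.cac_layers` | branch/layer/pool config dataclasses with channel accounting, functional conv / attention-augmented conv / layer forward / max-pool |
| `deepcac.nn` | batched trainable layers with manual backprop (conv, MHA, pool, dense, dropout) |
| `deepcac.model` | network assembly, BCE objective, closed-form parameter-count audit, checkpoints |
| `deepcac.training` | SGD + momentum loop, validation-accuracy early stopping (patience 20, max 200 epochs by default), best-epoch checkpoint restore |
| `deepcac.evaluation` | top-k accuracy, mid-rank ROC/AUC, step-wise AP, per-class/macro/micro reports, curve export |
| `deepcac.synthetic_data` | PWM generation and dataset simulation |
| `deepcac.cli` | `deepcac simulate / train / evaluate` |

## CLI

```sh
# 1. simulate a dataset (YAML config optional; --set overrides any key)
deepcac simulate --out runs/sim --set n=2000 --set length=100 --set n_classes=3

# 2. train (writes checkpoint.npz, history.tsv, resolved config, log)
deepcac train --data runs/sim/dataset.npz --out runs/train \
    --set model.D=48 --set model.n_heads=4 --set train.max_epochs=20

# 3. evaluate (writes metrics.tsv, topk.tsv, report.json, per-class curves)
deepcac evaluate --model runs/train/checkpoint.npz \
    --data runs/sim/dataset.npz --out runs/eval
```

All randomness is seeded through the configs; repeating a run reproduces the
metric tables byte-for-byte. Unknown config keys are rejected, and the fully
resolved config is always archived next to the outputs.

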