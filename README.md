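# mbcatt

Cross-modal attention fusion of paired EEG/fNIRS recordings for
cognitive-state decoding.

Hybrid brain–computer interfaces record electrical brain activity (EEG,
millisecond resolution, 30 channels @ 200 Hz) together with cortical
hemodynamics (fNIRS: oxy-/deoxyhemoglobin concentration changes, 36
channels @ 10 Hz).  The two signals are complementary — EEG captures fast
oscillatory dynamics, fNIRS slow metabolic responses — and this package
implements **MBC-ATT**, a dual-branch convolutional network that fuses them
with bidirectional multi-head cross-attention, for two within-subject
paradigms: **n-back** working-memory load (`0back`/`2back`/`3back`) and
**word generation** (`WG`/`BL`).

Each modality passes through its own CNN branch (EEG: 3×(7,1) temporal then
3×(4,4) spatial convolutions; fNIRS: 2×(4,1) then 2×(2,2); ReLU, max
pooling, batch norm, two FC layers).  Branch features become L tokens per
modality in a shared hidden space; EEG queries attend to fNIRS keys/values
and vice versa through 4-head scaled dot-product attention,

  Attention(Q, K, V) = softmax(QKᵀ/√d_head) V,

and the attended, pooled features are concatenated and classified.
Accuracy, precision, recall and F1 come from the confusion matrix; the
fusion mechanism is validated by an ablation (attention replaced by
concatenation; unimodal branches) with paired t-tests.

The package contains everything needed to run end to end without any
external data: a synthetic paired-signal generator that reproduces the
paradigm timing and plants controllable class structure in the theta/alpha
band power (EEG) and hemodynamic response amplitude (fNIRS), a
preprocessing pipeline (1–40 Hz Butterworth bandpass, polyphase
resampling, trial segmentation, 5 s / 1 s sliding windows), the network
with all ablation variants implemented directly on numpy with hand-derived
backprop, and the full evaluation protocol.  See `docs/methods.md` for the
model, generator and protocol details.

## Worked example

```python
import numpy as np
from mbcatt import (SynthConfig, generate_subject, build_window_set,
                    ModelConfig, build_variant, TrainSpec, train, evaluate,
                    split_within_subject)

cfg = SynthConfig(paradigm="nback", trials_per_class=1,
                  eeg_snr=4.0, fnirs_snr=4.0, seed=11)
ws = build_window_set(generate_subject(cfg, 0))   # 108 windows, 3 classes
tr, te = split_within_subject(ws, 0.8, seed=11)
model = build_variant("full", ModelConfig(n_classes=3), seed=11)
train(model, tr, TrainSpec(epochs=20, seed=11))
rep = evaluate(model, te)
print(f"held-out accuracy {rep.accuracy:.3f}")
```

prints

```
held-out accuracy 0.955
```

— one synthetic subject (one 40 s block per class, high SNR), 20 training
epochs: 95.5% of the 22 held-out 5 s windows are assigned the correct
working-memory load.  `rep` also carries precision/recall/F1 (macro and
per-class) and the confusion matrix (`rep.confusion.plot(path)` renders a
heatmap).

The same pipeline is scriptable from the shell:

```sh
mbcatt simulate --paradigm nback --subjects 2 --seed 1 --out raw/
mbcatt preprocess --in raw/ --out windows/
mbcatt train --windows windows/S01_windows.npz --epochs 60 --out run/
mbcatt evaluate --model run/model.npz --windows windows/S01_windows.npz --out eval/
mbcatt ablate --n-seeds 8 --out ablation/
```

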