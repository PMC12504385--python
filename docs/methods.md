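# Methods

This note documents the models, algorithms and numerical choices behind
`mbcatt`: a hybrid brain–computer-interface pipeline that decodes cognitive
state from simultaneously recorded EEG and fNIRS, fusing the two modalities
with bidirectional multi-head cross-attention.

## Problem setting

Two within-subject paradigms are supported:

* **n-back** (working-memory load): blocks of 2 s instruction, 40 s task,
  20 s rest; classes `0back`, `2back`, `3back`.
* **Word generation (WG)** (language activity): 2 s prompt, 10 s task,
  13–15 s rest; classes `WG` (silent word listing) vs `BL` (fixation
  baseline).

EEG is 30 channels at 200 Hz band-limited to 1–40 Hz; fNIRS is 36 channels
of oxy- (HbO) and deoxyhemoglobin (HbR) concentration change at 10 Hz.
Only the task period of each block is analysed; it is cut into 5 s windows
advanced by 1 s (36 windows per n-back block, 6 per WG block), and the
classifier operates on windows.

## Model

Each modality has its own convolutional branch operating on a one-channel
2-D plane laid out `[time x channels]`:

* **EEG branch** — three temporal convolutions with (7, 1) kernels (the
  kernel slides along time; channels stay independent), then three (4, 4)
  convolutions that mix neighbouring channels; ReLU after every
  convolution, max pooling then batch normalization per stage; the map is
  flattened into two fully connected layers.
* **fNIRS branch** — the same pattern with two (4, 1) and two (2, 2)
  convolutions.  HbO and HbR are stacked to 72 input rows.

Branch outputs are projected by a learned linear map into L tokens of width
`d_model` per modality and fused by **bidirectional 4-head cross-attention**:
EEG queries attend to fNIRS keys/values and vice versa, each direction with
its own Q/K/V/output projections, scaled dot-product weights
`softmax(QKᵀ/√d_head)` per head, heads concatenated and linearly mixed.
Attended tokens are mean-pooled, the two modality vectors concatenated, and
a linear softmax head yields class probabilities; no residual connections
or layer norm are added around the attention block.  Training minimizes
cross-entropy with Adam at learning rate 1e-3 for a fixed 60 epochs
(n-back) or 70 epochs (WG); no early stopping.

Ablation variants share the branch architectures exactly: `concat_ablation`
replaces attention with feature concatenation; `eeg_only` / `fnirs_only`
keep one branch plus the classifier head.

### Architecture choices that were genuinely open

The kernel counts and sizes, the 4 heads, ReLU, max pooling, batch
normalization and the two FC layers are fixed by the method definition.
Everything else is implementation-chosen and configurable:

| parameter | default | rationale |
|---|---|---|
| EEG filters per layer | 4, 4, 8, 8, 16, 16 | parameter count ~1.7e5 total; trainable on one CPU |
| fNIRS filters | 8, 8, 16, 16 | the 72×50 input is cheap |
| pooling | (4,1), (4,1), (2,1) then (2,2), (2,2), — per EEG layer; (2,1), (2,1), (2,2), (2,2) for fNIRS | one pool per conv stage, front-loaded so the 1000-sample time axis shrinks before the (4, 4) stack; pool sizes/counts are not fixed by the method description |
| stage order | conv → ReLU → pool → batch norm | a switch (`bn_before_pool`) flips the ambiguous pool/norm order |
| FC widths | 128, 64 | |
| `d_model` | 64 | divisible by 4 heads |
| tokens L | 4 | attention over a single FC vector is degenerate (sequence length 1); the projection is reshaped into L tokens per modality. `tokens=1` reproduces the literal single-token reading |
| dropout | 0.25 | after the first FC layer |
| batch size | 32 | more Adam steps at desk-scale window counts; lower peak im2col memory |
| loss | cross-entropy | natural choice for softmax classification |
| fusion head | mean-pool attended tokens → concatenate → linear | whether attended features are summed, concatenated or gated before classification is open; the plain concatenation of attended features is the most literal reading. A residual variant (attended plus unified-space features) was evaluated and did not improve held-out accuracy, so no residual connections or layer norm are added |
| weight init | Kaiming-uniform (convs), Xavier-uniform (linear), zero biases | fixed by the model seed |

The fNIRS model input is the union of HbO and HbR (both are recorded; the
method description does not choose between them).

## Numerical engine

No deep-learning framework is used: layers (conv via im2col + GEMM in a
channels-first layout, max pooling, batch norm, linear, dropout), the
cross-attention block, softmax cross-entropy and Adam are implemented
directly on numpy with hand-derived backward passes, verified against
central finite differences in the test suite.  Training pins BLAS to one
thread (via `threadpoolctl`), which makes the whole pipeline — generator →
windows → training → metrics — bit-reproducible from a single master seed.
Max-pool gradient ties route to the first maximal element; argmax
prediction ties break toward the lowest class index.

## Evaluation protocol

* **Within-subject split**: stratified 80/20 at the window level
  (`grouping="window"`).  Because consecutive windows overlap by 4 s,
  window-level splitting leaks trial-specific signal between train and
  test; `grouping="trial"` keeps each task block intact on one side and is
  used wherever that leakage would confound a comparison (notably the
  ablation study).  An optional 5-fold cross-validation inside the
  training subset is available (`inner_cv`).
* **Whole-data 5-fold CV**: windows pooled across subjects, stratified
  folds, per-fold rows plus the average.
* **Metrics**: accuracy, precision, recall and F1 from the confusion
  matrix, with `accuracy = (TP+TN)/(TP+TN+FP+FN)`, `precision = TP/(TP+FP)`,
  `recall = TP/(TP+FN)`, `F1 = 2PR/(P+R)` per one-vs-rest class.  Macro
  averaging is the headline number (the paradigms are class-balanced);
  micro and per-class values are always reported.  Zero-denominator classes
  contribute 0 with a warning.
* **Statistics**: two-sided paired t-tests (df = n−1) compare the full
  model with each baseline across seeds or subjects; exact p-values are
  reported against the 0.05 threshold, with no multiple-comparison
  correction.  Zero-variance differences are reported as degenerate and
  flagged.

## Synthetic data generator

The generator's contract is statistical, not physiological realism: it
reproduces the paradigm timing exactly and plants controllable class
structure.

* **EEG** = unit-variance 1/f (pink) noise per channel, inter-channel
  correlation 0.3 (volume-conduction proxy), plus a band-limited sinusoid
  on the first 10 channels during task periods: theta (4–7 Hz) with power
  increasing in working-memory load for n-back, alpha (8–12 Hz) suppressed
  during WG.  `eeg_snr` is the ratio of class-signal band power to noise
  power.
* **fNIRS HbO** = a double-gamma hemodynamic response (6 s peak, 16 s
  undershoot at 1/6 amplitude, 2 s lag) convolved with the task boxcar,
  scaled by a class-dependent amplitude and per-channel gain on the first
  18 channels, over slow sinusoidal drift (sd 0.5) plus white noise
  (total nuisance sd 1).  `fnirs_snr` scales the response amplitude.
  **HbR** = −0.4 × HbO plus independent noise.
* `complementarity="split"` divides the 3-class structure across
  modalities: EEG separates `0back` from the two high-load classes but not
  `2back` vs `3back`; fNIRS separates `3back` only.  Neither modality
  alone can solve the task — the regime in which fusion matters.

What the generator does **not** emulate: scalp topography and optode
geometry, EOG/motion artifacts, inter-subject variability structure,
non-stationarities, or realistic spectra beyond 1/f.  Passing tests on
synthetic data therefore demonstrate that the implementation learns and
fuses the kind of structure these signals carry — not that the reported
accuracies transfer to any real recording.

## Problem sizes

All experiments are desk-scale by design, chosen for single-CPU runtimes:
the learnability run pools 2 synthetic subjects (one series per subject, 72
windows per class, `eeg_snr=4`, `fnirs_snr=4`) and trains the full 60
epochs; the WG run uses 5 trials per class for 70 epochs; the ablation
study uses one subject per seed (2 trials per class, `eeg_snr=1`,
`fnirs_snr=1.5`, split complementarity), a trial-grouped 50/50 split, 15
epochs and batch 16 across 8 seeds.  These sizes, not the full 26-subject
protocol, are what the bundled tests and the acceptance script exercise.

## Known limitations

* On the split-complementarity synthetic task the advantage of attention
  fusion over plain feature concatenation is small: each modality's class
  signal is a level (band power, response amplitude), so a linear head on
  the concatenated branch features is already sufficient for the decision
  rule, and the attention model's edge reduces to an optimization effect.
  The full model beats both unimodal variants decisively; against
  concatenation it is statistically indistinguishable at the bundled
  8-seed scale.  A task whose classes depend on nonlinear cross-modal
  conjunctions would separate the mechanisms more sharply.

* The attention token structure (L=8-style reshaping) is one defensible
  reading of a method description that feeds FC vectors to multi-head
  attention; alternatives (e.g. per-channel tokens) are not implemented.
* Ingestion of the original BBCI/MATLAB dataset is an extension point: the
  on-disk container (`.npy` arrays + JSON sidecar) is documented and
  language-portable, but no `.mat` reader is included.
* EOG-based artifact removal is out of scope; real data are assumed
  pre-cleaned.
* Training is CPU-only and single-threaded; there is no GPU path.
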