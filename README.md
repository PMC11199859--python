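# tffusion

Self-supervised representation learning for windowed multichannel time
series (EEG sleep stages, accelerometry, gestures) via **time-frequency
fused contrastive pre-training**: each window is augmented once in the
time domain (jitter / scaling / permutation / masking) and once in the
frequency domain (low-pass / phase shift / remove / add frequency, on
the one-sided FFT), the two views are fused at the data level with a
pair of kernel PCAs,

    x_fused = KernelPCA_t(flatten(x_t_aug)) (+) KernelPCA_f(flatten(x_f_aug)),

and a 3-block 1-D residual encoder `f : R^{S x T} -> R^D` is trained
with the NT-Xent objective over (original, fused) positive pairs,

    L_{i,j} = -log [ exp(sim(z_i, z_j)/tau) / sum_{k != i}^{2N} exp(sim(z_i, z_k)/tau) ],

with cosine similarity `sim`, temperature `tau`, and in-batch
negatives. A softmax head `g : R^D -> R^C` (256/128 hidden units,
dropout 0.2) is then fine-tuned on a small labeled split and evaluated
with accuracy, macro precision/recall/F1 and a confusion matrix.

The package is organised as scikit-learn-style estimators —
`ContrastiveEncoder` (fit/transform), `FineTuneClassifier`
(fit/predict), `KernelPCAFusion` (fit/transform) — over a NumPy
neural-network core with hand-written, finite-difference-validated
backpropagation, so the whole pipeline runs on a plain scientific
Python stack and is bit-reproducible from a seed. A synthetic-data
module generates labeled windows whose classes carry both a spectral
cue and a temporal motif, so every stage (including the
time-only / freq-only / fused ablation) is exercisable without any
external dataset. See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
from tffusion import (generate_dataset, split_dataset, SplitSpec,
                      ContrastiveEncoder, FineTuneClassifier, evaluate)

data = generate_dataset(n_per_class=167, n_classes=3, n_channels=1,
                        window=128, noise_sd=1.5, seed=1)
pre, fin, test = split_dataset(data, SplitSpec(), seed=1)   # 60/20/20

enc = ContrastiveEncoder(mode="tf-fc", epochs=30, batch_size=64,
                         learning_rate=1e-3, channels=(8, 16, 32),
                         embed_dim=64, proj_dim=32, random_state=1).fit(pre)
clf = FineTuneClassifier(encoder=enc, epochs=100, learning_rate=3e-4,
                         batch_size=32, patience=10, random_state=1).fit(fin)
rep = evaluate(clf, test)
print(f"acc={rep.accuracy:.3f}  macro P={rep.precision:.3f} "
      f"R={rep.recall:.3f} F1={rep.f1:.3f}")
print(rep.confusion)
```

Output:

```
acc=0.941  macro P=0.943 R=0.941 F1=0.940
[[34  0  0]
 [ 3 29  2]
 [ 0  1 33]]
```

`acc` is the fraction of the 102 test windows classified correctly;
the macro scores weight the three classes equally; the confusion matrix
has true classes in rows. Fine-tuning the same head from a randomly
initialized encoder (`FineTuneClassifier(encoder=None, ...)`) lands
around 0.83 on this seed — the gap is what pre-training buys.

The same pipeline is scriptable from the shell:

```bash
tffusion generate --classes 3 --per-class 167 --window 128 --noise 1.5 \
         --seed 1 --out data.h5
tffusion pretrain --data data.h5 --mode tf-fc --epochs 30 --batch 64 \
         --seed 1 --out ckpt.npz
tffusion finetune --ckpt ckpt.npz --data data.h5 --seed 1 --out model.npz
tffusion evaluate --model model.npz --data data.h5 --report report.json
tffusion ablate --seed 1 --out runs/          # tf-fc vs time-only vs freq-only
```

Runs with the same config and seed reproduce bit-identical reports.

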