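# orchardvit

Vision-transformer classification of orchard fruit images with a loss
family built for class-imbalanced data, plus a fully synthetic image
generator so every component runs and is testable without downloading any
photographs.

The package is aimed at people studying automated fruit grading — variety
identification, fresh-vs-rotten sorting, disease phenotyping — and at
anyone who wants a small, fully inspectable ViT + custom-loss stack whose
every gradient is checked against finite differences.

## The model and the loss

**OAOM** (Optimized Apple Orchard Model) is a ViT-style classifier: an
image is cut into non-overlapping `Ph×Pw` patches, each patch is
flattened and sent through one shared affine projection to width *D*, a
learned positional encoding is added, a learned CLS token is prepended,
and the sequence passes through *L* pre-norm multi-head self-attention
encoder blocks; the final CLS state drives a softmax MLP head. The
reference configuration is 12 layers, *D* = 790, 12 heads, feed-forward
width 3092, 6×6 patches on a 70×70 image; tiny configurations run the
identical code path.

**MFCE** (measured focal cross-entropy) interpolates between
cross-entropy `CE(p) = −log p` and focal loss `FL(p) = −(1−p)^γ log p`
with a probability-dependent softmax gate of sharpness `dv`:

    MFCE(p) = −[ w_ce(p) + w_f(p)·(1−p)^γ ] · log p,
    w_ce(p) = σ((1−2p)·dv),   w_f = 1 − w_ce

so a poorly classified sample (small *p*) is penalised at near-CE
strength while a well-classified one is down-weighted like focal loss.
`FL ≤ MFCE ≤ CE` holds pointwise, with equality at γ = 0. The intent is
to keep minority classes from being drowned out by the majority's share
of the total loss.

The model and its training loop run on a small reverse-mode autodiff
engine over numpy (`orchardvit.autodiff`) — no deep-learning framework
required — wrapped in the scikit-learn estimator API.

## Worked example

```python
import tempfile
from orchardvit import (DatasetDesign, generate_dataset, load_dataset_arrays,
                        OAOMClassifier, confusion, report)
from orchardvit.synthetic import variety_specs

design = DatasetDesign("demo", ["gala", "granny", "fuji"], 24, 8, image_size=24)
specs = variety_specs(design.classes, clutter=0.1, noise_sd=0.01)
with tempfile.TemporaryDirectory() as d:
    generate_dataset(design, specs, d, master_seed=42)
    X, y, names = load_dataset_arrays(d, "train")
    Xt, yt, _ = load_dataset_arrays(d, "test")

clf = OAOMClassifier(image_size=(24, 24), hidden_size=32, num_layers=2,
                     num_heads=2, mlp_size=64, epochs=20, seed=0,
                     loss_kind="mfce", gamma=2.0, dv=1.0)
clf.fit(X, y)
rep = report(confusion(yt, clf.predict(Xt), m=3, labels=names))
print("final train accuracy:", round(clf.history_[-1]["train_acc"], 4))
print("test accuracy:", round(rep.accuracy, 4))
for label, s in rep.per_class.items():
    print(f"  {label}: precision={s['precision']:.3f} recall={s['recall']:.3f} f1={s['f1']:.3f}")
```

Output:

```
final train accuracy: 1.0
test accuracy: 1.0
  fuji: precision=1.000 recall=1.000 f1=1.000
  gala: precision=1.000 recall=1.000 f1=1.000
  granny: precision=1.000 recall=1.000 f1=1.000
```

Three hue-separated synthetic classes (24 training images each) are
learned perfectly by a two-layer, 32-wide model in 20 epochs — the
generator emits controllable signal, and the pipeline trains, selects
and evaluates deterministically from the given seeds.

## Command line

```bash
orchardvit datagen --preset adec --out data/adec --seed 1      # synthetic dataset tree
orchardvit losscurves --loss mfce --gamma 2 --dv 1 --dv 5 --out curves.csv
orchardvit train --config cfg.yaml --data data/adec --out runs/adec
orchardvit evaluate --checkpoint runs/adec/checkpoint.npz --data data/adec
orchardvit cv --config cfg.yaml --data data/adec --folds 10
orchardvit imbalance --majority 152 --minority 8 --out imbalance.csv
```

The YAML config has `model:`, `loss:` and `train:` sections mirroring
`OAOMConfig`, `LossParams` and `TrainConfig`; see `docs/methods.md` for
every parameter, default and the reasoning behind them.

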