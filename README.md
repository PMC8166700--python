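# fundusnet

Few-parameter U-Nets for retinal vessel segmentation: a configurable
encoder–decoder family with an exact parameter-counting algebra, the fundus
preprocessing chain, a vessel-caliber-weighted focal training objective, the
four-database experimental protocol (DRIVE, STARE, HRF, CHASE_DB1), and a
synthetic fundus phantom generator so the entire pipeline runs and is tested
at desk scale, on one CPU, without downloading the public databases.

The package is for researchers studying how small a segmentation network
can be: it lets you build any member of the family from a declarative spec,
count its weights in closed form, train it under the published protocol, and
evaluate it with the published metric conventions.

## The family and its counting algebra

A member has `L` resolution levels with `f_l = F0·2^(l-1)` filters at level
`l`, blocks of `C` bias-free 3×3 convolutions each followed by ReLU and
batch normalization, 2×2 max-pooling, nearest-neighbour up-pooling followed
by a 1×1 channel-halving convolution, optional concatenation skips, and a
3×3 two-channel softmax head.  Counting kernel elements only,

    encoder level l:  9·c_in·f_l + (C−1)·9·f_l²
    decoder level l:  f_{l+1}·f_l + 9·(1+s)·f_l² + (C−1)·9·f_l²
    head:             9·F0·n_classes ,

which reproduces the published counts exactly — the default
`(L=3, F0=16, C=2, skips)` has 108,976 weights, and the count is the exact
quadratic `424·F0² + 27·F0` in the initial width (451 weights at `F0=1`).

Training minimizes a weighted focal loss plus ℓ2 regularization,

    L = (1/N)·Σᵢ −α_c·(1−pᵢ)^γ·log pᵢ · W(xᵢ) + λ·L_ℓ2 ,

with `γ=2`, `α=0.9` on vessels, and per-pixel weights
`W(x) = max(1, 1/(0.18·d_x))` on vessels (1 on background), where `d_x` is
the vessel diameter from the annotation's medial axis — thin vessels weigh
more.  Adam (0.9, 0.999) with a 10%-per-10,000-iteration learning-rate
staircase, patch sampling and affine/photometric augmentation complete the
protocol.  Metrics (AUC, sensitivity, specificity, F1, accuracy) are
computed per image inside the four-pixel-eroded field of view, binarized at
the threshold maximizing validation F1, and aggregated two-stage: per image
over training repetitions, then over images.

The networks are implemented directly in NumPy (convolutions, batch norm,
pooling, softmax, Adam, and hand-written back-propagation, verified against
finite differences); the models are small enough that CPU matrix products
are entirely adequate.

## Worked example

Generate a small synthetic database, train the 4-filter member, and
evaluate it under the published conventions:

```python
from pathlib import Path
from fundusnet import (DEFAULT_SPEC, TrainConfig, aggregate, erode_fov,
                       kernel_weight_count, load_database, make_splits, train)
from fundusnet.data_pipeline import prepare_samples, synthetic_dataset_spec
from fundusnet.evaluation import image_metrics, predict_sample, select_threshold
from fundusnet.synthetic_fundus import make_dataset, preset_a
from fundusnet.training import restore_model

root = make_dataset(12, preset_a(image_size=256), seed=7, directory=Path("synthA"))
samples = load_database(root)
db = synthetic_dataset_spec(12, 256, patch_size=64, batch_size=6)
prepared = prepare_samples(samples, db)
plan = make_splits(db, fold=0, seed=7, ids=sorted(prepared))

spec = DEFAULT_SPEC.with_(init_filters=4)
print("kernel weights:", kernel_weight_count(spec))
run = train(spec, prepared, plan, db,
            TrainConfig(max_iterations=800, validation_interval=200, seed=1))
print(f"best validation loss {run.best_val_loss:.5f} "
      f"at iteration {run.converged_iteration}")

model = restore_model(run)
by_id = {s.image_id: s for s in samples}
val = [by_id[i] for i in plan.validation]
thr = select_threshold([predict_sample(model, s) for s in val],
                       [s.annotation for s in val],
                       [erode_fov(s.fov) for s in val])
print(f"selected threshold: {thr:.4f}")
recs = [image_metrics(predict_sample(model, by_id[t]), by_id[t].annotation,
                      erode_fov(by_id[t].fov), thr, t, 0) for t in plan.test]
for m, v in aggregate(recs).mean.items():
    print(f"{m:12s} {v:.4f}")
```

Output:

```
kernel weights: 6892
best validation loss 0.02646 at iteration 800
selected threshold: 0.8039
auc          0.9764
sensitivity  0.8983
specificity  0.9331
f1           0.8760
accuracy     0.9224
```

The 6,892-weight model separates vessels from background on held-out
phantoms with AUC 0.98: the family's headline behavior — strong
segmentation from very few parameters — at toy scale.  On the real
databases the published protocol (2000+ iterations, five repetitions,
fourfold cross-validation) applies unchanged via `fundusnet.workbench`.

A CLI covers the same ground:

```sh
fundusnet count-params                 # default member: 108976 kernels
fundusnet reproduce-counts             # computed vs published counts
fundusnet synth --n 12 --size 512 --seed 0 --out synthA
fundusnet make-splits --db stare --fold 2 --seed 1
fundusnet train --db-dir synthA --db synthetic --seed 1 --out runs/r1
fundusnet run --manifest experiment.yaml --out results/
```

Real databases are consumed from a directory with `images/`, `fov/`,
`labels/` rasters and a `manifest.csv` of identifiers; databases lacking
FOV masks can use the luminance-threshold fallback
(`fundusnet.data_pipeline.fov_fallback`).

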