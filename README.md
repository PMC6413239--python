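# polarseg

Polar-body detection in brightfield oocyte micrographs.

During micromanipulation procedures such as somatic cell nuclear transfer
and ICSI, the oocyte is rotated with micropipettes until its polar body —
the small cell sitting between the cytoplasm and the zona pellucida, a
proxy for the invisible nucleus — reaches a target position. Automating
that rotation requires detecting the polar body in every frame, including
frames where it is defocused, deformed by pipette contact, or unusually
small or large. Classical shape- and texture-based detectors fail
precisely in those frames.

`polarseg` implements a segmentation-based detector:

* an **inception-augmented U-net**: nine four-branch inception modules
  (kernels 1x1, 3x3, 1x3, 3x1 and a pooled branch) in a
  contraction-expansion layout with skip connections, mapping a grayscale
  micrograph `I ∈ [0,1]^{H×W}` to a per-pixel polar-body probability map
  `P ∈ [0,1]^{H×W}`;
* trained with the weighted objective

  ```
  L = L_dice + β · L_bce,   β = 0.5
  L_dice = 1 − (|P∩T| + ε) / (|P∪T| + ε)        (soft intersection/union)
  L_bce  = −(1/N) Σ_i [ t_i log p_i + (1−t_i) log(1−p_i) ]
  ```

  against binary annotation masks `T`;
* with paired-transform **data augmentation** (random rotation in
  [−90°, 90°], axis flips, seeded elastic deformation) expanding each
  annotated pair into four;
* and a **region-level non-maximum suppression**: connected regions of the
  probability map survive only if their peak probability reaches 0.5 and
  their area reaches a minimum pixel count; the winning region's mean
  pixel location is the polar-body centre, and no survivor means "no
  polar body". A prediction is counted correct when that centre falls
  within 10 px of the ground-truth centroid (or when absence is correctly
  declared).

Because no annotated oocyte dataset is publicly available, the package
ships a synthetic scene generator (cell, zona ring, pipettes, defocus,
deformation, size and brightness variation) so the entire
train → predict → evaluate loop is reproducible offline. The network and
its backpropagation are implemented in numpy/numba and run on a single
CPU core. See `docs/methods.md` for the full model description.

## Worked example

Run a small end-to-end experiment from Python (a few minutes on one CPU
core; the CLI equivalent is `polarseg run`):

```python
from polarseg import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    out_dir="run",
    seed=1,
    n_train_positive=300, n_train_negative=100,   # 400 training scenes
    n_test_positive=75,  n_test_negative=25,      # 100 held-out scenes
    difficulty="mixed",                            # defocus + deformation
    size=(128, 128),
    epochs=15,
))
print(report.summary())
```

```
Class       Samples  Correct     ACC
Positive         75       67   89.3%
Negative         25       23   92.0%
Summary         100       90   90.0%
```

The table mirrors how such experiments are reported: of 75 held-out
scenes that contain a polar body, 67 detections landed within 10 px of
the true centroid; of 25 scenes without one, 23 were correctly rejected.
`report.records` holds the per-sample rows (predicted and true centroids,
distance, confidence, region area) — in this run the misses are almost
all scenes whose polar body was blurred below the noise floor by the
defocus model. Artifacts (dataset manifests, checkpoint, training
history, predictions, report) are written under `run/`.

The CLI exposes the same stages individually:

```sh
polarseg synth --n-pos 300 --n-neg 100 --difficulty mixed --size 128 --seed 1 --out data
polarseg augment --manifest data/manifest.csv --out data_aug --seed 1
polarseg train --manifest data_aug/manifest.csv --out ckpt --epochs 15 --seed 1
polarseg predict --checkpoint ckpt/best --manifest data/manifest.csv --out preds.csv
polarseg evaluate --predictions preds.csv --manifest data/manifest.csv --tol 10
```

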