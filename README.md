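# colonyseg

Headless instance segmentation for microbial microcolonies in 2-D
microscopy — the complete workflow from training-data creation to result
export, as a Python library with a thin CLI.  It targets time-lapse
phase-contrast or fluorescence imaging of dense, rod-shaped bacteria
(*B. subtilis*, *E. coli*, *C. glutamicum*-like morphologies), where cells
touch but never overlap and per-cell growth statistics are the quantity of
interest.

The pipeline:

1. **Training data** — random crop proposals from non-overlapping image
   regions, optional pre-labeling with an existing model, automatic
   train/val/test assignment (0.600/0.225/0.175 largest-deficit rule).
   A synthetic microcolony generator (`colonyseg.fixtures`) stands in for
   the microscope so every stage runs offline with exact ground truth.
2. **Label representations** — either a 3-class boundary map (background /
   interior / boundary) or a pair of distance maps: the per-instance
   normalized distance-to-background *D_cell* and the inverse distance to
   the nearest neighboring cell *D_neigh* = clip(1 − d/r_cut, 0, 1)^γ.
3. **Networks** — U-Net (depth 5, two 3×3 conv + BN + ReLU per level); one
   softmax decoder for the boundary method, two regression decoders for the
   distance method.  34.5 M / 50.2 M parameters at full width; an optional
   parameter budget shrinks the width down to floors of ~2 M / ~3 M.
   Implemented in pure NumPy (`colonyseg.nn`), with hand-derived backprop.
4. **Instance recovery** — seeded watershed: foreground `D_cell > th_cell`,
   seeds from `D_cell − D_neigh > th_seed` (defaults 0.09 / 0.45), flooding
   on −*D_cell*; the boundary variant floods interior seeds over the
   boundary probability.
5. **Evaluation** — AJI+ (aggregated Jaccard index with optimal one-to-one
   matching, range 0–1, 1 = perfect), grid search of the two thresholds on
   the internal test split, automatic best-model selection, CSV report.
6. **Export** — per frame: original image, 16-bit label mask, outlines,
   red-outline overlay (all .tif), polygon ROIs (JSON), and an analysis CSV
   with cell count, mean area, mean minor/major axis lengths, total area.

## Worked example

```python
import numpy as np
from colonyseg import (
    ColonyParams, generate_colony, make_targets,
    distance_postprocess, aji_plus, shape_stats,
)
from colonyseg.fixtures import make_training_set
from colonyseg.training import TrainConfig, train_models
from colonyseg.evaluation import evaluate_model

# synthetic colony with exact ground truth
sample = generate_colony(ColonyParams(n_cells=30, packing="colony", seed=7))
print("cells:", sample.mask.max())                      # cells: 30

# ideal-target round trip: representations are self-consistent
t = make_targets(sample.mask, "distance")
recovered = distance_postprocess(t[0], t[1])
print("recovered:", recovered.max(),
      "AJI+: %.3f" % aji_plus(sample.mask, recovered))  # recovered: 30 AJI+: 1.000

# train one budget-reduced distance model on 24 synthetic 128-px crops
tset = make_training_set(24, 128, seed=1)
cfg = TrainConfig(n_models=1, seed=1, param_budget=3_000_000,
                  epochs_max=30, stop_patience=30)
model = train_models(tset, cfg)[0]                      # ~3 min on one CPU

held = [generate_colony(ColonyParams(image_height=128, image_width=128,
                                     n_cells=10 + i, seed=500 + i))
        for i in range(8)]
record = evaluate_model(model, [(h.image, h.mask) for h in held])
print("AJI+ %.3f ± %.3f at th_cell=%.2f th_seed=%.2f"
      % (record.aji_mean, record.aji_std,
         record.best_params.th_cell, record.best_params.th_seed))
# AJI+ 0.547 ± 0.070 at th_cell=0.13 th_seed=0.45

st = shape_stats(recovered)
print("mean area %.1f px², mean major axis %.1f px"
      % (st.mean_area, st.mean_major_axis))
# mean area 145.7 px², mean major axis 24.7 px
```

The numbers mean: the synthetic colony contains 30 touching rods; ideal
distance targets post-process back to exactly 30 instances at AJI+ 1.000
(the representation and the watershed agree); a 3.1 M-parameter model
trained for 30 epochs on 24 small crops segments unseen colonies at
AJI+ ≈ 0.55 with automatically chosen thresholds — usable but far from the
ideal-target ceiling, as expected at this training budget; the shape
statistics are the per-frame quantities the exporter writes for growth
curves.

The same workflow is scriptable from the shell:

```sh
colonyseg simulate --out data --n-images 4 --seed 0 --modality phase
colonyseg crops --project proj --dataset ds --images 'data/image_*.tif' --crop-size 128
colonyseg train --trainset proj/ds --n-models 5 --seed 0 --budget 3000000
colonyseg eval --trainset proj/ds
colonyseg infer --images 'data/image_*.tif' --model models/<id> --out results
```

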