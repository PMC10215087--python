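# rkseg — segmentation networks built as one Runge–Kutta time step

`rkseg` implements a family of encoder-decoder-free semantic-segmentation
networks for 2-D (bio)medical images.  Instead of an encoder, a decoder
and experimentally placed skip connections, the whole forward pass is a
single time step of an s-stage Runge–Kutta method,

    y1 = y0 + Σ_{i=1..s} U(e_i),

where `y0` is the image lifted to `k` feature channels by a pre-processor,
each stage increment `e_i` is computed by a small two-convolution node at
its own spatial scale (max-pooled inputs, divisor 2^i), `U` interpolates
the increments back to full resolution, and a post-processor decodes the
final state `y1` into per-class logits.  Every node and connection is
dictated by the integrator, which is why the family is tiny (0.1–0.35 M
parameters at width `k = 32`) while remaining competitive on multi-organ
segmentation.  Six variants are provided: scale orientation L
(large→small) or R (reversed) × stage wiring E (explicit), I (implicit,
with slope nodes X_i) or R (reduced implicit).

The package is aimed at researchers who want an exactly reproducible,
dependency-light reference implementation of the architecture family:
deterministic builds, closed-form parameter accounting, a seeded
synthetic-data benchmark, and a CPU-only numpy compute backend with its
own autodiff (validated against finite differences), so no GPU framework
is required.

## Worked example

```python
from rkseg import (ArchitectureConfig, RKSeg, SyntheticSpec, generate,
                   count_parameters_closed_form)
from rkseg.synth import split

# the heart-task configuration: depth 6, width 32, 1 modality, 2 classes
cfg = ArchitectureConfig(orientation="L", backbone="E", depth=6, width=32,
                         in_channels=1, num_classes=2)
report = count_parameters_closed_form(cfg)
print(report.total, report.total_millions_2dp)   # -> 278370 0.28

# train the smallest explicit variant on a seeded synthetic task
spec = SyntheticSpec(n_cases=60, image_size=(64, 64), seed=0)
train_set, val_set = split(generate(spec), 12)
model = RKSeg(ArchitectureConfig("L", "E", 3, 8, 1, 2), epochs=8, seed=0)
results = model.fit(train_set, val_set)
print(results.summary())
```

prints

```
278370 0.28
RKSeg fit results
========================================================
variant        RKSeg-L / backbone E
depth / stages 3 / 3    width k = 8
channels in    1    classes 2
parameters     7,242 (0.01 M)
optimizer      SGD(nesterov), lr0=0.01, momentum=0.99, schedule=poly
epochs         8    batch 8    seed 0
train cases    48    val cases 12
final loss     0.1645
final val DSC  0.8946 (per class {1: 0.8946})
best val DSC   0.8946 at epoch 8
wall time      7.8 s
========================================================
```

`278370` is the exact trainable-scalar count of the heart configuration
(0.28 M after rounding — the published table value), and the fit summary
shows the held-out Dice similarity coefficient (DSC,
`2|A∩B|/(|A|+|B|)`) of the foreground class after eight epochs of
Nesterov-SGD on the synthetic two-class task.  `results.predict(image)`
returns label maps, `results.evaluate(samples)` a per-class Dice report,
and `results.save(path)` a checkpoint that reloads bitwise.

## Command line

```bash
rkseg count-params --backbone E --depth 6 --width 32 --num-classes 2
rkseg build --backbone I --depth 4 --dry-run       # node/width/scale table
rkseg make-synth --out data/ --n-cases 50 --seed 1 # MSD-style NIfTI layout
rkseg train --config exp.yaml --data data/ --out run/
rkseg eval --checkpoint run/best.npz --data data/ --out run/eval
rkseg predict --checkpoint run/best.npz --data data/ --out run/pred
```

Config files are YAML with `model`, `train` and `data` sections; datasets
use the Medical-Segmentation-Decathlon folder convention
(`imagesTr`/`labelsTr` + `dataset.json`) or a paired-PNG dialect.

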