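# rotequiv

Rotation-equivariant convolutional classifiers for microscopy-style
images, built from scratch: p4/p4m group convolutions, paired
baseline/equivariant VGG16-style architectures, a synthetic
rotation-invariant image generator, and the convergence and
data-efficiency analyses that compare the two model families.

## Why

Particles under a microscope — stained virions in transmission electron
microscopy, blood cells in light microscopy — have no preferred
orientation, so their class is invariant to global rotation. A plain CNN
must *learn* that invariance, typically from rotation-augmented training
data. A group-equivariant CNN (GCNN) has it by construction: its
convolutions commute with the symmetry group

    C(T(x)) = T(C(x)),

where T is a group action and C a layer. For the input layer the
G-convolution over a group G is

    z(x, y)[g] = Σᵢ Σⱼ k(i, j) · f[g⁻¹(x−i, y−j)],   g ∈ G,

producing one feature-map slice per group element; deeper layers convolve
group stacks with kernels indexed by g⁻¹h, and a final max over the group
axis (group pooling) plus global spatial pooling makes the classifier
fully invariant. Here G is p4 (rotations by 0°, 90°, 180°, 270°) or p4m
(adding a reflection; order 8). Because quarter-turn actions are exact
pixel permutations, equivariance holds *exactly* — the test suite asserts
zero deviation on integer inputs.

The package lets you ask, on controlled synthetic data: does the GCNN
reach higher accuracy than an augmented CNN? Does it converge in fewer
epochs? Is it more data-efficient — i.e., does its error fall faster with
training-set size n when modelled as a power law error = a·nᵏ (fitted by
linear regression in log-log space)?

The networks run on a self-contained numpy engine (im2col convolutions,
explicit gradients, Adam), so there is no deep-learning-framework
dependency; everything is float64 and deterministic given seeds.

## Worked example

Generate a 4-class rotation-invariant dataset (ring / spiked-corona /
textured-capsid morphologies at random orientations with noise), train
the baseline CNN and the p4 GCNN without augmentation, and compare:

```python
import numpy as np
from rotequiv import (SyntheticDatasetSpec, generate_dataset,
                      desk_preset, build_classifier,
                      desk_training_config, train, stability_metrics)
from rotequiv.synthetic import split_dataset, samples_to_arrays

spec = SyntheticDatasetSpec(n_classes=4, per_class_counts=(50,) * 4,
                            image_size=64, seed=7)
samples, _ = generate_dataset(spec)
splits = split_dataset(samples, (0.7, 0.15, 0.15), seed=1)
tx, ty = samples_to_arrays(splits["train"])
vx, vy = samples_to_arrays(splits["validation"])

for name, equivariant in (("cnn", False), ("gcnn", True)):
    model = build_classifier(desk_preset(64, 4, equivariant=equivariant), seed=0)
    curve, model = train(model, tx, ty, vx, vy,
                         desk_training_config(n_epochs=15, seed=0))
    m = stability_metrics(curve)
    print(f"{name}: top accuracy {m.top_accuracy:.3f}, "
          f"stable at epoch {m.stable_epoch}")
```

Output:

```
cnn: top accuracy 1.000, stable at epoch 13
gcnn: top accuracy 1.000, stable at epoch 7
```

Both families reach the accuracy ceiling on this single-seed example, but
the GCNN reaches 95% of its best validation accuracy at epoch 7 where the
CNN needs 13 — built-in invariance converges faster because no capacity is
spent learning each orientation separately. Across 3 seeds the mean top
validation accuracy is 1.000 for the GCNN vs 0.990 for the CNN. The
GCNN's logits are invariant to any quarter-turn of its input to ~1e-13,
so it needs no rotation augmentation; the CNN's gap widens as training
data shrinks, which `rotequiv scaling` quantifies via the power-law
exponent.

The same protocol is available from the shell:

```sh
rotequiv generate --n-classes 4 --per-class 50 --out data/
rotequiv main-experiment --seeds 0,1,2 --epochs 15 --out runs/main
rotequiv scaling --sizes 48,96,140 --out runs/scaling
rotequiv crossval --folds 5 --out runs/cv
```

`main-experiment` runs the four-condition protocol (CNN/GCNN × with/
without 8-fold rotation-reflection orbit augmentation) and prints the
three planned comparisons; `scaling` fits one power law per model family
and prints `error ~ a * n^k`.

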