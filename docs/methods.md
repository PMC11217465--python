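# Methods

## Problem setting

Particles imaged under a microscope — negatively stained virions in
transmission electron microscopy, blood cells in light microscopy — have no
preferred orientation: rotating the sample grid does not change what the
particle is. A classifier for such images should therefore be *invariant*
to global rotations. Two routes exist: teach a plain convolutional network
the invariance by augmenting the training set with rotated copies, or build
the invariance into the network with group-equivariant convolutions. This
package implements both routes on a common footing and the analyses that
compare them: convergence speed, accuracy, and data efficiency.

## Group algebra (`rotequiv.groups`)

The point groups are p4 (rotations by multiples of 90°, order 4) and p4m
(the same rotations combined with a left-right reflection, order 8 — the
dihedral group D4). Elements are pairs `(mirror, rotation)` acting on an
image by mirror first, then counterclockwise rotation. The quarter-turn
restriction means every action is an exact index permutation
(`fliplr`/`rot90`) with no interpolation; even-sized arrays rotate about
the array centre, so no centre pixel is needed.

Design choices that the mathematics leaves open, fixed once here:

* rotation direction counterclockwise for positive indices;
* reflection about the vertical axis (left-right flip);
* composition convention "apply h, then g" for `compose(g, h)`.

The Cayley table is *derived* at group construction by composing actions on
an asymmetric probe array rather than hard-coded; this makes the table the
single source of truth, so the group-convolution index bookkeeping can
never drift from the action convention. Element order (rotations first,
then mirrored elements, each by increasing quarter turn) is fixed so the
group axis of feature stacks is reproducible across runs and files.

## Group convolutions (`rotequiv.gconv`, `rotequiv.conv_engine`)

The lifting convolution maps a planar image to a stack with one slice per
group element: slice g is the cross-correlation of the input with the
g-transformed kernel. The group convolution maps stack to stack: output
slice g sums over input slices h the correlation with the base kernel slice
g⁻¹h, spatially transformed by g (the regular-representation construction).
Group pooling takes the per-pixel maximum over the group axis, converting
equivariance into invariance; after a global spatial pool the network
output is fully rotation-invariant.

Numerical choices:

* **Correlation convention.** "Convolution" is implemented as
  cross-correlation, the usual deep-learning convention; the classical
  kernel flip is absorbed into the group bookkeeping. The binding contract
  is the equivariance identity `layer(g·x) = g·layer(x)`, which the test
  suite checks exhaustively over group elements, exactly on integer data.
* **Kernel expansion.** All transformed kernel copies are materialized into
  one planar weight tensor and dispatched to a single im2col correlation
  primitive. The expansion is a permutation of weight entries, so its
  gradient adjoint applies the inverse group elements; correctness is
  checked against independent nested-loop implementations of the defining
  sums and by finite differences.
* **Bias** is one scalar per output channel, shared across the group axis —
  anything per-slice would break equivariance.
* **Zero padding** everywhere. Padding breaks exact translation
  equivariance at borders but not 90°-rotation equivariance of square
  inputs, which is the property under test.
* **Precision.** All arithmetic is float64. Integer-valued test inputs make
  the equivariance identities exact (deviation 0.0); built classifiers
  satisfy logit invariance to ~1e-13, far inside the 1e-4 acceptance
  tolerance.

## Architectures (`rotequiv.architectures`)

One declarative `ArchitectureConfig` describes both the baseline CNN and
its equivariant twin. The full-scale default is a VGG16-style classifier
for 256×256 grayscale input: thirteen convolutions with channel widths
32-32-64-64-128-128-128-256-256-256-256-256-256, layers 1–12 as (3,1,1)
and layer 13 as kernel 4, stride 1, padding 0; max pools after conv layers
2, 4, 7, 10, 13 (four 2×2 stride-2, then a global 13×13); linear stack
4096–4096–classes with dropout 0.5 after each hidden linear layer; ReLU
activations; He initialization; no batch normalization.

Two schedule entries required interpretation and are package choices:

* A conv stride of 0 is impossible, so layer 13 is read as kernel 4,
  stride 1, padding 0 — the only reading for which the following 13×13
  global pool fits (16 − 4 + 1 = 13).
* Pool placement after layers 2, 4, 7, 10, 13 is the standard VGG16
  placement and the unique one making the printed pool specifications and
  the 256-wide first linear layer consistent at input 256.

The equivariant twin replaces conv 1 with a lifting convolution, convs
2–13 with group convolutions, halves every channel width
(`channel_divisor=2`), and inserts a single group-pool between the final
spatial pool and the linear stack. On p4 the halving exactly preserves each
group-to-group layer's weight count (half the channels in and out × 4
kernel slices); the lifting layer has half the baseline weights and the
first linear layer takes 128 rather than 256 features — a direct
consequence of halving everywhere, reported rather than hidden. On p4m the
divisor stays 2 by default and parity no longer cancels exactly; the
parameter table reports the actual counts. He fan-in for group layers
includes the group axis (in_channels × |G| × k²).

A `desk_preset` shrinks the schedule to five convolutions
(8-8-16-16-32) for 32×32 or 64×64 input, keeping every structural motif
(3×3 convs, final 4×4 conv, 2×2 pools, global pool to 1×1,
dropout-separated linear stack). It exists so the full protocol runs on a
single CPU in minutes; all structural and invariance tests that bind the
full-scale model also run against it.

## Training engine (`rotequiv.nn`, `rotequiv.training`)

The layer engine is a compact numpy implementation with explicit
forward/backward passes: im2col correlation, max pooling with argmax
routing, group pooling, inverted dropout, linear layers, softmax
cross-entropy, and Adam with the conventional moment defaults
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Every gradient is validated against
central finite differences in the test suite.

Reference training settings: Adam at learning rate 1e-5, 100 epochs, no
early stopping, no schedule, no weight decay. Batch size is not part of
the reference description; the default is 32 and it is configurable.
Desk-scale runs use `desk_training_config` (learning rate 1e-3, 15 epochs,
batch 16): a miniature network on a few hundred images makes no visible
progress in 15 epochs at 1e-5, and 1e-3 is the conventional Adam rate for
small networks. Shuffling and dropout draw from a single seeded generator,
so a fixed seed reproduces the loss sequence exactly in single-threaded
execution.

The convergence summary of a learning curve: top accuracy is the maximum
validation accuracy over epochs; the stable epoch is the *first* epoch
reaching at least 95% of it (ties count, per "at least"); stable accuracy
and time-until-stability are read at that epoch. Wall-clock time includes
per-epoch validation and is hardware-dependent, so it is recorded but
never asserted; reproducible comparisons use epoch counts.

## Synthetic data (`rotequiv.synthetic`)

Each class is a rotation-invariant morphology: a Gaussian-profile ring
(radius, thickness), optionally a corona of Gaussian spikes just outside
the ring (corona-like glycoprotein fringe), optionally a radial sinusoidal
interior texture (capsid-like). Classes cycle through these three families
at increasing radii, so any two classes differ in at least one parameter.
A sample is its class template at a uniformly random orientation —
quarter-turns by default (`orientation_mode="p4"`, exact, interpolation
free), or continuous angles via bilinear interpolation when explicitly
requested (excluded from exact-equivariance tests because interpolation
breaks exactness) — shifted by an integer jitter of ±2 px (wrap-around;
templates keep a background margin) and corrupted with additive Gaussian
noise clipped to [0, 1].

Default conditions: 64×64 images (256×256 available), noise sd 0.15,
jitter 2 px, 4 classes. The noise level is chosen to resemble the low
signal-to-noise of stained micrographs while leaving the classes
learnable from tens of examples; with weak noise every model saturates at
100% and comparisons are uninformative. What the generator does *not*
emulate: contrast-transfer effects, stain granularity, debris and
overlapping particles, illumination gradients, class-dependent scale
variation. Passing tests on this data demonstrate properties of the
learning machinery — equivariance, convergence behaviour, data-efficiency
trends — not performance on real micrographs.

Dataset procedures:

* **Orbit augmentation**: each training image is rotated by 90°, 180°, 270°
  and reflected, giving its full 8-element p4m orbit (identity included).
* **Rebalancing**: every class is downsampled to the smallest class count;
  augmented copies are removed first, then originals uniformly at random.
  Fourteen classes at minimum 93 give the 1302-sample reference total.
* **Subsampling** for size sweeps is class-balanced (quotas differ by ≤ 1)
  and *nested*: one seeded permutation per class, prefixes taken, so
  smaller subsets are contained in larger ones for the same seed.
* **Cross-validation folds** are class-stratified. Counts rarely divide
  evenly by k (123 by 5 does not): `mode="even"` partitions into folds
  differing by ≤ 1; `mode="fixed"` draws k disjoint test folds of an exact
  per-class size and leaves the remainder permanently in training, which
  reproduces the 100-train/23-test per-class layout from 123-image
  classes. Both modes are provided because the reference description is
  compatible only with the fixed-size reading.
* **I/O**: grayscale PNGs (8- or 16-bit; 16-bit round-trips [0,1] pixel
  values within 1/65535) plus a CSV manifest with header
  `filename,label,split,is_augmented,provenance`.

## Evaluation and scaling (`rotequiv.evaluation`)

Confusion matrices use rows = actual, columns = predicted. Sensitivity and
specificity are macro-averaged (unweighted over classes, one-vs-rest);
"average" is ambiguous between macro and micro, so macro is the default
and `micro_sensitivity` is provided alongside. Model comparisons use the
relative improvement 100·(new − baseline)/baseline, reported to one
decimal; sensitivity/specificity to two decimals.

Data efficiency is modelled as error = a·n^k, fitted by OLS of log error
on log n (natural logs; the slope is base-invariant). The *end error* of a
run is 1 − final-epoch accuracy on the held-out set by default
(`error_from="best"` switches to best-epoch error; the choice is
configurable because either reading is defensible). One power law is
fitted per condition on per-size mean errors; per-seed cells are kept so
per-seed fits are possible. Mean errors of exactly 0 are floored at 1e-6
before the log fit (a perfect score cannot enter a log-log regression);
sweeps should use sizes small enough that errors stay positive.

## Experiment protocol (`rotequiv.pipeline`)

Four conditions — {CNN, GCNN} × {no augmentation, p4m orbit augmentation}
— each repeated over a seed list (default 3 at desk scale; the reference
protocol used 5), yield three planned comparisons: Control 1 (CNN+aug vs
CNN), the main hypothesis (GCNN vs CNN+aug), and Control 2 (GCNN+aug vs
GCNN). Before any GCNN trains, a guard verifies logit invariance of the
freshly built model under its group (tolerance 1e-4) and aborts the
condition on failure. Reports carry mean ± sd of top accuracy, mean stable
epoch, epoch ratios, and wall-clock ratios (the last reported only, never
asserted). Output layout: `configs/`, `curves/`, `reports/` under the run
directory.

## Problem sizes

Chosen so the full test suite and the acceptance script each run in
minutes on one CPU: desk experiments use 4 classes × 50 images at 64×64
(140 training / 30 validation after the stratified 70/15/15 split), the
desk architecture preset, 15 epochs, 3 seeds; equivariance suites use
5×5–8×8 integer feature maps exhaustively over group elements; the
power-law recovery uses 100 replicates of 50 points. The directional
comparison (GCNN ≥ CNN without augmentation) is asserted as a direction
only; its margin is reported, since at these sizes run-to-run variance is
a substantial fraction of the gap.

## Known limitations

* No batch normalization or regularization beyond dropout, by design.
* The steerable-basis parameterization used by E(2)-equivariant frameworks
  differs numerically from plain kernel expansion, so weight-level
  replication of models built with those libraries is not possible (and
  not attempted); agreement is at the level of the defining equivariance
  property.
* Wall-clock convergence ratios depend on hardware and implementation
  constant factors; only epoch-based convergence statements are
  reproducible here.
* The synthetic generator's homogeneous backgrounds and exact quarter-turn
  orientations favour clean equivariance; continuous-angle mode exists but
  interpolation makes invariance approximate.
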