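"""Synthetic rotation-invariant microscopy-style datasets and split machinery.

The generator emulates the statistical structure of particle-centric
micrographs (negatively stained virions, blood cells): each class is a
radially organized morphology — a ring of given radius and thickness, an
optional corona of spikes, an internal radial texture — rendered as a
grayscale template and observed at an arbitrary global orientation with a
small translation jitter and additive Gaussian noise. Class identity depends
only on morphology, never on orientation, which is exactly the invariance a
rotation-equivariant classifier should exploit.

It is a statistical stand-in, not a physical simulation: there is no
contrast-transfer function, stain granularity, or instrument model, and
backgrounds are homogeneous. Conclusions drawn from it concern the learning
machinery (equivariance, convergence, data efficiency), not TEM physics.

The module also implements the dataset-side experimental procedures: the
8-fold p4m orbit augmentation, class rebalancing to the smallest class,
nested class-balanced subsampling for data-efficiency sweeps, stratified
k-fold construction, and PNG/CSV dataset I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd
from scipy import ndimage

from .groups import act_on_image, p4m

__all__ = [
    "ClassMorphology",
    "SyntheticDatasetSpec",
    "ImageSample",
    "DatasetManifest",
    "default_morphologies",
    "render_template",
    "generate_dataset",
    "split_dataset",
    "augment_p4m",
    "rebalance",
    "subsample_training",
    "make_cv_folds",
    "write_dataset",
    "read_dataset",
    "samples_to_arrays",
]

MANIFEST_COLUMNS = ["filename", "label", "split", "is_augmented", "provenance"]


@dataclass(frozen=True)
class ClassMorphology:
    """Rotation-invariant template parameters of one particle class.

    Lengths are fractions of the image size, so one morphology set renders
    consistently at any resolution.
    """

    class_id: int
    ring_radius: float = 0.28
    ring_thickness: float = 0.05
    n_spikes: int = 0
    texture_frequency: float = 0.0
    intensity: float = 0.9

    def __post_init__(self):
        if not 0 < self.intensity <= 1:
            raise ValueError("intensity must be in (0, 1]")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if self.ring_radius + 2 * self.ring_thickness >= 0.5:
            raise ValueError(
                f"class {self.class_id}: geometry exceeds the image half-width"
            )


def default_morphologies(n_classes: int) -> list[ClassMorphology]:
    """Distinct particle classes: bare rings, spiked coronas, textured capsids.

    Classes cycle through three families (plain ring, ring + spike corona,
    ring + internal texture) at varying radii so any pair differs in at
    least one parameter.
    """
    if n_classes < 1:
        raise ValueError("need at least one class")
    morphs = []
    for c in range(n_classes):
        family = c % 3
        step = c // 3
        radius = 0.20 + 0.05 * step
        morphs.append(
            ClassMorphology(
                class_id=c,
                ring_radius=radius,
                ring_thickness=0.035 + 0.01 * family,
                n_spikes=0 if family != 1 else 8 + 4 * step,
                texture_frequency=0.0 if family != 2 else 18.0 + 6.0 * step,
                intensity=0.9,
            )
        )
    return morphs


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Sampling plan for one synthetic dataset."""

    n_classes: int = 4
    per_class_counts: tuple[int, ...] = ()
    image_size: int = 64
    noise_sd: float = 0.15
    translation_jitter: int = 2
    orientation_mode: str = "p4"  # "p4" (exact quarter turns) or "continuous"
    seed: int = 0
    morphologies: tuple[ClassMorphology, ...] = field(default=())

    def __post_init__(self):
        counts = self.per_class_counts or tuple([25] * self.n_classes)
        object.__setattr__(self, "per_class_counts", tuple(counts))
        if len(self.per_class_counts) != self.n_classes:
            raise ValueError("per_class_counts length must equal n_classes")
        if any(c < 1 for c in self.per_class_counts):
            raise ValueError("all per-class counts must be >= 1")
        if self.orientation_mode not in ("p4", "continuous"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        morphs = self.morphologies or tuple(default_morphologies(self.n_classes))
        object.__setattr__(self, "morphologies", tuple(morphs))
        if len(self.morphologies) != self.n_classes:
            raise ValueError("morphologies length must equal n_classes")


@dataclass
class ImageSample:
    """One grayscale image in [0, 1] with its label and provenance."""

    image: np.ndarray
    label: int
    sample_id: str
    split: str = "train"
    is_augmented: bool = False
    provenance: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class DatasetManifest:
    """Tabular record of a dataset: one row per sample."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        splits = self.frame.groupby("split")["filename"]
        for a_name, a in splits:
            for b_name, b in splits:
                if a_name < b_name and set(a) & set(b):
                    raise ValueError(f"splits {a_name}/{b_name} share samples")

    @classmethod
    def from_samples(cls, samples: list[ImageSample]) -> "DatasetManifest":
        rows = [
            {
                "filename": f"{s.sample_id}.png",
                "label": s.label,
                "split": s.split,
                "is_augmented": s.is_augmented,
                "provenance": s.provenance,
            }
            for s in samples
        ]
        return cls(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))

    def class_counts(self) -> pd.Series:
        return self.frame["label"].value_counts().sort_index()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# rendering


def render_template(morph: ClassMorphology, image_size: int) -> np.ndarray:
    """Render one class template, centred, values in [0, 1]."""
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dx, dy = (xx - c) / image_size, (yy - c) / image_size
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    img = np.zeros((image_size, image_size))
    # ring
    img += morph.intensity * np.exp(-((rho - morph.ring_radius) ** 2)
                                    / (2 * morph.ring_thickness**2))
    # spike corona just outside the ring
    if morph.n_spikes:
        spike_r = morph.ring_radius + 1.8 * morph.ring_thickness
        angles = 2 * np.pi * np.arange(morph.n_spikes) / morph.n_spikes
        sigma2 = (0.6 * morph.ring_thickness) ** 2
        for a in angles:
            sx, sy = spike_r * np.cos(a), spike_r * np.sin(a)
            img += 0.8 * morph.intensity * np.exp(
                -((dx - sx) ** 2 + (dy - sy) ** 2) / (2 * sigma2)
            )
    # internal radial texture
    if morph.texture_frequency:
        interior = rho < morph.ring_radius - morph.ring_thickness
        img += interior * 0.5 * morph.intensity * (0.5 + 0.5 * np.sin(
            2 * np.pi * morph.texture_frequency * rho))
    return np.clip(img, 0.0, 1.0)


def _orient(template: np.ndarray, mode: str, rng: np.random.Generator):
    """Rotate a template by a random global orientation; returns (image, tag)."""
    if mode == "p4":
        k = int(rng.integers(0, 4))
        return np.rot90(template, k=k), f"r{k}"
    angle = float(rng.uniform(0.0, 360.0))
    out = ndimage.rotate(template, angle, reshape=False, order=1, mode="constant")
    return np.clip(out, 0.0, 1.0), f"deg{angle:.1f}"


def generate_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[list[ImageSample], DatasetManifest]:
    """Draw the dataset described by ``spec``; deterministic given its seed.

    Each sample is its class template at a random orientation, shifted by a
    small integer jitter (with wrap-around; templates carry a background
    margin so no structure crosses the border), plus clipped Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    templates = [render_template(m, spec.image_size) for m in spec.morphologies]
    samples: list[ImageSample] = []
    for label, count in enumerate(spec.per_class_counts):
        for i in range(count):
            img, tag = _orient(templates[label], spec.orientation_mode, rng)
            jx, jy = rng.integers(-spec.translation_jitter, spec.translation_jitter + 1, 2)
            img = np.roll(img, (int(jy), int(jx)), axis=(0, 1))
            img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)
            samples.append(
                ImageSample(
                    image=img,
                    label=label,
                    sample_id=f"c{label:02d}_{i:04d}",
                    provenance=f"template:c{label:02d}|orient:{tag}|jitter:{jx},{jy}",
                )
            )
    return samples, DatasetManifest.from_samples(samples)


def split_dataset(
    samples: list[ImageSample],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> dict[str, list[ImageSample]]:
    """Stratified train/validation/test split at the image level (no leakage)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    out: dict[str, list[ImageSample]] = {"train": [], "validation": [], "test": []}
    by_class: dict[int, list[ImageSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    for label in sorted(by_class):
        group = by_class[label]
        order = rng.permutation(len(group))
        n = len(group)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for rank, idx in enumerate(order):
            split = ("train" if rank < n_train
                     else "validation" if rank < n_train + n_val else "test")
            s = group[idx]
            s.split = split
            out[split].append(s)
    return out


# ---------------------------------------------------------------------------
# experimental procedures


def augment_p4m(samples: list[ImageSample]) -> list[ImageSample]:
    """Expand every sample into its full 8-element p4m orbit.

    The four rotations of the image and the four rotations of its mirror —
    eight images per original, the identity copy included and ordered by the
    canonical group order. Only the non-identity copies are flagged as
    augmented.
    """
    group = p4m()
    out: list[ImageSample] = []
    for s in samples:
        for g in group.elements:
            out.append(
                ImageSample(
                    image=act_on_image(g, s.image),
                    label=s.label,
                    sample_id=f"{s.sample_id}_{g!r}",
                    split=s.split,
                    is_augmented=not g.is_identity or s.is_augmented,
                    provenance=f"{s.sample_id}|{g!r}",
                )
            )
    return out


def rebalance(samples: list[ImageSample], seed: int = 0) -> list[ImageSample]:
    """Downsample every class to the smallest class count.

    For classes above the target, augmented copies are removed first (in
    seeded random order), then originals are removed uniformly at random.
    The smallest class is left untouched.
    """
    by_class: dict[int, list[ImageSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    if any(len(v) == 0 for v in by_class.values()) or not by_class:
        raise ValueError("every class needs at least one sample")
    target = min(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    kept: list[ImageSample] = []
    for label in sorted(by_class):
        group = by_class[label]
        excess = len(group) - target
        if excess == 0:
            kept.extend(group)
            continue
        augmented = [s for s in group if s.is_augmented]
        originals = [s for s in group if not s.is_augmented]
        drop_aug = min(excess, len(augmented))
        aug_order = rng.permutation(len(augmented))
        keep_aug = [augmented[i] for i in sorted(aug_order[drop_aug:])]
        drop_orig = excess - drop_aug
        orig_order = rng.permutation(len(originals))
        keep_orig = [originals[i] for i in sorted(orig_order[drop_orig:])]
        kept.extend(keep_orig + keep_aug)
    return kept


def subsample_training(
    samples: list[ImageSample], n_total: int, seed: int = 0
) -> list[ImageSample]:
    """Class-balanced subsample of exactly ``n_total`` images, nested in size.

    Per class, a single seeded shuffle fixes an order and the subsample takes
    a prefix; quotas differ by at most one across classes and grow
    monotonically with ``n_total``, so for a fixed seed smaller subsets are
    contained in larger ones (variance reduction across a size sweep).
    """
    if n_total > len(samples):
        raise ValueError(f"requested {n_total} of {len(samples)} available samples")
    by_class: dict[int, list[ImageSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    labels = sorted(by_class)
    k = len(labels)
    rng = np.random.default_rng(seed)
    # one permutation per class and one class-priority order, independent of n_total
    perms = {label: rng.permutation(len(by_class[label])) for label in labels}
    priority = rng.permutation(k)
    base, extra = divmod(n_total, k)
    quotas = {labels[j]: base + (1 if rank < extra else 0)
              for rank, j in enumerate(priority)}
    for label in labels:
        if quotas[label] > len(by_class[label]):
            raise ValueError(
                f"class {label} has {len(by_class[label])} samples, needs {quotas[label]}"
            )
    out: list[ImageSample] = []
    for label in labels:
        idx = perms[label][: quotas[label]]
        out.extend(by_class[label][i] for i in sorted(idx))
    return out


def make_cv_folds(
    samples: list[ImageSample],
    k: int,
    seed: int = 0,
    mode: str = "even",
    test_size_per_class: int | None = None,
) -> list[tuple[list[ImageSample], list[ImageSample]]]:
    """Class-stratified k-fold (train, test) pairs from a merged dataset.

    ``mode='even'`` partitions each class into k folds whose sizes differ by
    at most one; the test folds are disjoint and cover the dataset. When
    class counts do not divide by k (e.g. 123 by 5), ``mode='fixed'`` with
    ``test_size_per_class`` draws k disjoint test folds of exactly that size
    per class and leaves the remainder permanently in training — with 123
    images per class and test folds of 23, every training fold holds 100 per
    class.
    """
    if mode not in ("even", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    by_class: dict[int, list[ImageSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    for label, group in by_class.items():
        if len(group) < k:
            raise ValueError(f"class {label} has {len(group)} samples, fewer than k={k}")
    if mode == "fixed":
        if test_size_per_class is None:
            raise ValueError("mode='fixed' requires test_size_per_class")
        for label, group in by_class.items():
            if k * test_size_per_class > len(group):
                raise ValueError(
                    f"class {label}: cannot draw {k} disjoint folds of {test_size_per_class}"
                )
    rng = np.random.default_rng(seed)
    class_folds: dict[int, list[list[ImageSample]]] = {}
    leftovers: dict[int, list[ImageSample]] = {}
    for label in sorted(by_class):
        group = by_class[label]
        order = rng.permutation(len(group))
        shuffled = [group[i] for i in order]
        if mode == "even":
            bounds = np.linspace(0, len(shuffled), k + 1).round().astype(int)
            class_folds[label] = [shuffled[bounds[f]: bounds[f + 1]] for f in range(k)]
            leftovers[label] = []
        else:
            t = test_size_per_class
            class_folds[label] = [shuffled[f * t: (f + 1) * t] for f in range(k)]
            leftovers[label] = shuffled[k * t:]
    folds = []
    for f in range(k):
        test = [s for label in sorted(class_folds) for s in class_folds[label][f]]
        train = [
            s
            for label in sorted(class_folds)
            for other in range(k)
            if other != f
            for s in class_folds[label][other]
        ] + [s for label in sorted(leftovers) for s in leftovers[label]]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# dataset I/O


def write_dataset(samples: list[ImageSample], directory, bit_depth: int = 16) -> DatasetManifest:
    """Write grayscale PNGs plus a CSV manifest; returns the manifest."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    for s in samples:
        quantized = np.round(s.image * scale).astype(dtype)
        imageio.imwrite(directory / f"{s.sample_id}.png", quantized)
    manifest = DatasetManifest.from_samples(samples)
    manifest.frame = manifest.frame.assign(bit_depth=bit_depth)[
        MANIFEST_COLUMNS + ["bit_depth"]
    ]
    manifest.to_csv(directory / "manifest.csv")
    return manifest


def read_dataset(directory) -> tuple[list[ImageSample], DatasetManifest]:
    """Load a dataset written by :func:`write_dataset`; verifies integrity."""
    directory = Path(directory)
    manifest = DatasetManifest.from_csv(directory / "manifest.csv")
    missing = [f for f in manifest.frame["filename"] if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(f"manifest lists missing image files: {missing[:5]}...")
    samples = []
    for row in manifest.frame.itertuples():
        raw = imageio.imread(directory / row.filename)
        scale = 2 ** int(getattr(row, "bit_depth", 16)) - 1
        samples.append(
            ImageSample(
                image=raw.astype(float) / scale,
                label=int(row.label),
                sample_id=Path(row.filename).stem,
                split=str(row.split),
                is_augmented=bool(row.is_augmented),
                provenance=str(row.provenance),
            )
        )
    return samples, manifest


def samples_to_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N, 1, H, W) images and (N,) integer labels."""
    x = np.stack([s.image for s in samples])[:, None]
    y = np.array([s.label for s in samples], dtype=int)
    return x, y
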