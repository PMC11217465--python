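"""Point groups p4 and p4m with exact actions on square pixel grids.

The two groups are the rotational part of the wallpaper groups commonly used
for rotation-equivariant convolutions on square images:

* ``p4``  — rotations by 0, 90, 180 and 270 degrees (order 4);
* ``p4m`` — the same rotations combined with a reflection about the vertical
  axis, i.e. a left-right flip (order 8, the dihedral group D4).

Every element is a pair ``(mirror, rotation)`` and acts on an image by first
applying the mirror, then rotating counterclockwise by ``90° * rotation``.
Actions are exact index remappings (``fliplr``/``rot90``), never interpolated,
so acting on a square array permutes its pixel values.

The composition table of each group is derived numerically, by composing the
actions on a fixed asymmetric probe array, and is the single source of truth
for :func:`compose` and :func:`inverse`; all downstream group-convolution
bookkeeping indexes into it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "GroupElement",
    "SymmetryGroup",
    "p4",
    "p4m",
    "act_on_image",
    "compose",
    "inverse",
]


@dataclass(frozen=True, order=True)
class GroupElement:
    """One element ``(mirror, rotation)`` of p4 or p4m.

    ``mirror`` is 0 or 1 (reflection about the vertical axis, applied first);
    ``rotation`` counts counterclockwise quarter turns, 0..3.
    """

    mirror: int
    rotation: int

    def __post_init__(self) -> None:
        if self.mirror not in (0, 1):
            raise ValueError(f"mirror must be 0 or 1, got {self.mirror}")
        if self.rotation not in (0, 1, 2, 3):
            raise ValueError(f"rotation must be in 0..3, got {self.rotation}")

    @property
    def is_identity(self) -> bool:
        return self.mirror == 0 and self.rotation == 0

    def __repr__(self) -> str:  # compact: r2, mr3, e
        if self.is_identity:
            return "e"
        return f"{'m' if self.mirror else ''}r{self.rotation}"


IDENTITY = GroupElement(0, 0)


def act_on_image(g: GroupElement, image: np.ndarray) -> np.ndarray:
    """Apply ``g`` to a square 2-D array by exact index remapping.

    Mirror first (left-right flip), then rotate counterclockwise by
    ``90° * g.rotation`` about the array centre. Works for odd and even
    sizes; the output is always a permutation of the input values.
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.shape[-2] != image.shape[-1]:
        raise ValueError(
            f"act_on_image requires square trailing axes, got shape {image.shape}"
        )
    out = image[..., :, ::-1] if g.mirror else image
    return np.rot90(out, k=g.rotation, axes=(-2, -1))


def _derive_composition_table(elements: tuple[GroupElement, ...]) -> np.ndarray:
    """Build the Cayley table by composing actions on an asymmetric probe.

    ``table[i, j] = k`` iff acting with element j then element i equals
    acting with element k.  The probe array is injective for D4 (all eight
    transforms are pairwise distinct), so the lookup is unambiguous.
    """
    rng = np.random.default_rng(20240701)
    probe = rng.integers(0, 1_000_000, size=(5, 5))
    acted = [act_on_image(g, probe) for g in elements]
    for a in range(len(acted)):
        for b in range(a + 1, len(acted)):
            if np.array_equal(acted[a], acted[b]):  # pragma: no cover
                raise RuntimeError("probe array is not asymmetric enough")
    n = len(elements)
    table = np.empty((n, n), dtype=np.intp)
    for i, g in enumerate(elements):
        for j in range(n):
            combined = act_on_image(g, acted[j])
            matches = [k for k in range(n) if np.array_equal(combined, acted[k])]
            if len(matches) != 1:  # pragma: no cover
                raise RuntimeError("composition is not closed/unique")
            table[i, j] = matches[0]
    return table


class SymmetryGroup:
    """p4 or p4m with canonical element order and derived Cayley table.

    Canonical order: the four pure rotations by increasing quarter turn,
    then (for p4m) the four mirrored elements by increasing quarter turn.
    """

    def __init__(self, name: str):
        if name not in ("p4", "p4m"):
            raise ValueError(f"unknown group {name!r}; expected 'p4' or 'p4m'")
        self.name = name
        mirrors = (0,) if name == "p4" else (0, 1)
        self.elements: tuple[GroupElement, ...] = tuple(
            GroupElement(m, r) for m in mirrors for r in range(4)
        )
        self.order = len(self.elements)
        self.composition_table = _derive_composition_table(self.elements)
        self._index = {g: i for i, g in enumerate(self.elements)}
        # inverse of each element, found by scanning its table row for identity
        inv = np.empty(self.order, dtype=np.intp)
        for i in range(self.order):
            (hits,) = np.nonzero(self.composition_table[i] == self._index[IDENTITY])
            if hits.size != 1:  # pragma: no cover
                raise RuntimeError("element without unique inverse")
            inv[i] = hits[0]
        self._inverse = inv

    def __repr__(self) -> str:
        return f"SymmetryGroup({self.name!r}, order={self.order})"

    def __contains__(self, g: GroupElement) -> bool:
        return g in self._index

    def __iter__(self):
        return iter(self.elements)

    def index(self, g: GroupElement) -> int:
        try:
            return self._index[g]
        except KeyError:
            raise ValueError(f"{g!r} is not an element of {self.name}") from None

    def compose(self, g: GroupElement, h: GroupElement) -> GroupElement:
        """Element equal to 'apply h, then g'."""
        return self.elements[self.composition_table[self.index(g), self.index(h)]]

    def inverse(self, g: GroupElement) -> GroupElement:
        return self.elements[self._inverse[self.index(g)]]

    @property
    def identity(self) -> GroupElement:
        return IDENTITY


@lru_cache(maxsize=None)
def p4() -> SymmetryGroup:
    """The group of quarter-turn rotations (order 4)."""
    return SymmetryGroup("p4")


@lru_cache(maxsize=None)
def p4m() -> SymmetryGroup:
    """Quarter-turn rotations plus a left-right reflection (order 8)."""
    return SymmetryGroup("p4m")


def get_group(name: str) -> SymmetryGroup:
    """Look up a group by its config-file name ('p4' or 'p4m')."""
    return {"p4": p4, "p4m": p4m}[name]() if name in ("p4", "p4m") else SymmetryGroup(name)


def compose(g: GroupElement, h: GroupElement, group: SymmetryGroup) -> GroupElement:
    """Module-level convenience for ``group.compose``."""
    return group.compose(g, h)


def inverse(g: GroupElement, group: SymmetryGroup) -> GroupElement:
    """Module-level convenience for ``group.inverse``."""
    return group.inverse(g)
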