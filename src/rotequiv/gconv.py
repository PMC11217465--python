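"""Functional group-equivariant convolution operations.

This is the mathematical core: the *lifting* convolution takes a planar
image to a stack of feature maps indexed by group elements (one slice per
rotation/reflection of the kernel); the *group* convolution maps such a
stack to another one while commuting with the group's regular action; and
*group pooling* (max over the group axis) converts equivariance into
invariance. The contract is

    layer(action(g, x)) == action'(g, layer(x))        for every g,

where the action on planar maps transforms the pixel grid and the regular
action on group stacks additionally permutes the group axis by
left-multiplication. All actions are exact index remappings, so for
integer-valued inputs and weights the contract holds exactly (verified
exhaustively in the test suite; :func:`check_equivariance` measures it for
arbitrary layers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import conv_engine as ce
from .groups import GroupElement, SymmetryGroup, act_on_image

__all__ = [
    "ConvLayerSpec",
    "PlanarFeatureMap",
    "GroupFeatureMap",
    "LiftingKernelStack",
    "GroupKernelStack",
    "lift_conv",
    "group_conv",
    "group_pool",
    "spatial_max_pool",
    "regular_action",
    "check_equivariance",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """(kernel size, stride, zero padding) of one convolution or pool."""

    kernel_size: int
    stride: int = 1
    padding: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")


@dataclass
class PlanarFeatureMap:
    """Stack of 2-D feature maps, indexed (channel, row, column)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected (channel, row, col), got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class GroupFeatureMap:
    """Feature stack indexed (channel, group element, row, column)."""

    values: np.ndarray
    group: SymmetryGroup

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(
                f"expected (channel, group, row, col), got shape {self.values.shape}"
            )
        if self.values.shape[1] != self.group.order:
            raise ValueError(
                f"group axis has size {self.values.shape[1]}, expected {self.group.order}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class LiftingKernelStack:
    """Planar kernels (out_channel, in_channel, k, k) with per-channel bias."""

    weights: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 4 or self.weights.shape[2] != self.weights.shape[3]:
            raise ValueError(f"expected (oc, ic, k, k) square kernels, got {self.weights.shape}")
        if self.bias is not None:
            self.bias = np.asarray(self.bias)
            if self.bias.shape != (self.weights.shape[0],):
                raise ValueError("bias must have one entry per output channel")


@dataclass
class GroupKernelStack:
    """Group kernels (out_channel, in_channel, group, k, k) with shared bias."""

    weights: np.ndarray
    group: SymmetryGroup = field(kw_only=True)
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 5 or self.weights.shape[3] != self.weights.shape[4]:
            raise ValueError(
                f"expected (oc, ic, group, k, k) square kernels, got {self.weights.shape}"
            )
        if self.weights.shape[2] != self.group.order:
            raise ValueError("kernel group axis must match the group order")
        if self.bias is not None:
            self.bias = np.asarray(self.bias)
            if self.bias.shape != (self.weights.shape[0],):
                raise ValueError("bias must have one entry per output channel")


def lift_conv(
    f: PlanarFeatureMap,
    kernels: LiftingKernelStack,
    group: SymmetryGroup,
    spec: ConvLayerSpec | None = None,
) -> GroupFeatureMap:
    """Lifting convolution: planar input -> group feature stack.

    The output slice for group element g is the planar cross-correlation of
    the input with the g-transformed kernel (plus the channel bias, shared
    across the group axis).
    """
    spec = spec or ConvLayerSpec(kernels.weights.shape[-1])
    if f.values.shape[-2] != f.values.shape[-1]:
        raise ValueError("lifting convolution requires a square input")
    if f.n_channels != kernels.weights.shape[1]:
        raise ValueError(
            f"input has {f.n_channels} channels, kernel expects {kernels.weights.shape[1]}"
        )
    w_exp = ce.expand_lifting_kernel(kernels.weights, group)
    b_exp = None if kernels.bias is None else ce.expand_bias(kernels.bias, group)
    out, _ = ce.conv2d_forward(f.values[None], w_exp, b_exp, spec.stride, spec.padding)
    oc = kernels.weights.shape[0]
    values = out[0].reshape(oc, group.order, out.shape[-2], out.shape[-1])
    return GroupFeatureMap(values, group)


def group_conv(
    fmap: GroupFeatureMap,
    kernels: GroupKernelStack,
    group: SymmetryGroup,
    spec: ConvLayerSpec | None = None,
) -> GroupFeatureMap:
    """Group convolution: group stack -> group stack on the same group.

    Output slice at g sums, over input elements h, the correlation of the
    h-slice with the base kernel slice g^-1 h transformed spatially by g.
    """
    spec = spec or ConvLayerSpec(kernels.weights.shape[-1])
    if fmap.group is not group or kernels.group is not group:
        raise ValueError("feature map, kernels and group argument must share one group")
    if fmap.n_channels != kernels.weights.shape[1]:
        raise ValueError(
            f"input has {fmap.n_channels} channels, kernel expects {kernels.weights.shape[1]}"
        )
    c, go, h, w = fmap.values.shape
    w_exp = ce.expand_group_kernel(kernels.weights, group)
    b_exp = None if kernels.bias is None else ce.expand_bias(kernels.bias, group)
    x = fmap.values.reshape(1, c * go, h, w)
    out, _ = ce.conv2d_forward(x, w_exp, b_exp, spec.stride, spec.padding)
    oc = kernels.weights.shape[0]
    values = out[0].reshape(oc, go, out.shape[-2], out.shape[-1])
    return GroupFeatureMap(values, group)


def group_pool(fmap: GroupFeatureMap) -> PlanarFeatureMap:
    """Max over the group axis; turns equivariance into invariance."""
    return PlanarFeatureMap(fmap.values.max(axis=1))


def spatial_max_pool(fmap, spec: ConvLayerSpec):
    """Standard max pooling over the two spatial axes (group axis untouched)."""
    if isinstance(fmap, GroupFeatureMap):
        c, go, h, w = fmap.values.shape
        out, _ = ce.maxpool_forward(
            fmap.values.reshape(1, c * go, h, w), spec.kernel_size, spec.stride, spec.padding
        )
        return GroupFeatureMap(
            out[0].reshape(c, go, out.shape[-2], out.shape[-1]), fmap.group
        )
    if isinstance(fmap, PlanarFeatureMap):
        out, _ = ce.maxpool_forward(
            fmap.values[None], spec.kernel_size, spec.stride, spec.padding
        )
        return PlanarFeatureMap(out[0])
    raise TypeError(f"unsupported feature map type {type(fmap).__name__}")


def regular_action(g: GroupElement, fmap: GroupFeatureMap) -> GroupFeatureMap:
    """Regular representation: rotate/reflect spatially and permute the group axis.

    The slice of the output at element k is the g-transformed slice of the
    input at g^-1 k (left multiplication on the group axis).
    """
    group = fmap.group
    g_inv = group.inverse(g)
    out = np.empty_like(fmap.values)
    for ki, k in enumerate(group.elements):
        src = group.index(group.compose(g_inv, k))
        out[:, ki] = act_on_image(g, fmap.values[:, src])
    return GroupFeatureMap(out, group)


def planar_action(g: GroupElement, fmap: PlanarFeatureMap) -> PlanarFeatureMap:
    """Rotate/reflect every channel of a planar stack."""
    return PlanarFeatureMap(act_on_image(g, fmap.values))


def _act(g: GroupElement, fmap):
    if isinstance(fmap, GroupFeatureMap):
        return regular_action(g, fmap)
    if isinstance(fmap, PlanarFeatureMap):
        return planar_action(g, fmap)
    raise TypeError(f"unsupported feature map type {type(fmap).__name__}")


def check_equivariance(
    layer_fn,
    group: SymmetryGroup,
    *,
    make_input,
    trials: int = 5,
    seed: int = 0,
) -> dict[GroupElement, float]:
    """Measure the equivariance defect of ``layer_fn`` for every group element.

    ``make_input(rng)`` must return a Planar- or GroupFeatureMap; the layer
    may return either kind. For each element g the report holds the maximum
    absolute deviation between ``layer_fn(g . x)`` and ``g . layer_fn(x)``
    over ``trials`` random inputs. Deterministic given ``seed``; zero for
    exactly equivariant layers on integer data.
    """
    rng = np.random.default_rng(seed)
    report: dict[GroupElement, float] = {g: 0.0 for g in group.elements}
    for _ in range(trials):
        x = make_input(rng)
        ref = layer_fn(x)
        for g in group.elements:
            lhs = layer_fn(_act(g, x))
            rhs = _act(g, ref)
            dev = float(np.max(np.abs(lhs.values - rhs.values)))
            report[g] = max(report[g], dev)
    return report
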