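"""Low-level numpy kernels shared by the functional ops and the layer classes.

Everything here works on batched arrays ``(N, C, H, W)``. The "convolution"
is cross-correlation (the deep-learning convention): the kernel is swept over
the input without flipping. Group-equivariant layers are realized by *kernel
expansion*: all spatially transformed copies of the base weights are
materialized into one big planar weight tensor and dispatched to the ordinary
correlation below, so one well-tested primitive serves every layer kind.

Backward passes are the exact adjoints of the forward index bookkeeping,
including the fold-back of gradients through the kernel expansion (the
expansion is a permutation of weight entries, so its adjoint applies the
inverse group elements).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .groups import SymmetryGroup, act_on_image

# ---------------------------------------------------------------------------
# planar correlation


def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    eff = size + 2 * padding
    if kernel > eff:
        raise ValueError(
            f"kernel {kernel} larger than padded input {eff} (size {size}, padding {padding})"
        )
    return (eff - kernel) // stride + 1


def _windows(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(N, C, Ho, Wo, k, k) view of all kernel windows of a padded input."""
    w = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


def conv2d_forward(
    x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None, stride: int, padding: int
):
    """Cross-correlate ``x (N,Cin,H,W)`` with ``weight (Cout,Cin,k,k)``.

    Returns ``(out, cache)``; the cache feeds :func:`conv2d_backward`.
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels but kernel expects {cin_w}")
    if kh != kw:
        raise ValueError("only square kernels are supported")
    ho = conv_out_size(h, kh, stride, padding)
    wo = conv_out_size(w, kw, stride, padding)
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _windows(xp, kh, stride)  # (N, Cin, Ho, Wo, k, k)
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    out = cols2 @ weight.reshape(cout, -1).T
    if bias is not None:
        out += bias
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    cache = (x.shape, xp.shape, cols2, weight, stride, padding)
    return np.ascontiguousarray(out), cache


def conv2d_backward(grad_out: np.ndarray, cache):
    """Gradients of conv2d_forward w.r.t. input, weight and bias."""
    x_shape, xp_shape, cols2, weight, stride, padding = cache
    n, cin, h, w = x_shape
    cout, _, kh, kw = weight.shape
    _, _, ho, wo = grad_out.shape
    g2 = grad_out.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
    grad_w = (g2.T @ cols2).reshape(weight.shape)
    grad_b = g2.sum(axis=0)
    grad_cols = (g2 @ weight.reshape(cout, -1)).reshape(n, ho, wo, cin, kh, kw)
    grad_cols = grad_cols.transpose(0, 3, 1, 2, 4, 5)  # (N, Cin, Ho, Wo, k, k)
    grad_xp = np.zeros(xp_shape, dtype=grad_out.dtype)
    for i in range(kh):
        for j in range(kw):
            grad_xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                grad_cols[..., i, j]
            )
    if padding:
        grad_x = grad_xp[:, :, padding : padding + h, padding : padding + w]
    else:
        grad_x = grad_xp
    return grad_x, grad_w, grad_b


# ---------------------------------------------------------------------------
# max pooling


def maxpool_forward(x: np.ndarray, kernel: int, stride: int, padding: int = 0):
    """Spatial max pool on (N, C, H, W); zero padding only enlarges the grid."""
    n, c, h, w = x.shape
    ho = conv_out_size(h, kernel, stride, padding)
    wo = conv_out_size(w, kernel, stride, padding)
    if padding:
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x
    win = _windows(xp, kernel, stride)  # (N, C, Ho, Wo, k, k)
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    cache = (x.shape, xp.shape, arg, kernel, stride, padding)
    return np.ascontiguousarray(out), cache


def maxpool_backward(grad_out: np.ndarray, cache):
    x_shape, xp_shape, arg, kernel, stride, padding = cache
    n, c, ho, wo = grad_out.shape
    grad_xp = np.zeros(xp_shape, dtype=grad_out.dtype)
    ni, ci, hi, wi = np.indices((n, c, ho, wo), sparse=False)
    rows = hi * stride + arg // kernel
    cols = wi * stride + arg % kernel
    np.add.at(grad_xp, (ni, ci, rows, cols), grad_out)
    if padding:
        h, w = x_shape[2], x_shape[3]
        return grad_xp[:, :, padding : padding + h, padding : padding + w]
    return grad_xp


# ---------------------------------------------------------------------------
# kernel expansion for lifting and group convolutions


def expand_lifting_kernel(weight: np.ndarray, group: SymmetryGroup) -> np.ndarray:
    """(OC, IC, k, k) -> (OC*|G|, IC, k, k); copy g holds the g-transformed kernel."""
    oc, ic, kh, kw = weight.shape
    out = np.empty((oc, group.order, ic, kh, kw), dtype=weight.dtype)
    for gi, g in enumerate(group.elements):
        out[:, gi] = act_on_image(g, weight)
    return out.reshape(oc * group.order, ic, kh, kw)


def collapse_lifting_grad(grad_exp: np.ndarray, group: SymmetryGroup) -> np.ndarray:
    """Adjoint of expand_lifting_kernel (sum of inverse-transformed copies)."""
    n_exp, ic, kh, kw = grad_exp.shape
    oc = n_exp // group.order
    ge = grad_exp.reshape(oc, group.order, ic, kh, kw)
    out = np.zeros((oc, ic, kh, kw), dtype=grad_exp.dtype)
    for gi, g in enumerate(group.elements):
        out += act_on_image(group.inverse(g), ge[:, gi])
    return out


def expand_group_kernel(weight: np.ndarray, group: SymmetryGroup) -> np.ndarray:
    """(OC, IC, |G|, k, k) -> (OC*|G|, IC*|G|, k, k).

    Output copy for element g, input slice for element h, uses the base
    kernel slice indexed by g^-1 h, spatially transformed by g — the regular
    -representation group convolution.
    """
    oc, ic, go, kh, kw = weight.shape
    if go != group.order:
        raise ValueError(f"kernel group axis {go} != group order {group.order}")
    out = np.empty((oc, group.order, ic, group.order, kh, kw), dtype=weight.dtype)
    for gi, g in enumerate(group.elements):
        g_inv = group.inverse(g)
        for hi, h in enumerate(group.elements):
            src = group.index(group.compose(g_inv, h))
            out[:, gi, :, hi] = act_on_image(g, weight[:, :, src])
    return out.reshape(oc * group.order, ic * group.order, kh, kw)


def collapse_group_grad(grad_exp: np.ndarray, group: SymmetryGroup) -> np.ndarray:
    """Adjoint of expand_group_kernel."""
    n_out, n_in, kh, kw = grad_exp.shape
    go = group.order
    oc, ic = n_out // go, n_in // go
    ge = grad_exp.reshape(oc, go, ic, go, kh, kw)
    out = np.zeros((oc, ic, go, kh, kw), dtype=grad_exp.dtype)
    for gi, g in enumerate(group.elements):
        g_inv = group.inverse(g)
        for hi, h in enumerate(group.elements):
            src = group.index(group.compose(g_inv, h))
            out[:, :, src] += act_on_image(g_inv, ge[:, gi, :, hi])
    return out


def expand_bias(bias: np.ndarray, group: SymmetryGroup) -> np.ndarray:
    """One bias per output channel, shared over the group axis."""
    return np.repeat(bias, group.order)


def collapse_bias_grad(grad_exp: np.ndarray, group: SymmetryGroup) -> np.ndarray:
    return grad_exp.reshape(-1, group.order).sum(axis=1)
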