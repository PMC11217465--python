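"""G-convolution correctness: brute-force oracles and exact equivariance.

The oracles are independent nested-loop implementations of the stated
definitions (no convolution primitive); the fast kernel-expansion path must
agree with them exactly on integer-valued inputs.
"""

import numpy as np
import pytest

from rotequiv.gconv import (
    ConvLayerSpec,
    GroupFeatureMap,
    GroupKernelStack,
    LiftingKernelStack,
    PlanarFeatureMap,
    check_equivariance,
    group_conv,
    group_pool,
    lift_conv,
    planar_action,
    regular_action,
    spatial_max_pool,
)
from rotequiv.groups import GroupElement, act_on_image, p4, p4m

GROUPS = [p4(), p4m()]


# ---------------------------------------------------------------------------
# nested-loop oracles


def oracle_correlate(image, kernel, stride, padding):
    """Plain nested-loop cross-correlation of one 2-D map with one kernel."""
    k = kernel.shape[0]
    padded = np.pad(image, padding)
    ho = (padded.shape[0] - k) // stride + 1
    wo = (padded.shape[1] - k) // stride + 1
    out = np.zeros((ho, wo))
    for x in range(ho):
        for y in range(wo):
            acc = 0.0
            for i in range(k):
                for j in range(k):
                    acc += kernel[i, j] * padded[x * stride + i, y * stride + j]
            out[x, y] = acc
    return out


def oracle_lift(f, weights, bias, group, spec):
    """Slice at g = correlation with the g-transformed kernel, plus bias."""
    oc, ic = weights.shape[:2]
    slices = []
    for g in group.elements:
        per_g = np.zeros((oc,) + oracle_correlate(f[0], weights[0, 0],
                                                  spec.stride, spec.padding).shape)
        for o in range(oc):
            for c in range(ic):
                per_g[o] += oracle_correlate(
                    f[c], act_on_image(g, weights[o, c]), spec.stride, spec.padding
                )
            per_g[o] += bias[o]
        slices.append(per_g)
    return np.stack(slices, axis=1)  # (oc, |G|, H, W)


def oracle_group_conv(F, weights, bias, group, spec):
    """Slice at g = sum over h of corr(F[h], g-transformed kernel g^-1 h)."""
    oc, ic = weights.shape[:2]
    out_slices = []
    for g in group.elements:
        g_inv = group.inverse(g)
        shape = oracle_correlate(F[0, 0], weights[0, 0, 0], spec.stride, spec.padding).shape
        per_g = np.zeros((oc,) + shape)
        for o in range(oc):
            for c in range(ic):
                for hi, h in enumerate(group.elements):
                    src = group.index(group.compose(g_inv, h))
                    per_g[o] += oracle_correlate(
                        F[c, hi],
                        act_on_image(g, weights[o, c, src]),
                        spec.stride,
                        spec.padding,
                    )
            per_g[o] += bias[o]
        out_slices.append(per_g)
    return np.stack(out_slices, axis=1)


def oracle_max_pool(image, k, stride):
    ho = (image.shape[0] - k) // stride + 1
    wo = (image.shape[1] - k) // stride + 1
    out = np.empty((ho, wo))
    for x in range(ho):
        for y in range(wo):
            out[x, y] = image[x * stride : x * stride + k, y * stride : y * stride + k].max()
    return out


def random_planar(rng, channels=1, size=5):
    return PlanarFeatureMap(rng.integers(-5, 6, (channels, size, size)).astype(float))


def random_group_map(rng, group, channels=1, size=5):
    return GroupFeatureMap(
        rng.integers(-5, 6, (channels, group.order, size, size)).astype(float), group
    )


# ---------------------------------------------------------------------------
# lifting convolution


class TestLiftConv:
    def test_centered_delta_kernel_reproduces_input(self):
        group = p4()
        f = PlanarFeatureMap(np.arange(25.0).reshape(1, 5, 5))
        delta = np.zeros((1, 1, 3, 3))
        delta[0, 0, 1, 1] = 1.0
        out = lift_conv(f, LiftingKernelStack(delta, np.zeros(1)), group,
                        ConvLayerSpec(3, 1, 1))
        for gi in range(group.order):
            np.testing.assert_array_equal(out.values[0, gi], f.values[0])

    def test_fourfold_symmetric_kernel_gives_identical_slices(self):
        group = p4()
        rng = np.random.default_rng(0)
        k = rng.integers(-3, 4, (3, 3)).astype(float)
        sym = sum(np.rot90(k, i) for i in range(4))  # 4-fold symmetric by construction
        f = random_planar(rng, size=6)
        out = lift_conv(f, LiftingKernelStack(sym[None, None], np.zeros(1)), group,
                        ConvLayerSpec(3, 1, 1))
        for gi in range(1, group.order):
            np.testing.assert_array_equal(out.values[:, gi], out.values[:, 0])

    @pytest.mark.parametrize("group", GROUPS, ids=lambda g: g.name)
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_nested_loop_oracle(self, group, trial):
        rng = np.random.default_rng(100 + trial)
        f = random_planar(rng, channels=2, size=5)
        w = rng.integers(-3, 4, (2, 2, 3, 3)).astype(float)
        b = rng.integers(-2, 3, 2).astype(float)
        spec = ConvLayerSpec(3, 1, 1)
        out = lift_conv(f, LiftingKernelStack(w, b), group, spec)
        np.testing.assert_array_equal(out.values,
                                      oracle_lift(f.values, w, b, group, spec))

    def test_linearity_with_zero_bias(self):
        group = p4()
        rng = np.random.default_rng(5)
        w = rng.integers(-3, 4, (2, 1, 3, 3)).astype(float)
        K = LiftingKernelStack(w, np.zeros(2))
        spec = ConvLayerSpec(3, 1, 1)
        f1, f2 = random_planar(rng), random_planar(rng)
        combo = PlanarFeatureMap(3.0 * f1.values - 2.0 * f2.values)
        lhs = lift_conv(combo, K, group, spec).values
        rhs = 3.0 * lift_conv(f1, K, group, spec).values - 2.0 * lift_conv(
            f2, K, group, spec).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        f = PlanarFeatureMap(np.zeros((2, 5, 5)))
        K = LiftingKernelStack(np.zeros((1, 3, 3, 3)), np.zeros(1))
        with pytest.raises(ValueError):
            lift_conv(f, K, p4(), ConvLayerSpec(3, 1, 1))

    def test_oversized_kernel_rejected(self):
        f = PlanarFeatureMap(np.zeros((1, 4, 4)))
        K = LiftingKernelStack(np.zeros((1, 1, 7, 7)), np.zeros(1))
        with pytest.raises(ValueError):
            lift_conv(f, K, p4(), ConvLayerSpec(7, 1, 0))


# ---------------------------------------------------------------------------
# group convolution


class TestGroupConv:
    def test_delta_kernels_reduce_to_group_axis_sum(self):
        group = p4()
        rng = np.random.default_rng(2)
        F = random_group_map(rng, group, size=5)
        w = np.zeros((1, 1, group.order, 3, 3))
        w[:, :, :, 1, 1] = 1.0
        out = group_conv(F, GroupKernelStack(w, group=group, bias=np.zeros(1)), group,
                         ConvLayerSpec(3, 1, 1))
        expected = F.values.sum(axis=1, keepdims=True)[0]
        for gi in range(group.order):
            np.testing.assert_array_equal(out.values[0, gi], expected[0])

    @pytest.mark.parametrize("group", GROUPS, ids=lambda g: g.name)
    @pytest.mark.parametrize("trial", range(10))
    def test_matches_nested_loop_oracle(self, group, trial):
        rng = np.random.default_rng(300 + trial)
        F = random_group_map(rng, group, channels=1, size=5)
        w = rng.integers(-3, 4, (2, 1, group.order, 3, 3)).astype(float)
        b = rng.integers(-2, 3, 2).astype(float)
        spec = ConvLayerSpec(3, 1, 1)
        out = group_conv(F, GroupKernelStack(w, group=group, bias=b), group, spec)
        np.testing.assert_array_equal(out.values,
                                      oracle_group_conv(F.values, w, b, group, spec))

    def test_group_mismatch_rejected(self):
        F = random_group_map(np.random.default_rng(0), p4())
        K = GroupKernelStack(np.zeros((1, 1, 8, 3, 3)), group=p4m(), bias=np.zeros(1))
        with pytest.raises(ValueError):
            group_conv(F, K, p4m(), ConvLayerSpec(3, 1, 1))


# ---------------------------------------------------------------------------
# pooling


class TestPooling:
    def test_group_pool_of_equal_slices_is_that_slice(self):
        group = p4()
        base = np.arange(16.0).reshape(1, 4, 4)
        F = GroupFeatureMap(np.repeat(base[:, None], group.order, axis=1), group)
        np.testing.assert_array_equal(group_pool(F).values, base)

    def test_group_pool_dominates_every_slice(self):
        rng = np.random.default_rng(3)
        F = random_group_map(rng, p4m(), channels=2)
        pooled = group_pool(F).values
        for gi in range(8):
            assert (pooled >= F.values[:, gi]).all()

    def test_group_pool_intertwines_regular_and_planar_actions(self):
        """pool(g . F) == g . pool(F) for every p4m element."""
        rng = np.random.default_rng(4)
        F = random_group_map(rng, p4m(), channels=2, size=6)
        for g in p4m().elements:
            np.testing.assert_array_equal(
                group_pool(regular_action(g, F)).values,
                act_on_image(g, group_pool(F).values),
            )

    def test_spatial_pool_constant_and_global(self):
        const = PlanarFeatureMap(np.full((1, 8, 8), 3.5))
        out = spatial_max_pool(const, ConvLayerSpec(2, 2, 0))
        np.testing.assert_array_equal(out.values, np.full((1, 4, 4), 3.5))
        big = PlanarFeatureMap(np.arange(169.0).reshape(1, 13, 13))
        out = spatial_max_pool(big, ConvLayerSpec(13, 1, 0))
        np.testing.assert_array_equal(out.values, [[[168.0]]])

    @pytest.mark.parametrize("trial", range(5))
    def test_spatial_pool_matches_nested_loop_oracle(self, trial):
        rng = np.random.default_rng(40 + trial)
        x = rng.integers(-9, 10, (2, 8, 8)).astype(float)
        out = spatial_max_pool(PlanarFeatureMap(x), ConvLayerSpec(3, 2, 0))
        for c in range(2):
            np.testing.assert_array_equal(out.values[c], oracle_max_pool(x[c], 3, 2))

    def test_window_larger_than_input_rejected(self):
        with pytest.raises(ValueError):
            spatial_max_pool(PlanarFeatureMap(np.zeros((1, 4, 4))), ConvLayerSpec(5, 1, 0))


# ---------------------------------------------------------------------------
# equivariance (the binding contract)


@pytest.mark.parametrize("group", GROUPS, ids=lambda g: g.name)
class TestEquivariance:
    def test_lift_conv_exactly_equivariant_on_integers(self, group):
        rng = np.random.default_rng(7)
        w = rng.integers(-3, 4, (2, 1, 3, 3)).astype(float)
        K = LiftingKernelStack(w, rng.integers(-2, 3, 2).astype(float))
        spec = ConvLayerSpec(3, 1, 1)
        report = check_equivariance(
            lambda x: lift_conv(x, K, group, spec),
            group,
            make_input=lambda r: random_planar(r, size=6),
            trials=20,
            seed=11,
        )
        assert max(report.values()) == 0.0

    def test_group_conv_exactly_equivariant_on_integers(self, group):
        rng = np.random.default_rng(8)
        w = rng.integers(-3, 4, (2, 2, group.order, 3, 3)).astype(float)
        K = GroupKernelStack(w, group=group, bias=rng.integers(-2, 3, 2).astype(float))
        spec = ConvLayerSpec(3, 1, 1)
        report = check_equivariance(
            lambda x: group_conv(x, K, group, spec),
            group,
            make_input=lambda r: random_group_map(r, group, channels=2, size=6),
            trials=20,
            seed=12,
        )
        assert max(report.values()) == 0.0

    def test_group_pool_exactly_equivariant(self, group):
        report = check_equivariance(
            group_pool,
            group,
            make_input=lambda r: random_group_map(r, group, channels=2, size=6),
            trials=20,
            seed=13,
        )
        assert max(report.values()) == 0.0

    def test_composed_pipeline_is_invariant_after_global_pool(self, group):
        """lift -> group conv -> group pool -> global spatial max is invariant."""
        rng = np.random.default_rng(9)
        K1 = LiftingKernelStack(rng.integers(-3, 4, (2, 1, 3, 3)).astype(float),
                                np.zeros(2))
        K2 = GroupKernelStack(
            rng.integers(-3, 4, (3, 2, group.order, 3, 3)).astype(float),
            group=group, bias=np.zeros(3),
        )
        spec = ConvLayerSpec(3, 1, 1)

        def network(x):
            z = lift_conv(x, K1, group, spec)
            z = group_conv(z, K2, group, spec)
            v = group_pool(z)
            return spatial_max_pool(v, ConvLayerSpec(v.values.shape[-1], 1, 0))

        x = random_planar(np.random.default_rng(21), size=6)
        ref = network(x).values
        for g in group.elements:
            np.testing.assert_array_equal(network(planar_action(g, x)).values, ref)


class TestCheckEquivariance:
    def test_identity_layer_has_zero_deviation(self):
        report = check_equivariance(
            lambda x: x, p4m(),
            make_input=lambda r: random_group_map(r, p4m()), trials=5, seed=1,
        )
        assert set(report) == set(p4m().elements)
        assert max(report.values()) == 0.0

    def test_plain_convolution_fails_equivariance(self):
        """Negative control: a non-group conv with an asymmetric kernel."""
        from rotequiv.conv_engine import conv2d_forward

        kernel = np.zeros((1, 1, 3, 3))
        kernel[0, 0, 0, 0] = 1.0  # corner delta: rotation moves it

        def plain(x):
            out, _ = conv2d_forward(x.values[None], kernel, None, 1, 1)
            return PlanarFeatureMap(out[0])

        report = check_equivariance(
            plain, p4(),
            make_input=lambda r: random_planar(r, size=6), trials=5, seed=2,
        )
        assert report[GroupElement(0, 1)] > 0.0

    def test_deterministic_given_seed(self):
        args = dict(make_input=lambda r: random_group_map(r, p4()), trials=3, seed=9)
        assert check_equivariance(lambda x: x, p4(), **args) == check_equivariance(
            lambda x: x, p4(), **args
        )
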