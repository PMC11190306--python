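"""Layer-level correctness against finite-difference and recomposition
oracles, plus the attention module's analytic contracts."""

import numpy as np
import pytest

from spudnet.nn import (
    ECA,
    BasicBlock,
    BatchNorm1d,
    Conv1d,
    DepthwiseConv1d,
    Linear,
    MaxPool1d,
    ReLU,
    eca_kernel_size,
    residual_unit_forward,
    separable_conv_params,
    standard_conv_params,
)
from spudnet.nn.resnet import EcaConfig


def numerical_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "make_layer,shape",
    [
        (lambda rng: Conv1d(3, 5, 3, stride=2, padding=1, rng=rng), (2, 3, 9)),
        (lambda rng: Conv1d(2, 4, 7, stride=2, padding=3, bias=True, rng=rng), (2, 2, 12)),
        (lambda rng: DepthwiseConv1d(4, 3, stride=2, padding=1, rng=rng), (2, 4, 9)),
        (lambda rng: ECA(8, 3, rng=rng), (2, 8, 5)),
        (lambda rng: MaxPool1d(3, 2, 1), (2, 3, 9)),
        (lambda rng: ReLU(), (2, 3, 5)),
    ],
    ids=["conv", "conv_bias", "depthwise", "eca", "maxpool", "relu"],
)
def test_backward_matches_finite_differences(make_layer, shape):
    rng = np.random.default_rng(11)
    layer = make_layer(rng)
    x = rng.normal(size=shape)
    w = rng.normal(size=layer.forward(x).shape)

    def loss():
        return float((layer.forward(x) * w).sum())

    loss()
    layer.zero_grad()
    gx = layer.backward(w)
    assert np.abs(gx - numerical_gradient(loss, x)).max() < 1e-7
    for p in layer.parameters():
        assert np.abs(p.grad - numerical_gradient(loss, p.value)).max() < 1e-7


@pytest.mark.parametrize("mode", ["train", "eval"])
def test_batchnorm_backward_matches_finite_differences(mode):
    rng = np.random.default_rng(3)
    bn = BatchNorm1d(3)
    bn.momentum = 0.0  # freeze running stats so repeated forwards agree
    if mode == "eval":
        bn.running_mean = rng.normal(size=3)
        bn.running_var = rng.uniform(0.5, 2.0, size=3)
        bn.eval()
    x = rng.normal(size=(4, 3, 5))
    w = rng.normal(size=(4, 3, 5))

    def loss():
        return float((bn.forward(x) * w).sum())

    loss()
    bn.zero_grad()
    gx = bn.backward(w)
    assert np.abs(gx - numerical_gradient(loss, x)).max() < 1e-7
    assert np.abs(bn.gamma.grad - numerical_gradient(loss, bn.gamma.value)).max() < 1e-7
    assert np.abs(bn.beta.grad - numerical_gradient(loss, bn.beta.value)).max() < 1e-7


def test_linear_backward_matches_finite_differences():
    rng = np.random.default_rng(5)
    lin = Linear(6, 4, rng=rng)
    x = rng.normal(size=(3, 6))
    w = rng.normal(size=(3, 4))

    def loss():
        return float((lin.forward(x) * w).sum())

    loss()
    lin.zero_grad()
    gx = lin.backward(w)
    assert np.abs(gx - numerical_gradient(loss, x)).max() < 1e-7
    assert np.abs(lin.W.grad - numerical_gradient(loss, lin.W.value)).max() < 1e-7


class TestResidualUnit:
    def _zero_branch(self, block):
        for mod in (block.conv1, block.conv2):
            for p in mod.parameters():
                p.value[...] = 0.0
        for bn in (block.bn1, block.bn2):
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0
            bn.eps = 0.0

    def test_zero_branch_identity_on_nonnegative_input(self):
        block = BasicBlock(4, 4, stride=1).eval()
        self._zero_branch(block)
        x = np.abs(np.random.default_rng(0).normal(size=(2, 4, 8)))
        assert np.allclose(residual_unit_forward(x, block), x)

    def test_zero_branch_rectifies_negative_input(self):
        block = BasicBlock(4, 4, stride=1).eval()
        self._zero_branch(block)
        x = np.random.default_rng(1).normal(size=(2, 4, 8))
        assert np.allclose(residual_unit_forward(x, block), np.maximum(x, 0.0))

    def test_matches_independent_recomposition(self):
        """Brute-force oracle: re-compose conv/BN/shortcut/ReLU by hand."""
        rng = np.random.default_rng(7)
        block = BasicBlock(3, 6, stride=2, rng=rng).eval()
        for bn in (block.bn1, block.bn2, block.sc_bn):
            bn.running_mean = rng.normal(size=bn.channels)
            bn.running_var = rng.uniform(0.5, 2.0, size=bn.channels)
        x = rng.normal(size=(2, 3, 10))

        def conv(x, W, stride, pad):
            n, _, l = x.shape
            co, ci, k = W.shape
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
            lo = (l + 2 * pad - k) // stride + 1
            out = np.zeros((n, co, lo))
            for b in range(n):
                for o in range(co):
                    for t in range(lo):
                        acc = 0.0
                        for c in range(ci):
                            for j in range(k):
                                acc += xp[b, c, t * stride + j] * W[o, c, j]
                        out[b, o, t] = acc
            return out

        def bn(x, m):
            inv = 1 / np.sqrt(m.running_var + m.eps)
            return (
                m.gamma.value[None, :, None]
                * (x - m.running_mean[None, :, None])
                * inv[None, :, None]
                + m.beta.value[None, :, None]
            )

        branch = bn(conv(x, block.conv1.W.value, 2, 1), block.bn1)
        branch = np.maximum(branch, 0.0)
        branch = bn(conv(branch, block.conv2.W.value, 1, 1), block.bn2)
        shortcut = bn(conv(x, block.sc_conv.W.value, 2, 0), block.sc_bn)
        expected = np.maximum(branch + shortcut, 0.0)
        assert np.allclose(residual_unit_forward(x, block), expected, atol=1e-10)

    def test_shape_mismatch_without_shortcut_fails(self):
        block = BasicBlock(4, 8, stride=2, shortcut_mode="none").eval()
        x = np.random.default_rng(0).normal(size=(1, 4, 8))
        assert residual_unit_forward(x, block).shape == (1, 8, 4)
        with pytest.raises(ValueError):
            residual_unit_forward(np.zeros((1, 8, 8)), block)


class TestEca:
    def test_adaptive_kernel_sizes(self):
        assert eca_kernel_size(256) == 5
        assert eca_kernel_size(512) == 5
        assert eca_kernel_size(64) == 3

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            eca_kernel_size(100)

    def test_zero_input_maps_to_zero(self):
        eca = ECA(8, 3)
        assert np.allclose(eca.forward(np.zeros((2, 8, 6))), 0.0)

    def test_output_never_exceeds_input_magnitude(self):
        rng = np.random.default_rng(2)
        eca = ECA(16, 5, rng=rng)
        x = rng.normal(size=(3, 16, 7))
        out = eca.forward(x)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_zero_kernel_halves_input(self):
        eca = ECA(8, 3)
        eca.W.value[...] = 0.0
        x = np.random.default_rng(0).normal(size=(2, 8, 4))
        assert np.allclose(eca.forward(x), 0.5 * x)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ECA(8, 3).forward(np.zeros((1, 4, 6)))


class TestConvParamFormulas:
    @pytest.mark.parametrize(
        "args,std,sep",
        [((128, 256, 3), 98304, 33152), ((1, 1, 1), 1, 2), ((64, 64, 3), 12288, 4288),
         ((512, 512, 3), 786432, 263680)],
    )
    def test_printed_examples(self, args, std, sep):
        assert standard_conv_params(*args) == std
        assert separable_conv_params(*args) == sep

    def test_separable_always_cheaper_when_cout_exceeds_kernel(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ci = int(rng.integers(1, 600))
            co = int(rng.integers(4, 600))
            k = 3
            if co > k:
                assert separable_conv_params(ci, co, k) < standard_conv_params(ci, co, k)
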