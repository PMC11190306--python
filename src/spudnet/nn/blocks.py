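"""Residual building blocks: standard, depthwise-separable, and attended."""

from __future__ import annotations

import numpy as np

from .layers import (
    ECA,
    BatchNorm1d,
    Conv1d,
    DepthwiseConv1d,
    Module,
    ReLU,
)

__all__ = ["SeparableConv1d", "ZeroPadDownsample", "BasicBlock"]


class SeparableConv1d(Module):
    """Depthwise k-tap filter followed by a pointwise channel mixer.

    Parameter cost is c_in*k + c_in*c_out versus c_in*c_out*k for the
    standard convolution it replaces. An optional normalization between the
    two halves is exposed because implementations differ on it.
    """

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, depthwise_bn=False, rng=None):
        super().__init__()
        self.depthwise = self.register(
            DepthwiseConv1d(c_in, kernel, stride=stride, padding=padding, rng=rng)
        )
        self.mid_bn = (
            self.register(BatchNorm1d(c_in)) if depthwise_bn else None
        )
        self.pointwise = self.register(Conv1d(c_in, c_out, 1, rng=rng))

    def forward(self, x):
        out = self.depthwise(x)
        if self.mid_bn is not None:
            out = self.mid_bn(out)
        return self.pointwise(out)

    def backward(self, grad):
        grad = self.pointwise.backward(grad)
        if self.mid_bn is not None:
            grad = self.mid_bn.backward(grad)
        return self.depthwise.backward(grad)


class ZeroPadDownsample(Module):
    """Parameter-free shortcut: stride-subsample and zero-pad new channels."""

    def __init__(self, c_in, c_out, stride):
        super().__init__()
        if c_out < c_in:
            raise ValueError("zero-pad shortcut cannot shrink channels")
        self.c_in, self.c_out, self.stride = c_in, c_out, stride

    def forward(self, x):
        self._in_shape = x.shape
        sub = x[:, :, :: self.stride]
        n, _, l = sub.shape
        out = np.zeros((n, self.c_out, l), dtype=x.dtype)
        out[:, : self.c_in] = sub
        return out

    def backward(self, grad):
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, :: self.stride] = grad[:, : self.c_in]
        return dx


class BasicBlock(Module):
    """conv-BN-ReLU-conv-BN(-attention) plus shortcut, then ReLU.

    ``shortcut_mode`` applies only when the input shape differs from the
    output shape: 'projection' uses a kernel-1 convolution with
    normalization, 'zero_pad' a parameter-free subsample-and-pad identity,
    'none' drops the skip connection entirely. ``eca_placement`` puts the
    attention module either before ('pre_add', after the second
    normalization) or after ('post_add') the shortcut addition.
    """

    def __init__(
        self,
        c_in,
        c_out,
        stride=1,
        kernel=3,
        separable=False,
        depthwise_bn=False,
        eca_kernel=None,
        eca_placement="pre_add",
        shortcut_mode="projection",
        rng=None,
    ):
        super().__init__()
        pad = kernel // 2
        conv = (
            (lambda a, b, s: SeparableConv1d(a, b, kernel, stride=s, padding=pad,
                                             depthwise_bn=depthwise_bn, rng=rng))
            if separable
            else (lambda a, b, s: Conv1d(a, b, kernel, stride=s, padding=pad, rng=rng))
        )
        self.conv1 = self.register(conv(c_in, c_out, stride))
        self.bn1 = self.register(BatchNorm1d(c_out))
        self.relu1 = self.register(ReLU())
        self.conv2 = self.register(conv(c_out, c_out, 1))
        self.bn2 = self.register(BatchNorm1d(c_out))
        self.relu_out = self.register(ReLU())
        self.eca = None
        if eca_kernel is not None:
            self.eca = self.register(ECA(c_out, eca_kernel, rng=rng))
        if eca_placement not in ("pre_add", "post_add"):
            raise ValueError("eca_placement must be 'pre_add' or 'post_add'")
        self.eca_placement = eca_placement

        self.needs_shortcut = stride != 1 or c_in != c_out
        self.shortcut_mode = shortcut_mode if self.needs_shortcut else "identity"
        if self.shortcut_mode == "projection":
            self.sc_conv = self.register(Conv1d(c_in, c_out, 1, stride=stride, rng=rng))
            self.sc_bn = self.register(BatchNorm1d(c_out))
        elif self.shortcut_mode == "zero_pad":
            self.sc_pad = self.register(ZeroPadDownsample(c_in, c_out, stride))
        elif self.shortcut_mode not in ("identity", "none"):
            raise ValueError(f"unknown shortcut mode '{self.shortcut_mode}'")

    def forward(self, x):
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.eca is not None and self.eca_placement == "pre_add":
            out = self.eca(out)
        if self.shortcut_mode == "identity":
            sc = x
        elif self.shortcut_mode == "projection":
            sc = self.sc_bn(self.sc_conv(x))
        elif self.shortcut_mode == "zero_pad":
            sc = self.sc_pad(x)
        else:  # 'none'
            sc = 0.0
        y = self.relu_out(out + sc)
        if self.eca is not None and self.eca_placement == "post_add":
            y = self.eca(y)
        return y

    def backward(self, grad):
        if self.eca is not None and self.eca_placement == "post_add":
            grad = self.eca.backward(grad)
        grad = self.relu_out.backward(grad)
        # gradient splits between the residual branch and the shortcut
        if self.shortcut_mode == "identity":
            dsc = grad
        elif self.shortcut_mode == "projection":
            dsc = self.sc_conv.backward(self.sc_bn.backward(grad))
        elif self.shortcut_mode == "zero_pad":
            dsc = self.sc_pad.backward(grad)
        else:
            dsc = 0.0
        g = grad
        if self.eca is not None and self.eca_placement == "pre_add":
            g = self.eca.backward(g)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return g + dsc
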