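"""A single-convolution toy network used by saliency oracle tests."""

import numpy as np

from spudnet.nn import Conv1d, GlobalAvgPool1d, Linear, Module, ReLU
from spudnet.nn.layers import Sequential


class MiniNet(Module):
    """Single-convolution toy network exposing the saliency interface."""

    def __init__(self, channels=3, kernel=3, n_classes=2, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.named = [
            ("layer4", self.register(Sequential(
                Conv1d(1, channels, kernel, padding=kernel // 2, rng=rng), ReLU()))),
            ("avgpool", self.register(GlobalAvgPool1d())),
            ("fc", self.register(Linear(channels, n_classes, rng=rng))),
        ]
        self.activations = {}

    def forward(self, x):
        self.activations = {}
        for name, mod in self.named:
            x = mod.forward(x)
            self.activations[name] = x
        return x

    def backward_to(self, dlogits, upto=None):
        grad = dlogits
        for name, mod in reversed(self.named):
            if name == upto:
                return grad
            grad = mod.backward(grad)
        return grad
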