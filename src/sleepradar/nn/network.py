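"""Network assemblies: residual backbone, temporal convolution stack, variants.

The full classifier ("restcn") runs

    clone to 3 channels -> residual conv backbone (strides collapse the
    range axis, an early average pool shortens the temporal axis to ~15
    steps) -> mean over range -> 1x1 projection to a 1024-dim per-step
    embedding -> causal dilated TCN -> last time step -> linear to classes.

Variants: "resnet_only" replaces the TCN head with mean-over-time + linear;
"tcn_only" feeds the feature image directly to the TCN as a length-N_W
sequence of K1-dim vectors.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AvgPoolTime,
    BatchNorm,
    CausalConv1d,
    CloneChannels,
    Conv2d,
    Dropout,
    Linear,
    MeanOverRange,
    MeanOverTime,
    Module,
    ReLU,
    Sequential,
    TakeLastStep,
)


class _Residual(Module):
    """Shared residual wiring: relu(body(x) + skip(x))."""

    def __init__(self, body: Module, skip: Module | None) -> None:
        super().__init__()
        self.body = body
        self.skip = skip
        self.children = [body] + ([skip] if skip is not None else [])

    def forward(self, x):
        h = self.body.forward(x)
        s = self.skip.forward(x) if self.skip is not None else x
        self._pre = h + s
        return np.where(self._pre > 0, self._pre, 0.0).astype(np.float32)

    def backward(self, grad):
        grad = np.where(self._pre > 0, grad, 0.0).astype(np.float32)
        gskip = self.skip.backward(grad) if self.skip is not None else grad
        gbody = self.body.backward(grad)
        return (gbody + gskip).astype(np.float32)


class ResidualBlock2d(_Residual):
    """conv-bn-relu-conv-bn with an identity (or projected) skip connection."""

    def __init__(self, c_in: int, c_out: int, stride=(1, 1),
                 rng: np.random.Generator | None = None) -> None:
        body = Sequential(
            Conv2d(c_in, c_out, 3, stride, rng=rng),
            BatchNorm(c_out),
            ReLU(),
            Conv2d(c_out, c_out, 3, (1, 1), rng=rng),
            BatchNorm(c_out),
        )
        if stride != (1, 1) or c_in != c_out:
            skip = Sequential(Conv2d(c_in, c_out, 1, stride, rng=rng, pad=0),
                              BatchNorm(c_out))
        else:
            skip = None
        super().__init__(body, skip)


class TCNBlock(_Residual):
    """Two causal dilated convolutions with ReLU + dropout, residual skip."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator,
                 drop_rng: np.random.Generator) -> None:
        body = Sequential(
            CausalConv1d(c_in, c_out, kernel, dilation, rng=rng),
            ReLU(),
            Dropout(dropout, drop_rng),
            CausalConv1d(c_out, c_out, kernel, dilation, rng=rng),
            ReLU(),
            Dropout(dropout, drop_rng),
        )
        skip = CausalConv1d(c_in, c_out, 1, 1, rng=rng) if c_in != c_out else None
        super().__init__(body, skip)


def _make_tcn(c_in: int, channels, kernel: int, dilations, dropout: float,
              rng, drop_rng) -> Sequential:
    blocks = []
    prev = c_in
    for c, d in zip(channels, dilations):
        blocks.append(TCNBlock(prev, c, kernel, d, dropout, rng, drop_rng))
        prev = c
    return Sequential(*blocks)


def build_network(
    variant: str,
    input_shape: tuple[int, int],
    n_classes: int = 3,
    stage_channels=(16, 32, 64),
    embedding_dim: int = 1024,
    tcn_channels=(64, 64, 64),
    tcn_kernel: int = 3,
    tcn_dilations=(1, 2, 4),
    dropout: float = 0.1,
    seed: int = 0,
) -> Sequential:
    """Build a posture network for (K1, N_W)-shaped feature images.

    Two networks built with the same seed have identical initial weights.
    """
    k1, n_w = input_shape
    if len(tcn_channels) != len(tcn_dilations):
        raise ValueError("tcn_channels and tcn_dilations must have equal length")
    for a, b in zip(tcn_dilations, tcn_dilations[1:]):
        if b <= a:
            raise ValueError("tcn_dilations must be strictly increasing")
    for d in tcn_dilations:
        if d & (d - 1):
            raise ValueError("tcn_dilations must be powers of two")
    ss = np.random.SeedSequence(seed)
    rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    if variant == "tcn_only":
        # the image is read as a sequence of length N_W with K1 channels
        return Sequential(
            _make_tcn(k1, tcn_channels, tcn_kernel, tcn_dilations, dropout, rng, drop_rng),
            TakeLastStep(),
            Linear(tcn_channels[-1], n_classes, rng=rng),
        )

    pool = max(1, n_w // 15)  # shorten the temporal axis to ~15 embedding steps
    c0 = stage_channels[0]
    backbone = [
        AvgPoolTime(pool),
        CloneChannels(3),
        Conv2d(3, c0, 3, (2, 1), rng=rng),
        BatchNorm(c0),
        ReLU(),
        ResidualBlock2d(c0, c0, (2, 1), rng=rng),
    ]
    prev = c0
    for c in stage_channels[1:]:
        backbone.append(ResidualBlock2d(prev, c, (2, 1), rng=rng))
        prev = c
    bridge = [
        MeanOverRange(),
        CausalConv1d(prev, embedding_dim, 1, 1, rng=rng),
        ReLU(),
    ]

    if variant == "resnet_only":
        head = [MeanOverTime(), Linear(embedding_dim, n_classes, rng=rng)]
        return Sequential(*backbone, *bridge, *head)
    if variant == "restcn":
        return Sequential(
            *backbone,
            *bridge,
            _make_tcn(embedding_dim, tcn_channels, tcn_kernel, tcn_dilations,
                      dropout, rng, drop_rng),
            TakeLastStep(),
            Linear(tcn_channels[-1], n_classes, rng=rng),
        )
    raise ValueError(f"unknown variant {variant!r}; expected restcn, resnet_only or tcn_only")
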