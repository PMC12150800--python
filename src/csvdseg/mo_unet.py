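"""Multi-output U-shaped segmentation network (MO-UNet).

One shared encoder of stacked MBConv blocks (depthwise-separable + pointwise
convolutions, Swish activations, squeeze-excitation, residual connections
where shapes match) feeds, through a hard selection unit keyed on the input
sequence tag, four marker-specific decoders.  Each decoder upsamples with
transposed convolutions, merges encoder features at matching scales through
skip connections, applies a concurrent spatial-and-channel squeeze &
excitation (scSE) block per stage, and ends in a single-channel sigmoid
probability map at the input resolution.

The encoder can be pretrained as the encoder half of a reconstruction
autoencoder on unlabelled slices and its parameters transferred into the
segmentation model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor

MARKERS = ("WMH", "CMB", "lacune", "EPVS")

#: which decoders a given input sequence is routed to
DEFAULT_ROUTING = {
    "FLAIR": ("WMH", "lacune"),
    "SWI": ("CMB",),
    "T1": ("EPVS", "lacune"),
}


@dataclasses.dataclass
class NetworkConfig:
    input_size: int = 64
    encoder_stage_widths: tuple = (8, 16, 32)
    decoder_markers: tuple = MARKERS
    routing: dict = dataclasses.field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_ROUTING.items()})
    use_pretrained_encoder: bool = False
    expand_ratio: int = 2
    se_reduction: int = 2

    @property
    def n_stages(self) -> int:
        return len(self.encoder_stage_widths)

    def validate(self):
        if self.n_stages < 2:
            raise ValueError("need at least 2 encoder stages")
        if any(w <= 0 for w in self.encoder_stage_widths):
            raise ValueError("stage widths must be positive")
        routed = {m for ms in self.routing.values() for m in ms}
        missing = set(self.decoder_markers) - routed
        if missing:
            raise ValueError(f"markers never routed: {sorted(missing)}")
        if self.input_size % (2 ** self.n_stages):
            raise ValueError("input_size must be divisible by 2^n_stages")


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ChannelSE(nn.Module):
    """Channel squeeze-excitation: global pool -> bottleneck MLP -> gate."""

    def __init__(self, ch, reduction, rng):
        super().__init__()
        hidden = max(1, ch // reduction)
        self.fc1 = nn.Conv2d(ch, hidden, 1, rng=rng)
        self.fc2 = nn.Conv2d(hidden, ch, 1, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3), keepdims=True)
        return nn.sigmoid(self.fc2(nn.swish(self.fc1(z))))

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SpatialSE(nn.Module):
    """Spatial squeeze-excitation: 1x1 conv to a sigmoid saliency map."""

    def __init__(self, ch, rng):
        super().__init__()
        self.conv = nn.Conv2d(ch, 1, 1, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        return nn.sigmoid(self.conv(x))

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SCSE(nn.Module):
    """Concurrent scSE block: additive fusion of the two recalibrations."""

    def __init__(self, ch, reduction, rng):
        super().__init__()
        self.cse = ChannelSE(ch, reduction, rng)
        self.sse = SpatialSE(ch, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.cse(x) + self.sse(x)


class MBConv(nn.Module):
    """Mobile inverted residual bottleneck block.

    1x1 expansion -> depthwise 3x3 (optionally strided) -> channel SE ->
    1x1 projection, Swish activations and batch norm throughout, with a
    residual connection when input and output shapes match.
    """

    def __init__(self, in_ch, out_ch, stride=1, expand_ratio=2, se_reduction=2,
                 rng=None):
        super().__init__()
        mid = in_ch * expand_ratio
        self.expand = nn.Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.dw = nn.Conv2d(mid, mid, 3, stride=stride, padding=1, groups=mid,
                            bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.se = ChannelSE(mid, se_reduction, rng)
        self.project = nn.Conv2d(mid, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.residual = (stride == 1 and in_ch == out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        h = nn.swish(self.bn1(self.expand(x)))
        h = nn.swish(self.bn2(self.dw(h)))
        h = self.se(h)
        h = self.bn3(self.project(h))
        return h + x if self.residual else h


@dataclasses.dataclass
class EncoderOutput:
    bottleneck: Tensor
    skips: list               # full-resolution first, halving per stage


class Encoder(nn.Module):
    """Stem + stacked strided MBConv stages; exposes per-stage skip maps."""

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        config.validate()
        rng = rng or np.random.default_rng(0)
        w = config.encoder_stage_widths
        self.stem = nn.Conv2d(1, w[0], 3, padding=1, rng=rng)
        self.bn0 = nn.BatchNorm2d(w[0])
        self.stages = [
            MBConv(w[i - 1], w[i], stride=2, expand_ratio=config.expand_ratio,
                   se_reduction=config.se_reduction, rng=rng)
            for i in range(1, len(w))
        ]
        self.bottleneck = MBConv(w[-1], w[-1], stride=2,
                                 expand_ratio=config.expand_ratio,
                                 se_reduction=config.se_reduction, rng=rng)

    def __call__(self, x: Tensor) -> EncoderOutput:
        h = nn.swish(self.bn0(self.stem(x)))
        skips = [h]
        for stage in self.stages:
            h = stage(h)
            skips.append(h)
        return EncoderOutput(bottleneck=self.bottleneck(h), skips=skips)


class DecoderStage(nn.Module):
    def __init__(self, in_ch, skip_ch, se_reduction, rng):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_ch, skip_ch, stride=2, rng=rng)
        self.conv = nn.Conv2d(2 * skip_ch, skip_ch, 3, padding=1, bias=False,
                              rng=rng)
        self.bn = nn.BatchNorm2d(skip_ch)
        self.scse = SCSE(skip_ch, se_reduction, rng)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        h = nn.concat([self.up(x), skip], axis=1)
        h = nn.swish(self.bn(self.conv(h)))
        return self.scse(h)


class Decoder(nn.Module):
    """Marker-specific decoder: upsample, merge skips, scSE, sigmoid head."""

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = list(config.encoder_stage_widths)
        self.stages = []
        in_ch = w[-1]
        for skip_ch in reversed(w):
            self.stages.append(DecoderStage(in_ch, skip_ch,
                                            config.se_reduction, rng))
            in_ch = skip_ch
        self.head = nn.Conv2d(in_ch, 1, 1, rng=rng)

    def __call__(self, enc: EncoderOutput) -> Tensor:
        h = enc.bottleneck
        for stage, skip in zip(self.stages, reversed(enc.skips)):
            h = stage(h, skip)
        return nn.sigmoid(self.head(h))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class MOUNet(nn.Module):
    """Shared encoder + selection unit + four marker decoders."""

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        config.validate()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.encoder = Encoder(config, rng=rng)
        self.decoders = {m: Decoder(config, rng=rng)
                         for m in config.decoder_markers}

    def __call__(self, x: Tensor, sequence_tag: str) -> dict:
        if sequence_tag not in self.config.routing:
            raise KeyError(f"unknown sequence tag {sequence_tag!r}")
        enc = self.encoder(x)
        return {m: self.decoders[m](enc)
                for m in self.config.routing[sequence_tag]}


class AutoencoderDecoder(nn.Module):
    def __init__(self, config: NetworkConfig, rng):
        super().__init__()
        w = list(config.encoder_stage_widths)
        chain = [w[-1]] + list(reversed(w))
        self.ups, self.convs, self.bns = [], [], []
        for cin, cout in zip(chain[:-1], chain[1:]):
            self.ups.append(nn.ConvTranspose2d(cin, cout, stride=2, rng=rng))
            self.convs.append(nn.Conv2d(cout, cout, 3, padding=1, bias=False,
                                        rng=rng))
            self.bns.append(nn.BatchNorm2d(cout))
        self.head = nn.Conv2d(chain[-1], 1, 1, rng=rng)

    def __call__(self, h: Tensor) -> Tensor:
        for up, conv, bn in zip(self.ups, self.convs, self.bns):
            h = nn.swish(bn(conv(up(h))))
        return nn.sigmoid(self.head(h))


class Autoencoder(nn.Module):
    """Reconstruction autoencoder sharing the segmentation encoder design.

    The decoder recovers the input from the bottleneck via transposed
    convolutions; no skip connections, so the bottleneck must carry the
    information.
    """

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.encoder = Encoder(config, rng=rng)
        self.decoder = AutoencoderDecoder(config, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x).bottleneck)


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------

def build_encoder(config: NetworkConfig, seed: int = 0) -> Encoder:
    return Encoder(config, rng=np.random.default_rng(seed))


def build_mo_unet(config: NetworkConfig, pretrained_encoder: Encoder | None = None,
                  seed: int = 0) -> MOUNet:
    """Build the multi-output network, optionally loading encoder weights."""
    model = MOUNet(config, rng=np.random.default_rng(seed))
    if pretrained_encoder is not None:
        model.encoder.load_state_arrays(
            [a.copy() for a in pretrained_encoder.state_arrays()])
    return model


def _as_batch(images) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    return x


def pretrain_autoencoder(images, config: NetworkConfig, epochs: int = 10,
                         batch_size: int = 6, lr: float = 1e-3,
                         seed: int = 0):
    """Train the reconstruction autoencoder; return (encoder, loss history).

    ``images`` is an iterable of 2-D slices in [0, 1] (all sequences pooled).
    Aborts with diagnostics if the loss goes non-finite.
    """
    x_all = _as_batch(images)
    if len(x_all) < 1:
        raise ValueError("need at least one training image")
    rng = np.random.default_rng(seed)
    ae = Autoencoder(config, rng=rng)
    opt = nn.Adam(ae.parameters())
    losses = []
    for epoch in range(epochs):
        order = rng.permutation(len(x_all))
        epoch_loss = 0.0
        for start in range(0, len(x_all), batch_size):
            xb = Tensor(x_all[order[start:start + batch_size]])
            recon = ae(xb)
            diff = recon - xb
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {epoch}")
            ae.zero_grad()
            loss.backward()
            opt.step(lr)
            epoch_loss += float(loss.data) * len(xb.data)
        losses.append(epoch_loss / len(x_all))
    return ae.encoder, losses


def forward_route(model: MOUNet, batch, sequence_tag: str) -> dict:
    """Segment a batch of slices from one sequence; numpy in, numpy out.

    Returns probability maps only for the markers routed from this sequence;
    un-routed markers are absent from the result.  Runs in evaluation mode
    (deterministic: running normalisation statistics, no parameter updates).
    """
    x = _as_batch(batch)
    was_training = model.training
    model.eval()
    try:
        out = model(Tensor(x), sequence_tag)
    finally:
        model.train(was_training)
    return {m: t.data[:, 0] for m, t in out.items()}
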