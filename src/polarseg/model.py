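"""Inception-augmented U-net for polar-body segmentation.

The network is a contraction-expansion stack of nine inception modules
(I1..I9).  Each module feeds its input through four parallel branches —
a 1x1 convolution; a 1x1 then 3x3; a 1x1 then the factorised 1x3 + 3x1
pair; and a 3x3 same-padded max-pool followed by a 1x1 convolution — and
concatenates the branch outputs along channels.  The mixture of kernel
shapes lets one module respond to polar bodies of different sizes, which
a fixed 3x3 stack handles poorly.

I1..I4 each feed a 2x2 max-pool (encoder), I5 is the bottleneck, and
I6..I9 are each preceded by a 2x up-convolution whose output is
concatenated with the symmetric encoder module's output (skip
connection).  A 1x1 convolution plus sigmoid head turns the final feature
map into a per-pixel polar-body probability.  Channel widths follow the
usual U-net schedule: ``base_channels`` at I1, doubling at each encoder
level, halving back through the decoder.

Every convolution is followed by batch normalisation and a ReLU; weights
are He-uniform initialised from an explicit seed so builds are
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io import Micrograph

__all__ = [
    "InceptionModuleConfig",
    "NetworkConfig",
    "InceptionModule",
    "SegmentationNetwork",
    "build_inception_module",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class InceptionModuleConfig:
    in_channels: int
    branch_channels: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if len(self.branch_channels) != 4 or any(c < 1 for c in self.branch_channels):
            raise ValueError("branch_channels must be four counts >= 1")

    @property
    def out_channels(self) -> int:
        return sum(self.branch_channels)


@dataclass(frozen=True)
class NetworkConfig:
    """Configuration of the nine-module segmentation network.

    ``up_mode`` selects how the decoder restores resolution: a stride-2
    transposed convolution (default) or nearest-upsample + 3x3 convolution.
    """

    base_channels: int = 32
    up_mode: str = "transposed"  # or "upsample"
    seed: int = 0
    n_modules: int = 9
    #: prior foreground probability used to initialise the head bias; the
    #: polar body covers ~1% of a frame, and starting the sigmoid there
    #: instead of at 0.5 saves the first epochs of training
    head_prior: float = 0.01

    def __post_init__(self) -> None:
        if self.n_modules != 9:
            raise ValueError("the architecture is fixed at nine modules (I1..I9)")
        if self.base_channels < 4 or self.base_channels % 4:
            raise ValueError("base_channels must be a positive multiple of 4")
        if self.up_mode not in ("transposed", "upsample"):
            raise ValueError(f"unknown up_mode {self.up_mode!r}")
        if not 0.0 < self.head_prior < 1.0:
            raise ValueError("head_prior must lie in (0, 1)")

    def level_channels(self) -> list[int]:
        """Output widths of I1..I5 (the decoder mirrors them back down)."""
        return [self.base_channels * 2**level for level in range(5)]


def _conv_bn_relu(in_ch: int, out_ch: int, ksize, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, ksize, rng), nn.BatchNorm2d(out_ch, relu=True)
    )


class InceptionModule(nn.Module):
    """Four-branch inception block; output channels = sum of branch widths."""

    def __init__(self, cfg: InceptionModuleConfig, rng: np.random.Generator):
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.branch_channels
        ic = cfg.in_channels
        self.branch1 = _conv_bn_relu(ic, c1, 1, rng)
        self.branch2 = nn.Sequential(
            *_conv_bn_relu(ic, c2, 1, rng).layers, *_conv_bn_relu(c2, c2, 3, rng).layers
        )
        self.branch3 = nn.Sequential(
            *_conv_bn_relu(ic, c3, 1, rng).layers,
            *_conv_bn_relu(c3, c3, (1, 3), rng).layers,
            *_conv_bn_relu(c3, c3, (3, 1), rng).layers,
        )
        self.branch4 = nn.Sequential(nn.MaxPool3x3Same(), *_conv_bn_relu(ic, c4, 1, rng).layers)
        self._branches = [self.branch1, self.branch2, self.branch3, self.branch4]

    def children(self) -> list[nn.Module]:
        return list(self._branches)

    def parameters(self) -> list[nn.Parameter]:
        return [p for b in self._branches for p in b.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [b.forward(x) for b in self._branches]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        splits = np.cumsum(self.cfg.branch_channels)[:-1]
        grads = np.split(grad, splits, axis=-1)
        dx = self._branches[0].backward(np.ascontiguousarray(grads[0]))
        for b, g in zip(self._branches[1:], grads[1:]):
            dx = dx + b.backward(np.ascontiguousarray(g))
        return dx


def build_inception_module(cfg: InceptionModuleConfig, rng: np.random.Generator | int = 0) -> InceptionModule:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return InceptionModule(cfg, rng)


def _split4(channels: int) -> tuple[int, int, int, int]:
    q = channels // 4
    return (channels - 3 * q, q, q, q)


class SegmentationNetwork(nn.Module):
    """Nine-module encoder-decoder mapping a micrograph to a probability map."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.level_channels()  # I1..I5 outputs

        def inception(in_ch: int, out_ch: int) -> InceptionModule:
            return InceptionModule(InceptionModuleConfig(in_ch, _split4(out_ch)), rng)

        # encoder: I1..I4 + 2x2 pooling, bottleneck I5
        self.encoders = [inception(1 if i == 0 else widths[i - 1], widths[i]) for i in range(4)]
        self.pools = [nn.MaxPool2x2() for _ in range(4)]
        self.bottleneck = inception(widths[3], widths[4])

        # decoder: up-convolution, concat with symmetric encoder output, inception
        up_cls = nn.ConvTranspose2x2 if cfg.up_mode == "transposed" else nn.UpsampleConv2x
        self.upconvs = [up_cls(widths[4 - i], widths[3 - i], rng) for i in range(4)]
        self.decoders = [inception(2 * widths[3 - i], widths[3 - i]) for i in range(4)]

        self.head = nn.Conv2d(widths[0], 1, 1, rng)
        self.head.bias.value[:] = np.log(cfg.head_prior / (1.0 - cfg.head_prior))
        self.out_act = nn.Sigmoid()
        self._modules: list[nn.Module] = (
            self.encoders + self.pools + [self.bottleneck] + self.upconvs + self.decoders + [self.head, self.out_act]
        )

    # -- module plumbing ---------------------------------------------------
    def children(self) -> list[nn.Module]:
        return list(self._modules)

    def parameters(self) -> list[nn.Parameter]:
        return [p for m in self._modules for p in m.parameters()]

    # -- forward / backward ------------------------------------------------
    @staticmethod
    def _check_input(x: np.ndarray) -> None:
        h, w = x.shape[1], x.shape[2]
        if h % 16 or w % 16 or h < 16 or w < 16:
            raise ValueError(f"input height/width must be >= 16 and divisible by 16, got {(h, w)}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = [s.shape[-1] for s in skips]
        for up, dec, skip in zip(self.upconvs, self.decoders, reversed(skips)):
            x = up.forward(x)
            x = dec.forward(np.concatenate([skip, x], axis=-1))
        x = self.head.forward(x)
        return self.out_act.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.out_act.backward(grad)
        grad = self.head.backward(grad)
        # decoder i consumed skips[3 - i]; walking decoders last-to-first
        # therefore yields skip gradients in encoder order I1..I4
        skip_grads = []
        for up, dec, ch in zip(reversed(self.upconvs), reversed(self.decoders), self._skip_channels):
            g = dec.backward(grad)
            gs, gu = g[..., :ch], g[..., ch:]
            skip_grads.append(np.ascontiguousarray(gs))
            grad = up.backward(np.ascontiguousarray(gu))
        grad = self.bottleneck.backward(grad)
        for enc, pool, gs in zip(reversed(self.encoders), reversed(self.pools), reversed(skip_grads)):
            grad = pool.backward(grad)
            grad = enc.backward(grad + gs)
        return grad

    # -- inference convenience --------------------------------------------
    def predict(self, img: Micrograph) -> np.ndarray:
        """Probability map for a single micrograph (eval mode)."""
        was_training = self.training
        self.eval()
        out = self.forward(img.pixels[None, :, :, None].astype(np.float32))
        if was_training:
            self.train(True)
        return out[0, :, :, 0].astype(np.float64)

    # -- state -------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i:04d}"] = p.value
        for i, m in enumerate(self._iter_bn()):
            state[f"bn_{i:04d}_mean"] = m.running_mean
            state[f"bn_{i:04d}_var"] = m.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for i, p in enumerate(params):
            arr = state[f"param_{i:04d}"]
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint/config mismatch: parameter {i} has shape {arr.shape}, expected {p.value.shape}"
                )
            p.value = arr.astype(np.float32).copy()
        for i, m in enumerate(self._iter_bn()):
            m.running_mean = state[f"bn_{i:04d}_mean"].astype(np.float32).copy()
            m.running_var = state[f"bn_{i:04d}_var"].astype(np.float32).copy()

    def _iter_bn(self):
        def walk(mod: nn.Module):
            if isinstance(mod, nn.BatchNorm2d):
                yield mod
            for ch in mod.children():
                yield from walk(ch)

        for m in self._modules:
            yield from walk(m)


def build_network(cfg: NetworkConfig) -> SegmentationNetwork:
    return SegmentationNetwork(cfg)


def save_checkpoint(net: SegmentationNetwork, path: str | Path) -> None:
    """Save weights as .npz with a JSON sidecar recording the NetworkConfig."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.state_arrays())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(net.cfg), indent=2))


def load_checkpoint(path: str | Path) -> SegmentationNetwork:
    """Rebuild a network from a .npz checkpoint and its JSON sidecar."""
    path = Path(path)
    npz_path, sidecar = path.with_suffix(".npz"), path.with_suffix(".json")
    if not npz_path.exists():
        raise FileNotFoundError(f"no checkpoint at {npz_path}")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing config sidecar {sidecar}")
    cfg = NetworkConfig(**json.loads(sidecar.read_text()))
    net = SegmentationNetwork(cfg)
    with np.load(npz_path) as state:
        expected = set(net.state_arrays())
        if set(state.files) != expected:
            raise ValueError("checkpoint/config mismatch: state keys differ from architecture")
        net.load_state_arrays({k: state[k] for k in state.files})
    net.eval()
    return net
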