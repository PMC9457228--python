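"""The 2.5-dimensional CNN that classifies one ASPECTS region subvolume.

Architecture
------------
A *slice encoder* of seven 3-D convolutions whose kernels are 3x3x1 — i.e.
2-D convolutions applied independently per slice (channels 8, 8, 16, 16,
32, 32, 32; in-plane strides 1, 2, 1, 2, 1, 1, 2; in-plane padding 1,
through-plane padding 0; ReLU after each).  A *prediction aggregator*:
adaptive 3-D max pooling to a 4x4x20 grid followed by a 16-channel 1x1x20
convolution that collapses the slice axis.  A *classifier*: a 32-channel
4x4x1 convolution (a fully connected map over the pooled grid) with ReLU
and dropout 0.5, then a 1-channel 1x1x1 convolution and a sigmoid.

With the default configuration the stack has exactly 45,801 trainable
parameters.  Because all encoder kernels have through-plane extent 1 and
the pooling is adaptive, any slice count Z >= 1 is accepted; in-plane
dimensions must be at least 8 so that three stride-2 layers leave a
nonempty grid.

A *slice-level head* (global in-plane max pooling of the encoder's
32-channel slice features, then 32->32 ReLU -> 32->1 sigmoid) shares the
encoder and is used only during pre-training on slice-level labels.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import sigmoid
from .atlas import ASPECTSRegion

__all__ = ["ModelConfig", "RegionPrediction", "AspectsNet", "SliceHead",
           "build_model", "build_slice_head", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network stack (defaults are the reference
    architecture; change them only for toy experiments)."""

    encoder_channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32, 32)
    encoder_strides: tuple[int, ...] = (1, 2, 1, 2, 1, 1, 2)
    pool_target: tuple[int, int, int] = (4, 4, 20)
    aggregator_channels: int = 16
    classifier_hidden: int = 32
    dropout_p: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.encoder_channels) != len(self.encoder_strides):
            raise ValueError("encoder_channels and encoder_strides must have equal length")
        if any(c <= 0 for c in self.encoder_channels) or self.aggregator_channels <= 0 \
                or self.classifier_hidden <= 0:
            raise ValueError("channel counts must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if sum(s == 2 for s in self.encoder_strides) != 3:
            raise ValueError("encoder must contain exactly three stride-2 layers")

    @property
    def min_inplane(self) -> int:
        """Smallest legal in-plane dimension (2^#stride-2 layers)."""
        return 2 ** sum(s == 2 for s in self.encoder_strides)


@dataclass(frozen=True)
class RegionPrediction:
    """Per-region network output with the thresholded decision."""

    region: ASPECTSRegion
    probability: float
    threshold: float

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")

    @property
    def decision(self) -> bool:
        return self.probability >= self.threshold


class AspectsNet:
    """Encoder + aggregator + classifier; operates on ``(N, 1, H, W, Z)``
    arrays of normalized intensities."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.encoder = []
        c_in = 1
        for li, (c, s) in enumerate(zip(cfg.encoder_channels, cfg.encoder_strides)):
            self.encoder.append(_nn.ConvSlice2D(c_in, c, stride=s, rng=rng, name=f"enc{li}"))
            self.encoder.append(_nn.ReLU())
            c_in = c
        self.pool = _nn.AdaptiveMaxPool3D(cfg.pool_target)
        self.aggregator = _nn.DepthConv(c_in, cfg.aggregator_channels, cfg.pool_target[2],
                                        rng=rng, name="agg")
        self.cls_conv = _nn.DenseConv(cfg.aggregator_channels, cfg.classifier_hidden,
                                      cfg.pool_target[0], cfg.pool_target[1],
                                      rng=rng, name="cls")
        self.cls_relu = _nn.ReLU()
        self.dropout = _nn.Dropout(cfg.dropout_p)
        self.out = _nn.DenseConv(cfg.classifier_hidden, 1, 1, 1, rng=rng, name="out")
        self._layers = self.encoder + [self.pool, self.aggregator, self.cls_conv,
                                       self.cls_relu, self.dropout, self.out]

    # -- introspection -----------------------------------------------------
    def params(self) -> list[_nn.Param]:
        out = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    @property
    def n_encoder_convs(self) -> int:
        return sum(isinstance(l, _nn.ConvSlice2D) for l in self.encoder)

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W, Z) input, got shape {x.shape}")
        m = self.config.min_inplane
        if x.shape[2] < m or x.shape[3] < m:
            raise ValueError(
                f"in-plane dims {x.shape[2]}x{x.shape[3]} too small: the three stride-2 "
                f"encoder layers require at least {m}x{m}; pad the region crop first")
        if x.shape[4] < 1:
            raise ValueError("slice axis must be nonempty")
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        x = self._check_input(x)
        self.dropout.rng = rng
        h = x
        for layer in self._layers:
            h = layer.forward(h, training=training)
        return h[:, 0, 0, 0, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = np.asarray(dlogits)[:, None, None, None, None]
        for layer in reversed(self._layers):
            g = layer.backward(g)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode probabilities, one per input volume, each in (0, 1)."""
        return sigmoid(self.forward_logits(x, training=False))

    def predict_region(self, x: np.ndarray, region: ASPECTSRegion,
                       threshold: float | None = None) -> RegionPrediction:
        p = float(self.forward(x[None] if x.ndim == 4 else x)[0])
        return RegionPrediction(region, p, self.config.threshold if threshold is None else threshold)

    # -- encoder reuse -----------------------------------------------------
    def encode_slices(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        h = x
        for layer in self.encoder:
            h = layer.forward(h, training=training)
        return h

    def encoder_backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.encoder):
            g = layer.backward(g)

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {p.name: p for p in self.params()}
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"checkpoint/architecture mismatch; differing keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}")
            p.value[...] = arr


class SliceHead:
    """Per-slice classifier sharing the main model's encoder.

    Maps encoder slice features through global in-plane max pooling and a
    two-layer fully connected head (32 -> 32 ReLU -> 1 sigmoid), producing
    one probability per slice.
    """

    def __init__(self, model: AspectsNet):
        self.model = model
        cfg = model.config
        c = cfg.encoder_channels[-1]
        rng = np.random.default_rng(cfg.seed + 1)
        self.pool = _nn.GlobalSliceMaxPool()
        self.fc1 = _nn.Linear(c, c, rng=rng, name="slice_fc1")
        self.relu = _nn.ReLU()
        self.fc2 = _nn.Linear(c, 1, rng=rng, name="slice_fc2")

    def params(self) -> list[_nn.Param]:
        """Encoder parameters (shared) plus the head's own."""
        enc = [p for layer in self.model.encoder for p in layer.params()]
        return enc + self.fc1.params() + self.fc2.params()

    def head_params(self) -> list[_nn.Param]:
        return self.fc1.params() + self.fc2.params()

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feats = self.model.encode_slices(x, training=training)
        h = self.pool.forward(feats)                 # (N, Z, C)
        h = self.relu.forward(self.fc1.forward(h))
        return self.fc2.forward(h)[..., 0]           # (N, Z)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-slice probabilities, shape ``(N, Z)``."""
        return sigmoid(self.forward_logits(x, training=False))

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc2.backward(np.asarray(dlogits)[..., None])
        g = self.fc1.backward(self.relu.backward(g))
        g = self.pool.backward(g)
        self.model.encoder_backward(g)


def build_model(config: ModelConfig | None = None) -> AspectsNet:
    """Construct the network; raises on a configuration violating the
    architectural invariants."""
    return AspectsNet(config)


def build_slice_head(model: AspectsNet) -> SliceHead:
    """Attach the pre-training slice-level head to ``model``'s encoder."""
    return SliceHead(model)


def save_checkpoint(path, model: AspectsNet, extra: dict | None = None) -> None:
    """Single-file archive: config JSON + weight tensors (versioned)."""
    meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(model.config),
            "extra": extra or {}}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = io.BytesIO()
        np.savez(buf, **model.state_dict())
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> AspectsNet:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        cfg_d = meta["config"]
        for key in ("encoder_channels", "encoder_strides", "pool_target"):
            cfg_d[key] = tuple(cfg_d[key])
        model = AspectsNet(ModelConfig(**cfg_d))
        with zf.open("weights.npz") as fh:
            state = dict(np.load(io.BytesIO(fh.read())))
    model.load_state_dict(state)
    return model
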