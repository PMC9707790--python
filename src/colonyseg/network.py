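"""Encoder-decoder segmentation networks.

Both segmentation methods share a U-Net backbone: ``depth`` resolution
levels, two 3x3 convolution + batch-norm + ReLU layers per level, channel
doubling per level, 2x max-pool downsampling, stride-2 transposed-convolution
upsampling and skip concatenation.  The *boundary* method uses a single
decoder with a 3-class softmax head; the *distance* method uses two
independent decoders (cell distance and neighbor distance), each with a
linear single-channel head, sharing only the encoder.

When a parameter budget is given, the first-level filter count is walked
down the sequence 64 -> 48 -> 32 -> 24 -> 16 until the trainable-parameter
count fits the budget; 16 is the floor, which corresponds to roughly 2
million parameters for the single-decoder and 3 million for the
double-decoder network.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ModelSpec",
    "UNet",
    "build_model",
    "count_parameters",
    "forward",
    "percentile_normalize",
    "save_model",
    "load_model",
    "PARAM_FLOORS",
    "REDUCTION_SEQUENCE",
]

PARAM_FLOORS = {"boundary": 2_000_000, "distance": 3_000_000}
REDUCTION_SEQUENCE = (64, 48, 32, 24, 16)
FULL_DEPTH = 5
FULL_BASE_FILTERS = 64


def percentile_normalize(image: np.ndarray, low: float = 1.0, high: float = 99.0) -> np.ndarray:
    """Robust per-image intensity scaling: ``low`` percentile -> 0, ``high``
    percentile -> 1, clipped to [0, 1].  Polarity-agnostic input conditioning
    used in front of the network for both phase-contrast and fluorescence."""
    img = np.asarray(image, np.float32)
    lo, hi = np.percentile(img, [low, high])
    if hi <= lo:
        return np.zeros_like(img, np.float32)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


class _DecoderStage:
    def __init__(self, cin: int, cout: int, rng):
        self.up = nn.ConvTranspose2x(cin, cout, rng=rng)
        self.block = _conv_block(2 * cout, cout, rng)


def _conv_block(cin: int, cout: int, rng) -> list:
    return [
        nn.Conv2d(cin, cout, 3, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
        nn.Conv2d(cout, cout, 3, bias=False, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    ]


class UNet:
    """Manually wired U-Net with one or two decoders."""

    def __init__(self, method: str, depth: int = FULL_DEPTH, base_filters: int = FULL_BASE_FILTERS, seed: int = 0):
        if method not in ("boundary", "distance"):
            raise ValueError(f"unknown method {method!r}")
        rng = np.random.default_rng(seed)
        self.method = method
        self.depth = depth
        self.base_filters = base_filters
        self.n_decoders = 1 if method == "boundary" else 2
        chans = [base_filters * 2**i for i in range(depth)]
        self.enc_blocks = []
        cin = 1
        for c in chans:
            self.enc_blocks.append(_conv_block(cin, c, rng))
            cin = c
        self.pools = [nn.MaxPool2() for _ in range(depth - 1)]
        self.decoders = []
        self.heads = []
        out_ch = 3 if method == "boundary" else 1
        for _ in range(self.n_decoders):
            stages = [
                _DecoderStage(chans[i + 1], chans[i], rng)
                for i in reversed(range(depth - 1))
            ]
            self.decoders.append(stages)
            self.heads.append(nn.Conv2d(chans[0], out_ch, 1, bias=True, rng=rng))

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        for stages, head in zip(self.decoders, self.heads):
            for st in stages:
                yield st.up
                yield from st.block
            yield head

    @property
    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params]
        for layer in self._layers():
            if isinstance(layer, nn.BatchNorm2d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state length mismatch")
        for dst, src in zip(own, arrays):
            dst[...] = src

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Raw head outputs, one array (N, out_ch, H, W) per decoder."""
        x = np.ascontiguousarray(x, np.float32)
        if x.ndim == 3:
            x = x[:, None]
        div = 2 ** (self.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"spatial dims must be divisible by {div}, got {x.shape[2:]}")
        skips = []
        h = x
        for i, block in enumerate(self.enc_blocks):
            for layer in block:
                h = layer.forward(h, train)
            if i < self.depth - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        outputs = []
        self._dec_caches = []
        for stages, head in zip(self.decoders, self.heads):
            d = h
            for st, skip in zip(stages, reversed(skips)):
                d = st.up.forward(d, train)
                d = np.concatenate([skip, d], axis=1)
                for layer in st.block:
                    d = layer.forward(d, train)
            outputs.append(head.forward(d, train))
        self._n_skips = len(skips)
        return outputs

    def backward(self, grads: list[np.ndarray]) -> None:
        """Accumulate parameter gradients; ``grads`` matches forward output."""
        chans = [self.base_filters * 2**i for i in range(self.depth)]
        skip_grads = [None] * self._n_skips
        dbottom = None
        for stages, head, g in zip(self.decoders, self.heads, grads):
            d = head.backward(np.ascontiguousarray(g, np.float32))
            for si, st in reversed(list(enumerate(stages))):
                for layer in reversed(st.block):
                    d = layer.backward(d)
                c = st.up.weight.value.shape[1]
                skip_idx = self._n_skips - 1 - si
                gs, gd = d[:, :c], d[:, c:]
                if skip_grads[skip_idx] is None:
                    skip_grads[skip_idx] = gs.copy()
                else:
                    skip_grads[skip_idx] += gs
                d = st.up.backward(gd)
            dbottom = d if dbottom is None else dbottom + d
        h = dbottom
        for i in reversed(range(self.depth)):
            if i < self.depth - 1:
                h = self.pools[i].backward(h)
                h = h + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                h = layer.backward(h)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def finalize_bn(self) -> None:
        """Adopt precise batch-norm statistics for eval mode (see
        :meth:`colonyseg.nn.BatchNorm2d.finalize_epoch_stats`)."""
        for layer in self._layers():
            if isinstance(layer, nn.BatchNorm2d):
                layer.finalize_epoch_stats()


@dataclass
class ModelSpec:
    """Architecture description plus a handle to trained weights."""

    method: str
    depth: int
    base_filters: int
    decoders: int
    out_channels: int
    param_count: int
    net: UNet | None = None
    weights_ref: str | None = None
    train_meta: dict = field(default_factory=dict)
    best_params: dict | None = None  # post-processing thresholds after eval
    model_id: str = ""


def _count_block(cin: int, cout: int) -> int:
    return cin * cout * 9 + 2 * cout + cout * cout * 9 + 2 * cout


def config_param_count(method: str, depth: int = FULL_DEPTH, base_filters: int = FULL_BASE_FILTERS) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    chans = [base_filters * 2**i for i in range(depth)]
    n = 0
    cin = 1
    for c in chans:
        n += _count_block(cin, c)
        cin = c
    n_dec = 1 if method == "boundary" else 2
    out_ch = 3 if method == "boundary" else 1
    dec = 0
    for i in reversed(range(depth - 1)):
        dec += chans[i + 1] * chans[i] * 9 + chans[i]  # transposed conv + bias
        dec += _count_block(2 * chans[i], chans[i])
    dec += chans[0] * out_ch + out_ch  # 1x1 head
    return n + n_dec * dec


def build_model(
    method: str,
    budget: int | None = None,
    depth: int = FULL_DEPTH,
    seed: int = 0,
    model_id: str = "",
) -> ModelSpec:
    """Build a network, reducing the first-level filter count to fit
    ``budget`` trainable parameters (never below the base-16 floor)."""
    if method not in PARAM_FLOORS:
        raise ValueError(f"unknown method {method!r}")
    floor = PARAM_FLOORS[method]
    if budget is not None and budget < floor:
        raise ValueError(
            f"parameter budget {budget} is below the {method}-method floor of {floor}"
        )
    base = REDUCTION_SEQUENCE[0]
    if budget is not None:
        for cand in REDUCTION_SEQUENCE:
            base = cand
            if config_param_count(method, depth, cand) <= budget:
                break
    net = UNet(method, depth=depth, base_filters=base, seed=seed)
    count = net.param_count()
    assert count == config_param_count(method, depth, base)
    return ModelSpec(
        method=method,
        depth=depth,
        base_filters=base,
        decoders=net.n_decoders,
        out_channels=3 if method == "boundary" else 1,
        param_count=count,
        net=net,
        model_id=model_id or f"{method}_base{base}",
    )


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-scalar count of the built network."""
    if spec.net is None:
        raise ValueError("spec has no built network")
    return spec.net.param_count()


def forward(spec: ModelSpec, image_batch: np.ndarray) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Inference-mode prediction.

    boundary -> (N, 3, H, W) per-pixel class probabilities (softmax);
    distance -> tuple of (N, H, W) cell-distance and neighbor-distance maps.
    """
    if spec.net is None:
        raise ValueError("spec has no built network")
    outs = spec.net.forward(image_batch, train=False)
    if spec.method == "boundary":
        logits = outs[0]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    return outs[0][:, 0], outs[1][:, 0]


def save_model(spec: ModelSpec, path: str) -> str:
    """Serialize weights to ``<path>.npz`` with a ``<path>.json`` sidecar."""
    if spec.net is None:
        raise ValueError("spec has no built network")
    arrays = {f"arr_{i}": a for i, a in enumerate(spec.net.state_arrays())}
    np.savez_compressed(path + ".npz", **arrays)
    meta = {
        "method": spec.method,
        "depth": spec.depth,
        "base_filters": spec.base_filters,
        "decoders": spec.decoders,
        "out_channels": spec.out_channels,
        "param_count": spec.param_count,
        "train_meta": spec.train_meta,
        "best_params": spec.best_params,
        "model_id": spec.model_id,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
    spec.weights_ref = path + ".npz"
    return path + ".npz"


def load_model(path: str) -> ModelSpec:
    """Load a model saved by :func:`save_model` (path without extension)."""
    with open(path + ".json") as fh:
        meta = json.load(fh)
    net = UNet(meta["method"], depth=meta["depth"], base_filters=meta["base_filters"])
    data = np.load(path + ".npz")
    net.set_state([data[f"arr_{i}"] for i in range(len(data.files))])
    return ModelSpec(
        method=meta["method"],
        depth=meta["depth"],
        base_filters=meta["base_filters"],
        decoders=meta["decoders"],
        out_channels=meta["out_channels"],
        param_count=meta["param_count"],
        net=net,
        weights_ref=path + ".npz",
        train_meta=meta.get("train_meta", {}),
        best_params=meta.get("best_params"),
        model_id=meta.get("model_id", os.path.basename(path)),
    )
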