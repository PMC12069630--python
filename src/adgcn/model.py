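"""The ADGCN network.

Stacked first-order graph convolutions H^{l+1} = σ(BN(Â H^l W^l) + R(H^l))
over the renormalized operator Â, with a palindromic "U-shaped" width
schedule (default 16-32-64-128-64-32-16), per-layer residual connections
(identity when the width is unchanged, a learned projection otherwise),
batch normalization over the N graph nodes (batch size is one graph), a
squeeze-and-excitation channel-attention block after the first layer, and
a graph-convolutional softmax head.

Because widths are palindromic, encoder and decoder layers pair up; with
``long_skips`` on, each encoder output is added to its width-matched
mirror decoder output, passing fine-grained detail across the bottleneck
the way U-Net skip connections do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import BrainGraph

__all__ = [
    "ModelConfig",
    "LayerParams",
    "SEParams",
    "ModelParams",
    "PRESETS",
    "preset",
    "init_params",
    "n_parameters",
    "gcn_layer_forward",
    "se_forward",
    "model_forward",
    "predict_labels",
    "save_params",
    "load_params",
]

_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 6
    hidden_widths: tuple = (16, 32, 64, 128, 64, 32, 16)
    n_classes: int = 31
    se_enabled: bool = True
    se_ratio: int = 4
    se_position: int = 0
    dropout: float = 0.1
    long_skips: bool = True
    batch_norm: bool = True
    residual: bool = True

    def __post_init__(self):
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))
        w = self.hidden_widths
        if len(w) < 1 or any(c <= 0 for c in w):
            raise ValueError("hidden_widths must be positive")
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("bad channel/class counts")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.long_skips and w != w[::-1]:
            raise ValueError("hidden_widths must be palindromic when long_skips is on")
        if self.se_enabled:
            if not 0 <= self.se_position < len(w):
                raise ValueError("se_position out of range")
            if self.se_ratio < 1 or w[self.se_position] % self.se_ratio != 0:
                raise ValueError("se_ratio must divide the width at se_position")


# Table-style architecture presets: 1..7 hidden layers (widths climb to 128
# then shrink back), with and without the SE attention block.
def _widths(n_hidden: int) -> tuple:
    ladder = (16, 32, 64, 128, 64, 32, 16)
    return ladder[:n_hidden]


PRESETS = {
    "adgcn": ModelConfig(),  # 7 hidden layers + SE(r=4): the full model
    **{
        f"gcn_h{k}": ModelConfig(hidden_widths=_widths(k), se_enabled=False,
                                 long_skips=False)
        for k in range(1, 8)
    },
    "gcn_h7_skips": ModelConfig(se_enabled=False),
    **{
        f"adgcn_h1_r{r}": ModelConfig(hidden_widths=(16,), se_enabled=True,
                                      se_ratio=r, long_skips=False)
        for r in (2, 4, 8, 16)
    },
}


def preset(name: str) -> ModelConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset '{name}'; choices: {sorted(PRESETS)}") from None


@dataclass
class LayerParams:
    weight: np.ndarray                       # (C_in, C_out)
    bn_scale: np.ndarray
    bn_shift: np.ndarray
    bn_running_mean: np.ndarray
    bn_running_var: np.ndarray
    residual_projection: np.ndarray | None = None


@dataclass
class SEParams:
    reduce_weight: np.ndarray   # W1: (C/r, C)
    restore_weight: np.ndarray  # W2: (C, C/r)
    ratio: int = 4


@dataclass
class ModelParams:
    config: ModelConfig
    layers: list
    head_weight: np.ndarray
    se: SEParams | None = None
    extra: dict = field(default_factory=dict)

    def trainable(self):
        """Yield (name, array) for every trainable parameter."""
        for i, lp in enumerate(self.layers):
            yield f"layer{i}.weight", lp.weight
            if self.config.batch_norm:
                yield f"layer{i}.bn_scale", lp.bn_scale
                yield f"layer{i}.bn_shift", lp.bn_shift
            if lp.residual_projection is not None:
                yield f"layer{i}.proj", lp.residual_projection
        if self.se is not None:
            yield "se.w1", self.se.reduce_weight
            yield "se.w2", self.se.restore_weight
        yield "head.weight", self.head_weight

    def weight_matrices(self):
        """The matrices subject to L2 decay (batch-norm affines excluded)."""
        for name, arr in self.trainable():
            if "bn_" not in name:
                yield name, arr


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: ModelConfig, seed: int) -> ModelParams:
    """Deterministic variance-preserving initialization."""
    rng = np.random.default_rng(seed)
    layers = []
    c_in = config.in_channels
    for w in config.hidden_widths:
        proj = None
        if config.residual and c_in != w:
            proj = _glorot(rng, c_in, w)
        layers.append(LayerParams(
            weight=_glorot(rng, c_in, w),
            bn_scale=np.ones(w), bn_shift=np.zeros(w),
            bn_running_mean=np.zeros(w), bn_running_var=np.ones(w),
            residual_projection=proj,
        ))
        c_in = w
    se = None
    if config.se_enabled:
        c = config.hidden_widths[config.se_position]
        cr = c // config.se_ratio
        se = SEParams(_glorot(rng, cr, c), _glorot(rng, c, cr), config.se_ratio)
    head = _glorot(rng, c_in, config.n_classes)
    return ModelParams(config, layers, head, se)


def n_parameters(params: ModelParams) -> int:
    return sum(arr.size for _, arr in params.trainable())


# ---------------------------------------------------------------------------
# forward passes (tensor-level; public wrappers return plain arrays)
# ---------------------------------------------------------------------------

def _layer_forward_t(a_hat, h: Tensor, t: dict, i: int, lp: LayerParams,
                     config: ModelConfig, training: bool,
                     bn_momentum: float = 0.1) -> Tensor:
    pre = ad.spmm(a_hat, h) @ t[f"layer{i}.weight"]
    if config.batch_norm:
        if training:
            pre, mu, var = ad.batch_norm(pre, t[f"layer{i}.bn_scale"],
                                         t[f"layer{i}.bn_shift"])
            lp.bn_running_mean *= 1.0 - bn_momentum
            lp.bn_running_mean += bn_momentum * mu
            lp.bn_running_var *= 1.0 - bn_momentum
            lp.bn_running_var += bn_momentum * var
        else:
            pre = ad.batch_norm_inference(pre, t[f"layer{i}.bn_scale"],
                                          t[f"layer{i}.bn_shift"],
                                          lp.bn_running_mean, lp.bn_running_var)
    if config.residual:
        key = f"layer{i}.proj"
        pre = pre + (h @ t[key] if key in t else h)
    return ad.relu(pre)


def _se_forward_t(h: Tensor, t: dict) -> Tensor:
    z = ad.mean_rows(h)                             # squeeze: (C,)
    s = ad.sigmoid(t["se.w2"] @ ad.relu(t["se.w1"] @ z))  # excite: gates in (0,1)
    return h * s                                    # scale channels


def _model_forward_t(graph: BrainGraph, x, t: dict, params: ModelParams,
                     training: bool, rng: np.random.Generator | None) -> Tensor:
    config = params.config
    a_hat = graph.norm_operator
    h = ad.as_tensor(x)
    if h.data.shape != (graph.n_vertices, config.in_channels):
        raise ValueError("feature matrix shape does not match graph/config")
    drop = config.dropout if training else 0.0
    if drop > 0 and rng is None:
        raise ValueError("training-mode dropout requires an rng")
    n_hidden = len(config.hidden_widths)
    mid = (n_hidden - 1) // 2
    outs = []
    for i, lp in enumerate(params.layers):
        if drop > 0:
            h = ad.dropout(h, drop, rng)
        h = _layer_forward_t(a_hat, h, t, i, lp, config, training)
        if params.se is not None and i == config.se_position:
            h = _se_forward_t(h, t)
        if config.long_skips and i > mid:
            h = h + outs[n_hidden - 1 - i]  # width-matched mirror encoder output
        outs.append(h)
    if drop > 0:
        h = ad.dropout(h, drop, rng)
    logits = ad.spmm(a_hat, h) @ t["head.weight"]
    return ad.softmax_rows(logits)


def tensors_for(params: ModelParams, trainable: bool = True) -> dict:
    return {name: Tensor(arr, requires_grad=trainable)
            for name, arr in params.trainable()}


def gcn_layer_forward(a_hat, h: np.ndarray, lp: LayerParams,
                      training: bool = False, use_bn: bool = True,
                      use_residual: bool = True) -> np.ndarray:
    """One graph-convolution layer: σ(BN(Â H W) + R(H)) on plain arrays."""
    cfg = ModelConfig(in_channels=lp.weight.shape[0],
                      hidden_widths=(lp.weight.shape[1],), n_classes=2,
                      se_enabled=False, long_skips=False,
                      batch_norm=use_bn, residual=use_residual, dropout=0.0)
    t = {"layer0.weight": Tensor(lp.weight)}
    if use_bn:
        t["layer0.bn_scale"] = Tensor(lp.bn_scale)
        t["layer0.bn_shift"] = Tensor(lp.bn_shift)
    if use_residual and lp.residual_projection is not None:
        t["layer0.proj"] = Tensor(lp.residual_projection)
    return _layer_forward_t(a_hat, ad.as_tensor(np.asarray(h, dtype=np.float64)),
                            t, 0, lp, cfg, training).data


def se_forward(h: np.ndarray, se: SEParams) -> np.ndarray:
    """Squeeze-and-excitation on plain arrays: h_c -> s_c · h_c."""
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or se.reduce_weight.shape[1] != h.shape[1]:
        raise ValueError("channel count does not match SE parameters")
    t = {"se.w1": Tensor(se.reduce_weight), "se.w2": Tensor(se.restore_weight)}
    return _se_forward_t(ad.as_tensor(h), t).data


def model_forward(graph: BrainGraph, x: np.ndarray, params: ModelParams,
                  training: bool = False,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Full forward pass; returns the N×K row-stochastic probability matrix."""
    t = tensors_for(params, trainable=False)
    return _model_forward_t(graph, np.asarray(x, dtype=np.float64), t, params,
                            training, rng).data


def predict_labels(z: np.ndarray, tol: float = 1e-5) -> np.ndarray:
    """Per-vertex argmax of a probability matrix; ties -> lowest class."""
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 2 or np.any(z < -tol) or np.any(np.abs(z.sum(axis=1) - 1) > tol):
        raise ValueError("not a probability matrix")
    return np.argmax(z, axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    arrays = {name: arr for name, arr in params.trainable()}
    for i, lp in enumerate(params.layers):
        arrays[f"layer{i}.bn_running_mean"] = lp.bn_running_mean
        arrays[f"layer{i}.bn_running_var"] = lp.bn_running_var
    cfg = params.config.__dict__.copy()
    cfg["hidden_widths"] = list(cfg["hidden_widths"])
    meta = {"version": _ARCHIVE_VERSION, "config": cfg, "extra": params.extra}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_params(path, expect_config: ModelConfig | None = None) -> ModelParams:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("version") != _ARCHIVE_VERSION:
            raise ValueError("unsupported model archive version")
        cfg_dict = meta["config"]
        cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        config = ModelConfig(**cfg_dict)
        if expect_config is not None and config != expect_config:
            raise ValueError("model archive config does not match expected config")
        params = init_params(config, seed=0)
        for name, arr in params.trainable():
            arr[...] = npz[name]
        for i, lp in enumerate(params.layers):
            lp.bn_running_mean[...] = npz[f"layer{i}.bn_running_mean"]
            lp.bn_running_var[...] = npz[f"layer{i}.bn_running_var"]
        params.extra = meta.get("extra", {})
    return params
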