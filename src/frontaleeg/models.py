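"""The three network architectures.

Hybrid fusion model: three parallel branches over the FeatureBundle triple.
The raw branch is a three-block Conv1D stack (kernels 11/7/5, pool 4 after
each block, batch norm, dropout) that reduces a 3840-sample window
3840 -> 960 -> 240 -> 60, flattens, and projects to a raw embedding.  The
map branch consumes the 3x8 per-channel feature matrix as a length-8
sequence with 3 channels (two Conv1D layers, kernel 3, pool 2, global
average pooling, 128-unit embedding).  The global branch is a 64-32 MLP on
the 17-dim vector.  Embeddings are concatenated (192+128+32 = 352 with the
selected configuration), batch-normalized, and classified by a dense head
with softmax over {HC, MDD}.

Baselines: Conv1D-raw (64/128/256 filters, fixed dropout schedule) and
Conv1D-SE, which inserts a squeeze-and-excitation gate (r=8) after each
convolution.  All conv/dense layers carry L2 weight regularization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nnet
from .nnet import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool1D,
    MaxPool1D,
    SEBlock,
    Sequential,
    softmax,
    weighted_softmax_xent,
)

RAW_KERNELS = (11, 7, 5)
RAW_POOL = 4
MAP_KERNEL = 3
MAP_POOL = 2
MAP_EMB = 128
GLOB_HIDDEN = (64, 32)
RAW_EMB_DROP = 0.5
HEAD_DROP = 0.5  # fusion-head dropout; unstated upstream, matches raw-emb dropout
N_CLASSES = 2


@dataclass(frozen=True)
class HybridConfig:
    """Tunable hyperparameters of the fusion network.

    Defaults are the selected configuration (refinement Trial 4).
    """

    emb_raw: int = 192
    head_units: int = 384
    lr_init: float = 5e-4
    map_drop: float = 0.35
    map_filters: tuple[int, int] = (48, 96)
    raw_drop: tuple[float, float, float] = (0.3, 0.4, 0.5)
    raw_filters: tuple[int, int, int] = (96, 192, 256)
    wd: float = 1e-4

    def __post_init__(self) -> None:
        drops = (self.map_drop, *self.raw_drop)
        if any(not 0.0 <= d < 1.0 for d in drops):
            raise ValueError("dropout rates must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelSpec:
    """Symbolic layer list with output shapes and parameter counts."""

    layers: list = field(default_factory=list)
    total_params: int = 0

    def add(self, name: str, kind: str, shape, params: int) -> None:
        self.layers.append(
            {"name": name, "type": kind, "output_shape": tuple(shape), "params": params}
        )
        self.total_params += params

    def to_json(self) -> str:
        return json.dumps(
            {"layers": self.layers, "total_params": self.total_params}, indent=2
        )


class ConfigurationError(ValueError):
    pass


class _BaseModel:
    """Shared prediction/serialization plumbing for the engine models."""

    branches: dict  # name -> Sequential

    def all_layers(self):
        out = []
        for seq in self.branches.values():
            out.extend(seq.layers)
        return out

    def l2_loss(self) -> float:
        return sum(seq.l2_loss() for seq in self.branches.values())

    @property
    def param_count(self) -> int:
        return sum(seq.param_count for seq in self.branches.values())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.all_layers():
            for key in sorted(layer.params):
                out.append(layer.params[key].copy())
            if isinstance(layer, BatchNorm):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.all_layers():
            for key in sorted(layer.params):
                layer.params[key][...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez_compressed(
            path, *self.get_weights(), config=json.dumps(self._config_dict())
        )
        return path

    def load(self, path: str | Path) -> None:
        with np.load(Path(path), allow_pickle=False) as data:
            arrays = [data[k] for k in data.files if k.startswith("arr_")]
        self.set_weights(arrays)

    def _config_dict(self) -> dict:
        return {}


class HybridModel(_BaseModel):
    """Three-branch fusion network operating on (raw, map, glob) inputs."""

    def __init__(self, cfg: HybridConfig, L: int, seed: int = 42):
        self.cfg = cfg
        self.L = L
        rng = np.random.default_rng(seed)
        wd = cfg.wd
        f = cfg.raw_filters
        d = cfg.raw_drop
        t_out = L // RAW_POOL**3
        raw_layers: list = []
        in_ch = 3
        for i in range(3):
            raw_layers += [
                Conv1D(in_ch, f[i], RAW_KERNELS[i], l2=wd, rng=rng, name=f"raw_conv{i+1}"),
                MaxPool1D(RAW_POOL, name=f"raw_pool{i+1}"),
                BatchNorm(f[i], name=f"raw_bn{i+1}"),
                Dropout(d[i], name=f"raw_drop{i+1}"),
            ]
            in_ch = f[i]
        raw_layers += [
            Flatten(name="raw_flatten"),
            Dense(t_out * f[2], cfg.emb_raw, l2=wd, activation="relu", rng=rng,
                  name="raw_emb"),
            Dropout(RAW_EMB_DROP, name="raw_emb_drop"),
        ]
        m = cfg.map_filters
        map_layers = [
            Conv1D(3, m[0], MAP_KERNEL, l2=wd, rng=rng, name="map_conv1"),
            MaxPool1D(MAP_POOL, name="map_pool"),
            Conv1D(m[0], m[1], MAP_KERNEL, l2=wd, rng=rng, name="map_conv2"),
            BatchNorm(m[1], name="map_bn"),
            Dropout(cfg.map_drop, name="map_drop1"),
            GlobalAvgPool1D(name="map_gap"),
            Dense(m[1], MAP_EMB, l2=wd, activation="relu", rng=rng, name="map_emb"),
            Dropout(cfg.map_drop, name="map_drop2"),
        ]
        glob_layers = [
            Dense(17, GLOB_HIDDEN[0], l2=wd, activation="relu", rng=rng, name="glob_fc1"),
            Dense(GLOB_HIDDEN[0], GLOB_HIDDEN[1], l2=wd, activation="relu", rng=rng,
                  name="glob_fc2"),
        ]
        self.concat_dim = cfg.emb_raw + MAP_EMB + GLOB_HIDDEN[1]
        head_layers = [
            BatchNorm(self.concat_dim, name="fusion_bn"),
            Dense(self.concat_dim, cfg.head_units, l2=wd, activation="relu", rng=rng,
                  name="fusion_fc"),
            Dropout(HEAD_DROP, name="fusion_drop"),
            Dense(cfg.head_units, N_CLASSES, l2=wd, rng=rng, name="output"),
        ]
        self.branches = {
            "raw": Sequential(raw_layers),
            "map": Sequential(map_layers),
            "glob": Sequential(glob_layers),
            "head": Sequential(head_layers),
        }

    @staticmethod
    def prepare_inputs(raw, maps, glob):
        """Orient inputs for the network: the 3x8 map becomes an 8x3 sequence."""
        return (
            np.asarray(raw, dtype=nnet.DTYPE),
            np.asarray(maps, dtype=nnet.DTYPE).transpose(0, 2, 1),
            np.asarray(glob, dtype=nnet.DTYPE),
        )

    def forward(self, inputs, training=False, rng=None):
        raw, map_seq, glob = inputs
        e_raw = self.branches["raw"].forward(raw, training, rng)
        e_map = self.branches["map"].forward(map_seq, training, rng)
        e_glob = self.branches["glob"].forward(glob, training, rng)
        self._splits = (e_raw.shape[1], e_map.shape[1])
        z = np.concatenate([e_raw, e_map, e_glob], axis=1)
        return self.branches["head"].forward(z, training, rng)

    def backward(self, g_logits):
        gz = self.branches["head"].backward(g_logits)
        a, b = self._splits
        self.branches["raw"].backward(gz[:, :a])
        self.branches["map"].backward(gz[:, a : a + b])
        self.branches["glob"].backward(gz[:, a + b :])

    def predict_proba(self, raw, maps, glob, batch_size: int = 256) -> np.ndarray:
        inputs = self.prepare_inputs(raw, maps, glob)
        out = []
        for i in range(0, inputs[0].shape[0], batch_size):
            batch = tuple(x[i : i + batch_size] for x in inputs)
            out.append(softmax(self.forward(batch, training=False)))
        return np.concatenate(out) if out else np.zeros((0, 2))

    def _config_dict(self) -> dict:
        return {"kind": "hybrid", "L": self.L, **self.cfg.to_dict()}


class Conv1DModel(_BaseModel):
    """Single-input sequential Conv1D classifier (the two raw baselines)."""

    def __init__(self, layers: list, L: int, kind: str, lr_init: float):
        self.branches = {"net": Sequential(layers)}
        self.L = L
        self.kind = kind
        self.lr_init = lr_init

    def forward(self, inputs, training=False, rng=None):
        (x,) = inputs if isinstance(inputs, tuple) else (inputs,)
        return self.branches["net"].forward(
            np.asarray(x, dtype=nnet.DTYPE), training, rng
        )

    def backward(self, g_logits):
        self.branches["net"].backward(g_logits)

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=nnet.DTYPE)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out) if out else np.zeros((0, 2))

    def _config_dict(self) -> dict:
        return {"kind": self.kind, "L": self.L}


def _spec_from_chain(model, L: int, input_desc: list) -> ModelSpec:
    spec = ModelSpec()
    for name, kind, shape in input_desc:
        spec.add(name, kind, shape, 0)
    for seq_name, seq in model.branches.items():
        for layer in seq.layers:
            spec.add(layer.name or seq_name, type(layer).__name__, (), layer.param_count)
    return spec


def build_hybrid(cfg: HybridConfig, L: int = 3840, seed: int = 42
                 ) -> tuple[ModelSpec, HybridModel]:
    """Construct the hybrid fusion model for windows of L samples.

    L must be divisible by 4^3 = 64 so the three pool-4 stages land on an
    integer temporal length without padding (3840 -> 960 -> 240 -> 60).
    """
    if L % RAW_POOL**3 != 0:
        raise ConfigurationError(
            f"window length {L} is not divisible by {RAW_POOL**3} "
            f"(three max-pool stages of size {RAW_POOL})"
        )
    model = HybridModel(cfg, L, seed=seed)
    spec = ModelSpec()
    t = L
    f = cfg.raw_filters
    spec.add("raw_input", "Input", (L, 3), 0)
    for i in range(3):
        in_ch = 3 if i == 0 else f[i - 1]
        spec.add(f"raw_conv{i+1}", "Conv1D", (t, f[i]), (RAW_KERNELS[i] * in_ch + 1) * f[i])
        t //= RAW_POOL
        spec.add(f"raw_pool{i+1}", "MaxPool1D", (t, f[i]), 0)
        spec.add(f"raw_bn{i+1}", "BatchNorm", (t, f[i]), 2 * f[i])
        spec.add(f"raw_drop{i+1}", "Dropout", (t, f[i]), 0)
    spec.add("raw_flatten", "Flatten", (t * f[2],), 0)
    spec.add("raw_emb", "Dense", (cfg.emb_raw,), (t * f[2] + 1) * cfg.emb_raw)
    m = cfg.map_filters
    spec.add("map_input", "Input", (8, 3), 0)
    spec.add("map_conv1", "Conv1D", (8, m[0]), (MAP_KERNEL * 3 + 1) * m[0])
    spec.add("map_pool", "MaxPool1D", (4, m[0]), 0)
    spec.add("map_conv2", "Conv1D", (4, m[1]), (MAP_KERNEL * m[0] + 1) * m[1])
    spec.add("map_bn", "BatchNorm", (4, m[1]), 2 * m[1])
    spec.add("map_gap", "GlobalAvgPool1D", (m[1],), 0)
    spec.add("map_emb", "Dense", (MAP_EMB,), (m[1] + 1) * MAP_EMB)
    spec.add("glob_input", "Input", (17,), 0)
    spec.add("glob_fc1", "Dense", (GLOB_HIDDEN[0],), (17 + 1) * GLOB_HIDDEN[0])
    spec.add("glob_fc2", "Dense", (GLOB_HIDDEN[1],), (GLOB_HIDDEN[0] + 1) * GLOB_HIDDEN[1])
    spec.add("concat", "Concatenate", (model.concat_dim,), 0)
    spec.add("fusion_bn", "BatchNorm", (model.concat_dim,), 2 * model.concat_dim)
    spec.add("fusion_fc", "Dense", (cfg.head_units,), (model.concat_dim + 1) * cfg.head_units)
    spec.add("output", "Dense", (N_CLASSES,), (cfg.head_units + 1) * N_CLASSES)
    assert spec.total_params == model.param_count
    return spec, model


BASELINE_FILTERS = (64, 128, 256)
BASELINE_DROPS = (0.25, 0.35, 0.45)
BASELINE_WD = 5e-5
CONV1D_RAW_DEFAULT_L = 2560  # 10.24 s at 250 Hz
CONV1D_SE_DEFAULT_L = 6000  # 24 s at 250 Hz


def _conv_backbone(rng: np.random.Generator, se: bool) -> tuple[list, int]:
    layers: list = []
    in_ch = 3
    for i, filt in enumerate(BASELINE_FILTERS):
        layers.append(
            Conv1D(in_ch, filt, RAW_KERNELS[i], l2=BASELINE_WD, rng=rng,
                   name=f"conv{i+1}")
        )
        if se:
            layers.append(SEBlock(filt, r=8, rng=rng, name=f"se{i+1}"))
        layers += [
            MaxPool1D(RAW_POOL, name=f"pool{i+1}"),
            BatchNorm(filt, name=f"bn{i+1}"),
            Dropout(BASELINE_DROPS[i], name=f"drop{i+1}"),
        ]
        in_ch = filt
    return layers, in_ch


def _finish_baseline(layers: list, L: int, rng, kind: str, lr: float) -> Conv1DModel:
    t = L
    for _ in range(3):
        t //= RAW_POOL
    layers += [
        Flatten(name="flatten"),
        Dense(t * BASELINE_FILTERS[-1], 256, l2=BASELINE_WD, activation="relu",
              rng=rng, name="fc"),
        Dropout(0.5, name="fc_drop"),
        Dense(256, N_CLASSES, l2=BASELINE_WD, rng=rng, name="output"),
    ]
    return Conv1DModel(layers, L, kind, lr)


def build_conv1d_raw(L: int = CONV1D_RAW_DEFAULT_L, seed: int = 42
                     ) -> tuple[ModelSpec, Conv1DModel]:
    """Plain Conv1D baseline (Adam lr 8e-4; no augmentation by protocol)."""
    if L < 64:
        raise ConfigurationError("window too short for three pool-4 stages")
    rng = np.random.default_rng(seed)
    layers, _ = _conv_backbone(rng, se=False)
    model = _finish_baseline(layers, L, rng, "conv1d_raw", lr=8e-4)
    return _seq_spec(model), model


def build_conv1d_se(L: int = CONV1D_SE_DEFAULT_L, seed: int = 42
                    ) -> tuple[ModelSpec, Conv1DModel]:
    """Conv1D baseline with SE channel attention after each conv (Adam lr 1e-3)."""
    if L < 64:
        raise ConfigurationError("window too short for three pool-4 stages")
    rng = np.random.default_rng(seed)
    layers, _ = _conv_backbone(rng, se=True)
    model = _finish_baseline(layers, L, rng, "conv1d_se", lr=1e-3)
    return _seq_spec(model), model


def _seq_spec(model: Conv1DModel) -> ModelSpec:
    spec = ModelSpec()
    spec.add("input", "Input", (model.L, 3), 0)
    t = model.L
    for layer in model.branches["net"].layers:
        if isinstance(layer, MaxPool1D):
            t //= layer.pool
            spec.add(layer.name, "MaxPool1D", (t, None), 0)
        else:
            spec.add(layer.name, type(layer).__name__, (t, None), layer.param_count)
    spec.total_params = model.param_count
    return spec


def make_optimizer(model, lr: float | None = None) -> Adam:
    lr = lr if lr is not None else getattr(model, "lr_init", None) or (
        model.cfg.lr_init if isinstance(model, HybridModel) else 1e-3
    )
    return Adam(lr=lr)


__all__ = [
    "HybridConfig",
    "ModelSpec",
    "ConfigurationError",
    "HybridModel",
    "Conv1DModel",
    "build_hybrid",
    "build_conv1d_raw",
    "build_conv1d_se",
    "make_optimizer",
    "weighted_softmax_xent",
]
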