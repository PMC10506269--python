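"""Full network assembly, training objective and parameter audit.

Architecture: three parallel-branch concatenated layers with max pooling
after the first two, then flatten -> dropout -> dense(ReLU) -> dropout ->
sigmoid output head.  The output is multi-label: one sigmoid per class,
trained with summed binary cross-entropy.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .cac_layers import CACLayerConfig, PoolConfig

__all__ = [
    "ModelConfig",
    "Model",
    "build_model",
    "bce_loss",
    "count_parameters",
    "parameter_count_formula",
    "save_model",
    "load_model",
]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the whole network.

    Pooling is applied after every feature layer except the last, which for
    the default three layers means after layers 1 and 2 only.
    """

    input_length: int
    n_classes: int
    cac_layers: tuple[CACLayerConfig, ...]
    pool: PoolConfig = PoolConfig()
    fc_hidden: int = 512
    dropout_feature: float = 0.2
    dropout_fc: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "cac_layers", tuple(self.cac_layers))
        if self.input_length < 1 or self.n_classes < 1:
            raise ValueError("input_length and n_classes must be >= 1")
        if not self.cac_layers:
            raise ValueError("need at least one feature layer")
        if not (0.0 <= self.dropout_feature < 1.0 and 0.0 <= self.dropout_fc < 1.0):
            raise ValueError("dropout rates must be in [0, 1)")
        d_in = 4
        for idx, layer in enumerate(self.cac_layers):
            if layer.input_channels != d_in:
                raise ValueError(
                    f"layer {idx} expects {layer.input_channels} input channels, "
                    f"but receives {d_in}"
                )
            d_in = layer.D
        self.stage_lengths()  # raises if pooling exhausts the sequence

    @classmethod
    def default(
        cls,
        input_length: int = 1000,
        n_classes: int = 12,
        D: int = 192,
        i: int = 3,
        n_layers: int = 3,
        n_heads: int = 8,
        kernel_sizes: tuple[int, ...] = (7, 11, 19),
        fc_hidden: int = 512,
        d_v: int | None = None,
        dropout_feature: float = 0.2,
        dropout_fc: float = 0.5,
    ) -> "ModelConfig":
        layers = []
        d_in = 4
        for _ in range(n_layers):
            layers.append(
                CACLayerConfig.default(
                    D=D, i=i, input_channels=d_in, n_heads=n_heads,
                    kernel_sizes=kernel_sizes, d_v=d_v,
                )
            )
            d_in = D
        return cls(
            input_length=input_length,
            n_classes=n_classes,
            cac_layers=tuple(layers),
            fc_hidden=fc_hidden,
            dropout_feature=dropout_feature,
            dropout_fc=dropout_fc,
        )

    def stage_lengths(self) -> list[int]:
        """Sequence length after each feature layer (pooling included)."""
        lengths = []
        length = self.input_length
        n = len(self.cac_layers)
        for idx in range(n):
            if idx < n - 1:  # pool after all but the last feature layer
                length = self.pool.output_length(length)
            lengths.append(length)
        return lengths

    @property
    def flattened_width(self) -> int:
        return self.stage_lengths()[-1] * self.cac_layers[-1].D

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "n_classes": self.n_classes,
            "pool": {"size": self.pool.size, "stride": self.pool.stride},
            "fc_hidden": self.fc_hidden,
            "dropout_feature": self.dropout_feature,
            "dropout_fc": self.dropout_fc,
            "cac_layers": [
                {
                    "D": layer.D,
                    "activation": layer.activation,
                    "branches": [dataclasses.asdict(br) for br in layer.branches],
                }
                for layer in self.cac_layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        from .cac_layers import AAConvConfig

        layers = tuple(
            CACLayerConfig(
                D=ld["D"],
                activation=ld.get("activation", "relu"),
                branches=tuple(AAConvConfig(**br) for br in ld["branches"]),
            )
            for ld in d["cac_layers"]
        )
        return cls(
            input_length=d["input_length"],
            n_classes=d["n_classes"],
            cac_layers=layers,
            pool=PoolConfig(**d.get("pool", {})),
            fc_hidden=d.get("fc_hidden", 512),
            dropout_feature=d.get("dropout_feature", 0.2),
            dropout_fc=d.get("dropout_fc", 0.5),
        )


def _build_cac_layer(layer_cfg: CACLayerConfig, rng: np.random.Generator) -> nn.Layer:
    act = nn.ACTIVATIONS[layer_cfg.activation]
    branches: list[nn.Layer] = []
    for br in layer_cfg.branches:
        inner = nn.Concat([
            nn.Conv1dSame(br.kernel_size, br.input_channels, br.d_conv, rng=rng),
            nn.MultiHeadSelfAttention(br.input_channels, br.n_heads, br.d_head, rng=rng),
        ])
        branches.append(nn.Sequential([inner, act()]))
    return nn.Concat(branches)


class Model:
    """The assembled network: feature layers plus the sigmoid output head."""

    def __init__(self, cfg: ModelConfig, seed: int) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        n = len(cfg.cac_layers)
        for idx, layer_cfg in enumerate(cfg.cac_layers):
            layers.append(_build_cac_layer(layer_cfg, rng))
            if idx < n - 1:
                layers.append(nn.MaxPool1d(cfg.pool.size, cfg.pool.stride))
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(cfg.dropout_feature))
        layers.append(nn.Dense(cfg.flattened_width, cfg.fc_hidden, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(cfg.dropout_fc))
        layers.append(nn.Dense(cfg.fc_hidden, cfg.n_classes, rng=rng))
        self.net = nn.Sequential(layers)

    @property
    def params(self) -> list[np.ndarray]:
        return self.net.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.net.grads

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def logits(self, x: np.ndarray, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        return self.net.forward(x, train=train, rng=rng)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-class probabilities in (0, 1), shape ``(B, C)``."""
        z = self.logits(x, train=train, rng=rng)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode probabilities, batched to bound memory."""
        x = np.asarray(x, dtype=np.float64)
        outs = [
            self.forward(x[s:s + batch_size])
            for s in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def backward_from_logits(self, glogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output-head logits."""
        self.net.backward(glogits)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError(
                f"expected {len(self.params)} weight arrays, got {len(weights)}"
            )
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    """Deterministically initialise the network under ``seed``."""
    return Model(cfg, seed)


def bce_loss(pred: np.ndarray, y: np.ndarray, clamp: float = 1e-12) -> float:
    """Summed binary cross-entropy over all (sample, class) cells.

    ``zeta = -sum[y log p + (1 - y) log(1 - p)]`` with probabilities clamped
    to ``[clamp, 1 - clamp]`` before the logs.
    """
    pred = np.asarray(pred, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if pred.shape != y.shape:
        raise ValueError(f"pred shape {pred.shape} != label shape {y.shape}")
    p = np.clip(pred, clamp, 1.0 - clamp)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def count_parameters(model: Model) -> int:
    """Trainable scalar count by framework introspection."""
    return sum(p.size for p in model.params)


def parameter_count_formula(cfg: ModelConfig) -> int:
    """Closed-form parameter count; must equal :func:`count_parameters`.

    Per branch: convolution ``k * D_in * d_conv + d_conv`` plus attention
    ``D_in * (2 * d_k_total + d_v) + d_v**2`` (q/k/v projections and the
    output mix, all bias-free), summed over branches and layers, plus the
    two dense layers of the classifier head.
    """
    total = 0
    for layer in cfg.cac_layers:
        for br in layer.branches:
            d_in = br.input_channels
            total += br.kernel_size * d_in * br.d_conv + br.d_conv
            d_k_total = br.n_heads * br.d_head
            total += d_in * (2 * d_k_total + br.d_v) + br.d_v ** 2
    f = cfg.flattened_width
    total += f * cfg.fc_hidden + cfg.fc_hidden
    total += cfg.fc_hidden * cfg.n_classes + cfg.n_classes
    return total


def save_model(path: str | Path, model: Model) -> None:
    """Checkpoint weights + config + seed to an ``.npz`` container."""
    payload = {f"param_{i}": p for i, p in enumerate(model.params)}
    payload["config_json"] = np.asarray(json.dumps(model.cfg.to_dict()))
    payload["seed"] = np.asarray(model.seed)
    np.savez_compressed(path, **payload)


def load_model(path: str | Path) -> Model:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_dict(json.loads(str(z["config_json"])))
        model = build_model(cfg, seed=int(z["seed"]))
        weights = [z[f"param_{i}"] for i in range(len(model.params))]
    model.set_weights(weights)
    return model
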